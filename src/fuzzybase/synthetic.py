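"""Synthetic per-base trace features and supervised training files.

The real trace-derived sample files this package was designed around are
not distributable, so this module fabricates statistically similar ones:
500-record files of normalized per-base features in [0, 1], where "clean"
bases have a well-formed, tall called peak and a weak runner-up, and
"problem" bases have an elevated runner-up (sometimes exceeding the called
peak) and perturbed spacing.  Supervised targets come from smooth monotone
reference functions, one per trainable system.

Everything is reproducible from a single seed; the per-file records and
spacing chain share one stream derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .pipeline import BaseCallRecord
from .training import SampleSet

_BASES = np.array(list("ACGT"))

#: location/scale multipliers (relative to noise_sd) of each feature draw,
#: per record class; "folded" features are 1 - |Normal(0, k * noise_sd)|
_CLEAN = {
    "np_called": ("folded", 2.0),
    "np_2nd": ("truncnorm", 0.4, 3.0),
    "nh_called": ("folded", 3.0),
    "nh_2nd": ("truncnorm", 0.5, 3.0),
}
_PROBLEM = {
    "np_called": ("truncnorm", 0.75, 3.0),
    "np_2nd": ("truncnorm", 0.8, 3.0),
    "nh_called": ("truncnorm", 0.65, 3.0),
    "nh_2nd": ("truncnorm", 0.6, 3.0),
}
_FEATURES = ("np_called", "np_2nd", "nh_called", "nh_2nd")

#: spacing jitter of ordinary gaps, and extra jitter of gaps that follow a
#: problem base (relative to noise_sd for the latter)
_SPACING_SD = 0.02
_PROBLEM_SPACING_EXTRA = 1.5


@dataclass
class GeneratorConfig:
    n_records: int = 500
    seed: int = 0
    clean_fraction: float = 0.7
    noise_sd: float = 0.03
    nominal_spacing: float = 0.3

    def __post_init__(self):
        if self.n_records < 10:
            raise ConfigurationError(f"n_records must be >= 10, got {self.n_records}")
        if not 0.0 <= self.clean_fraction <= 1.0:
            raise ConfigurationError(
                f"clean_fraction must be in [0, 1], got {self.clean_fraction}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 < self.nominal_spacing < 1.0:
            raise ConfigurationError(
                f"nominal_spacing must be in (0, 1), got {self.nominal_spacing}"
            )


def _default_f_p(np_called, np_2nd):
    return np.clip(np_called * (1.0 - 0.6 * np.asarray(np_2nd) ** 2), 0.0, 1.0)


def _default_f_h(nh_called, nh_2nd):
    return np.clip(nh_called * (1.0 - 0.6 * np.asarray(nh_2nd) ** 2), 0.0, 1.0)


#: width of the spacing reference's Gaussian bump; wide enough that a
#: 5-MF-per-input grid can recover the function to held-out RMSE <= 0.05
_SPACING_BANDWIDTH = 0.25


def make_default_f_s(nominal_spacing: float = 0.3) -> Callable:
    """Symmetric spacing score peaking where both gaps equal the nominal one."""

    def f_s(dns_next, dns_prev):
        d1 = np.asarray(dns_next) - nominal_spacing
        d2 = np.asarray(dns_prev) - nominal_spacing
        return np.exp(-(d1**2 + d2**2) / (2.0 * _SPACING_BANDWIDTH**2))

    return f_s


def _default_f_c(nc_p, nc_h, nc_ds):
    return np.clip(
        np.sqrt(np.asarray(nc_p) * np.asarray(nc_h)) * (0.7 + 0.3 * np.asarray(nc_ds)),
        0.0,
        1.0,
    )


@dataclass
class ReferenceFunctions:
    """Smooth monotone targets supervising the four trainable systems.

    ``f_p``/``f_h`` increase in the called-peak feature and decrease in the
    runner-up feature; ``f_s`` is symmetric with its maximum at the nominal
    spacing; ``f_c`` increases in every feature score.
    """

    f_p: Callable = _default_f_p
    f_h: Callable = _default_f_h
    f_s: Callable = field(default_factory=make_default_f_s)
    f_c: Callable = _default_f_c

    @classmethod
    def for_config(cls, cfg: GeneratorConfig) -> "ReferenceFunctions":
        return cls(f_s=make_default_f_s(cfg.nominal_spacing))


def _draw(rng, spec, sd, size):
    """One feature column; degenerate (sd == 0) draws collapse to the mean."""
    if spec[0] == "folded":
        scale = spec[1] * sd
        if scale == 0:
            return np.ones(size)
        return np.clip(1.0 - np.abs(rng.normal(0.0, scale, size)), 0.0, 1.0)
    _, loc, k = spec
    scale = k * sd
    if scale == 0:
        return np.full(size, loc)
    a, b = (0.0 - loc) / scale, (1.0 - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _mean(spec, sd) -> float:
    """Closed-form mean of one feature draw (folded normal / truncated normal)."""
    if spec[0] == "folded":
        scale = spec[1] * sd
        return 1.0 - scale * np.sqrt(2.0 / np.pi)
    _, loc, k = spec
    scale = k * sd
    if scale == 0:
        return loc
    a, b = (0.0 - loc) / scale, (1.0 - loc) / scale
    return float(stats.truncnorm.mean(a, b, loc=loc, scale=scale))


def expected_feature_means(cfg: GeneratorConfig) -> dict:
    """Population means of the generated feature columns (mixture closed forms).

    Spacing columns are symmetric around the nominal spacing up to the [0, 1]
    truncation, which the truncated-normal mean accounts for exactly.
    """
    cf = cfg.clean_fraction
    out = {}
    for name in _FEATURES:
        out[name] = cf * _mean(_CLEAN[name], cfg.noise_sd) + (1 - cf) * _mean(
            _PROBLEM[name], cfg.noise_sd
        )
    loc = cfg.nominal_spacing

    def gap_mean(scale):
        if scale == 0:
            return loc
        a, b = (0.0 - loc) / scale, (1.0 - loc) / scale
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=scale))

    problem_scale = _SPACING_SD + _PROBLEM_SPACING_EXTRA * cfg.noise_sd
    spacing = cf * gap_mean(_SPACING_SD) + (1 - cf) * gap_mean(problem_scale)
    out["dns_next"] = spacing
    out["dns_prev"] = spacing
    return out


def generate_records(cfg: GeneratorConfig) -> list:
    """Simulate one contiguous read of ``cfg.n_records`` called bases.

    Consecutive records share their boundary gap, so ``dns_prev`` of record
    *i* equals ``dns_next`` of record *i - 1* exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_records
    clean = rng.random(n) < cfg.clean_fraction
    cols = {}
    for name in _FEATURES:
        col = np.empty(n)
        col[clean] = _draw(rng, _CLEAN[name], cfg.noise_sd, int(clean.sum()))
        col[~clean] = _draw(rng, _PROBLEM[name], cfg.noise_sd, int((~clean).sum()))
        cols[name] = col

    # gap i sits before record i; gap i+1 (after record i) widens its jitter
    # when record i is a problem base
    gap_sd = np.full(n + 1, _SPACING_SD)
    gap_sd[1:][~clean] = _SPACING_SD + _PROBLEM_SPACING_EXTRA * cfg.noise_sd
    loc = cfg.nominal_spacing
    gaps = np.empty(n + 1)
    for scale in np.unique(gap_sd):
        m = gap_sd == scale
        if scale == 0:
            gaps[m] = loc
        else:
            a, b = (0.0 - loc) / scale, (1.0 - loc) / scale
            gaps[m] = stats.truncnorm.rvs(
                a, b, loc=loc, scale=scale, size=int(m.sum()), random_state=rng
            )
    bases = rng.choice(_BASES, n)

    return [
        BaseCallRecord(
            base=str(bases[i]),
            np_called=float(cols["np_called"][i]),
            np_2nd=float(cols["np_2nd"][i]),
            nh_called=float(cols["nh_called"][i]),
            nh_2nd=float(cols["nh_2nd"][i]),
            dns_next=float(gaps[i + 1]),
            dns_prev=float(gaps[i]),
        )
        for i in range(n)
    ]


def make_training_files(cfg: GeneratorConfig, ref: ReferenceFunctions | None = None):
    """Four supervised sample sets: one per subsystem plus the main system.

    Files 1-3 pair each record's relevant feature duo with its reference
    score; file 4 pairs the (peakness, height, spacing) score triple with
    the reference confidence.
    """
    if ref is None:
        ref = ReferenceFunctions.for_config(cfg)
    records = generate_records(cfg)
    npc = np.array([r.np_called for r in records])
    np2 = np.array([r.np_2nd for r in records])
    nhc = np.array([r.nh_called for r in records])
    nh2 = np.array([r.nh_2nd for r in records])
    dnn = np.array([r.dns_next for r in records])
    dnp = np.array([r.dns_prev for r in records])

    nc_p = ref.f_p(npc, np2)
    nc_h = ref.f_h(nhc, nh2)
    nc_s = ref.f_s(dnn, dnp)
    nc_o = ref.f_c(nc_p, nc_h, nc_s)

    return {
        "peakness": SampleSet(np.column_stack([npc, np2]), nc_p, name="peakness"),
        "height": SampleSet(np.column_stack([nhc, nh2]), nc_h, name="height"),
        "spacing": SampleSet(np.column_stack([dnn, dnp]), nc_s, name="spacing"),
        "confidence": SampleSet(
            np.column_stack([nc_p, nc_h, nc_s]), nc_o, name="confidence"
        ),
    }
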