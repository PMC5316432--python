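"""Cascaded per-base confidence model.

Three two-input feature subsystems — peakness (triangular MFs), height
(two-sided-Gaussian MFs) and spacing (trapezoidal MFs) — score a called
base's trace features; their outputs feed a three-input main system
(two-sided-Gaussian MFs) that produces the final confidence in [0, 1].
Every system uses 5 membership functions per input and a full-factorial
rule base with constant consequents.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import NotFittedError, ValidationError
from .fis import SugenoFIS, grid_partition, make_variable
from .training import SampleSet, TrainingConfig, evaluate, split, train

BASES = ("A", "C", "G", "T")

#: per-system layout: input names and membership-function family
SYSTEM_SPECS = {
    "peakness": (("NP_called", "NP_2nd"), "triangular"),
    "height": (("NH_called", "NH_2nd"), "gauss2"),
    "spacing": (("dNS_next", "dNS_prev"), "trapezoidal"),
    "confidence": (("NC_P", "NC_H", "NC_dS"), "gauss2"),
}
SYSTEM_NAMES = tuple(SYSTEM_SPECS)

_MODEL_FORMAT = "fuzzybase-model/1"


def _check_unit(name, value):
    v = float(value)
    if not np.isfinite(v) or not 0.0 <= v <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")
    return v


@dataclass(frozen=True)
class BaseCallRecord:
    """Six normalized trace features of one called base."""

    base: str
    np_called: float
    np_2nd: float
    nh_called: float
    nh_2nd: float
    dns_next: float
    dns_prev: float

    def __post_init__(self):
        if self.base not in BASES:
            raise ValidationError(f"base must be one of {BASES}, got {self.base!r}")
        for name in (
            "np_called",
            "np_2nd",
            "nh_called",
            "nh_2nd",
            "dns_next",
            "dns_prev",
        ):
            object.__setattr__(self, name, _check_unit(name, getattr(self, name)))


@dataclass(frozen=True)
class FeatureVector:
    """Subsystem outputs: peakness, height and spacing scores."""

    nc_p: float
    nc_h: float
    nc_ds: float

    def __post_init__(self):
        for name in ("nc_p", "nc_h", "nc_ds"):
            object.__setattr__(self, name, _check_unit(name, getattr(self, name)))


@dataclass(frozen=True)
class ConfidenceResult:
    base: str
    features: FeatureVector
    nc_o: float


def build_system(name: str, n_mfs: int = 5, consequent: float = 0.5) -> SugenoFIS:
    """Fresh grid-partitioned FIS for one of the four named systems."""
    if name not in SYSTEM_SPECS:
        raise ValidationError(f"unknown system {name!r}")
    input_names, family = SYSTEM_SPECS[name]
    variables = [
        make_variable(v, domain=(0.0, 1.0), n_mfs=n_mfs, family=family)
        for v in input_names
    ]
    return grid_partition(variables, consequent=consequent)


class PipelineModel:
    """The four Sugeno systems plus training provenance.

    A freshly built model carries untrained structure; scoring before
    :func:`fit_pipeline` (or loading a trained bundle) raises
    :class:`~fuzzybase.errors.NotFittedError`.
    """

    def __init__(self, systems: dict, fitted: bool = False, provenance: dict | None = None):
        missing = [n for n in SYSTEM_NAMES if n not in systems]
        if missing:
            raise ValidationError(f"model is missing systems: {missing}")
        self.systems = {n: systems[n] for n in SYSTEM_NAMES}
        self.fitted = fitted
        self.provenance = provenance or {}

    @classmethod
    def build(cls, n_mfs: int = 5) -> "PipelineModel":
        return cls({name: build_system(name, n_mfs) for name in SYSTEM_NAMES})

    # -- scoring -----------------------------------------------------------

    def _fis(self, name: str) -> SugenoFIS:
        if not self.fitted:
            raise NotFittedError(
                f"cannot score with an untrained model (system {name!r}); "
                "call fit_pipeline or load a trained bundle first"
            )
        return self.systems[name]

    def _score(self, name: str, x) -> float:
        # trained consequents may drift marginally outside [0, 1]; scores are
        # clipped back to the unit interval at the pipeline surface
        return float(np.clip(self._fis(name).infer(x), 0.0, 1.0))

    def score_peakness(self, np_called: float, np_2nd: float) -> float:
        return self._score("peakness", [np_called, np_2nd])

    def score_height(self, nh_called: float, nh_2nd: float) -> float:
        return self._score("height", [nh_called, nh_2nd])

    def score_spacing(self, dns_next: float, dns_prev: float) -> float:
        return self._score("spacing", [dns_next, dns_prev])

    def score_confidence(self, fv: FeatureVector) -> float:
        return self._score("confidence", [fv.nc_p, fv.nc_h, fv.nc_ds])

    def call_record(self, record: BaseCallRecord) -> ConfidenceResult:
        fv = FeatureVector(
            nc_p=self.score_peakness(record.np_called, record.np_2nd),
            nc_h=self.score_height(record.nh_called, record.nh_2nd),
            nc_ds=self.score_spacing(record.dns_next, record.dns_prev),
        )
        return ConfidenceResult(base=record.base, features=fv, nc_o=self.score_confidence(fv))

    def call_sequence(self, records) -> list:
        """Score each record independently, preserving order."""
        out = []
        for i, rec in enumerate(records):
            if not isinstance(rec, BaseCallRecord):
                raise ValidationError(f"row {i}: not a BaseCallRecord")
            out.append(self.call_record(rec))
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": _MODEL_FORMAT,
            "fitted": self.fitted,
            "systems": {n: fis.to_dict() for n, fis in self.systems.items()},
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineModel":
        if doc.get("format") != _MODEL_FORMAT:
            raise ValidationError(f"unrecognized model format {doc.get('format')!r}")
        systems = {n: SugenoFIS.from_dict(d) for n, d in doc["systems"].items()}
        return cls(systems, fitted=doc.get("fitted", False), provenance=doc.get("provenance", {}))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def config_digest(cfg: TrainingConfig) -> str:
    """Stable hash of a training configuration, recorded in provenance."""
    blob = json.dumps(vars(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def fit_pipeline(
    train_files: dict,
    cfg: TrainingConfig | None = None,
    n_train: int = 350,
    split_mode: str = "contiguous",
    n_mfs: int = 5,
) -> PipelineModel:
    """Train all four systems from their sample files.

    ``train_files`` maps system name -> :class:`SampleSet` with the system's
    input columns plus one target column.  Each file is divided into
    ``n_train`` training rows and the remainder for testing; consequents are
    initialized at the midpoint of the training targets' range.
    """
    cfg = cfg or TrainingConfig()
    missing = [n for n in SYSTEM_NAMES if n not in train_files]
    if missing:
        raise ValidationError(f"missing training files for: {missing}")

    systems = {}
    provenance = {"config": vars(cfg).copy(), "config_digest": config_digest(cfg), "systems": {}}
    for name in SYSTEM_NAMES:
        samples = train_files[name]
        expected_dim = len(SYSTEM_SPECS[name][0])
        if samples.n_inputs != expected_dim:
            raise ValidationError(
                f"file {samples.name or name!r}: expected {expected_dim} input "
                f"columns for system {name!r}, got {samples.n_inputs}"
            )
        tr, te = split(samples, n_train, mode=split_mode, seed=cfg.seed)
        mid = 0.5 * float(tr.y.min() + tr.y.max()) if len(tr) else 0.5
        fis = build_system(name, n_mfs=n_mfs, consequent=mid)
        run = train(fis, tr, cfg)
        run.test_rmse = evaluate(run.fis, te)
        systems[name] = run.fis
        provenance["systems"][name] = {
            "n_train": len(tr),
            "n_test": len(te),
            "final_train_rmse": run.train_rmse_by_epoch[-1],
            "test_rmse": run.test_rmse,
        }
    return PipelineModel(systems, fitted=True, provenance=provenance)
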