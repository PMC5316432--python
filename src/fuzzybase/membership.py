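"""Parameterized unimodal fuzzy membership functions on a real interval.

Three families are supported:

``triangular``
    params ``(a, b, c)`` with ``a <= b <= c``: feet at *a* and *c*, apex at
    *b*.  Degree is ``max(min((x-a)/(b-a), (c-x)/(c-b)), 0)``.

``trapezoidal``
    params ``(a, b, c, d)`` with ``a <= b <= c <= d``: feet at *a*/*d*,
    shoulders at *b*/*c*.  Degree is ``max(min((x-a)/(b-a), 1, (d-x)/(d-c)), 0)``.

``gauss2``
    params ``(sigma1, c1, sigma2, c2)`` with ``sigma1, sigma2 > 0`` and
    ``c1 <= c2``: a plateau of degree 1 on ``[c1, c2]`` with Gaussian flanks
    ``exp(-(x-c1)^2 / (2 sigma1^2))`` on the left and the analogous form on
    the right.

All families map the whole real line into ``[0, 1]`` and are continuous.
Every function also exposes the analytic gradient of the degree with
respect to its parameters, which the trainer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

FAMILIES = ("triangular", "trapezoidal", "gauss2")

#: minimal separation enforced between ordered breakpoints during projection
_MIN_GAP = 1e-6
#: lower bound on Gaussian flank widths during projection
_MIN_SIGMA = 1e-3


def _validate_params(family: str, params: tuple) -> None:
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown membership family {family!r}")
    p = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ConfigurationError(f"{family} params must be finite, got {params}")
    if family == "triangular":
        if p.shape != (3,) or not (p[0] <= p[1] <= p[2]):
            raise ConfigurationError(
                f"triangular needs (a <= b <= c), got {params}"
            )
    elif family == "trapezoidal":
        if p.shape != (4,) or not (p[0] <= p[1] <= p[2] <= p[3]):
            raise ConfigurationError(
                f"trapezoidal needs (a <= b <= c <= d), got {params}"
            )
    else:  # gauss2
        if p.shape != (4,) or p[0] <= 0 or p[2] <= 0 or p[1] > p[3]:
            raise ConfigurationError(
                f"gauss2 needs (sigma1 > 0, c1, sigma2 > 0, c2) with c1 <= c2, "
                f"got {params}"
            )


@dataclass(frozen=True)
class MembershipFunction:
    """One fuzzy set: a family name plus its ordered parameter tuple."""

    family: str
    params: tuple

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        _validate_params(self.family, self.params)

    @property
    def center(self) -> float:
        """Location of the (midpoint of the) region of full membership."""
        p = self.params
        if self.family == "triangular":
            return p[1]
        if self.family == "trapezoidal":
            return 0.5 * (p[1] + p[2])
        return 0.5 * (p[1] + p[3])

    def __call__(self, x) -> np.ndarray:
        """Evaluate the membership degree at ``x`` (scalar or array)."""
        x = np.asarray(x, dtype=float)
        if self.family == "triangular":
            a, b, c = self.params
            left = _ramp_up(x, a, b)
            right = _ramp_down(x, b, c)
            deg = np.minimum(left, right)
        elif self.family == "trapezoidal":
            a, b, c, d = self.params
            deg = np.minimum(_ramp_up(x, a, b), _ramp_down(x, c, d))
        else:
            s1, c1, s2, c2 = self.params
            deg = np.ones_like(x)
            lo = x < c1
            hi = x > c2
            deg = np.where(lo, np.exp(-((x - c1) ** 2) / (2.0 * s1 * s1)), deg)
            deg = np.where(hi, np.exp(-((x - c2) ** 2) / (2.0 * s2 * s2)), deg)
        return np.clip(deg, 0.0, 1.0)

    def param_grad(self, x) -> np.ndarray:
        """Gradient of the degree w.r.t. the params, shape ``(n, len(params))``.

        Piecewise-linear families return the one-sided derivative inside each
        linear piece and zero at kinks and outside the support.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        n = x.shape[0]
        g = np.zeros((n, len(self.params)))
        if self.family == "triangular":
            a, b, c = self.params
            if b > a:
                m = (x > a) & (x < b)
                den = (b - a) ** 2
                g[m, 0] = (x[m] - b) / den
                g[m, 1] = -(x[m] - a) / den
            if c > b:
                m = (x > b) & (x < c)
                den = (c - b) ** 2
                g[m, 1] = (c - x[m]) / den
                g[m, 2] = (x[m] - b) / den
        elif self.family == "trapezoidal":
            a, b, c, d = self.params
            if b > a:
                m = (x > a) & (x < b)
                den = (b - a) ** 2
                g[m, 0] = (x[m] - b) / den
                g[m, 1] = -(x[m] - a) / den
            if d > c:
                m = (x > c) & (x < d)
                den = (d - c) ** 2
                g[m, 2] = (d - x[m]) / den
                g[m, 3] = (x[m] - c) / den
        else:
            s1, c1, s2, c2 = self.params
            m = x < c1
            mu = np.exp(-((x[m] - c1) ** 2) / (2.0 * s1 * s1))
            g[m, 0] = mu * (x[m] - c1) ** 2 / s1**3
            g[m, 1] = mu * (x[m] - c1) / s1**2
            m = x > c2
            mu = np.exp(-((x[m] - c2) ** 2) / (2.0 * s2 * s2))
            g[m, 2] = mu * (x[m] - c2) ** 2 / s2**3
            g[m, 3] = mu * (x[m] - c2) / s2**2
        return g

    def with_params(self, params) -> "MembershipFunction":
        """Copy with new params, projected back onto the feasible set."""
        return MembershipFunction(self.family, project_params(self.family, params))

    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, doc: dict) -> "MembershipFunction":
        return cls(doc["family"], tuple(doc["params"]))


def _ramp_up(x, lo, hi):
    if hi > lo:
        return (x - lo) / (hi - lo)
    return (x >= hi).astype(float)


def _ramp_down(x, lo, hi):
    if hi > lo:
        return (hi - x) / (hi - lo)
    return (x <= lo).astype(float)


def project_params(family: str, params) -> tuple:
    """Project a raw parameter vector onto the family's feasible set.

    Sort-and-clamp: breakpoints are sorted ascending and separated by a tiny
    gap; gauss2 widths are clamped positive and its plateau endpoints swapped
    (as (sigma, c) pairs) if they crossed.  Used after every training update.
    """
    p = np.asarray(params, dtype=float).copy()
    if family in ("triangular", "trapezoidal"):
        p = np.sort(p)
        for i in range(1, p.size):
            p[i] = max(p[i], p[i - 1] + _MIN_GAP)
    elif family == "gauss2":
        s1, c1, s2, c2 = p
        s1 = max(s1, _MIN_SIGMA)
        s2 = max(s2, _MIN_SIGMA)
        if c1 > c2:
            s1, c1, s2, c2 = s2, c2, s1, c1
        p = np.array([s1, c1, s2, c2])
    else:
        raise ConfigurationError(f"unknown membership family {family!r}")
    return tuple(p.tolist())
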