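"""Fuzzy variables, grid-partitioned rule bases, and zero-order Sugeno inference.

A :class:`SugenoFIS` holds one :class:`FuzzyVariable` per input, a full
factorial rule base (one rule per combination of input membership
functions), and one constant consequent per rule.  Inference is the
ANFIS-standard weighted average::

    output = sum_i w_i c_i / sum_i w_i

where ``w_i`` is the t-norm (product by default, min optionally) of the
rule's antecedent membership degrees.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .membership import MembershipFunction

logger = logging.getLogger(__name__)

TNORMS = ("product", "min")

#: added to an exactly-zero total firing strength (with a warning) so that
#: inference still returns a number instead of dividing by zero
_DEGENERATE_EPS = 1e-12


@dataclass
class FuzzyVariable:
    """A named input with an ordered list of membership functions."""

    name: str
    domain: tuple = (0.0, 1.0)
    mfs: list = field(default_factory=list)

    def __post_init__(self):
        lo, hi = self.domain
        self.domain = (float(lo), float(hi))
        if not self.domain[0] < self.domain[1]:
            raise ConfigurationError(f"empty domain {self.domain} for {self.name!r}")

    @property
    def n_mfs(self) -> int:
        return len(self.mfs)

    def memberships(self, x) -> np.ndarray:
        """Degrees of all MFs at ``x``; shape ``(n, n_mfs)``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.stack([mf(x) for mf in self.mfs], axis=1)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "domain": list(self.domain),
            "mfs": [mf.to_dict() for mf in self.mfs],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FuzzyVariable":
        return cls(
            name=doc["name"],
            domain=tuple(doc["domain"]),
            mfs=[MembershipFunction.from_dict(m) for m in doc["mfs"]],
        )


@dataclass(frozen=True)
class Rule:
    """One grid cell: an MF index per input plus a constant consequent."""

    antecedent: tuple
    consequent: float


def make_variable(name, domain=(0.0, 1.0), n_mfs=5, family="triangular"):
    """Build a variable with ``n_mfs`` MFs uniformly partitioning ``domain``.

    Centers sit at ``linspace(lo, hi, n_mfs)``; with center spacing *h*:

    * triangular: feet at the neighboring centers ``(c-h, c, c+h)``;
    * trapezoidal: shoulders at ``c -/+ h/4``, feet at neighboring centers;
    * gauss2: plateau ``[c - h/8, c + h/8]``, flank width ``h/2.5``.

    Edge MFs extend past the domain boundary, which keeps every domain
    point covered by at least one MF with positive degree.
    """
    if n_mfs < 2:
        raise ConfigurationError(f"need at least 2 MFs per input, got {n_mfs}")
    lo, hi = float(domain[0]), float(domain[1])
    centers = np.linspace(lo, hi, n_mfs)
    h = (hi - lo) / (n_mfs - 1)
    mfs = []
    for c in centers:
        if family == "triangular":
            params = (c - h, c, c + h)
        elif family == "trapezoidal":
            params = (c - h, c - h / 4.0, c + h / 4.0, c + h)
        elif family == "gauss2":
            params = (h / 2.5, c - h / 8.0, h / 2.5, c + h / 8.0)
        else:
            raise ConfigurationError(f"unknown membership family {family!r}")
        mfs.append(MembershipFunction(family, params))
    return FuzzyVariable(name=name, domain=(lo, hi), mfs=mfs)


class SugenoFIS:
    """Grid-partitioned zero-order Sugeno fuzzy inference system.

    Parameters
    ----------
    inputs:
        One :class:`FuzzyVariable` per input, in order.
    antecedents:
        Integer array of shape ``(n_rules, n_inputs)``; entry ``[r, j]`` is
        the MF index of input *j* in rule *r*.
    consequents:
        Constant rule outputs, shape ``(n_rules,)``.
    tnorm:
        ``"product"`` (default) or ``"min"``.
    """

    def __init__(self, inputs, antecedents, consequents, tnorm="product"):
        if tnorm not in TNORMS:
            raise ConfigurationError(f"unknown t-norm {tnorm!r}")
        self.inputs = list(inputs)
        self.antecedents = np.asarray(antecedents, dtype=np.intp)
        self.consequents = np.asarray(consequents, dtype=float).copy()
        self.tnorm = tnorm
        d = len(self.inputs)
        if self.antecedents.ndim != 2 or self.antecedents.shape[1] != d:
            raise ConfigurationError("antecedent width must equal the input count")
        if self.consequents.shape != (self.antecedents.shape[0],):
            raise ConfigurationError("one consequent per rule required")
        for j, var in enumerate(self.inputs):
            if self.antecedents[:, j].max(initial=-1) >= var.n_mfs:
                raise ConfigurationError(f"rule references missing MF of {var.name!r}")

    # -- structure ---------------------------------------------------------

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_rules(self) -> int:
        return self.antecedents.shape[0]

    @property
    def rules(self) -> list:
        return [
            Rule(tuple(int(i) for i in ant), float(c))
            for ant, c in zip(self.antecedents, self.consequents)
        ]

    def copy(self) -> "SugenoFIS":
        return SugenoFIS(
            [FuzzyVariable.from_dict(v.to_dict()) for v in self.inputs],
            self.antecedents.copy(),
            self.consequents.copy(),
            self.tnorm,
        )

    # -- inference ---------------------------------------------------------

    def _clip_inputs(self, X: np.ndarray) -> np.ndarray:
        lo = np.array([v.domain[0] for v in self.inputs])
        hi = np.array([v.domain[1] for v in self.inputs])
        if np.any(X < lo) or np.any(X > hi):
            logger.warning(
                "inputs outside the variable domains were clipped before inference"
            )
            X = np.clip(X, lo, hi)
        return X

    def firing_strengths(self, X) -> np.ndarray:
        """Rule firing strengths for a batch; shape ``(n, n_rules)``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        M = [var.memberships(X[:, j]) for j, var in enumerate(self.inputs)]
        per_rule = [M[j][:, self.antecedents[:, j]] for j in range(self.n_inputs)]
        stacked = np.stack(per_rule, axis=0)
        if self.tnorm == "product":
            return stacked.prod(axis=0)
        return stacked.min(axis=0)

    def infer_batch(self, X) -> np.ndarray:
        """Weighted-average Sugeno output for each row of ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite inference input")
        if X.shape[1] != self.n_inputs:
            raise ValidationError(
                f"expected {self.n_inputs} inputs per row, got {X.shape[1]}"
            )
        X = self._clip_inputs(X)
        W = self.firing_strengths(X)
        S = W.sum(axis=1)
        dead = S == 0.0
        if np.any(dead):
            logger.warning(
                "%d input(s) fired no rule; output guarded with eps denominator",
                int(dead.sum()),
            )
            S = S + dead * _DEGENERATE_EPS
        return (W @ self.consequents) / S

    def infer(self, x) -> float:
        """Single-vector convenience wrapper around :meth:`infer_batch`."""
        return float(self.infer_batch(np.asarray(x, dtype=float).reshape(1, -1))[0])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "inputs": [v.to_dict() for v in self.inputs],
            "rules": [
                {"antecedent": [int(i) for i in ant], "consequent": float(c)}
                for ant, c in zip(self.antecedents, self.consequents)
            ],
            "tnorm": self.tnorm,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SugenoFIS":
        inputs = [FuzzyVariable.from_dict(v) for v in doc["inputs"]]
        ant = np.array([r["antecedent"] for r in doc["rules"]], dtype=np.intp)
        con = np.array([r["consequent"] for r in doc["rules"]], dtype=float)
        return cls(inputs, ant, con, doc.get("tnorm", "product"))

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "SugenoFIS":
        return cls.from_dict(json.loads(text))


def grid_partition(variables, consequent=0.5, tnorm="product") -> SugenoFIS:
    """Full-factorial rule base over the variables' MF grids.

    Produces exactly ``prod(n_mfs per input)`` rules, one per antecedent
    combination, each with the same initial constant ``consequent``.
    """
    variables = list(variables)
    if not variables:
        raise ConfigurationError("grid partition needs at least one variable")
    combos = list(itertools.product(*(range(v.n_mfs) for v in variables)))
    ant = np.array(combos, dtype=np.intp)
    con = np.full(len(combos), float(consequent))
    return SugenoFIS(variables, ant, con, tnorm)
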