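"""Supervised training of a zero-order Sugeno FIS.

The default method is full-batch backpropagation of the squared error
through the weighted-average output, with a normalized step (the update
direction is the gradient scaled to length ``learning_rate``) and an
accept/reject step-size schedule: a step that does not increase the
training RMSE is accepted, and four consecutive accepted steps grow the
step length by 10%; a step that increases the RMSE is rejected and the
step length shrinks by 10%.  A ``hybrid`` method additionally solves the
rule consequents by (lightly ridge-regularized) linear least squares at
the start of every epoch, with the premise parameters held fixed.

After every update, membership-function parameters are projected back
onto their feasible ordering (see :func:`fuzzybase.membership.project_params`),
so MF invariants hold throughout training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, NumericError, ValidationError
from .fis import SugenoFIS

logger = logging.getLogger(__name__)

METHODS = ("backprop", "hybrid")
LR_ADAPTATIONS = ("fixed", "step_adaptive")
SPLIT_MODES = ("contiguous", "shuffled")

#: ridge weight pulling unidentified consequents toward their previous value
_RIDGE = 1e-6


@dataclass
class SampleSet:
    """A labeled batch: input matrix ``X`` (n, d) and targets ``y`` (n,)."""

    X: np.ndarray
    y: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError(
                f"{self.name or 'sample set'}: {self.X.shape[0]} rows of inputs "
                f"but {self.y.shape[0]} targets"
            )
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValidationError(f"{self.name or 'sample set'}: non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.X.shape[1]


@dataclass
class TrainingConfig:
    epochs: int = 500
    learning_rate: float = 0.02
    lr_adaptation: str = "step_adaptive"
    method: str = "backprop"
    seed: int = 0
    batch: str = "full"

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError(f"epochs must be >= 1, got {self.epochs}")
        if not self.learning_rate > 0:
            raise ConfigurationError(
                f"learning_rate must be > 0, got {self.learning_rate}"
            )
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.lr_adaptation not in LR_ADAPTATIONS:
            raise ConfigurationError(f"unknown lr_adaptation {self.lr_adaptation!r}")
        if self.batch != "full":
            raise ConfigurationError("only full-batch training is supported")


@dataclass
class TrainingRun:
    """Trained system plus its per-epoch training-error trace."""

    fis: SugenoFIS
    train_rmse_by_epoch: list = field(default_factory=list)
    test_rmse: float | None = None


def split(samples: SampleSet, n_train: int, mode: str = "contiguous", seed=None):
    """Divide ``samples`` into a training and a testing :class:`SampleSet`.

    ``contiguous`` (default) takes the first ``n_train`` rows for training;
    ``shuffled`` permutes rows reproducibly from ``seed`` first.
    """
    n = len(samples)
    if not 0 < n_train < n:
        raise ValidationError(f"n_train must be in (0, {n}), got {n_train}")
    if mode not in SPLIT_MODES:
        raise ValidationError(f"unknown split mode {mode!r}")
    idx = np.arange(n)
    if mode == "shuffled":
        if seed is None:
            raise ValidationError("shuffled split requires a seed")
        idx = np.random.default_rng(seed).permutation(n)
    tr, te = idx[:n_train], idx[n_train:]
    return (
        SampleSet(samples.X[tr], samples.y[tr], name=f"{samples.name}/train"),
        SampleSet(samples.X[te], samples.y[te], name=f"{samples.name}/test"),
    )


def evaluate(fis: SugenoFIS, test_set: SampleSet) -> float:
    """Root-mean-square error of ``fis`` on a labeled sample set."""
    if len(test_set) == 0:
        raise ValidationError("cannot evaluate on an empty sample set")
    if test_set.n_inputs != fis.n_inputs:
        raise ValidationError(
            f"sample dimension {test_set.n_inputs} != FIS input count {fis.n_inputs}"
        )
    resid = fis.infer_batch(test_set.X) - test_set.y
    return float(np.sqrt(np.mean(resid**2)))


def train(fis: SugenoFIS, train_set: SampleSet, cfg: TrainingConfig) -> TrainingRun:
    """Fit a copy of ``fis`` to ``train_set``; the input system is untouched."""
    if len(train_set) == 0:
        raise ValidationError("training set is empty")
    if train_set.n_inputs != fis.n_inputs:
        raise ValidationError(
            f"sample dimension {train_set.n_inputs} != FIS input count {fis.n_inputs}"
        )
    if fis.tnorm != "product":
        raise ConfigurationError("training requires the differentiable product t-norm")

    work = fis.copy()
    X, y = train_set.X, train_set.y
    lr = cfg.learning_rate
    current = evaluate(work, train_set)
    history: list[float] = []
    accepts = 0

    for epoch in range(1, cfg.epochs + 1):
        if cfg.method == "hybrid":
            _solve_consequents(work, X, y)
            current = evaluate(work, train_set)

        prem_grads, cons_grad = _gradients(work, X, y)
        step = _step_length(prem_grads, cons_grad, cfg.method)
        if step > 0:
            try:
                candidate = _apply_step(
                    work, prem_grads, cons_grad, lr / step,
                    premises_only=(cfg.method == "hybrid"),
                )
            except ConfigurationError as exc:
                raise NumericError(
                    f"non-finite parameter update at epoch {epoch}: {exc}"
                ) from exc
        else:
            candidate = work
        cand_rmse = evaluate(candidate, train_set)
        if not np.isfinite(cand_rmse):
            raise NumericError(f"non-finite training loss at epoch {epoch}")

        if cfg.lr_adaptation == "step_adaptive":
            if cand_rmse <= current:
                work, current = candidate, cand_rmse
                accepts += 1
                if accepts >= 4:
                    lr *= 1.1
                    accepts = 0
            else:  # rejected step: keep params, shrink the rate
                lr *= 0.9
                accepts = 0
        else:
            work, current = candidate, cand_rmse
        history.append(current)
        logger.debug("epoch %d: train rmse %.6g (lr %.4g)", epoch, current, lr)

    return TrainingRun(fis=work, train_rmse_by_epoch=history)


# -- internals -------------------------------------------------------------


def _forward(fis: SugenoFIS, X: np.ndarray):
    M = [var.memberships(X[:, j]) for j, var in enumerate(fis.inputs)]
    per_rule = [M[j][:, fis.antecedents[:, j]] for j in range(fis.n_inputs)]
    W = np.stack(per_rule, axis=0).prod(axis=0)
    S = W.sum(axis=1)
    S = np.where(S == 0.0, 1e-12, S)
    yhat = (W @ fis.consequents) / S
    return M, per_rule, W, S, yhat


def _gradients(fis: SugenoFIS, X: np.ndarray, y: np.ndarray):
    """Full-batch gradient of mean squared error w.r.t. all parameters.

    Returns ``(premise_grads, consequent_grad)`` where ``premise_grads`` is a
    nested list ``[input][mf] -> array(len(params))``.
    """
    n = X.shape[0]
    M, per_rule, W, S, yhat = _forward(fis, X)
    e = yhat - y
    # d(mse)/d(consequent_r) = (2/n) sum_n e_n * W_nr / S_n
    Wn = W / S[:, None]
    cons_grad = (2.0 / n) * (Wn.T @ e)
    # d(mse)/d(W_nr) = (2/n) e_n (c_r - yhat_n) / S_n
    g_w = (2.0 / n) * (e / S)[:, None] * (fis.consequents[None, :] - yhat[:, None])

    prem_grads = []
    for j, var in enumerate(fis.inputs):
        # product of the other inputs' memberships per rule
        other = np.ones_like(W)
        for k in range(fis.n_inputs):
            if k != j:
                other *= per_rule[k]
        contrib = g_w * other  # (n, R)
        ant_j = fis.antecedents[:, j]
        grads_j = []
        for m, mf in enumerate(var.mfs):
            dmu = contrib[:, ant_j == m].sum(axis=1)  # (n,)
            grads_j.append(dmu @ mf.param_grad(X[:, j]))
        prem_grads.append(grads_j)
    return prem_grads, cons_grad


def _step_length(prem_grads, cons_grad, method: str) -> float:
    total = float(np.sum(cons_grad**2)) if method == "backprop" else 0.0
    for grads_j in prem_grads:
        for g in grads_j:
            total += float(np.sum(g**2))
    return float(np.sqrt(total))


def _apply_step(fis: SugenoFIS, prem_grads, cons_grad, scale, premises_only=False):
    out = fis.copy()
    with np.errstate(invalid="ignore", over="ignore"):  # caught as NumericError
        for j, var in enumerate(out.inputs):
            var.mfs = [
                mf.with_params(np.asarray(mf.params) - scale * prem_grads[j][m])
                for m, mf in enumerate(var.mfs)
            ]
        if not premises_only:
            out.consequents = out.consequents - scale * cons_grad
    return out


def _solve_consequents(fis: SugenoFIS, X: np.ndarray, y: np.ndarray) -> None:
    """Least-squares consequents with premises fixed (in place).

    A tiny ridge term pulls consequents toward their previous values so that
    rules that never fire keep their prior constant instead of blowing up.
    """
    _, _, W, S, _ = _forward(fis, X)
    B = W / S[:, None]
    A = B.T @ B + _RIDGE * np.eye(fis.n_rules)
    b = B.T @ y + _RIDGE * fis.consequents
    fis.consequents = np.linalg.solve(A, b)
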