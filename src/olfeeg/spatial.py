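"""Spatial feature extraction: CSP and covariance tangent-space (CMTS).

Two complementary spatial descriptors of a multi-channel trial:

* **Common spatial patterns (CSP)** - supervised spatial filters that
  maximize the variance of one class relative to the rest, obtained from the
  generalized eigenproblem ``C_c w = lambda (C_c + C_rest) w`` on per-class
  covariances of time-concatenated training trials.  The three-class problem
  is handled one-vs-rest: each sub-problem contributes eigenvectors in
  alternating extremal order and near-duplicates are removed before keeping
  ``n_components`` filters.  A trial's feature is the average power of each
  filtered signal.

* **Covariance matrix tangent space (CMTS)** - each trial's channel
  covariance (an SPD matrix, estimated with oracle-approximating shrinkage)
  is projected to the tangent space of the SPD manifold at the Riemannian
  (Karcher) mean of the training covariances via the matrix logarithm,
  yielding a Euclidean vector of length d(d+1)/2 whose norm equals the
  affine-invariant Riemannian distance to the reference.

Both extractors follow a strict fit/transform contract: fitting consumes
training trials only, and the identities of the trials seen during fitting
are recorded so evaluation code can audit against data leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .dataset import EEGTrial, EEGTrialSet
from .errors import (
    ConvergenceError,
    DataError,
    DegenerateDataError,
    ParameterError,
    StateError,
    StructuralError,
)

__all__ = [
    "SPDMatrix",
    "CSPModel",
    "TangentSpaceModel",
    "fit_csp",
    "transform_csp",
    "estimate_covariance",
    "trial_covariances",
    "riemannian_mean",
    "fit_tangent",
    "tangent_map",
]


@dataclass
class SPDMatrix:
    """A symmetric positive-definite matrix (validated on construction)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise StructuralError(f"SPD matrix must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise StructuralError("matrix is not symmetric to 1e-10")
        self.values = 0.5 * (v + v.T)
        if np.linalg.eigvalsh(self.values)[0] <= 0:
            raise DegenerateDataError("matrix is not positive definite")

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# covariance estimation
# ---------------------------------------------------------------------------

def estimate_covariance(trial: EEGTrial, method: str = "oas") -> SPDMatrix:
    """Estimate a trial's channel covariance.

    ``method='oas'`` applies oracle-approximating shrinkage toward scaled
    identity, ``C = (1 - rho) S + rho (tr S / d) I`` with the closed-form
    rho in [0, 1]; ``method='sample'`` returns the plain sample covariance.
    The base S is the uncentered second-moment matrix ``X X^T / n`` - the
    usual convention for band-passed (zero-mean) EEG.
    """
    x = trial.data
    d, n = x.shape
    if np.any(x.std(axis=1) == 0):
        raise DegenerateDataError("a channel is constant; covariance is degenerate")
    s = x @ x.T / n
    if method == "sample":
        if n <= d:
            raise DataError(f"sample covariance needs samples > channels ({n} <= {d})")
        return SPDMatrix(s)
    if method != "oas":
        raise ParameterError(f"unknown covariance method {method!r}")
    mu = np.trace(s) / d
    tr_s2 = np.sum(s * s)
    tr2_s = np.trace(s) ** 2
    num = (1.0 - 2.0 / d) * tr_s2 + tr2_s
    den = (n + 1.0 - 2.0 / d) * (tr_s2 - tr2_s / d)
    rho = 1.0 if den <= 0 else min(1.0, num / den)
    shrunk = (1.0 - rho) * s + rho * mu * np.eye(d)
    return SPDMatrix(shrunk)


def trial_covariances(ts: EEGTrialSet, method: str = "oas") -> list[SPDMatrix]:
    """Per-trial covariances for a whole set (order-preserving)."""
    return [estimate_covariance(t, method=method) for t in ts]


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

@dataclass
class CSPModel:
    """Fitted CSP filter bank: ``filters`` is n_components x channels."""

    filters: np.ndarray
    n_components: int
    classes: list[int]
    fitted: bool = False
    log_power: bool = False
    fit_trial_ids: list[int] | None = field(default=None, repr=False)


def _class_covariance(trials: list[EEGTrial]) -> np.ndarray:
    """Trace-normalized sample covariance of time-concatenated trials."""
    x = np.concatenate([t.data for t in trials], axis=1)
    c = x @ x.T / x.shape[1]
    tr = np.trace(c)
    if tr <= 0 or np.linalg.matrix_rank(c) < c.shape[0]:
        raise DegenerateDataError(
            "class covariance is rank deficient; provide more or longer trials"
        )
    return c / tr


def fit_csp(
    train: EEGTrialSet,
    n_components: int = 4,
    log_power: bool = False,
    trial_ids: list[int] | None = None,
) -> CSPModel:
    """Fit one-vs-rest CSP filters on training trials only.

    For each class c the generalized eigenproblem ``C_c w = lambda (C_c +
    C_rest) w`` is solved (plain sample covariances, no regularization);
    eigenvectors are taken in alternating extremal order (most
    class-enhancing first, most class-suppressing second, ...), pooled
    round-robin across the one-vs-rest sub-problems, deduplicated at
    absolute cosine similarity > 0.95, and the first ``n_components`` are
    kept.
    """
    labels = sorted({int(t.label) for t in train})
    if len(labels) < 2:
        raise DataError("CSP needs at least two classes in the training set")
    per_problem: list[list[np.ndarray]] = []
    for lab in labels:
        own = [t for t in train if int(t.label) == lab]
        rest = [t for t in train if int(t.label) != lab]
        c_own = _class_covariance(own)
        c_rest = _class_covariance(rest)
        evals, evecs = scipy.linalg.eigh(c_own, c_own + c_rest)
        order = np.argsort(evals)[::-1]  # most class-enhancing first
        alternating: list[np.ndarray] = []
        lo, hi = 0, len(order) - 1
        while lo <= hi:
            alternating.append(evecs[:, order[lo]])
            if hi != lo:
                alternating.append(evecs[:, order[hi]])
            lo += 1
            hi -= 1
        per_problem.append(alternating)
    pooled: list[np.ndarray] = []
    for rank in range(max(len(p) for p in per_problem)):
        for p in per_problem:
            if rank < len(p):
                pooled.append(p[rank])
    kept: list[np.ndarray] = []
    for w in pooled:
        w = w / np.linalg.norm(w)
        if all(abs(float(w @ k)) <= 0.95 for k in kept):
            kept.append(w)
        if len(kept) == n_components:
            break
    if len(kept) < n_components:
        raise DataError(
            f"could only assemble {len(kept)} distinct filters "
            f"(requested {n_components})"
        )
    return CSPModel(
        filters=np.array(kept),
        n_components=n_components,
        classes=labels,
        fitted=True,
        fit_trial_ids=list(trial_ids) if trial_ids is not None else None,
    )


def transform_csp(model: CSPModel, trial: EEGTrial) -> np.ndarray:
    """Average power of each spatial filter: ``mean_t (w_i . x(t))**2``."""
    if not model.fitted:
        raise StateError("CSP model is not fitted")
    if trial.n_channels != model.filters.shape[1]:
        raise StructuralError(
            f"trial has {trial.n_channels} channels, filters expect {model.filters.shape[1]}"
        )
    projected = model.filters @ trial.data
    power = np.mean(projected ** 2, axis=1)
    return np.log(np.maximum(power, 1e-30)) if model.log_power else power


# ---------------------------------------------------------------------------
# Riemannian geometry on SPD matrices
# ---------------------------------------------------------------------------

def _eigh_fun(mats: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to symmetric matrices via batched eigh."""
    w, v = np.linalg.eigh(mats)
    return (v * fun(w)[..., None, :]) @ np.swapaxes(v, -1, -2)


def riemannian_mean(
    mats: list[SPDMatrix], tol: float = 1e-8, max_iter: int = 50
) -> SPDMatrix:
    """Affine-invariant (Karcher) mean by fixed-point iteration.

    Starts at the arithmetic mean and iterates ``R <- R^1/2 exp(mean_i
    log(R^-1/2 C_i R^-1/2)) R^1/2`` until the tangent-space gradient norm
    drops below ``tol``.
    """
    if not mats:
        raise DataError("riemannian_mean needs at least one matrix")
    stack = np.stack([m.values for m in mats])
    if len(mats) == 1:
        return SPDMatrix(stack[0])
    ref = stack.mean(axis=0)
    grad_norm = np.inf
    for _ in range(max_iter):
        w, v = np.linalg.eigh(ref)
        inv_sqrt = (v * (w ** -0.5)) @ v.T
        sqrt = (v * (w ** 0.5)) @ v.T
        whitened = inv_sqrt @ stack @ inv_sqrt
        logs = _eigh_fun(0.5 * (whitened + np.swapaxes(whitened, -1, -2)), np.log)
        grad = logs.mean(axis=0)
        grad_norm = np.linalg.norm(grad)
        if grad_norm <= tol:
            return SPDMatrix(ref)
        w2, v2 = np.linalg.eigh(grad)
        ref = sqrt @ ((v2 * np.exp(w2)) @ v2.T) @ sqrt
    raise ConvergenceError(
        f"Karcher mean did not reach tol={tol} in {max_iter} iterations "
        f"(final gradient norm {grad_norm:.3e})"
    )


@dataclass
class TangentSpaceModel:
    """Tangent-space projector anchored at a Riemannian mean reference."""

    reference: SPDMatrix
    fitted: bool = False
    fit_trial_ids: list[int] | None = field(default=None, repr=False)


def fit_tangent(
    train_covs: list[SPDMatrix], trial_ids: list[int] | None = None
) -> TangentSpaceModel:
    """Fit the tangent-space reference = Karcher mean of training covariances."""
    ref = riemannian_mean(train_covs)
    return TangentSpaceModel(
        reference=ref,
        fitted=True,
        fit_trial_ids=list(trial_ids) if trial_ids is not None else None,
    )


def tangent_map(model: TangentSpaceModel, cov: SPDMatrix) -> np.ndarray:
    """Project one covariance to the tangent space at the reference.

    Computes ``S = log(R^-1/2 C R^-1/2)`` and returns its upper triangle
    with off-diagonal entries weighted by sqrt(2), so the Euclidean norm of
    the vector equals the affine-invariant Riemannian distance delta(R, C).
    """
    if not model.fitted:
        raise StateError("tangent-space model is not fitted")
    r = model.reference.values
    if cov.dimension != r.shape[0]:
        raise StructuralError(
            f"covariance dimension {cov.dimension} != reference {r.shape[0]}"
        )
    w, v = np.linalg.eigh(r)
    inv_sqrt = (v * (w ** -0.5)) @ v.T
    m = inv_sqrt @ cov.values @ inv_sqrt
    s = _eigh_fun(0.5 * (m + m.T), np.log)
    d = r.shape[0]
    iu = np.triu_indices(d)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return s[iu] * weights


def tangent_dim(n_channels: int) -> int:
    """Length of a tangent-space vector: d(d+1)/2."""
    return n_channels * (n_channels + 1) // 2
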