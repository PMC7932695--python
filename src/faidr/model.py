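"""Multiple-instance penalized logistic regression for IDR function.

Proteins carry binary function labels; each protein has one or more IDRs, and
which IDR is responsible for the label is a hidden variable.  The marginal
likelihood over n proteins is

    P(Y | Z, b) = prod_i sum_j P(X_ij = 1) h(Z_ij)^Y_i (1 - h(Z_ij))^(1 - Y_i)

with h(z) = 1 / (1 + exp(-(z . b + b0))) and r_i IDRs in protein i.  Fitting
alternates an E-step (Bayes posterior over the responsible IDR, the
"responsibility" <X_ij>) with an M-step that runs a fixed number of IRLS
iterations of elastic-net-penalized weighted logistic regression, where each
IDR row carries its protein's label weighted by its responsibility.  The IRLS
weights are w_ij = <X_ij> h(Z_ij) (1 - h(Z_ij)), floored for stability.

The penalty scale follows the working-response LASSO convention: each IRLS
iteration solves a weighted gaussian elastic net on the working response with
the modified weights above, normalized against their value at h = 1/2.  With
W0 = (1/4) sum_k v_k for observation weights v, the M-step objective is

    -(1/W0) sum v_k loglik_k + lambda * (alpha ||b||_1 + (1 - alpha)/2 ||b||_2^2)

with the intercept unpenalized.  W0 is a fixed constant, so the M-step is a
fixed convex problem and EM ascends the correspondingly penalized marginal
log-likelihood.  lambda = 0.2 and alpha = 0.99 (a small ridge admixture for
numerical stability) are the defaults used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .io import AnnotationTable, FaidrFit, FeatureTable

__all__ = [
    "EMConfig",
    "FitError",
    "logistic_probability",
    "marginal_log_likelihood",
    "expected_complete_log_likelihood",
    "penalized_marginal_objective",
    "e_step",
    "irls_weights",
    "weighted_penalized_logistic",
    "fit_faidr",
    "predict_idr",
    "predict_protein",
]

_ETA_MAX = 700.0  # exp overflow guard on the linear predictor
_PROB_CLAMP = 1e-12  # log-argument clamp


class FitError(RuntimeError):
    """Numerical failure or invalid setup during fitting."""


@dataclass
class EMConfig:
    """Hyperparameters of the EM fit.

    lambda_: L1/elastic-net penalty strength (glmnet scale).
    alpha: elastic-net mixing; 0.99 means mostly-L1 with a small ridge term.
    irls_iterations_per_mstep: IRLS iterations run in each (truncated) M-step.
    em_tolerance: stop when the largest absolute change in any responsibility
        falls below this.
    weight_floor: lower bound applied to IRLS weights that reach zero.
    min_positives: refuse to fit a function with fewer positive proteins.
    """

    lambda_: float = 0.2
    alpha: float = 0.99
    irls_iterations_per_mstep: int = 5
    max_em_iterations: int = 100
    em_tolerance: float = 1e-4
    weight_floor: float = 1e-8
    include_intercept: bool = True
    min_positives: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be > 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.irls_iterations_per_mstep < 1:
            raise ValueError("irls_iterations_per_mstep must be >= 1")
        if self.weight_floor <= 0:
            raise ValueError("weight_floor must be > 0")


def logistic_probability(
    z: np.ndarray, b: np.ndarray, intercept: float = 0.0
) -> np.ndarray | float:
    """h = 1 / (1 + exp(-(z.b + intercept))), stable for |eta| up to 700."""
    z = np.asarray(z, dtype=float)
    b = np.asarray(b, dtype=float)
    if z.shape[-1] != b.shape[0]:
        raise ValueError(f"feature dimension mismatch: {z.shape[-1]} vs {b.shape[0]}")
    eta = np.clip(z @ b + intercept, -_ETA_MAX, _ETA_MAX)
    out = expit(eta)
    return float(out) if np.ndim(out) == 0 else out


def _row_labels(table: FeatureTable, labels) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein and per-row 0/1 label arrays aligned to the table."""
    if isinstance(labels, Mapping):
        missing = [p for p in table.protein_index if p not in labels]
        if missing:
            raise FitError(f"{len(missing)} proteins lack labels (e.g. {missing[0]!r})")
        y_prot = np.array([labels[p] for p in table.protein_index], dtype=float)
    else:
        y_prot = np.asarray(labels, dtype=float).ravel()
        if y_prot.shape[0] != table.n_proteins:
            raise FitError(
                f"label vector length {y_prot.shape[0]} != {table.n_proteins} proteins"
            )
    if not np.isin(y_prot, (0.0, 1.0)).all():
        raise FitError("labels must be binary")
    return y_prot, y_prot[table.row_group]


def _h_rows(table: FeatureTable, b, intercept) -> np.ndarray:
    return np.asarray(logistic_probability(table.X, b, intercept))


def _bag_term(h: np.ndarray, y_row: np.ndarray) -> np.ndarray:
    """P(Y_i | X_ij = 1, Z_ij) per row, clamped away from 0/1."""
    hc = np.clip(h, _PROB_CLAMP, 1.0 - _PROB_CLAMP)
    return y_row * hc + (1.0 - y_row) * (1.0 - hc)


def marginal_log_likelihood(
    table: FeatureTable,
    labels,
    b: np.ndarray,
    intercept: float,
    prior: np.ndarray | None = None,
) -> float:
    """Log of the marginal likelihood, summed over proteins.

    ``prior`` gives P(X_ij = 1) per IDR row and must sum to one within each
    protein; by default it is uniform (1 / r_i, an uninformative prior).
    """
    _, y_row = _row_labels(table, labels)
    group = table.row_group
    counts = np.bincount(group, minlength=table.n_proteins).astype(float)
    if prior is None:
        prior = 1.0 / counts[group]
    else:
        prior = np.asarray(prior, dtype=float)
        sums = np.bincount(group, weights=prior, minlength=table.n_proteins)
        if np.abs(sums - 1.0).max() > 1e-8:
            raise ValueError("prior must sum to 1 within each protein")
    a = _bag_term(_h_rows(table, b, intercept), y_row)
    per_protein = np.bincount(group, weights=prior * a, minlength=table.n_proteins)
    return float(np.sum(np.log(np.maximum(per_protein, 1e-300))))


def expected_complete_log_likelihood(
    table: FeatureTable,
    labels,
    b: np.ndarray,
    intercept: float,
    responsibilities: np.ndarray,
) -> float:
    """sum_ij <X_ij> [Y_i log h(Z_ij) + (1 - Y_i) log(1 - h(Z_ij))]."""
    _, y_row = _row_labels(table, labels)
    resp = np.asarray(responsibilities, dtype=float)
    sums = np.bincount(table.row_group, weights=resp, minlength=table.n_proteins)
    if np.abs(sums - 1.0).max() > 1e-8:
        raise ValueError("responsibilities must sum to 1 within each protein")
    h = np.clip(_h_rows(table, b, intercept), _PROB_CLAMP, 1.0 - _PROB_CLAMP)
    return float(np.sum(resp * (y_row * np.log(h) + (1.0 - y_row) * np.log1p(-h))))


def _enet_penalty(b: np.ndarray, lambda_: float, alpha: float) -> float:
    return lambda_ * (
        alpha * np.abs(b).sum() + 0.5 * (1.0 - alpha) * np.square(b).sum()
    )


def penalized_marginal_objective(
    table: FeatureTable, labels, b, intercept, lambda_: float, alpha: float
) -> float:
    """Marginal log-likelihood minus the elastic-net penalty.

    The penalty is scaled by n_proteins / 4 — the M-step normalizer W0
    evaluated at responsibilities summing to one per protein — so this is
    exactly the quantity EM ascends when the M-step is run to inner
    convergence.
    """
    return marginal_log_likelihood(table, labels, b, intercept) - (
        0.25 * table.n_proteins
        * _enet_penalty(np.asarray(b, dtype=float), lambda_, alpha)
    )


def e_step(
    table: FeatureTable, labels, b: np.ndarray, intercept: float
) -> np.ndarray:
    """Posterior responsibility of each IDR for its protein's label.

    <X_ij> = [Y_i h_ij + (1 - Y_i)(1 - h_ij)] / sum_k [Y_i h_ik + (1 - Y_i)(1 - h_ik)]
    under a uniform prior over the IDRs of each protein.
    """
    _, y_row = _row_labels(table, labels)
    a = _bag_term(_h_rows(table, b, intercept), y_row)
    denom = np.bincount(table.row_group, weights=a, minlength=table.n_proteins)
    assert denom.min() > 0.0, "zero posterior normalizer (h left (0,1)?)"
    return a / denom[table.row_group]


def irls_weights(
    responsibilities: np.ndarray, probabilities: np.ndarray, weight_floor: float = 1e-8
) -> np.ndarray:
    """Modified IRLS weights w_ij = <X_ij> h_ij (1 - h_ij), floored."""
    w = np.asarray(responsibilities, float) * np.asarray(probabilities, float)
    w = w * (1.0 - np.asarray(probabilities, float))
    return np.maximum(w, weight_floor)


def _soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _cd_solve(
    X: np.ndarray,
    X2: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    b: np.ndarray,
    b0: float,
    lam_l1: float,
    lam_l2: float,
    w0: float,
    tol: float = 1e-9,
    max_passes: int = 1000,
) -> tuple[np.ndarray, float]:
    """Cyclic coordinate descent for penalized weighted least squares.

    Minimizes (1/(2 w0)) sum_k w_k (z_k - b0 - x_k . b)^2
              + lam_l1 ||b||_1 + lam_l2/2 ||b||_2^2
    with an unpenalized intercept, using an active-set strategy: full sweeps
    alternate with sweeps over the currently nonzero coefficients.
    """
    n = w0
    denom = (w @ X2) / n + lam_l2
    sw = w.sum()
    r = z - b0 - X @ b

    def sweep(idx) -> float:
        nonlocal b0, r
        max_d = 0.0
        for j in idx:
            bj = b[j]
            wxj = w * X[:, j]
            rho = (wxj @ r) / n + (denom[j] - lam_l2) * bj
            bn = _soft_threshold(rho, lam_l1) / denom[j]
            if bn != bj:
                d = bn - bj
                r -= X[:, j] * d
                b[j] = bn
                max_d = max(max_d, abs(d))
        d0 = (w @ r) / sw
        if d0 != 0.0:
            b0 += d0
            r -= d0
            max_d = max(max_d, abs(d0))
        return max_d

    all_idx = np.arange(X.shape[1])
    for _ in range(max_passes):
        if sweep(all_idx) < tol:
            break
        for _ in range(max_passes):
            active = np.flatnonzero(b)
            if active.size == 0 or sweep(active) < tol:
                break
    return b, b0


def weighted_penalized_logistic(
    X: np.ndarray,
    y: np.ndarray,
    observation_weights: np.ndarray,
    config: EMConfig | None = None,
    warm_start: tuple[np.ndarray, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Truncated IRLS for elastic-net-penalized weighted logistic regression.

    Runs exactly ``config.irls_iterations_per_mstep`` IRLS iterations; each
    iteration forms the quadratic approximation at the current coefficients
    and solves the penalized weighted least-squares problem to convergence by
    coordinate descent, with weights w_k = v_k h_k (1 - h_k) normalized
    against the fixed constant W0 = (1/4) sum v_k (their total at h = 1/2).
    This puts ``lambda_`` on the scale of a weighted LASSO on the IRLS
    working response, comparable across reweightings and EM rounds.
    """
    cfg = config or EMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    v = np.asarray(observation_weights, dtype=float).ravel()
    n, m = X.shape
    if y.shape[0] != n or v.shape[0] != n:
        raise ValueError("X, y and weights must have matching first dimension")
    w0 = 0.25 * v.sum()
    X2 = np.square(X)
    if warm_start is not None:
        b = np.array(warm_start[0], dtype=float, copy=True)
        b0 = float(warm_start[1])
    else:
        b = np.zeros(m)
        b0 = 0.0
    lam_l1 = cfg.lambda_ * cfg.alpha
    lam_l2 = cfg.lambda_ * (1.0 - cfg.alpha)
    for it in range(cfg.irls_iterations_per_mstep):
        eta = np.clip(X @ b + b0, -_ETA_MAX, _ETA_MAX)
        h = expit(eta)
        q = np.maximum(h * (1.0 - h), cfg.weight_floor)
        w = np.maximum(v * h * (1.0 - h), cfg.weight_floor)
        z = eta + (y - h) / q
        b, b0 = _cd_solve(X, X2, w, z, b, b0, lam_l1, lam_l2, w0)
        if not cfg.include_intercept:
            b0 = 0.0
        if not (np.all(np.isfinite(b)) and np.isfinite(b0)):
            raise FitError(f"non-finite coefficients at IRLS iteration {it + 1}")
    return b, b0


def fit_faidr(
    table: FeatureTable,
    labels,
    config: EMConfig | None = None,
    function_name: str = "function",
) -> FaidrFit:
    """Fit the multiple-instance model for one function by EM.

    Responsibilities are initialized uniformly at 1 / r_i so every IDR of a
    protein is downweighted equally; each EM round runs the truncated-IRLS
    M-step (warm-started from the previous coefficients) followed by an
    E-step, until the largest responsibility change drops below
    ``em_tolerance``.  The penalized marginal log-likelihood is recorded at
    initialization and after every round.
    """
    cfg = config or EMConfig()
    y_prot, y_row = _row_labels(table, labels)
    n_pos = int(y_prot.sum())
    n_neg = int((1 - y_prot).sum())
    if n_pos < cfg.min_positives:
        raise FitError(
            f"{function_name!r} has {n_pos} positive proteins; "
            f"at least {cfg.min_positives} required"
        )
    if n_neg < 1:
        raise FitError(f"{function_name!r} has no negative proteins")
    counts = np.bincount(table.row_group, minlength=table.n_proteins).astype(float)
    resp = 1.0 / counts[table.row_group]
    b = np.zeros(len(table.feature_names))
    b0 = 0.0
    trace = [penalized_marginal_objective(table, y_prot, b, b0, cfg.lambda_, cfg.alpha)]
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_em_iterations + 1):
        b, b0 = weighted_penalized_logistic(
            table.X, y_row, resp, cfg, warm_start=(b, b0)
        )
        new_resp = e_step(table, y_prot, b, b0)
        trace.append(
            penalized_marginal_objective(table, y_prot, b, b0, cfg.lambda_, cfg.alpha)
        )
        delta = float(np.abs(new_resp - resp).max())
        resp = new_resp
        if delta < cfg.em_tolerance:
            converged = True
            break
    return FaidrFit(
        function_name=function_name,
        feature_names=list(table.feature_names),
        coefficients=b,
        intercept=b0,
        idr_ids=list(table.idr_ids),
        responsibilities=resp,
        lambda_=cfg.lambda_,
        alpha=cfg.alpha,
        n_em_iterations=n_iter,
        objective_trace=trace,
        converged=converged,
    )


def _check_features(fit: FaidrFit, table: FeatureTable) -> None:
    if list(table.feature_names) != list(fit.feature_names):
        raise ValueError("feature columns do not match the fitted model")


def predict_idr(fit: FaidrFit, table: FeatureTable) -> np.ndarray:
    """Per-IDR probability of function, h(Z_ij) applied row by row."""
    _check_features(fit, table)
    return np.asarray(logistic_probability(table.X, fit.coefficients, fit.intercept))


def predict_protein(fit: FaidrFit, table: FeatureTable) -> np.ndarray:
    """Per-protein probability: the uniform-prior mixture (1/r_i) sum_j h(Z_ij).

    For unseen proteins the label-conditional posterior over the responsible
    IDR is unavailable, so each IDR contributes equally — a simple average of
    the per-IDR probabilities.  Returned in ``table.protein_ids`` order.
    """
    h = predict_idr(fit, table)
    counts = np.bincount(table.row_group, minlength=table.n_proteins).astype(float)
    sums = np.bincount(table.row_group, weights=h, minlength=table.n_proteins)
    return sums / counts


def labels_for_function(
    table: FeatureTable, annotations: AnnotationTable, function: str
) -> dict[str, int]:
    """Protein -> 0/1 labels for one annotation column, restricted to proteins
    that have at least one IDR row."""
    col = annotations.column(function)
    return {p: col[p] for p in table.protein_index if p in col}
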