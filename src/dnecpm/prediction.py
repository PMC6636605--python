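"""L1-penalised connectome-based prediction of clinical scores.

The model regresses a per-subject clinical score y on the vectorised upper
triangle of the dnE matrix, minimising

    ||y - x beta||_2^2  +  (lambda/2) ||beta||_1

with lambda = 0.08 by default.  Features are standardised and y centred
within each training set so a single penalty acts comparably across
features; the objective above is solved in that standardised frame.

Solver mapping.  scikit-learn's :class:`~sklearn.linear_model.Lasso`
minimises ``(1/(2n)) ||y - Xw||^2 + alpha ||w||_1``.  Multiplying by 2n and
matching the penalty terms, ``2 n alpha = lambda / 2``, i.e.

    alpha = lambda / (4 n)

with n the number of training samples.  The optimality (KKT subgradient)
conditions of the original objective are therefore

    |2 x_k^T (y - x beta)| <= lambda/2      where beta_k = 0
     2 x_k^T (y - x beta)  = (lambda/2) sign(beta_k)   otherwise,

which :func:`kkt_violation` evaluates and the test suite pins down.

Generalisation error is estimated by leave-one-out cross-validation
(standardisation re-fit per fold, so the held-out subject never influences
training), summarised by the Pearson correlation between predicted and
actual scores (Bonferroni-corrected across prediction targets) and the mean
absolute error, with significance from a label-permutation test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso, LassoLars

from .errors import InputError
from .network import DnEMatrix

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.08


def pair_index(n_nodes: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle node pairs (i < j) for an n-node matrix."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def vectorize_upper(dne: DnEMatrix | np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Flatten the strict upper triangle of a symmetric matrix row-major.

    Returns the feature row and the pair index mapping feature position to
    node pair; ``n(n-1)/2`` features for n nodes (30,135 at n = 246).
    """
    data = dne.data if isinstance(dne, DnEMatrix) else np.asarray(dne, dtype=float)
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        raise InputError("expected a square matrix")
    if not np.allclose(data, data.T, atol=1e-10):
        raise InputError("matrix asymmetric beyond 1e-10 tolerance")
    iu, ju = np.triu_indices(data.shape[0], k=1)
    return data[iu, ju].copy(), list(zip(iu.tolist(), ju.tolist()))


def unvectorize_upper(row: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric matrix (unit diagonal) from its upper triangle."""
    mat = np.eye(n_nodes)
    iu, ju = np.triu_indices(n_nodes, k=1)
    mat[iu, ju] = row
    mat[ju, iu] = row
    return mat


@dataclass
class FeatureMatrix:
    """Subject-by-feature design built from per-subject dnE matrices."""

    X: np.ndarray
    pair_index: list[tuple[int, int]]
    subject_ids: list[str]

    @classmethod
    def from_dne(cls, mats: list[DnEMatrix], subject_ids: list[str] | None = None
                 ) -> "FeatureMatrix":
        rows, pairs = [], None
        for m in mats:
            row, pairs = vectorize_upper(m)
            rows.append(row)
        ids = subject_ids or [f"s{i}" for i in range(len(mats))]
        return cls(X=np.vstack(rows), pair_index=pairs, subject_ids=ids)


@dataclass
class CvResult:
    """Leave-one-out cross-validation output."""

    predictions: np.ndarray
    per_fold_beta: np.ndarray      # n_folds x n_features, standardised frame
    r: float
    p_raw: float
    p_bonferroni: float
    mae: float
    n_folds: int
    target_label: str = ""


@dataclass
class PermutationResult:
    """Label-permutation null distribution for the LOOCV correlation."""

    r_observed: float
    null_rs: np.ndarray
    n_perm: int
    p_perm: float
    seed: int


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centre/scale columns; zero-variance columns are dropped (mask False)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    mask = sd > 0
    if not mask.all():
        logger.warning("dropping %d zero-variance feature(s)", (~mask).sum())
    Xs = (X[:, mask] - mean[mask]) / sd[mask]
    return Xs, mean, sd, mask


def _solve_l1(Xs: np.ndarray, yc: np.ndarray, lam: float,
              max_iter: int, tol: float, solver: str = "lars") -> np.ndarray:
    """Minimise ||yc - Xs b||^2 + (lam/2)||b||_1 in the standardised frame.

    The default "lars" solver computes the homotopy path and is essentially
    exact (KKT residuals at machine precision), which matters in the
    many-features / few-subjects regime where coordinate descent ("cd")
    converges slowly at small penalties.  Every call starts the solver
    cold: warm-starting across cross-validation folds is deliberately
    avoided, because an incompletely converged fit would retain information
    from the previous fold's training set, which includes the current
    held-out subject.
    """
    n = Xs.shape[0]
    if lam == 0:
        coef, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        return coef
    alpha = lam / (4.0 * n)
    if solver == "lars":
        est = LassoLars(alpha=alpha, fit_intercept=False)
    elif solver == "cd":
        est = Lasso(alpha=alpha, fit_intercept=False, max_iter=max_iter, tol=tol)
    else:
        raise InputError(f"unknown solver {solver!r}; use 'lars' or 'cd'")
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Xs, yc)
    return np.asarray(est.coef_, dtype=float).copy()


class CpmLasso(BaseEstimator, RegressorMixin):
    """L1-penalised linear regressor for connectome features.

    Fits the objective ``||y - x beta||^2 + (lam/2) ||beta||_1`` after
    per-feature standardisation and y-centring on the training data, and
    predicts on the original scale.

    Parameters
    ----------
    lam : float, default 0.08
        Penalty weight of the half-L1 term.  ``lam = 0`` (least squares,
        minimum-norm if underdetermined) is permitted for testing.
    solver : {"lars", "cd"}, default "lars"
        "lars" solves the homotopy path exactly; "cd" is scikit-learn
        coordinate descent controlled by ``max_iter`` and ``tol``.
    max_iter, tol : coordinate-descent controls (ignored by "lars").

    Attributes
    ----------
    coef_ : ndarray, original-scale coefficients (zeros for dropped features)
    intercept_ : float
    coef_std_ : ndarray, coefficients in the standardised frame
    feature_mask_ : boolean ndarray, False where a feature had zero variance
    """

    def __init__(self, lam: float = DEFAULT_LAMBDA, solver: str = "lars",
                 max_iter: int = 5000, tol: float = 1e-4):
        self.lam = lam
        self.solver = solver
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise InputError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise InputError("X and y disagree on sample count")
        if X.shape[0] < 2:
            raise InputError("need at least 2 training samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise InputError("non-finite values in X or y")
        if self.lam < 0:
            raise InputError("lam must be non-negative")
        Xs, mean, sd, mask = _standardize_train(X)
        y_mean = y.mean()
        yc = y - y_mean
        coef_kept = _solve_l1(Xs, yc, self.lam, self.max_iter, self.tol,
                              self.solver)
        coef_std = np.zeros(X.shape[1])
        coef_std[mask] = coef_kept
        coef = np.zeros(X.shape[1])
        coef[mask] = coef_kept / sd[mask]
        self.coef_std_ = coef_std
        self.coef_ = coef
        self.intercept_ = y_mean - float(coef @ mean)
        self.feature_mask_ = mask
        self.x_mean_, self.x_scale_ = mean, sd
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def fit_lasso(X_train, y_train, lambda_: float = DEFAULT_LAMBDA, **kwargs) -> CpmLasso:
    """Fit :class:`CpmLasso` on a training set; thin functional wrapper."""
    return CpmLasso(lam=lambda_, **kwargs).fit(X_train, y_train)


def kkt_violation(model: CpmLasso, X_train, y_train, zero_tol: float = 1e-12) -> float:
    """Maximum KKT subgradient violation of the fitted objective.

    Evaluated in the standardised frame on the training data the model saw:
    for zero coefficients, ``max(0, |2 x^T r| - lam/2)``; for nonzero ones,
    ``|2 x^T r - (lam/2) sign(beta)|``.  Exact minimisers give 0.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    mask = model.feature_mask_
    Xs = (X[:, mask] - model.x_mean_[mask]) / model.x_scale_[mask]
    yc = y - y.mean()
    beta = model.coef_std_[mask]
    g = 2.0 * Xs.T @ (yc - Xs @ beta)
    half = model.lam / 2.0
    zero = np.abs(beta) <= zero_tol
    viol_zero = np.maximum(0.0, np.abs(g[zero]) - half)
    viol_nz = np.abs(g[~zero] - half * np.sign(beta[~zero]))
    parts = [v for v in (viol_zero, viol_nz) if v.size]
    return float(max(p.max() for p in parts)) if parts else 0.0


def lambda_max(X, y) -> float:
    """Smallest penalty at which the all-zero solution is optimal.

    In the standardised frame, ``beta = 0`` satisfies the KKT conditions iff
    ``|2 x_k^T y_c| <= lambda/2`` for every feature, i.e.
    ``lambda_max = 4 max_k |x_k^T y_c|``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xs, _, _, mask = _standardize_train(X)
    yc = y - y.mean()
    return 4.0 * float(np.max(np.abs(Xs.T @ yc))) if mask.any() else 0.0


def evaluate(predictions, y, n_targets: int = 1) -> tuple[float, float, float, float]:
    """Pearson r (two-tailed t-transform p, Bonferroni over targets) and MAE.

    A constant y or constant prediction vector has no defined correlation;
    r and the p-values are then NaN while MAE is still returned.
    """
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if pred.shape[0] != y.shape[0]:
        raise InputError("predictions and y differ in length")
    if pred.shape[0] < 3:
        raise InputError("need at least 3 subjects to evaluate")
    mae = float(np.mean(np.abs(pred - y)))
    if np.std(y) == 0 or np.std(pred) == 0:
        logger.warning("constant scores or predictions: correlation undefined")
        return float("nan"), float("nan"), float("nan"), mae
    r, p_raw = stats.pearsonr(pred, y)
    p_bonf = min(1.0, float(p_raw) * n_targets)
    return float(r), float(p_raw), p_bonf, mae


def loocv_predict(X, y, lambda_: float = DEFAULT_LAMBDA, n_targets: int = 1,
                  solver: str = "lars", max_iter: int = 5000, tol: float = 1e-4,
                  target_label: str = "") -> CvResult:
    """Leave-one-out cross-validated prediction.

    Each subject is predicted by a model fitted on the other N-1 subjects;
    feature standardisation is re-estimated inside every fold so no
    information about the held-out subject leaks into training.  Per-fold
    coefficients (standardised frame) are recorded for feature aggregation.
    """
    Xmat = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = Xmat.shape[0]
    if n < 3:
        raise InputError("LOOCV needs at least 3 subjects")
    if n != y.shape[0]:
        raise InputError("X and y disagree on subject count")
    preds = np.empty(n)
    betas = np.empty((n, Xmat.shape[1]))
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        model = CpmLasso(lam=lambda_, solver=solver, max_iter=max_iter, tol=tol)
        model.fit(Xmat[train], y[train])
        preds[i] = model.predict(Xmat[i][None, :])[0]
        betas[i] = model.coef_std_
    r, p_raw, p_bonf, mae = evaluate(preds, y, n_targets=n_targets)
    return CvResult(predictions=preds, per_fold_beta=betas, r=r, p_raw=p_raw,
                    p_bonferroni=p_bonf, mae=mae, n_folds=n,
                    target_label=target_label)


def permutation_test(X, y, lambda_: float = DEFAULT_LAMBDA, n_perm: int = 1000,
                     seed: int = 0, solver: str = "lars", max_iter: int = 5000,
                     tol: float = 1e-4) -> PermutationResult:
    """One-sided permutation test of the LOOCV correlation.

    Each iteration permutes the score labels uniformly at random and reruns
    the complete cross-validation (per-fold standardisation and fitting
    included).  ``p = (1 + #{r_null >= r_obs}) / (1 + n_perm)`` — the
    add-one estimator, which never returns exactly zero.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    obs = loocv_predict(X, y, lambda_, solver=solver, max_iter=max_iter, tol=tol)
    rng = np.random.default_rng(seed)
    null_rs = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        null_rs[b] = loocv_predict(X, y_perm, lambda_, solver=solver,
                                   max_iter=max_iter, tol=tol).r
    count = int(np.sum(null_rs >= obs.r)) if np.isfinite(obs.r) else n_perm
    p_perm = (1.0 + count) / (1.0 + n_perm)
    return PermutationResult(r_observed=obs.r, null_rs=null_rs, n_perm=n_perm,
                             p_perm=p_perm, seed=seed)
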