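"""Ridge-regularized logistic regression, fitted from scratch.

The classifier minimizes the mean binary cross-entropy plus an L2 penalty on
the weights (the bias is unpenalized):

    E(w0, w) = -(1/T) sum_t [ d_t log f(z_t) + (1 - d_t) log(1 - f(z_t)) ]
               + (lambda/2) w'w,          z_t = w0 + X_t w,

with f the logistic sigmoid.  E equals log 2 at the null model (f = 0.5
everywhere, balanced labels) and tends to 0 under perfect prediction.

Fitting uses damped Newton iterations (backtracking line search on E, ridge
jitter if the Hessian is near-singular); lambda is chosen by stratified,
repeated k-fold cross-validation minimizing the held-out cross-entropy, the
same protocol used to pick the analysis-window length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import DataError, ParameterError, StratificationError
from .features import as_labels, as_matrix, build_feature_matrix
from .trials import TrialSet

__all__ = [
    "LogisticModel",
    "CVResult",
    "SweepResult",
    "sigmoid",
    "cost",
    "fit",
    "predict_proba",
    "classify",
    "auc",
    "cross_validate",
    "default_lambda_grid",
    "frame_window_sweep",
]

logger = logging.getLogger(__name__)


def sigmoid(z):
    """Numerically stable logistic function 1 / (1 + exp(-z))."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LogisticModel:
    """Fitted bias, weights and regularization strength."""

    w0: float
    w: np.ndarray
    lam: float
    converged: bool = True
    n_iter: int = 0
    final_cost: float = np.nan

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()


def _check_xd(X, d):
    x = as_matrix(X)
    y = as_labels(d)
    if x.shape[0] != y.shape[0]:
        raise DataError(f"X has {x.shape[0]} rows but d has {y.shape[0]} labels")
    if not np.all(np.isfinite(x)):
        raise DataError("X contains non-finite values")
    return x, y


def _cross_entropy(z, d):
    # mean of log(1 + exp(z)) - d*z, in overflow-safe form
    return float(np.mean(np.maximum(z, 0.0) - d * z + np.log1p(np.exp(-np.abs(z)))))


def cost(w0, w, X, d, lam):
    """The regularized cross-entropy objective E(w0, w)."""
    x, y = _check_xd(X, d)
    w = np.asarray(w, dtype=float).ravel()
    if lam < 0:
        raise ParameterError(f"lambda must be >= 0, got {lam}")
    if not (np.isfinite(w0) and np.all(np.isfinite(w))):
        raise DataError("non-finite parameters")
    z = w0 + x @ w
    return _cross_entropy(z, y) + 0.5 * lam * float(w @ w)


def _grad(w0, w, x, y, lam):
    p = sigmoid(w0 + x @ w)
    r = (p - y) / len(y)
    g = np.empty(len(w) + 1)
    g[0] = r.sum()
    g[1:] = x.T @ r + lam * w
    return g, p


def fit(
    X,
    d,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 1000,
    w0_init: float = 0.0,
    w_init=None,
) -> LogisticModel:
    """Minimize E(w0, w) by damped Newton with backtracking line search.

    The bias is excluded from the penalty.  With ``lam == 0`` on linearly
    separable data the minimizer does not exist (weights diverge); the fit
    then stops at ``max_iter`` with ``converged=False`` and a warning.
    """
    x, y = _check_xd(X, d)
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present to fit a classifier")
    if lam < 0:
        raise ParameterError(f"lambda must be >= 0, got {lam}")
    t, dim = x.shape
    beta = np.zeros(dim + 1)
    beta[0] = w0_init
    if w_init is not None:
        beta[1:] = np.asarray(w_init, dtype=float).ravel()

    def eval_cost(b):
        z = b[0] + x @ b[1:]
        return _cross_entropy(z, y) + 0.5 * lam * float(b[1:] @ b[1:])

    c = eval_cost(beta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g, p = _grad(beta[0], beta[1:], x, y, lam)
        gnorm = float(np.linalg.norm(g))
        if gnorm <= tol:
            converged = True
            n_iter -= 1
            break
        wvar = np.clip(p * (1.0 - p), 1e-12, None) / t
        xw = x * wvar[:, None]
        h = np.empty((dim + 1, dim + 1))
        h[0, 0] = wvar.sum()
        h[0, 1:] = h[1:, 0] = xw.sum(axis=0)
        h[1:, 1:] = x.T @ xw
        h[1:, 1:][np.diag_indices(dim)] += lam
        jitter = 0.0
        while True:
            try:
                step = np.linalg.solve(
                    h + jitter * np.eye(dim + 1) if jitter else h, g
                )
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-10)
        # backtracking (Armijo) line search on the cost
        alpha, accepted = 1.0, False
        gdot = float(g @ step)
        for _ in range(60):
            cand = beta - alpha * step
            c_new = eval_cost(cand)
            if c_new <= c - 1e-4 * alpha * gdot:
                beta, c = cand, c_new
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # Newton direction unusable; fall back to plain gradient descent
            alpha = 1.0
            for _ in range(60):
                cand = beta - alpha * g
                c_new = eval_cost(cand)
                if c_new < c:
                    beta, c = cand, c_new
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break  # no descent possible at machine precision
    g, _ = _grad(beta[0], beta[1:], x, y, lam)
    if not converged and float(np.linalg.norm(g)) <= tol:
        converged = True
    if lam == 0.0:
        z = beta[0] + x @ beta[1:]
        if np.all(z[y == 1] > 0) and np.all(z[y == 0] < 0):
            converged = False
            warnings.warn(
                "data are linearly separable and lambda = 0: the cost has no "
                "minimizer (weights diverge); returning the final iterate",
                RuntimeWarning,
                stacklevel=2,
            )
            return LogisticModel(
                w0=float(beta[0]), w=beta[1:].copy(), lam=0.0,
                converged=False, n_iter=n_iter, final_cost=c,
            )
    if not converged:
        warnings.warn(
            "logistic fit did not reach the gradient tolerance "
            f"(|g| = {np.linalg.norm(g):.3g} after {n_iter} iterations); "
            "with lambda = 0 this is expected on separable data",
            RuntimeWarning,
            stacklevel=2,
        )
    return LogisticModel(
        w0=float(beta[0]),
        w=beta[1:].copy(),
        lam=float(lam),
        converged=converged,
        n_iter=n_iter,
        final_cost=c,
    )


def predict_proba(model: LogisticModel, X) -> np.ndarray:
    """p(d = 1) for each row of X."""
    x = as_matrix(X)
    if x.shape[1] != len(model.w):
        raise DataError(
            f"X has {x.shape[1]} features but model expects {len(model.w)}"
        )
    return sigmoid(model.w0 + x @ model.w)


def classify(model: LogisticModel, X, threshold: float = 0.5) -> np.ndarray:
    """Estimated labels: 1 iff p(d=1) > threshold; exact ties go to class 0."""
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    p = predict_proba(model, X)
    ties = int(np.sum(p == threshold))
    if ties:
        logger.warning(
            "%d trial(s) with p exactly at threshold %.3g assigned to class 0",
            ties,
            threshold,
        )
    return (p > threshold).astype(int)


def auc(scores, d) -> float:
    """Area under the ROC curve = P(score_1 > score_0) + P(tie)/2.

    Computed exactly over all cross-class pairs via midranks
    (the Mann-Whitney U normalization).
    """
    s = np.asarray(scores, dtype=float)
    y = as_labels(d)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise DataError("AUC requires both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def default_lambda_grid(X, d, n: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced lambda grid anchored at the data.

    For a ridge penalty the weights satisfy |w(lambda)| <= |g0| / lambda,
    where g0 is the cross-entropy gradient at the null model; the top of the
    grid is chosen so |w| <~ 1e-3 there, and the grid spans ``decades``
    decades downward.
    """
    x, y = _check_xd(X, d)
    g0 = x.T @ (np.full(len(y), y.mean()) - y) / len(y)
    gnorm = float(np.linalg.norm(g0))
    lam_max = max(gnorm, 1e-6) / 1e-3
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Fold id per trial, balanced within each class."""
    if len(y) < k:
        raise StratificationError(f"T = {len(y)} < k = {k}")
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    # every training fold must contain both classes
    for f in range(k):
        train_y = y[folds != f]
        if len(np.unique(train_y)) < 2:
            raise StratificationError(
                f"training fold {f} is missing a class; too few trials per class"
            )
    return folds


@dataclass
class CVResult:
    """Repeated stratified k-fold cross-validation summary."""

    lambda_grid: np.ndarray
    mean_cv_cost: np.ndarray
    se_cv_cost: np.ndarray
    chosen_lambda: float
    fold_assignments: list  # one fold-id array per repeat
    accuracy_mean: float
    accuracy_sem: float
    auc_mean: float
    auc_sem: float
    seed: int
    k: int = 10
    repeats: int = 5
    per_fold_accuracy: np.ndarray = field(default=None)


def cross_validate(
    X,
    d,
    lambda_grid=None,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    normalize: str = "per-fold",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> CVResult:
    """Choose lambda by repeated stratified k-fold CV on held-out cross-entropy.

    Per fold, z-scoring parameters are computed on the training split and
    applied to the held-out split (``normalize="per-fold"``, default); pass
    ``normalize="none"`` when X is already on a common scale.  Held-out
    accuracy and AUC are reported at the chosen lambda; everything is
    reproducible from ``seed``.
    """
    x, y = _check_xd(X, d)
    if normalize not in ("per-fold", "none"):
        raise ParameterError(f"unknown normalize policy {normalize!r}")
    grid = (
        default_lambda_grid(x, y)
        if lambda_grid is None
        else np.asarray(lambda_grid, dtype=float)
    )
    order = np.argsort(grid)[::-1]  # descending: warm starts shrink downward
    rng = np.random.default_rng(seed)
    n_lam = len(grid)
    fold_ce, fold_acc, fold_auc = [], [], []
    assignments = []
    for _ in range(repeats):
        folds = _stratified_folds(y, k, rng)
        assignments.append(folds)
        for f in range(k):
            test = folds == f
            xtr, ytr = x[~test], y[~test]
            xte, yte = x[test], y[test]
            if normalize == "per-fold":
                mu = xtr.mean(axis=0)
                sd = xtr.std(axis=0, ddof=1)
                sd = np.where((sd > 0) & np.isfinite(sd), sd, 1.0)
                xtr = (xtr - mu) / sd
                xte = (xte - mu) / sd
            ce = np.empty(n_lam)
            acc = np.empty(n_lam)
            aucs = np.full(n_lam, np.nan)
            w0_ws, w_ws = 0.0, None
            for j in order:
                m = fit(
                    xtr, ytr, grid[j], tol=tol, max_iter=max_iter,
                    w0_init=w0_ws, w_init=w_ws,
                )
                w0_ws, w_ws = m.w0, m.w
                z = m.w0 + xte @ m.w
                ce[j] = _cross_entropy(z, yte)
                pred = (sigmoid(z) > 0.5).astype(int)
                acc[j] = float(np.mean(pred == yte))
                if len(np.unique(yte)) == 2:
                    aucs[j] = auc(z, yte)
            fold_ce.append(ce)
            fold_acc.append(acc)
            fold_auc.append(aucs)
    fold_ce = np.array(fold_ce)
    fold_acc = np.array(fold_acc)
    fold_auc = np.array(fold_auc)
    mean_ce = fold_ce.mean(axis=0)
    se_ce = fold_ce.std(axis=0, ddof=1) / np.sqrt(fold_ce.shape[0])
    best = int(np.argmin(mean_ce))
    nf = fold_ce.shape[0]
    acc_at = fold_acc[:, best]
    auc_at = fold_auc[:, best]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN fold AUCs
        auc_mean = float(np.nanmean(auc_at))
        auc_sem = float(np.nanstd(auc_at, ddof=1) / np.sqrt(np.sum(~np.isnan(auc_at))))
    return CVResult(
        lambda_grid=grid,
        mean_cv_cost=mean_ce,
        se_cv_cost=se_ce,
        chosen_lambda=float(grid[best]),
        fold_assignments=assignments,
        accuracy_mean=float(acc_at.mean()),
        accuracy_sem=float(acc_at.std(ddof=1) / np.sqrt(nf)),
        auc_mean=auc_mean,
        auc_sem=auc_sem,
        seed=seed,
        k=k,
        repeats=repeats,
        per_fold_accuracy=acc_at,
    )


@dataclass
class SweepResult:
    """Accuracy as a function of the analysis-window length."""

    table: "object"  # pandas DataFrame: window_frames, accuracy_mean, ...
    best_window: int


def frame_window_sweep(
    trials: TrialSet,
    max_frames: int,
    anchor: str = "release",
    include_anchor: bool = True,
    lambda_grid=None,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
) -> SweepResult:
    """Cross-validated accuracy for window lengths F = 1..max_frames.

    Returns the per-F table and the argmax window (ties resolved toward the
    smaller F), mirroring how the analysis window is selected from data.
    """
    import pandas as pd

    rows = []
    for f in range(1, int(max_frames) + 1):
        fm, d = build_feature_matrix(
            trials, f, anchor=anchor, include_anchor=include_anchor
        )
        cv = cross_validate(
            fm, d, lambda_grid=lambda_grid, k=k, repeats=repeats, seed=seed
        )
        rows.append(
            {
                "window_frames": f,
                "accuracy_mean": cv.accuracy_mean,
                "accuracy_sem": cv.accuracy_sem,
                "auc_mean": cv.auc_mean,
                "chosen_lambda": cv.chosen_lambda,
            }
        )
    table = pd.DataFrame(rows)
    best = int(table.loc[table["accuracy_mean"].idxmax(), "window_frames"])
    return SweepResult(table=table, best_window=best)
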