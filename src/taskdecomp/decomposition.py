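"""Closed-form split of motion data into task-relevant and task-irrelevant parts.

Given a fitted linear classifier with weight vector w, the task-relevant
component of the data matrix X is its rank-one projection onto w,

    X_rel = X w w' / |w|^2,      X_irr = X - X_rel,

so that X_rel w = X w (the task-relevant part carries the entire
classification probability, f(w0 + X_rel,t w) = f(w0 + X_t w)) and
X_irr w = 0 (the task-irrelevant part carries none).  The map P = w w'/|w|^2
is an orthogonal projector (P^2 = P), which also makes X_rel the minimizer
of the squared classification-score discrepancy |Xw - X_rel w|^2 among
rank-constrained candidates.

The per-class grouping routes trials by the *estimated* class label (the
classifier's own prediction), not the true label; splitting by true labels
is available for sensitivity analysis and is flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DegenerateDirectionError, ParameterError
from .features import as_labels, as_matrix
from .logistic import LogisticModel, classify

__all__ = ["Decomposition", "ClassSplit", "decompose", "split_by_estimated_class"]


@dataclass
class Decomposition:
    """X = X_rel + X_irr with X_rel the projection of each row onto w."""

    X_rel: np.ndarray
    X_irr: np.ndarray
    w_used: np.ndarray
    w0_used: float
    scores: np.ndarray  # signed scalar projection s = X w / |w|


@dataclass
class ClassSplit:
    """The decomposed components grouped by predicted (or true) class."""

    X_rel_0: np.ndarray
    X_rel_1: np.ndarray
    X_irr_0: np.ndarray
    X_irr_1: np.ndarray
    estimated_labels: np.ndarray
    T0: int
    T1: int
    by: str = "estimated"


def _extract_w(model) -> tuple[np.ndarray, float]:
    if isinstance(model, LogisticModel):
        return np.asarray(model.w, dtype=float), float(model.w0)
    return np.asarray(model, dtype=float).ravel(), 0.0


def decompose(X, model) -> Decomposition:
    """Project X onto the classifier direction; X_irr is the residual.

    ``model`` may be a fitted :class:`LogisticModel` or a bare weight
    vector.  Raises :class:`DegenerateDirectionError` when |w| is
    numerically zero — a null model defines no task-relevant direction.
    """
    x = as_matrix(X)
    w, w0 = _extract_w(model)
    if x.shape[1] != len(w):
        raise DataError(f"X has {x.shape[1]} features but w has {len(w)}")
    nrm = float(np.linalg.norm(w))
    if nrm < 1e-12 * np.sqrt(len(w)):
        raise DegenerateDirectionError(
            f"|w| = {nrm:.3g} is numerically zero; the task-relevant "
            "direction is undefined"
        )
    xw = x @ w
    x_rel = np.outer(xw / (nrm * nrm), w)
    return Decomposition(
        X_rel=x_rel,
        X_irr=x - x_rel,
        w_used=w.copy(),
        w0_used=w0,
        scores=xw / nrm,
    )


def split_by_estimated_class(
    dec: Decomposition,
    model: LogisticModel,
    X,
    threshold: float = 0.5,
    by: str = "estimated",
    true_labels=None,
) -> ClassSplit:
    """Group the decomposed rows by the classifier's predicted class.

    With ``by="true"`` the split uses ``true_labels`` instead (sensitivity
    analysis); the choice is recorded in the result.
    """
    x = as_matrix(X)
    if x.shape[0] != dec.X_rel.shape[0]:
        raise DataError("X and Decomposition have different numbers of trials")
    if by == "estimated":
        labels = classify(model, x, threshold=threshold)
    elif by == "true":
        if true_labels is None:
            raise ParameterError("by='true' requires true_labels")
        labels = as_labels(true_labels)
        if len(labels) != x.shape[0]:
            raise DataError("true_labels length does not match X")
    else:
        raise ParameterError(f"unknown split mode {by!r}")
    g0 = labels == 0
    g1 = ~g0
    return ClassSplit(
        X_rel_0=dec.X_rel[g0],
        X_rel_1=dec.X_rel[g1],
        X_irr_0=dec.X_irr[g0],
        X_irr_1=dec.X_irr[g1],
        estimated_labels=labels,
        T0=int(g0.sum()),
        T1=int(g1.sum()),
        by=by,
    )
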