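"""Feature-matrix construction and normalization.

The classifier operates on ``X`` (T trials x D features), the vectorized
joint-angle window: for each trial the F consecutive frames ending at an
anchor (the ball-release frame by default, inclusive) are concatenated
joint-major, so D = J x F.  Columns are z-scored across trials before
fitting; the per-column mean/sd are retained so the transform is invertible.

The vectorization order is frozen and recorded in ``column_map`` — a list of
``(joint_name, frame_offset)`` pairs where ``frame_offset`` k in 0..F-1 maps
column ``X[:, col]`` to ``angles[joint, anchor - F + 1 + k]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, DataError, ParameterError
from .trials import TrialSet

__all__ = [
    "FeatureMatrix",
    "LabelVector",
    "Normalization",
    "build_feature_matrix",
    "zscore",
    "inverse_zscore",
    "write_feature_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class Normalization:
    """Per-column mean/sd used for z-scoring (sample sd, ddof=1)."""

    mean: np.ndarray
    sd: np.ndarray
    ddof: int = 1
    dropped: list = field(default_factory=list)  # (joint, offset) of removed columns


@dataclass
class FeatureMatrix:
    """T x D design matrix with column provenance and optional normalization."""

    X: np.ndarray
    column_map: list  # [(joint_name, frame_offset), ...] length D
    window_frames: int = 1
    anchor: str = "release"
    normalization: Normalization | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DataError(f"X must be 2-D, got shape {self.X.shape}")
        if len(self.column_map) != self.X.shape[1]:
            raise DataError(
                f"column_map length {len(self.column_map)} != D {self.X.shape[1]}"
            )

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class LabelVector:
    """Length-T vector of {0, 1} outcome labels aligned with FeatureMatrix rows."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 1:
            raise DataError("labels must be a 1-D vector")
        bad = set(np.unique(self.values)) - {0, 1}
        if bad:
            raise DataError(f"labels must be in {{0, 1}}; found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.values)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def as_matrix(X) -> np.ndarray:
    """Plain ndarray view of a FeatureMatrix or array-like."""
    if isinstance(X, FeatureMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def as_labels(d) -> np.ndarray:
    if isinstance(d, LabelVector):
        return d.values
    return LabelVector(np.asarray(d)).values


def build_feature_matrix(
    trials: TrialSet,
    window_frames: int,
    anchor: str = "release",
    include_anchor: bool = True,
):
    """Vectorize each trial's joint-angle window into one row of X.

    Parameters
    ----------
    trials
        TrialSet with consistent joints.
    window_frames
        F >= 1 frames per joint.
    anchor
        ``"release"`` — window ends at each trial's release frame
        (requires ``release_frame`` to be set); ``"series-end"`` — window
        ends at the last frame.
    include_anchor
        If True (default) the anchor frame is the last frame of the window;
        if False the window ends one frame before the anchor.

    Returns
    -------
    (FeatureMatrix, LabelVector)
        Raw (un-normalized) features, D = J * F, and aligned labels.
    """
    f = int(window_frames)
    if f < 1:
        raise ParameterError(f"window_frames must be >= 1, got {window_frames}")
    if anchor not in ("release", "series-end"):
        raise ParameterError(f"unknown anchor {anchor!r}")
    j = trials.n_joints
    rows = np.empty((len(trials), j * f))
    for i, t in enumerate(trials):
        if anchor == "release":
            if t.release_frame is None:
                raise CoverageError(
                    f"trial {t.trial_index} (subject {t.subject_id}): "
                    "anchor='release' but release_frame is not set"
                )
            end = t.release_frame if include_anchor else t.release_frame - 1
        else:
            end = t.n_frames - 1 if include_anchor else t.n_frames - 2
        start = end - f + 1
        if start < 0 or end >= t.n_frames:
            raise CoverageError(
                f"trial {t.trial_index} (subject {t.subject_id}, day {t.day}): "
                f"window of {f} frames ending at frame {end} does not fit in "
                f"{t.n_frames} frames"
            )
        rows[i] = t.angles[:, start : end + 1].reshape(-1)
    column_map = [
        (joint, k) for joint in trials.joint_names for k in range(f)
    ]
    fm = FeatureMatrix(
        X=rows, column_map=column_map, window_frames=f, anchor=anchor
    )
    return fm, LabelVector(trials.labels)


def zscore(fm: FeatureMatrix, zero_variance: str = "drop") -> FeatureMatrix:
    """Normalize each column to mean 0 / sample sd 1 across trials.

    Zero-variance columns carry no class information and cannot be scaled;
    policy ``"drop"`` (default) removes them with a logged warning and
    records them in ``normalization.dropped``; ``"error"`` raises.
    """
    if zero_variance not in ("drop", "error"):
        raise ParameterError(f"unknown zero_variance policy {zero_variance!r}")
    x = fm.X
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    degenerate = ~np.isfinite(sd) | (sd <= 0.0)
    if degenerate.any():
        bad = [fm.column_map[i] for i in np.flatnonzero(degenerate)]
        if zero_variance == "error":
            raise DataError(f"zero-variance columns: {bad}")
        logger.warning("dropping %d zero-variance column(s): %s", len(bad), bad)
    keep = ~degenerate
    z = (x[:, keep] - mean[keep]) / sd[keep]
    return FeatureMatrix(
        X=z,
        column_map=[fm.column_map[i] for i in np.flatnonzero(keep)],
        window_frames=fm.window_frames,
        anchor=fm.anchor,
        normalization=Normalization(
            mean=mean[keep],
            sd=sd[keep],
            dropped=[fm.column_map[i] for i in np.flatnonzero(degenerate)],
        ),
    )


def write_feature_matrix(fm: FeatureMatrix, csv_path, sidecar_path=None) -> None:
    """Export X as CSV (column_map header) + normalization JSON sidecar."""
    import json

    import pandas as pd

    header = [f"{joint}:{offset}" for joint, offset in fm.column_map]
    pd.DataFrame(fm.X, columns=header).to_csv(csv_path, index=False)
    if sidecar_path is not None:
        norm = fm.normalization
        payload = {
            "window_frames": fm.window_frames,
            "anchor": fm.anchor,
            "column_map": [list(c) for c in fm.column_map],
            "normalization": None
            if norm is None
            else {
                "mean": norm.mean.tolist(),
                "sd": norm.sd.tolist(),
                "ddof": norm.ddof,
                "dropped": [list(c) for c in norm.dropped],
            },
        }
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def inverse_zscore(fm: FeatureMatrix) -> FeatureMatrix:
    """Undo :func:`zscore` (dropped columns are gone and stay gone)."""
    if fm.normalization is None:
        raise ParameterError("FeatureMatrix carries no normalization to invert")
    x = fm.X * fm.normalization.sd + fm.normalization.mean
    return FeatureMatrix(
        X=x,
        column_map=list(fm.column_map),
        window_frames=fm.window_frames,
        anchor=fm.anchor,
        normalization=None,
    )
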