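"""Trial containers and file I/O.

A :class:`Trial` holds the joint-angle time series of one throw together with
its categorical outcome label (0 = fastball, 1 = breaking ball by convention)
and bookkeeping metadata; a :class:`TrialSet` is an ordered, structurally
consistent collection of trials sharing joint names, angle units and sampling
rate.

Two on-disk formats are supported:

* **long CSV** — one row per (trial, joint, frame) with columns
  ``subject, day, trial, label, joint, frame, angle_rad`` and an optional
  ``release_frame`` column (constant within a trial);
* **JSON manifest** — a header with shared metadata plus a list of per-trial
  wide CSV files (``frame`` column followed by one column per joint).

Angles are stored in radians internally; degrees are converted on load when
the file/metadata declares ``angle_deg`` or ``units: deg``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, StructuralError

__all__ = ["Trial", "TrialSet", "load_trials", "write_trials"]

_REQUIRED_LONG_COLUMNS = ("subject", "day", "trial", "label", "joint", "frame")


@dataclass
class Trial:
    """One throw: a J x N joint-angle matrix plus outcome label and metadata."""

    subject_id: str
    day: int
    trial_index: int
    label: int
    angles: np.ndarray  # shape (J, N), radians
    release_frame: int | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise DataError(
                f"trial {self.trial_index}: angles must be a J x N matrix, "
                f"got shape {self.angles.shape}"
            )
        if not np.all(np.isfinite(self.angles)):
            raise DataError(
                f"trial {self.trial_index} (subject {self.subject_id}): "
                "non-finite joint angles"
            )
        if self.label not in (0, 1):
            raise DataError(
                f"trial {self.trial_index}: label must be 0 or 1, got {self.label!r}"
            )
        if self.release_frame is not None:
            n = self.angles.shape[1]
            if not 0 <= int(self.release_frame) < n:
                raise DataError(
                    f"trial {self.trial_index}: release_frame {self.release_frame} "
                    f"outside [0, {n})"
                )
            self.release_frame = int(self.release_frame)

    @property
    def n_joints(self) -> int:
        return self.angles.shape[0]

    @property
    def n_frames(self) -> int:
        return self.angles.shape[1]


@dataclass
class TrialSet:
    """Ordered collection of trials with shared joint names / units / rate."""

    trials: list[Trial]
    joint_names: list[str]
    fs: float = 120.0
    angle_units: str = "rad"

    def __post_init__(self) -> None:
        j = len(self.joint_names)
        for t in self.trials:
            if t.n_joints != j:
                raise StructuralError(
                    f"trial {t.trial_index} (subject {t.subject_id}, day {t.day}) "
                    f"has {t.n_joints} joints; expected {j} ({self.joint_names})"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=int)

    def subset(self, indices) -> "TrialSet":
        """A new TrialSet containing the trials at ``indices`` (order kept)."""
        return TrialSet(
            trials=[self.trials[i] for i in indices],
            joint_names=list(self.joint_names),
            fs=self.fs,
            angle_units=self.angle_units,
        )

    def groupby_session(self):
        """Yield ((subject_id, day), TrialSet) per recording session, sorted."""
        keys = sorted({(t.subject_id, t.day) for t in self.trials})
        for key in keys:
            idx = [
                i
                for i, t in enumerate(self.trials)
                if (t.subject_id, t.day) == key
            ]
            yield key, self.subset(idx)


def _trials_sort_key(t: Trial):
    return (t.subject_id, t.day, t.trial_index)


def load_trials(path, format: str = "auto") -> TrialSet:
    """Read a :class:`TrialSet` from a long CSV or a JSON manifest.

    Parameters
    ----------
    path
        CSV or JSON file.
    format
        ``"long-csv"``, ``"json-manifest"`` or ``"auto"`` (by extension).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "auto":
        format = "json-manifest" if path.suffix.lower() == ".json" else "long-csv"
    if format == "long-csv":
        return _load_long_csv(path)
    if format == "json-manifest":
        return _load_manifest(path)
    raise FormatError(f"unknown format {format!r}")


def _load_long_csv(path: Path) -> TrialSet:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _REQUIRED_LONG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "angle_rad" in df.columns:
        angle_col, scale = "angle_rad", 1.0
    elif "angle_deg" in df.columns:
        angle_col, scale = "angle_deg", math.pi / 180.0
    elif "angle" in df.columns:
        angle_col, scale = "angle", 1.0
    else:
        raise FormatError(f"{path}: missing required column 'angle_rad'")

    joint_names: list[str] | None = None
    trials: list[Trial] = []
    for (subj, day, tr), g in df.groupby(["subject", "day", "trial"], sort=True):
        joints_here = list(dict.fromkeys(g["joint"]))
        if joint_names is None:
            joint_names = joints_here
        elif set(joints_here) != set(joint_names):
            raise StructuralError(
                f"trial {tr} (subject {subj}, day {day}) has joints "
                f"{joints_here}; expected {joint_names}"
            )
        frames = np.sort(g["frame"].unique())
        n = len(frames)
        angles = np.empty((len(joint_names), n))
        for j, joint in enumerate(joint_names):
            gj = g[g["joint"] == joint].sort_values("frame")
            if len(gj) != n:
                raise StructuralError(
                    f"trial {tr} (subject {subj}, day {day}): joint {joint!r} "
                    f"has {len(gj)} frames, expected {n}"
                )
            angles[j] = gj[angle_col].to_numpy() * scale
        release = None
        if "release_frame" in g.columns:
            vals = g["release_frame"].dropna().unique()
            if len(vals) == 1:
                release = int(vals[0])
            elif len(vals) > 1:
                raise StructuralError(
                    f"trial {tr}: inconsistent release_frame values {vals}"
                )
        labels = g["label"].unique()
        if len(labels) != 1:
            raise StructuralError(f"trial {tr}: inconsistent labels {labels}")
        trials.append(
            Trial(
                subject_id=str(subj),
                day=int(day),
                trial_index=int(tr),
                label=int(labels[0]),
                angles=angles,
                release_frame=release,
            )
        )
    if joint_names is None:
        raise FormatError(f"{path}: file contains no trials")
    trials.sort(key=_trials_sort_key)
    return TrialSet(trials=trials, joint_names=joint_names)


def _load_manifest(path: Path) -> TrialSet:
    with open(path) as fh:
        try:
            manifest = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("joint_names", "trials"):
        if key not in manifest:
            raise FormatError(f"{path}: manifest missing key {key!r}")
    joint_names = list(manifest["joint_names"])
    scale = math.pi / 180.0 if manifest.get("angle_units", "rad") == "deg" else 1.0
    base = path.parent
    trials = []
    for entry in manifest["trials"]:
        for key in ("subject", "day", "trial", "label", "file"):
            if key not in entry:
                raise FormatError(f"{path}: trial entry missing key {key!r}")
        tfile = base / entry["file"]
        if not tfile.exists():
            raise StructuralError(
                f"manifest {path}: trial file {entry['file']!r} not found"
            )
        tdf = pd.read_csv(tfile, float_precision="round_trip")
        missing = [j for j in joint_names if j not in tdf.columns]
        if missing:
            raise StructuralError(
                f"trial file {entry['file']!r}: missing joint columns {missing}"
            )
        tdf = tdf.sort_values("frame")
        angles = tdf[joint_names].to_numpy().T * scale
        trials.append(
            Trial(
                subject_id=str(entry["subject"]),
                day=int(entry["day"]),
                trial_index=int(entry["trial"]),
                label=int(entry["label"]),
                angles=angles,
                release_frame=entry.get("release_frame"),
            )
        )
    trials.sort(key=_trials_sort_key)
    return TrialSet(
        trials=trials,
        joint_names=joint_names,
        fs=float(manifest.get("fs", 120.0)),
    )


def write_trials(trialset: TrialSet, path, format: str = "long-csv") -> None:
    """Write a :class:`TrialSet` to disk; round-trips bit-exactly via repr floats."""
    path = Path(path)
    if format != "long-csv":
        raise FormatError(f"unsupported write format {format!r}")
    rows = []
    for t in trialset:
        for j, joint in enumerate(trialset.joint_names):
            for f in range(t.n_frames):
                rows.append(
                    (
                        t.subject_id,
                        t.day,
                        t.trial_index,
                        t.label,
                        joint,
                        f,
                        repr(float(t.angles[j, f])),
                        "" if t.release_frame is None else t.release_frame,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "subject",
            "day",
            "trial",
            "label",
            "joint",
            "frame",
            "angle_rad",
            "release_frame",
        ],
    )
    df.to_csv(path, index=False)


def with_release(trial: Trial, release_frame: int) -> Trial:
    """Copy of ``trial`` with ``release_frame`` set."""
    return replace(trial, release_frame=release_frame)
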