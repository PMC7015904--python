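"""Session-level orchestration: trials -> features -> model -> decomposition -> stats.

One classifier is fitted per recording session (subject, day); the fitted
decomposition is then evaluated per trial subset (e.g. former/latter half
of a session) to build the cell table that the group-level tests consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition import decompose, split_by_estimated_class
from .errors import IncompleteDesignError
from .features import build_feature_matrix, zscore
from .logistic import LogisticModel, cross_validate, fit
from .stats import (
    AnovaResult,
    assign_parts,
    paired_ttest,
    rm_anova_2x2,
    task_relevant_stats,
)
from .trials import TrialSet

__all__ = ["SessionFit", "fit_session", "session_stats", "ModulationReport", "modulation_report"]


@dataclass
class SessionFit:
    """Fitted classifier and normalized features for one (subject, day)."""

    subject_id: str
    day: int
    model: LogisticModel
    features: "object"  # normalized FeatureMatrix
    labels: np.ndarray
    cv: "object"  # CVResult or None
    window_frames: int


def fit_session(
    session: TrialSet,
    window_frames: int = 17,
    lambda_grid=None,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    lam: float | None = None,
    include_anchor: bool = True,
    anchor: str = "release",
) -> SessionFit:
    """Build features for one session, select lambda by CV (unless ``lam``
    is given) and fit the final model on the full normalized matrix."""
    fm_raw, d = build_feature_matrix(
        session, window_frames, anchor=anchor, include_anchor=include_anchor
    )
    fm = zscore(fm_raw)
    cv = None
    if lam is None:
        cv = cross_validate(
            fm_raw, d, lambda_grid=lambda_grid, k=k, repeats=repeats, seed=seed
        )
        lam = cv.chosen_lambda
    model = fit(fm, d, lam=lam)
    t0 = session.trials[0]
    return SessionFit(
        subject_id=t0.subject_id,
        day=t0.day,
        model=model,
        features=fm,
        labels=np.asarray(d),
        cv=cv,
        window_frames=window_frames,
    )


def session_stats(
    sfit: SessionFit,
    part_fraction: float = 0.5,
    trial_indices=None,
    split_by: str = "estimated",
) -> pd.DataFrame:
    """Per-(part) task-relevant statistics for one fitted session.

    The session's trials are split into former/latter halves by trial
    index; the decomposition uses the session's single fitted model, and
    statistics are computed within each part.
    """
    fm = sfit.features
    dec = decompose(fm, sfit.model)
    if trial_indices is None:
        trial_indices = np.arange(fm.n_trials)
    parts = assign_parts(trial_indices, fraction=part_fraction)
    rows = []
    for part in ("former", "latter"):
        mask = parts == part
        from .features import FeatureMatrix

        sub_fm = FeatureMatrix(
            X=fm.X[mask],
            column_map=list(fm.column_map),
            window_frames=fm.window_frames,
            anchor=fm.anchor,
        )
        sub_dec = decompose(sub_fm, sfit.model)
        split = split_by_estimated_class(
            sub_dec,
            sfit.model,
            sub_fm,
            by=split_by,
            true_labels=sfit.labels[mask] if split_by == "true" else None,
        )
        st = task_relevant_stats(split, sfit.model.w)
        rows.append(
            {
                "subject": sfit.subject_id,
                "day": sfit.day,
                "part": part,
                "difference": st.difference,
                "variability": st.variability,
                "dprime": st.dprime,
                "T0": st.T0,
                "T1": st.T1,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ModulationReport:
    """Group-level outcome: cell stats, paired tests, ANOVA + post hoc."""

    cells: pd.DataFrame
    ttest_difference: "object"  # PairedTTestResult (day 1 vs day 2) or None
    ttest_variability: "object"
    anova_difference: AnovaResult | None
    anova_variability: AnovaResult | None


def modulation_report(cells: pd.DataFrame) -> ModulationReport:
    """Hypothesis tests on a per-(subject, day, part) cell table.

    Requires columns subject, day, part, difference, variability.  The
    paired t-tests compare per-subject day means; the 2x2 within-subject
    ANOVA (Part x Day) with Tukey post hoc runs when both days and both
    parts are present for every subject.
    """
    required = {"subject", "day", "part", "difference", "variability"}
    missing = required - set(cells.columns)
    if missing:
        raise IncompleteDesignError(f"cell table missing columns {sorted(missing)}")
    days = sorted(cells["day"].unique())
    tt_diff = tt_var = an_diff = an_var = None
    if len(days) == 2:
        per_subj = (
            cells.groupby(["subject", "day"])[["difference", "variability"]]
            .mean()
            .reset_index()
        )
        piv_d = per_subj.pivot(index="subject", columns="day", values="difference")
        piv_v = per_subj.pivot(index="subject", columns="day", values="variability")
        if not piv_d.isna().any().any():
            tt_diff = paired_ttest(piv_d[days[0]], piv_d[days[1]])
            tt_var = paired_ttest(piv_v[days[0]], piv_v[days[1]])
        if set(cells["part"].unique()) == {"former", "latter"} and len(cells) >= 12:
            try:
                an_diff = rm_anova_2x2(
                    cells, subject="subject", factor_a="part",
                    factor_b="day", value="difference",
                )
                an_var = rm_anova_2x2(
                    cells, subject="subject", factor_a="part",
                    factor_b="day", value="variability",
                )
            except IncompleteDesignError:
                pass
    return ModulationReport(
        cells=cells,
        ttest_difference=tt_diff,
        ttest_variability=tt_var,
        anova_difference=an_diff,
        anova_variability=an_var,
    )
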