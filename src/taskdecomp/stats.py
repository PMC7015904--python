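"""Outcome measures on the task-relevant components and their hypothesis tests.

Because every row of X_rel lies on the line spanned by w, its statistics
reduce to statistics of the scalar scores s_t = X_t w / |w|.  For the two
predicted-class groups g in {0, 1} with means m_g and sample variances v_g:

* task-relevant difference  = |m_1 - m_0|   (between-class mean separation);
* task-relevant variability = (v_0 + v_1)/2 (average within-class variance);
* d' = |m_1 - m_0| / sqrt((v_0 + v_1)/2)    (signal-detection sensitivity).

A smaller d' means the two motion categories are harder to discriminate;
d' can shrink through a smaller mean separation ("mean modulation") or a
larger within-class variance ("variability modulation").

Group-level inference uses paired t-tests across subjects and a balanced
2x2 within-subject ANOVA with factors Part (former/latter trials of a day)
and Day, followed by Tukey-corrected pairwise comparisons among the four
cells using the pooled within-subject error term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decomposition import ClassSplit
from .errors import (
    DataError,
    IncompleteDesignError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "TaskStats",
    "task_relevant_stats",
    "dprime",
    "PairedTTestResult",
    "paired_ttest",
    "AnovaResult",
    "rm_anova_2x2",
    "assign_parts",
]


@dataclass
class TaskStats:
    """Task-relevant difference / variability / d' for one trial group."""

    difference: float
    variability: float
    dprime: float
    group_means: tuple
    group_vars: tuple
    T0: int
    T1: int
    degenerate_variance: bool = False
    irr_total_variance: float = np.nan  # total variance of X_irr (audit only)


def task_relevant_stats(split: ClassSplit, w) -> TaskStats:
    """Scalar-score statistics of the per-class task-relevant components.

    Scores are projections onto the unit direction w/|w|, so the result is
    invariant to rescaling w.  Both groups need at least two trials for a
    variance; a zero pooled variance is flagged rather than producing an
    infinite d' silently.
    """
    w = np.asarray(w, dtype=float).ravel()
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ParameterError("w must be nonzero")
    if split.T0 < 2 or split.T1 < 2:
        group = "0 (fastball)" if split.T0 < 2 else "1 (breaking ball)"
        raise InsufficientDataError(
            f"group {group} has fewer than 2 trials "
            f"(T0={split.T0}, T1={split.T1}); variance undefined"
        )
    u = w / nrm
    s0 = split.X_rel_0 @ u
    s1 = split.X_rel_1 @ u
    m0, m1 = float(s0.mean()), float(s1.mean())
    v0, v1 = float(s0.var(ddof=1)), float(s1.var(ddof=1))
    diff = abs(m1 - m0)
    var = 0.5 * (v0 + v1)
    degenerate = var <= 0.0
    dp = math.inf if degenerate else diff / math.sqrt(var)
    x_irr = np.vstack([split.X_irr_0, split.X_irr_1])
    return TaskStats(
        difference=diff,
        variability=var,
        dprime=dp,
        group_means=(m0, m1),
        group_vars=(v0, v1),
        T0=split.T0,
        T1=split.T1,
        degenerate_variance=degenerate,
        irr_total_variance=float(x_irr.var(axis=0, ddof=1).sum()),
    )


def dprime(m0: float, m1: float, sigma: float, signed: bool = False) -> float:
    """Sensitivity index (m1 - m0) / sigma; absolute value unless ``signed``."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    d = (m1 - m0) / sigma
    return d if signed else abs(d)


@dataclass
class PairedTTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_ttest(a, b) -> PairedTTestResult:
    """Two-sided paired t-test on per-subject values.

    Zero-variance differences are guarded: identical samples give t=0, p=1;
    a constant nonzero difference gives |t|=inf, p=0 — both flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired samples must be 1-D and equal length")
    n = len(a)
    if n < 2:
        raise InsufficientDataError("paired t-test needs n >= 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if diff[0] == 0.0:
            return PairedTTestResult(t=0.0, df=n - 1, p=1.0, degenerate=True)
        t = math.inf if diff[0] > 0 else -math.inf
        return PairedTTestResult(t=t, df=n - 1, p=0.0, degenerate=True)
    t = float(diff.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return PairedTTestResult(t=t, df=n - 1, p=p)


@dataclass
class AnovaResult:
    """Within-subject ANOVA table plus Tukey-corrected cell comparisons."""

    table: pd.DataFrame  # source, SS, df, MS, F, p
    posthoc: pd.DataFrame  # cell_a, cell_b, diff, q, p_tukey
    cell_means: pd.DataFrame


def _to_cells(data, subject, factor_a, factor_b, value):
    """(n, 2, 2) array of cell values, level names, subject order."""
    if isinstance(data, pd.DataFrame):
        levels_a = sorted(data[factor_a].unique())
        levels_b = sorted(data[factor_b].unique())
        subjects = sorted(data[subject].unique())
        if len(levels_a) != 2 or len(levels_b) != 2:
            raise IncompleteDesignError(
                f"need exactly 2 levels per factor; got {factor_a}={levels_a}, "
                f"{factor_b}={levels_b}"
            )
        arr = np.full((len(subjects), 2, 2), np.nan)
        for (s, la, lb), g in data.groupby([subject, factor_a, factor_b]):
            if len(g) != 1:
                raise IncompleteDesignError(
                    f"cell ({s}, {la}, {lb}) has {len(g)} rows; expected 1"
                )
            arr[subjects.index(s), levels_a.index(la), levels_b.index(lb)] = g[
                value
            ].iloc[0]
        if np.isnan(arr).any():
            missing = np.argwhere(np.isnan(arr))[0]
            raise IncompleteDesignError(
                f"missing cell: subject {subjects[missing[0]]}, "
                f"{factor_a}={levels_a[missing[1]]}, {factor_b}={levels_b[missing[2]]}"
            )
        return arr, levels_a, levels_b, subjects
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 3 or arr.shape[1:] != (2, 2):
        raise IncompleteDesignError(
            f"array input must have shape (n_subjects, 2, 2); got {arr.shape}"
        )
    if np.isnan(arr).any():
        raise IncompleteDesignError("design contains missing cells (NaN)")
    n = arr.shape[0]
    return arr, ["a1", "a2"], ["b1", "b2"], list(range(n))


def _f_p(ss_eff, df_eff, ss_err, df_err):
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err == 0.0:
        if ms_eff == 0.0:
            return 0.0, 1.0  # completely null data
        return math.inf, 0.0
    f = ms_eff / ms_err
    return f, float(sps.f.sf(f, df_eff, df_err))


def rm_anova_2x2(
    data,
    subject: str = "subject",
    factor_a: str = "part",
    factor_b: str = "day",
    value: str = "value",
) -> AnovaResult:
    """Balanced 2x2 within-subject ANOVA with per-effect error terms.

    ``data`` is either a long DataFrame (one row per subject x cell) or an
    (n_subjects, 2, 2) array.  Each main effect and the interaction is
    tested against its own effect-by-subject mean square (the standard
    univariate repeated-measures partition; with 2-level factors sphericity
    holds trivially).  Tukey comparisons among the four cell means use the
    pooled within-subject error term, with the alternative of
    Tukey-corrected pairwise paired t-tests available downstream.
    """
    arr, levels_a, levels_b, subjects = _to_cells(
        data, subject, factor_a, factor_b, value
    )
    n = arr.shape[0]
    if n < 3:
        raise InsufficientDataError(f"need >= 3 subjects, got {n}")
    gm = arr.mean()
    subj_m = arr.mean(axis=(1, 2))
    a_m = arr.mean(axis=(0, 2))  # per level of A
    b_m = arr.mean(axis=(0, 1))
    cell_m = arr.mean(axis=0)  # (2, 2)
    ia_m = arr.mean(axis=2)  # (n, 2) subject x A
    ib_m = arr.mean(axis=1)  # (n, 2) subject x B

    ss_subj = 4.0 * np.sum((subj_m - gm) ** 2)
    ss_a = 2.0 * n * np.sum((a_m - gm) ** 2)
    ss_b = 2.0 * n * np.sum((b_m - gm) ** 2)
    ss_ab = n * np.sum(
        (cell_m - a_m[:, None] - b_m[None, :] + gm) ** 2
    )
    ss_as = 2.0 * np.sum(
        (ia_m - a_m[None, :] - subj_m[:, None] + gm) ** 2
    )
    ss_bs = 2.0 * np.sum(
        (ib_m - b_m[None, :] - subj_m[:, None] + gm) ** 2
    )
    resid = (
        arr
        - ia_m[:, :, None]
        - ib_m[:, None, :]
        - cell_m[None, :, :]
        + a_m[None, :, None]
        + b_m[None, None, :]
        + subj_m[:, None, None]
        - gm
    )
    ss_abs = float(np.sum(resid**2))

    dfe = n - 1
    fa, pa = _f_p(ss_a, 1, ss_as, dfe)
    fb, pb = _f_p(ss_b, 1, ss_bs, dfe)
    fab, pab = _f_p(ss_ab, 1, ss_abs, dfe)
    table = pd.DataFrame(
        {
            "source": [
                "subject",
                factor_a,
                f"{factor_a} x subject",
                factor_b,
                f"{factor_b} x subject",
                f"{factor_a} x {factor_b}",
                f"{factor_a} x {factor_b} x subject",
            ],
            "SS": [ss_subj, ss_a, ss_as, ss_b, ss_bs, ss_ab, ss_abs],
            "df": [dfe, 1, dfe, 1, dfe, 1, dfe],
        }
    )
    table["MS"] = table["SS"] / table["df"]
    table["F"] = [np.nan, fa, np.nan, fb, np.nan, fab, np.nan]
    table["p"] = [np.nan, pa, np.nan, pb, np.nan, pab, np.nan]

    # Tukey HSD among the four cells, pooled within-subject error
    ms_pool = (ss_as + ss_bs + ss_abs) / (3 * dfe)
    df_pool = 3 * dfe
    cells = [
        (f"{la}/{lb}", cell_m[i, j])
        for i, la in enumerate(levels_a)
        for j, lb in enumerate(levels_b)
    ]
    rows = []
    se = math.sqrt(ms_pool / n) if ms_pool > 0 else 0.0
    for i in range(4):
        for j in range(i + 1, 4):
            diff = cells[i][1] - cells[j][1]
            if se > 0:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, 4, df_pool))
            else:
                q = 0.0 if diff == 0 else math.inf
                p = 1.0 if diff == 0 else 0.0
            rows.append(
                {
                    "cell_a": cells[i][0],
                    "cell_b": cells[j][0],
                    "diff": diff,
                    "q": q,
                    "p_tukey": p,
                }
            )
    posthoc = pd.DataFrame(rows)
    cell_means = pd.DataFrame(
        cell_m, index=pd.Index(levels_a, name=factor_a),
        columns=pd.Index(levels_b, name=factor_b),
    )
    return AnovaResult(table=table, posthoc=posthoc, cell_means=cell_means)


def assign_parts(trial_indices, fraction: float = 0.5) -> np.ndarray:
    """Label trials 'former'/'latter' by rank order within a session.

    The first ``fraction`` of trials (by trial index; ties broken by
    position) are 'former' — with 100 trials and the default 0.5 this is
    trials 1-50 vs 51-100.
    """
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"fraction must be in (0, 1), got {fraction}")
    idx = np.asarray(trial_indices)
    order = np.argsort(idx, kind="stable")
    n_former = int(math.ceil(len(idx) * fraction))
    out = np.empty(len(idx), dtype=object)
    out[order[:n_former]] = "former"
    out[order[n_former:]] = "latter"
    return out.astype(str)
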