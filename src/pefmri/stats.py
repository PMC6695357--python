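"""Group-level statistical battery for ROI contrast values.

Operates on a tidy table of COPE records — one scalar per subject x
session x ROI x contrast — and reproduces the analysis battery of a
two-group (control/OCD), three-session (placebo/amisulpride/pramipexole)
pharmacological design:

* pooled 3-SD outlier exclusion (listwise by subject, per ROI x contrast),
* mixed group x session ANOVA with partial eta squared,
* Bonferroni-corrected within-group session post-hocs,
* per-session univariate (one-way) group ANOVAs,
* a dichotomized SSRI-dose between factor within the patient group,
* Spearman correlations between contrast values and trait scales.

Repeated-measures machinery is delegated to :mod:`pingouin`; the one-way
ANOVA, outlier rule and effect sizes are computed directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "ExclusionReport",
    "exclude_outliers",
    "mixed_anova",
    "posthoc_within",
    "univariate_by_session",
    "medication_factor_anova",
    "spearman_corr",
]

RECORD_COLUMNS = ("subject_id", "group", "session", "roi", "contrast", "value")


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class PairwiseResult:
    pair: Tuple[str, str]
    mean_a: float
    mean_b: float
    t: float
    p_raw: float
    p_adj: float


@dataclass
class ExclusionReport:
    k: float
    excluded: List[str]
    offending: pd.DataFrame  # subject_id, session, value, z


def _check_records(records: pd.DataFrame) -> None:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")


def exclude_outliers(
    records: pd.DataFrame, k: float = 3.0
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], ExclusionReport]]:
    """Pooled k-SD outlier rule, listwise by subject.

    For each ROI x contrast, the mean and SD pool every value — both
    groups, all sessions. A subject whose value in *any* session lies
    strictly more than ``k`` SDs from that pooled mean is dropped from
    that ROI x contrast analysis entirely (all sessions). Returns the
    kept table and one report per ROI x contrast.
    """
    _check_records(records)
    if len(records) < 4:
        raise ValueError("need at least 4 records")
    reports: Dict[Tuple[str, str], ExclusionReport] = {}
    kept_parts = []
    for (roi, contrast), part in records.groupby(["roi", "contrast"], sort=False):
        mean = part["value"].mean()
        sd = part["value"].std(ddof=1)
        z = (part["value"] - mean) / sd
        offending = part.loc[np.abs(z) > k, ["subject_id", "session", "value"]].copy()
        offending["z"] = z[np.abs(z) > k]
        bad_subjects = sorted(offending["subject_id"].unique())
        reports[(roi, contrast)] = ExclusionReport(k, bad_subjects, offending)
        kept_parts.append(part[~part["subject_id"].isin(bad_subjects)])
    return pd.concat(kept_parts, ignore_index=True), reports


def _require_complete(records: pd.DataFrame) -> None:
    counts = records.groupby("subject_id")["session"].nunique()
    if counts.nunique() > 1:
        raise ValueError(
            "subjects with missing sessions; exclusion must be listwise upstream"
        )


def mixed_anova(
    records: pd.DataFrame,
    dv: str = "value",
    within: str = "session",
    between: str = "group",
    subject: str = "subject_id",
    correction: bool = False,
) -> List[AnovaResult]:
    """Mixed-design ANOVA: between-group factor x within-subject session.

    Returns the group main effect, session main effect and interaction,
    each with F, numerator/denominator dfs, p and partial eta squared
    (SS_effect / (SS_effect + SS_error)). Plain (uncorrected) dfs by
    default; ``correction=True`` applies Greenhouse-Geisser to the
    within-subject effects.
    """
    _require_complete(records)
    aov = pg.mixed_anova(
        data=records,
        dv=dv,
        within=within,
        subject=subject,
        between=between,
        correction=correction,
    )
    out = []
    for _, row in aov.iterrows():
        name = {between: "group", within: "session"}.get(
            row["Source"], "interaction"
        )
        p = row["p_unc"]
        if correction and "p_GG_corr" in aov.columns and np.isfinite(
            row.get("p_GG_corr", np.nan)
        ):
            p = row["p_GG_corr"]
        out.append(
            AnovaResult(
                name,
                float(row["F"]),
                float(row["DF1"]),
                float(row["DF2"]),
                float(p),
                float(row["np2"]),
            )
        )
    return out


def rm_anova_one_group(
    records: pd.DataFrame,
    dv: str = "value",
    within: str = "session",
    subject: str = "subject_id",
) -> AnovaResult:
    """One-way repeated-measures ANOVA (session effect within one group)."""
    _require_complete(records)
    aov = pg.rm_anova(
        data=records, dv=dv, within=within, subject=subject, detailed=True,
        effsize="np2",
    )
    row = aov.iloc[0]
    return AnovaResult(
        "session",
        float(row["F"]),
        float(row["DF"]),
        float(aov.iloc[1]["DF"]),
        float(row["p_unc"]),
        float(row["np2"]),
    )


def posthoc_within(
    records: pd.DataFrame, sessions: Optional[Sequence[str]] = None
) -> Tuple[AnovaResult, List[PairwiseResult]]:
    """Within-group drug effect: RM ANOVA plus Bonferroni paired post-hocs.

    Pairwise paired t-tests for every session pair; adjusted
    ``p = min(1, m * p_raw)`` with ``m`` the number of pairs (3 for the
    standard three-session design).
    """
    _require_complete(records)
    if sessions is None:
        sessions = list(pd.unique(records["session"]))
    if len(sessions) < 2:
        raise ValueError("need at least two sessions")
    omnibus = rm_anova_one_group(records)
    wide = records.pivot(index="subject_id", columns="session", values="value")
    m = len(sessions) * (len(sessions) - 1) // 2
    pairs = []
    for i, a in enumerate(sessions):
        for b in sessions[i + 1 :]:
            diff = wide[a] - wide[b]
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(wide[a], wide[b])
            pairs.append(
                PairwiseResult(
                    (a, b),
                    float(wide[a].mean()),
                    float(wide[b].mean()),
                    float(t),
                    float(p),
                    float(min(1.0, m * p)),
                )
            )
    return omnibus, pairs


def univariate_by_session(records: pd.DataFrame, session: str) -> AnovaResult:
    """One-way two-group ANOVA on a single session's values.

    Computed from the sums-of-squares decomposition; cross-checked
    against the two-sample equal-variance t statistic (F = t^2).
    """
    part = records[records["session"] == session]
    groups = [g["value"].to_numpy() for _, g in part.groupby("group", sort=False)]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need exactly two non-empty groups")
    allv = np.concatenate(groups)
    ss_between = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_num, df_den = 1, len(allv) - 2
    if ss_within == 0.0:
        F = 0.0 if ss_between == 0.0 else float("inf")
    else:
        F = (ss_between / df_num) / (ss_within / df_den)
    t = sps.ttest_ind(groups[0], groups[1], equal_var=True).statistic
    if np.isfinite(F) and not np.isclose(F, t**2, rtol=1e-8, atol=1e-12):
        raise AssertionError("one-way F does not equal t^2; internal error")
    p = float(sps.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    eta = ss_between / (ss_between + ss_within) if (ss_between + ss_within) else 0.0
    return AnovaResult("group", float(F), df_num, df_den, p, float(eta))


def medication_factor_anova(
    records: pd.DataFrame, med_class: pd.Series
) -> List[AnovaResult]:
    """Session x dichotomized-medication ANOVA within the patient group.

    ``med_class`` maps subject_id -> "high"/"not_high". If only one class
    is present the between effect is skipped with a warning and only the
    session effect is returned.
    """
    _require_complete(records)
    df = records.copy()
    df["med_class"] = df["subject_id"].map(med_class)
    if df["med_class"].isna().any():
        raise ValueError("med_class missing for some subjects")
    if df["med_class"].nunique() < 2:
        warnings.warn("single medication class; between effect skipped")
        return [rm_anova_one_group(df)]
    return mixed_anova(df, between="med_class")


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation with average-rank tie handling.

    p-value from the t approximation for n > 10, otherwise from a seeded
    permutation test (the approximation is unreliable at small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need paired samples, n >= 5")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance; correlation undefined")
    rho, p = sps.spearmanr(x, y)
    if len(x) <= 10:
        res = sps.permutation_test(
            (x, y),
            lambda a, b: sps.spearmanr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=5000,
            random_state=0,
        )
        p = float(res.pvalue)
    return float(rho), float(p)
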