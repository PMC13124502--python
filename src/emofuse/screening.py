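"""Repeated-measures ANOVA machinery for group analysis and feature screening.

One-way repeated-measures ANOVA over the three emotional conditions with
Greenhouse–Geisser sphericity correction and Tukey HSD post-hoc tests.
The same machinery serves two purposes: group-level sensitivity analysis
of the eleven physiological features (and the SAM ratings), and
fold-embedded feature selection, where the ANOVA runs on the training
trials of a cross-validation fold only and features with a corrected
p-value below alpha are retained for modeling.

Trials are aggregated to participant × condition means before the ANOVA,
so the observational unit is the participant (df = (k−1, (n−1)(k−1))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = [
    "RMAnovaResult",
    "ScreeningResult",
    "build_design_matrix",
    "rm_anova",
    "tukey_hsd_rm",
    "screen_features",
    "categorize_video",
]

CONDITIONS = ("positive", "neutral", "negative")
DEFAULT_ALPHA = 0.05
MIN_SELECTED = 2
FALLBACK_K = 3


@dataclass
class RMAnovaResult:
    F: float
    df1: float
    df2: float
    p_uncorrected: float
    epsilon_gg: float
    p_gg: float
    eta_sq: float  # partial eta squared
    ms_error: float
    defined: bool = True


@dataclass
class ScreeningResult:
    """Per-feature screening outcome for one fold (or the full dataset)."""

    anova: dict[str, RMAnovaResult]
    selected: list[str]
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    dropped_participants: list[str] = field(default_factory=list)
    fallback_used: bool = False


def build_design_matrix(
    table: pd.DataFrame, feature: str, conditions: tuple[str, ...] = CONDITIONS
) -> tuple[np.ndarray, list[str], list[str]]:
    """Participant × condition matrix of per-cell trial means.

    Participants missing any condition cell (or with an all-NaN cell) are
    dropped and reported. Returns (matrix, participant ids, dropped ids).
    """
    cell = table.pivot_table(
        index="participant", columns="label", values=feature, aggfunc="mean"
    )
    missing = [c for c in conditions if c not in cell.columns]
    if missing:
        raise ValueError(f"conditions absent from the table: {missing}")
    cell = cell[list(conditions)]
    ok = cell.notna().all(axis=1)
    dropped = [str(p) for p in cell.index[~ok]]
    cell = cell.loc[ok]
    if len(cell) < 3:
        raise ValueError("need at least 3 complete participants")
    return cell.to_numpy(float), [str(p) for p in cell.index], dropped


def rm_anova(design: np.ndarray) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on an n × k design matrix.

    Classical within-subject partition: SS_error = SS_within − SS_subjects,
    F = MS_cond / MS_error with df (k−1, (n−1)(k−1)). The Greenhouse–Geisser
    epsilon comes from the double-centered condition covariance matrix,
    epsilon = tr(S)² / ((k−1)·tr(S²)), clipped to [1/(k−1), 1]; the
    corrected p evaluates F at epsilon-scaled dfs. Effect size is partial
    eta² = SS_cond / (SS_cond + SS_error). Zero error variance yields an
    undefined (degenerate) result.
    """
    y = np.asarray(design, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("design must be n >= 2 participants x k >= 2 conditions")
    n, k = y.shape
    grand = y.mean()
    cond_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_error = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1.0, (n - 1.0) * (k - 1.0)
    ms_cond = ss_cond / df1
    ms_error = ss_error / df2

    if ms_error <= 1e-12 * max(ms_cond, 1.0):
        if ms_cond <= 1e-12 * max(abs(grand), 1.0):
            # no condition effect and no error variance: F is 0, not undefined
            return RMAnovaResult(0.0, df1, df2, 1.0, 1.0, 1.0, 0.0, 0.0)
        return RMAnovaResult(
            float("nan"), df1, df2, float("nan"), float("nan"), float("nan"),
            float("nan"), float(ms_error), defined=False,
        )

    F = ms_cond / ms_error
    p = float(stats.f.sf(F, df1, df2))

    # Greenhouse-Geisser epsilon from the double-centered covariance
    S = np.cov(y, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    tr = np.trace(Sc)
    denom = (k - 1) * float(np.sum(Sc * Sc))
    eps = float(tr**2 / denom) if denom > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
    eta = float(ss_cond / (ss_cond + ss_error))
    return RMAnovaResult(float(F), df1, df2, p, eps, p_gg, eta, float(ms_error))


def tukey_hsd_rm(
    design: np.ndarray,
    ms_error: float,
    df_error: float,
    conditions: tuple[str, ...] = CONDITIONS,
) -> pd.DataFrame:
    """Tukey HSD pairwise table using the omnibus repeated-measures MS_error.

    q = |mean_i − mean_j| / sqrt(MS_error / n); p from the studentized
    range distribution with k groups and df_error degrees of freedom.
    """
    y = np.asarray(design, dtype=float)
    n, k = y.shape
    means = y.mean(axis=0)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if ms_error <= 0:
                q, p = float("nan"), float("nan")
            else:
                q = abs(diff) / np.sqrt(ms_error / n)
                p = float(stats.studentized_range.sf(q, k, df_error))
            rows.append(
                {
                    "pair": f"{conditions[i]} - {conditions[j]}",
                    "difference": float(diff),
                    "q": float(q),
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def screen_features(
    training_trials: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    features: tuple[str, ...] = FEATURE_NAMES,
    *,
    posthoc: bool = False,
) -> ScreeningResult:
    """ANOVA-based feature selection on training trials only.

    Builds the participant × condition design per feature, runs the
    repeated-measures ANOVA and keeps features with GG-corrected p < alpha.
    If fewer than two features pass, the three smallest-p features are
    taken instead (logged via ``fallback_used``) so downstream PCA always
    has something to work with.
    """
    results: dict[str, RMAnovaResult] = {}
    posthocs: dict[str, pd.DataFrame] = {}
    dropped: set[str] = set()
    pvals: dict[str, float] = {}
    for feat in features:
        design, _, drp = build_design_matrix(training_trials, feat)
        dropped.update(drp)
        res = rm_anova(design)
        results[feat] = res
        pvals[feat] = res.p_gg if res.defined else float("inf")
        if posthoc and res.defined:
            posthocs[feat] = tukey_hsd_rm(design, res.ms_error, res.df2)

    selected = [f for f in features if results[f].defined and results[f].p_gg < alpha]
    fallback = False
    if len(selected) < MIN_SELECTED:
        fallback = True
        ranked = sorted(features, key=lambda f: pvals[f])
        selected = list(ranked[:FALLBACK_K])
    return ScreeningResult(
        anova=results,
        selected=selected,
        posthoc=posthocs,
        dropped_participants=sorted(dropped),
        fallback_used=fallback,
    )


def categorize_video(valence: float, arousal: float) -> str:
    """Assign a stimulus category from mean SAM ratings.

    positive: valence > 7 and arousal > 6; negative: valence < 3 and
    arousal > 6; neutral: valence in [4, 6] and arousal < 4; otherwise
    ``"none"``. Ratings must lie on the 1–9 scale.
    """
    if not (1.0 <= valence <= 9.0 and 1.0 <= arousal <= 9.0):
        raise ValueError("ratings must lie in [1, 9]")
    if valence > 7.0 and arousal > 6.0:
        return "positive"
    if valence < 3.0 and arousal > 6.0:
        return "negative"
    if 4.0 <= valence <= 6.0 and arousal < 4.0:
        return "neutral"
    return "none"
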