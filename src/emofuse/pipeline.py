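"""End-to-end glue: trials → cleaned signals → feature tables → analysis.

``extract_feature_tables`` takes trial records grouped by participant
(GSR normalization constants are pooled per participant, label-blind),
runs the per-modality preprocessing and feature extraction, and returns
the two tables the analysis consumes:

* trial table — one row per trial, full-trial features (screening input),
* window table — one row per trial × window (classifier input),

plus a per-trial quality log (rejections, ectopic corrections, bad
channels). ``simulate_and_extract`` wires the synthetic generator in
front of it; ``group_level_stats`` reproduces the group analysis
(repeated-measures ANOVA with Greenhouse–Geisser correction and Tukey
post-hoc tests) for the SAM ratings and all eleven features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, Windowing, extract_features
from .preprocess import (
    correct_ectopics,
    detect_r_peaks,
    participant_gsr_stats,
    preprocess_eeg,
    preprocess_gsr,
    rr_from_peaks,
)
from .screening import rm_anova, build_design_matrix, tukey_hsd_rm
from .synth import SynthConfig, TrialRecord, generate_experiment

__all__ = [
    "QualityLog",
    "extract_feature_tables",
    "simulate_and_extract",
    "group_level_stats",
]

META_COLUMNS = ("participant", "trial", "label", "sam_valence", "sam_arousal")


@dataclass
class QualityLog:
    excluded: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)

    def note(self, trial_id: str, **info) -> None:
        self.events.append({"trial": trial_id, **info})

    def exclude(self, trial_id: str, reason: str) -> None:
        self.excluded.append({"trial": trial_id, "reason": reason})


def extract_feature_tables(
    trials: list[TrialRecord], windowing: Windowing = Windowing()
) -> tuple[pd.DataFrame, pd.DataFrame, QualityLog]:
    """Preprocess every trial and emit (trial table, window table, log).

    Trials with a rejected EEG epoch (or an unusable ECG) are excluded and
    logged, never silently dropped.
    """
    log = QualityLog()
    by_participant: dict[str, list[TrialRecord]] = {}
    for tr in trials:
        by_participant.setdefault(tr.participant_id, []).append(tr)

    trial_rows: list[dict] = []
    window_rows: list[dict] = []
    for pid, recs in by_participant.items():
        gsr_stats = participant_gsr_stats([r.gsr for r in recs], recs[0].gsr_fs)
        for tr in recs:
            clean_eeg = preprocess_eeg(tr.eeg, tr.eeg_fs)
            if clean_eeg.rejected:
                log.exclude(tr.trial_id, "EEG epoch rejected (amplitude threshold)")
                continue
            if clean_eeg.bad_channels:
                log.note(tr.trial_id, bad_channels=clean_eeg.bad_channels)

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                peaks = detect_r_peaks(tr.ecg, tr.ecg_fs)
            rr = rr_from_peaks(peaks)
            if rr.size < 10:
                log.exclude(tr.trial_id, "too few detected heartbeats")
                continue
            nn = correct_ectopics(rr)
            if nn.n_corrected:
                log.note(tr.trial_id, n_corrected=nn.n_corrected, low_quality=nn.low_quality)

            clean_gsr = preprocess_gsr(tr.gsr, tr.gsr_fs, gsr_stats)

            trial_vec, seq = extract_features(tr, clean_eeg, nn, clean_gsr, windowing)
            meta = {
                "participant": pid,
                "trial": tr.trial_id,
                "label": tr.label,
                "sam_valence": tr.sam_valence,
                "sam_arousal": tr.sam_arousal,
            }
            trial_rows.append({**meta, "window_index": -1, **trial_vec})
            for wi, vec in enumerate(seq):
                window_rows.append({**meta, "window_index": wi, **vec})

    cols = [*META_COLUMNS, "window_index", *FEATURE_NAMES]
    trial_table = pd.DataFrame(trial_rows, columns=cols)
    window_table = pd.DataFrame(window_rows, columns=cols)
    return trial_table, window_table, log


def simulate_and_extract(
    config: SynthConfig, windowing: Windowing = Windowing()
) -> tuple[pd.DataFrame, pd.DataFrame, QualityLog]:
    """Generate a synthetic experiment and extract its feature tables."""
    return extract_feature_tables(generate_experiment(config), windowing)


def group_level_stats(trial_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Group-level repeated-measures ANOVA for ratings and features.

    One row per measure (sam_valence, sam_arousal and the eleven
    physiological features): F, dfs, uncorrected and GG-corrected p,
    epsilon, partial eta² and the Tukey pairwise p-values.
    """
    if trial_table["label"].nunique() < 3:
        raise ValueError("group statistics need all three conditions")
    measures = ["sam_valence", "sam_arousal", *FEATURE_NAMES]
    rows = []
    for m in measures:
        design, _, _ = build_design_matrix(trial_table, m)
        res = rm_anova(design)
        row = {
            "measure": m,
            "F": res.F,
            "df1": res.df1,
            "df2": res.df2,
            "p": res.p_uncorrected,
            "epsilon_gg": res.epsilon_gg,
            "p_gg": res.p_gg,
            "partial_eta_sq": res.eta_sq,
            "significant": bool(res.defined and res.p_gg < alpha),
        }
        if res.defined:
            ph = tukey_hsd_rm(design, res.ms_error, res.df2)
            for _, r in ph.iterrows():
                row[f"p_tukey[{r['pair']}]"] = r["p"]
        rows.append(row)
    return pd.DataFrame(rows)
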