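"""File formats: trial-set directories, feature tables, run reports.

A trial set is a directory with one subdirectory per trial holding one
CSV per modality (``eeg.csv`` with header ``time_s,FP1,...``; ``ecg.csv``
and ``gsr.csv`` with ``time_s,value``), a ``ground_truth.json``, and a
top-level ``manifest.tsv`` (participant, trial, label, valence, arousal).
Feature tables are TSV with the fixed 11-feature column order. Run
reports are JSON plus a human-readable markdown summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import CVResult
from .features import FEATURE_NAMES
from .synth import EEG_CHANNELS, TrialRecord

__all__ = [
    "write_trial_set",
    "read_trial_set",
    "write_feature_table",
    "read_feature_table",
    "write_run_report",
    "render_markdown_report",
]


def write_trial_set(trials: list[TrialRecord], out_dir: str | Path) -> Path:
    """Write a trial set; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for tr in trials:
        tdir = out / tr.trial_id
        tdir.mkdir(exist_ok=True)
        t_eeg = np.arange(tr.eeg.shape[1]) / tr.eeg_fs
        eeg = pd.DataFrame({"time_s": t_eeg})
        for ci, ch in enumerate(EEG_CHANNELS):
            eeg[ch] = tr.eeg[ci]
        eeg.to_csv(tdir / "eeg.csv", index=False)
        pd.DataFrame(
            {"time_s": np.arange(tr.ecg.size) / tr.ecg_fs, "value": tr.ecg}
        ).to_csv(tdir / "ecg.csv", index=False)
        pd.DataFrame(
            {"time_s": np.arange(tr.gsr.size) / tr.gsr_fs, "value": tr.gsr}
        ).to_csv(tdir / "gsr.csv", index=False)
        gt = {
            k: (v.tolist() if isinstance(v, np.ndarray) else list(v) if isinstance(v, tuple) else v)
            for k, v in tr.ground_truth.items()
        }
        meta = {
            "participant_id": tr.participant_id,
            "trial_id": tr.trial_id,
            "label": tr.label,
            "eeg_fs": tr.eeg_fs,
            "ecg_fs": tr.ecg_fs,
            "gsr_fs": tr.gsr_fs,
            "sam_valence": tr.sam_valence,
            "sam_arousal": tr.sam_arousal,
            "ground_truth": gt,
        }
        (tdir / "ground_truth.json").write_text(json.dumps(meta))
        manifest.append(
            {
                "participant": tr.participant_id,
                "trial": tr.trial_id,
                "label": tr.label,
                "valence": tr.sam_valence,
                "arousal": tr.sam_arousal,
            }
        )
    pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out


def read_trial_set(in_dir: str | Path) -> list[TrialRecord]:
    """Read a trial set written by :func:`write_trial_set`."""
    root = Path(in_dir)
    manifest_path = root / "manifest.tsv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.tsv under {root}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    trials = []
    for _, row in manifest.iterrows():
        tdir = root / str(row["trial"])
        meta = json.loads((tdir / "ground_truth.json").read_text())
        eeg = pd.read_csv(tdir / "eeg.csv")
        ecg = pd.read_csv(tdir / "ecg.csv")
        gsr = pd.read_csv(tdir / "gsr.csv")
        gt = meta["ground_truth"]
        gt["r_peak_indices"] = np.asarray(gt.get("r_peak_indices", []), dtype=int)
        gt["scr_onsets_s"] = np.asarray(gt.get("scr_onsets_s", []), dtype=float)
        trials.append(
            TrialRecord(
                participant_id=meta["participant_id"],
                trial_id=meta["trial_id"],
                label=meta["label"],
                eeg=eeg[list(EEG_CHANNELS)].to_numpy(float).T,
                ecg=ecg["value"].to_numpy(float),
                gsr=gsr["value"].to_numpy(float),
                eeg_fs=float(meta["eeg_fs"]),
                ecg_fs=float(meta["ecg_fs"]),
                gsr_fs=float(meta["gsr_fs"]),
                sam_valence=float(meta["sam_valence"]),
                sam_arousal=float(meta["sam_arousal"]),
                ground_truth=gt,
            )
        )
    return trials


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return table


def save_checkpoint(
    path: str | Path,
    pca,
    classifier,
    *,
    standardizer=None,
    selected_features: list[str] | None = None,
) -> Path:
    """Serialize a fitted fold model (PCA + LSTM weights) to one .npz file.

    The archive stores the PCA means/components/eigenvalues, the optional
    feature standardizer, the selected-feature list and every network
    parameter, plus the training history as JSON — enough to reload and
    predict without retraining.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    w = classifier.weights
    arrays = {
        "pca_means": pca.feature_means,
        "pca_components": pca.components,
        "pca_eigenvalues": pca.eigenvalues,
        "W_f": w.W_f, "W_i": w.W_i, "W_c": w.W_c, "W_o": w.W_o,
        "b_f": w.b_f, "b_i": w.b_i, "b_c": w.b_c, "b_o": w.b_o,
    }
    for li, (mw, mb) in enumerate(zip(w.fc_W, w.fc_b)):
        arrays[f"fc_W{li}"] = mw
        arrays[f"fc_b{li}"] = mb
    if standardizer is not None:
        arrays["std_mean"] = standardizer.mean
        arrays["std_sd"] = standardizer.sd
    meta = {
        "k": pca.k,
        "cumvar_k": pca.cumvar_k,
        "n_fc_layers": len(w.fc_W),
        "input_dim": int(w.W_f.shape[1] - w.b_f.size),
        "selected_features": selected_features or [],
        "train_config": {
            key: (list(v) if isinstance(v, tuple) else v)
            for key, v in classifier.cfg.__dict__.items()
        },
        "history": classifier.history,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path):
    """Reload a checkpoint; returns (PCAModel, PCALSTMClassifier, meta)."""
    from .lstm import LSTMWeights, PCALSTMClassifier, TrainConfig
    from .pca import PCAModel

    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        pca = PCAModel(
            feature_means=data["pca_means"],
            components=data["pca_components"],
            eigenvalues=data["pca_eigenvalues"],
            k=int(meta["k"]),
            cumvar_k=float(meta["cumvar_k"]),
        )
        cfg_raw = meta["train_config"]
        cfg = TrainConfig(**{
            key: tuple(v) if isinstance(v, list) else v for key, v in cfg_raw.items()
        })
        clf = PCALSTMClassifier(int(meta["input_dim"]), cfg)
        clf.weights = LSTMWeights(
            W_f=data["W_f"], W_i=data["W_i"], W_c=data["W_c"], W_o=data["W_o"],
            b_f=data["b_f"], b_i=data["b_i"], b_c=data["b_c"], b_o=data["b_o"],
            fc_W=[data[f"fc_W{li}"] for li in range(meta["n_fc_layers"])],
            fc_b=[data[f"fc_b{li}"] for li in range(meta["n_fc_layers"])],
        )
        clf.history = meta["history"]
    return pca, clf, meta


def _cv_to_dict(result: CVResult) -> dict:
    return {
        "mean_accuracy": result.mean_accuracy,
        "sd_accuracy": result.sd_accuracy,
        "per_fold_accuracy": {m: v.tolist() for m, v in result.accuracies.items()},
        "folds": [
            {
                "selected_features": f.screening.selected,
                "screening": {
                    feat: {
                        "F": r.F, "df1": r.df1, "df2": r.df2,
                        "p": r.p_uncorrected, "p_gg": r.p_gg,
                        "epsilon_gg": r.epsilon_gg, "partial_eta_sq": r.eta_sq,
                        "selected": feat in f.screening.selected,
                    }
                    for feat, r in f.screening.anova.items()
                },
                "fallback_used": f.screening.fallback_used,
                "k_retained": f.k,
                "pca_cumvar": f.pca.cumvar_k,
                "confusion": {m: cm.tolist() for m, cm in f.confusion.items()},
                "metrics": {
                    m: {
                        "accuracy": r.accuracy,
                        "precision": r.precision,
                        "recall": r.recall,
                        "f1": r.f1,
                        "macro_f1": r.macro_f1,
                        "weighted_f1": r.weighted_f1,
                    }
                    for m, r in f.metrics.items()
                },
            }
            for f in result.folds
        ],
        "comparison": (
            result.comparison.to_dict(orient="records")
            if result.comparison is not None
            else None
        ),
    }


def write_run_report(
    result: CVResult, out_dir: str | Path, provenance: dict | None = None
) -> tuple[Path, Path]:
    """Write JSON + markdown report; returns both paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = _cv_to_dict(result)
    if provenance:
        payload["provenance"] = provenance
    json_path = out / "run_report.json"
    json_path.write_text(json.dumps(payload, indent=2))
    md_path = out / "run_report.md"
    md_path.write_text(render_markdown_report(payload))
    return json_path, md_path


def render_markdown_report(payload: dict) -> str:
    """Render the JSON run report as a readable markdown summary."""
    lines = ["# Nested cross-validation report", ""]
    lines.append("## Accuracy (mean ± SD over folds)")
    for m, acc in payload["mean_accuracy"].items():
        sd = payload["sd_accuracy"][m]
        lines.append(f"- **{m}**: {acc * 100:.2f}% ± {sd * 100:.2f}%")
    lines.append("")
    folds = payload.get("folds", [])
    if folds:
        lines.append("## Per-class metrics (pooled over folds, primary model)")
        first_model = next(iter(payload["mean_accuracy"]))
        cm = np.sum([np.asarray(f["confusion"][first_model]) for f in folds], axis=0)
        lines.append("")
        lines.append("| class | precision | recall | F1 |")
        lines.append("|---|---|---|---|")
        from .evaluate import CLASS_ORDER, compute_metrics

        rep = compute_metrics(cm)
        for c in CLASS_ORDER:
            lines.append(
                f"| {c} | {rep.precision[c] * 100:.1f}% | {rep.recall[c] * 100:.1f}% "
                f"| {rep.f1[c] * 100:.1f}% |"
            )
        lines.append(
            f"| macro | {np.mean(list(rep.precision.values())) * 100:.1f}% "
            f"| {np.mean(list(rep.recall.values())) * 100:.1f}% | {rep.macro_f1 * 100:.1f}% |"
        )
        lines.append("")
        lines.append("Selected features per fold:")
        for fi, f in enumerate(folds):
            lines.append(
                f"- fold {fi + 1}: k={f['k_retained']} "
                f"({f['pca_cumvar'] * 100:.1f}% var) — {', '.join(f['selected_features'])}"
            )
        lines.append("")
    comp = payload.get("comparison")
    if comp:
        lines.append("## Model comparison (paired t-tests)")
        lines.append("")
        lines.append("| comparison | diff (%) | 95% CI | t | p | p_adj | d |")
        lines.append("|---|---|---|---|---|---|---|")
        for r in comp:
            lines.append(
                f"| {r['comparison']} | {r['difference_pct']:.2f} "
                f"| [{r['ci95_low']:.2f}, {r['ci95_high']:.2f}] | {r['t']:.2f} "
                f"| {r['p']:.4f} | {r['p_bonferroni']:.4f} | {r['cohens_d']:.2f} |"
            )
        lines.append("")
    return "\n".join(lines)
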