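"""Nested stratified cross-validation, metrics, and model comparison.

The outer loop is a stratified 5-fold split of trials; inside each fold,
feature screening (repeated-measures ANOVA on the training trials only),
feature standardization, PCA (90 % cumulative variance) and classifier
training all see nothing but the training portion. A stratified 15 %
validation split carved from the training portion drives the LSTM's early
stopping, approximating a 7 : 1.5 : 1.5 train/validation/test split.
The test fold is touched exactly once, for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import BASELINE_KINDS, flatten_sequences, train_baseline
from .features import FEATURE_NAMES
from .lstm import PCALSTMClassifier, TrainConfig
from .pca import PCAModel, Standardizer, fit_pca, transform_pca
from .screening import ScreeningResult, screen_features

__all__ = [
    "CLASS_ORDER",
    "FoldSplit",
    "MetricsReport",
    "FoldResult",
    "CVResult",
    "make_folds",
    "compute_metrics",
    "f1_score",
    "run_nested_cv",
    "compare_models",
    "permute_labels",
]

CLASS_ORDER = ("positive", "neutral", "negative")
LABEL_TO_INT = {c: i for i, c in enumerate(CLASS_ORDER)}
LSTM_NAME = "PCA-LSTM"


@dataclass
class FoldSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def make_folds(
    labels: np.ndarray | pd.Series,
    n_folds: int = 5,
    seed: int = 0,
    val_fraction: float = 0.15,
) -> list[FoldSplit]:
    """Class-stratified outer folds plus a stratified validation split.

    Each class is shuffled once and dealt round-robin to the test folds
    (fold sizes differ by at most one per class); within each fold's
    training portion a stratified ``val_fraction`` is held out for early
    stopping. Deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    missing = set(CLASS_ORDER) - set(classes.astype(str))
    if missing:
        raise ValueError(f"class absent from the trial set: {sorted(missing)}")
    if counts.min() < n_folds:
        raise ValueError("every class needs at least n_folds trials")
    rng = np.random.default_rng(seed)

    test_sets: list[list[int]] = [[] for _ in range(n_folds)]
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))
        for f in range(n_folds):
            test_sets[f].extend(idx[f::n_folds])

    folds = []
    all_idx = np.arange(labels.size)
    for f in range(n_folds):
        test = np.sort(np.asarray(test_sets[f], dtype=int))
        rest = np.setdiff1d(all_idx, test)
        val: list[int] = []
        for c in classes:
            cand = rng.permutation(rest[labels[rest] == c])
            n_val = max(1, int(round(val_fraction * cand.size)))
            val.extend(cand[:n_val])
        val = np.sort(np.asarray(val, dtype=int))
        train = np.setdiff1d(rest, val)
        assert not (set(train) & set(val) or set(train) & set(test) or set(val) & set(test))
        folds.append(FoldSplit(train, val, test))
    return folds


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float
    weighted_f1: float
    undefined_precision: list[str] = field(default_factory=list)


def f1_score(precision: float, recall: float) -> float:
    """F1 = 2·P·R/(P+R); zero when both are zero."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(cm: np.ndarray, classes: tuple[str, ...] = CLASS_ORDER) -> MetricsReport:
    """Per-class one-vs-rest precision/recall/F1 plus macro and weighted F1.

    ``cm`` is k × k with rows = true class, columns = predicted. Undefined
    precision (no predictions for a class) is reported as 0 and flagged.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.sum() <= 0:
        raise ValueError("confusion matrix must be square with positive total")
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)
    precision, recall, f1 = {}, {}, {}
    undef = []
    supports = cm.sum(axis=1)
    for ci, cname in enumerate(classes):
        tp = cm[ci, ci]
        fp = cm[:, ci].sum() - tp
        fn = cm[ci, :].sum() - tp
        if tp + fp == 0:
            precision[cname] = 0.0
            undef.append(cname)
        else:
            precision[cname] = float(tp / (tp + fp))
        recall[cname] = float(tp / (tp + fn)) if tp + fn > 0 else 0.0
        f1[cname] = f1_score(precision[cname], recall[cname])
    macro = float(np.mean([f1[c] for c in classes]))
    weighted = float(np.sum([f1[c] * supports[i] for i, c in enumerate(classes)]) / total)
    return MetricsReport(accuracy, precision, recall, f1, macro, weighted, undef)


# ---------------------------------------------------------------------------
# nested CV


@dataclass
class FoldResult:
    screening: ScreeningResult
    pca: PCAModel
    k: int
    confusion: dict[str, np.ndarray]
    metrics: dict[str, MetricsReport]
    history: dict[str, list[float]]


@dataclass
class CVResult:
    folds: list[FoldResult]
    accuracies: dict[str, np.ndarray]  # model -> per-fold test accuracy
    mean_accuracy: dict[str, float]
    sd_accuracy: dict[str, float]  # n−1 denominator over folds
    comparison: pd.DataFrame | None = None


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, k: int = 3) -> np.ndarray:
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    return cm


def _sequence_arrays(
    window_table: pd.DataFrame, trial_ids: list[str], features: list[str]
) -> np.ndarray:
    """(n_trials, T, k) array of windowed features in trial/window order."""
    sub = window_table[window_table["trial"].isin(trial_ids)]
    sub = sub.sort_values(["trial", "window_index"])
    t_steps = sub["window_index"].nunique()
    by_trial = {t: g[features].to_numpy(float) for t, g in sub.groupby("trial")}
    out = np.stack([by_trial[t] for t in trial_ids])
    if out.shape[1] != t_steps:
        raise ValueError("trials have unequal window counts")
    return out


def run_nested_cv(
    trial_table: pd.DataFrame,
    window_table: pd.DataFrame,
    *,
    n_folds: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    train_config: TrainConfig | None = None,
    models: tuple[str, ...] = (LSTM_NAME, *BASELINE_KINDS),
    compare: bool = True,
) -> CVResult:
    """Run the full nested cross-validation on extracted feature tables.

    ``trial_table`` holds one row per trial (full-trial features, used for
    screening); ``window_table`` one row per trial × window (the model
    input). Per fold: screen on training trials, impute missing values
    with training medians, standardize on training windows, fit PCA at the
    90 % rule, train the LSTM (and baselines on window-averaged scores),
    and evaluate once on the untouched test fold.
    """
    trial_table = trial_table.reset_index(drop=True)
    labels = trial_table["label"].to_numpy()
    y_all = np.array([LABEL_TO_INT[l] for l in labels])
    trial_ids = trial_table["trial"].astype(str).tolist()
    folds = make_folds(labels, n_folds=n_folds, seed=seed)
    base_cfg = train_config or TrainConfig()

    fold_results: list[FoldResult] = []
    acc: dict[str, list[float]] = {m: [] for m in models}

    for fi, split in enumerate(folds):
        train_rows = trial_table.iloc[split.train_idx]
        screening = screen_features(train_rows, alpha=alpha)
        feats = screening.selected

        ids_tr = [trial_ids[i] for i in split.train_idx]
        ids_va = [trial_ids[i] for i in split.val_idx]
        ids_te = [trial_ids[i] for i in split.test_idx]
        X_tr = _sequence_arrays(window_table, ids_tr, feats)
        X_va = _sequence_arrays(window_table, ids_va, feats)
        X_te = _sequence_arrays(window_table, ids_te, feats)

        # impute missing window features with training medians
        med = np.nanmedian(X_tr.reshape(-1, X_tr.shape[2]), axis=0)
        for X in (X_tr, X_va, X_te):
            nan = np.isnan(X)
            if nan.any():
                X[nan] = np.broadcast_to(med, X.shape)[nan]

        std = Standardizer.fit(X_tr.reshape(-1, X_tr.shape[2]))
        pca = fit_pca(std.transform(X_tr.reshape(-1, X_tr.shape[2])))

        def project(X):
            flat = std.transform(X.reshape(-1, X.shape[2]))
            return transform_pca(pca, flat).reshape(X.shape[0], X.shape[1], pca.k)

        Z_tr, Z_va, Z_te = project(X_tr), project(X_va), project(X_te)
        y_tr, y_va, y_te = (y_all[ix] for ix in (split.train_idx, split.val_idx, split.test_idx))

        confusion: dict[str, np.ndarray] = {}
        metrics: dict[str, MetricsReport] = {}
        history: dict[str, list[float]] = {}
        fold_seed = (seed * 1009 + fi) % (2**31 - 1)
        k_retained = pca.k
        for name in models:
            if name == LSTM_NAME:
                cfg = TrainConfig(
                    **{**base_cfg.__dict__, "seed": fold_seed}
                )
                clf = PCALSTMClassifier(k_retained, cfg).fit(Z_tr, y_tr, Z_va, y_va)
                y_pred = clf.predict(Z_te)
                history = clf.history
            else:
                model = train_baseline(name, flatten_sequences(Z_tr), y_tr, seed=fold_seed)
                y_pred = np.asarray(model.predict(flatten_sequences(Z_te)), dtype=int)
            cm = _confusion(y_te, y_pred)
            confusion[name] = cm
            metrics[name] = compute_metrics(cm)
            acc[name].append(metrics[name].accuracy)

        fold_results.append(
            FoldResult(screening, pca, k_retained, confusion, metrics, history)
        )

    accuracies = {m: np.asarray(v) for m, v in acc.items()}
    mean_acc = {m: float(v.mean()) for m, v in accuracies.items()}
    sd_acc = {m: float(v.std(ddof=1)) if v.size > 1 else 0.0 for m, v in accuracies.items()}
    comparison = None
    if compare and LSTM_NAME in models and len(models) > 1:
        comparison = compare_models(accuracies, reference=LSTM_NAME)
    return CVResult(fold_results, accuracies, mean_acc, sd_acc, comparison)


def compare_models(
    accuracies: dict[str, np.ndarray], reference: str = LSTM_NAME
) -> pd.DataFrame:
    """Paired t-tests of the reference model against every other model.

    Differences are in percentage points. p_adj is Bonferroni over the
    number of comparisons; Cohen's d is the paired effect size
    (mean difference / SD of differences). Zero-variance differences give
    NaN t and p.
    """
    ref = np.asarray(accuracies[reference], dtype=float) * 100.0
    others = [m for m in accuracies if m != reference]
    m_comp = len(others)
    rows = []
    for name in others:
        diff = ref - np.asarray(accuracies[name], dtype=float) * 100.0
        n = diff.size
        mean = float(diff.mean())
        sd = float(diff.std(ddof=1))
        if sd == 0:
            t = p = ci_lo = ci_hi = float("nan") if mean != 0 else 0.0
            d = 0.0 if mean == 0 else float("nan")
            if mean == 0:
                t, p, d = 0.0, 1.0, 0.0
        else:
            se = sd / np.sqrt(n)
            t = mean / se
            p = float(2 * stats.t.sf(abs(t), n - 1))
            tcrit = stats.t.ppf(0.975, n - 1)
            ci_lo, ci_hi = mean - tcrit * se, mean + tcrit * se
            d = mean / sd
        rows.append(
            {
                "comparison": f"{reference} vs. {name}",
                "difference_pct": mean,
                "ci95_low": ci_lo,
                "ci95_high": ci_hi,
                "t": float(t),
                "p": float(p),
                "p_bonferroni": float(min(1.0, m_comp * p)) if np.isfinite(p) else p,
                "cohens_d": float(d),
            }
        )
    return pd.DataFrame(rows)


def permute_labels(
    trial_table: pd.DataFrame, window_table: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle trial labels consistently across both tables (chance control)."""
    rng = np.random.default_rng(seed)
    trials = trial_table["trial"].astype(str).tolist()
    labels = trial_table["label"].to_numpy().copy()
    rng.shuffle(labels)
    mapping = dict(zip(trials, labels))
    t2 = trial_table.copy()
    t2["label"] = [mapping[t] for t in t2["trial"].astype(str)]
    w2 = window_table.copy()
    w2["label"] = [mapping[t] for t in w2["trial"].astype(str)]
    return t2, w2
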