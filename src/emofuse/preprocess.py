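"""Modality-specific signal cleaning.

EEG: average reference over retained channels, 50 Hz notch, 0.05–100 Hz
band-pass, bad-channel exclusion and ±100 μV amplitude rejection.
ECG: Pan-Tompkins QRS detection (band-pass, derivative, squaring,
moving-window integration, adaptive dual thresholds with search-back) and
ectopic-beat correction of the RR series (>20 % rule, linear interpolation)
to a normal-to-normal (NN) series.
GSR: 0.3 Hz low-pass and within-participant Z-score normalization.

All IIR filtering is zero-phase (forward–backward Butterworth, order 4
unless stated), so features keep their temporal alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "CleanEEGEpoch",
    "RPeakList",
    "NNSeries",
    "CleanGSR",
    "preprocess_eeg",
    "detect_r_peaks",
    "rr_from_peaks",
    "correct_ectopics",
    "participant_gsr_stats",
    "preprocess_gsr",
]

REJECTION_UV = 100.0  # amplitude-rejection threshold after cleaning
ECTOPIC_TOLERANCE = 0.20  # relative RR deviation beyond which a beat is ectopic


@dataclass
class CleanEEGEpoch:
    """Average-referenced, notch- and band-pass-filtered 6-channel epoch."""

    channels: np.ndarray  # (6, n) μV; bad channels zeroed
    fs: float
    rejected: bool
    bad_channels: list[int] = field(default_factory=list)


@dataclass
class RPeakList:
    indices: np.ndarray  # sample indices, strictly increasing
    fs: float


@dataclass
class NNSeries:
    """Artifact-corrected normal-to-normal intervals in ms."""

    intervals: np.ndarray
    n_corrected: int
    low_quality: bool = False


@dataclass
class CleanGSR:
    samples: np.ndarray  # z-scored, low-passed
    fs: float
    participant_mean: float  # μS, normalization constants
    participant_sd: float


def preprocess_eeg(raw: np.ndarray, fs: float) -> CleanEEGEpoch:
    """Clean one 6-channel EEG epoch.

    Channels whose SD exceeds 5× the median channel SD are marked bad and
    excluded from the average reference (and zeroed in the output). After
    referencing, a 50 Hz notch (Q = 30) and a 0.05–100 Hz band-pass
    (re-applying the hardware band digitally) are run zero-phase. The
    epoch is flagged rejected if any retained sample exceeds ±100 μV.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != 6:
        raise ValueError(f"expected a (6, n) array, got shape {raw.shape}")
    if fs < 256:
        raise ValueError("EEG sampling rate must be at least 256 Hz")

    sds = raw.std(axis=1)
    med = np.median(sds)
    bad = [] if med == 0 else [i for i in range(6) if sds[i] > 5.0 * med]
    good = [i for i in range(6) if i not in bad]
    if not good:
        return CleanEEGEpoch(np.zeros_like(raw), fs, rejected=True, bad_channels=bad)

    ref = raw[good].mean(axis=0)
    x = raw - ref  # reference subtracted from all, bad zeroed below

    b_notch, a_notch = sps.iirnotch(50.0, Q=30.0, fs=fs)
    x = sps.filtfilt(b_notch, a_notch, x, axis=1)
    high = min(100.0, 0.45 * fs)
    sos = sps.butter(4, [0.05, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    x[bad] = 0.0

    # a 0.5 s guard keeps zero-phase filter edge transients from
    # masquerading as physiological artifacts
    guard = int(round(0.5 * fs))
    core = x[good][:, guard : x.shape[1] - guard] if x.shape[1] > 2 * guard else x[good]
    rejected = bool(np.any(np.abs(core) > REJECTION_UV))
    return CleanEEGEpoch(x, fs, rejected=rejected, bad_channels=bad)


# ---------------------------------------------------------------------------
# ECG


def detect_r_peaks(ecg: np.ndarray, fs: float) -> RPeakList:
    """Pan-Tompkins QRS detection.

    Stages: 5–15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, then adaptive dual-threshold peak picking
    with a 200 ms refractory period and a search-back pass at half
    threshold when more than 1.66× the running RR estimate elapses
    without a detection. Accepted fiducials are relocated to the local
    ECG maximum within ±50 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 200:
        raise ValueError("ECG sampling rate must be at least 200 Hz")
    if ecg.size < 5 * fs:
        raise ValueError("need at least 5 s of ECG")

    sos = sps.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, ecg)
    deriv = np.convolve(filtered, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), mode="same")
    squared = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        warnings.warn("no QRS candidates found", stacklevel=2)
        return RPeakList(np.array([], dtype=int), fs)

    # threshold initialization from the first 2 s
    init = mwi[: int(2 * fs)]
    spki = float(init.max()) * 0.25 if init.size else float(mwi.max()) * 0.25
    npki = float(init.mean()) * 0.5 if init.size else 0.0
    thr = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    noise_cand: list[int] = []
    rr_hist: list[float] = []

    def accept(idx: int, peak_val: float) -> None:
        nonlocal spki, thr
        accepted.append(idx)
        spki = 0.125 * peak_val + 0.875 * spki
        thr = npki + 0.25 * (spki - npki)
        if len(accepted) >= 2:
            rr_hist.append(accepted[-1] - accepted[-2])
            if len(rr_hist) > 8:
                rr_hist.pop(0)

    for idx in cand:
        val = mwi[idx]
        if val > thr:
            if accepted and idx - accepted[-1] < refractory:
                continue
            # search-back first if a long gap preceded this detection
            if rr_hist and accepted:
                rr_avg = float(np.mean(rr_hist))
                if idx - accepted[-1] > 1.66 * rr_avg:
                    missed = [
                        j
                        for j in noise_cand
                        if accepted[-1] + refractory < j < idx - refractory
                        and mwi[j] > 0.5 * thr
                    ]
                    if missed:
                        best = max(missed, key=lambda j: mwi[j])
                        accept(best, mwi[best])
            accept(idx, val)
            noise_cand = []
        else:
            noise_cand.append(idx)
            npki = 0.125 * val + 0.875 * npki
            thr = npki + 0.25 * (spki - npki)

    if not accepted:
        warnings.warn("no R peaks above threshold", stacklevel=2)
        return RPeakList(np.array([], dtype=int), fs)

    # relocate to the local raw-ECG maximum within ±50 ms
    half = int(round(0.050 * fs))
    out = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(ecg.size, idx + half + 1)
        out.append(lo + int(np.argmax(ecg[lo:hi])))
    out = np.unique(np.asarray(out, dtype=int))
    return RPeakList(out, fs)


def rr_from_peaks(peaks: RPeakList) -> np.ndarray:
    """RR intervals in ms from detected R-peak indices."""
    if peaks.indices.size < 2:
        return np.array([])
    return np.diff(peaks.indices) / peaks.fs * 1000.0


def correct_ectopics(rr: np.ndarray) -> NNSeries:
    """Correct ectopic beats in an RR series (ms) by the >20 % rule.

    A single left-to-right pass compares each interval with the last
    accepted (already corrected) value; an interval deviating by strictly
    more than 20 % is replaced by linear interpolation between that left
    neighbour and the next interval that itself lies within 20 % of the
    left neighbour. If no such right neighbour exists the run is filled
    with the left neighbour's value. The trial is flagged low-quality if
    more than 20 % of beats needed correction.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError("need at least 3 RR intervals")
    out = rr.copy()
    n_corrected = 0
    i = 1
    while i < out.size:
        ref = out[i - 1]
        if abs(out[i] - ref) / ref > ECTOPIC_TOLERANCE:
            j = i + 1
            while j < out.size and abs(rr[j] - ref) / ref > ECTOPIC_TOLERANCE:
                j += 1
            if j < out.size:
                right = rr[j]
                span = j - (i - 1)
                for k in range(i, j):
                    out[k] = ref + (right - ref) * (k - (i - 1)) / span
            else:
                out[i:] = ref
            n_corrected += j - i
            i = j
        else:
            i += 1
    return NNSeries(out, n_corrected, low_quality=n_corrected > ECTOPIC_TOLERANCE * rr.size)


# ---------------------------------------------------------------------------
# GSR


def _lowpass_gsr(raw: np.ndarray, fs: float) -> np.ndarray:
    sos = sps.butter(4, 0.3, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(raw, dtype=float))


def participant_gsr_stats(trials: list[np.ndarray], fs: float) -> tuple[float, float]:
    """Label-blind normalization constants pooled over a participant's trials.

    Trials are low-pass filtered first, then the mean and SD of the
    concatenated filtered recording are returned.
    """
    filt = np.concatenate([_lowpass_gsr(x, fs) for x in trials])
    return float(filt.mean()), float(filt.std())


def preprocess_gsr(
    raw: np.ndarray, fs: float, participant_stats: tuple[float, float] | None = None
) -> CleanGSR:
    """Low-pass (0.3 Hz, zero-phase) and Z-score one GSR trial.

    ``participant_stats`` are the (mean, SD) pooled over all of that
    participant's trials; when omitted, the trial's own statistics are
    used (single-trial fallback). Zero variance raises.
    """
    if fs < 4:
        raise ValueError("GSR sampling rate must be at least 4 Hz")
    filt = _lowpass_gsr(raw, fs)
    if participant_stats is None:
        mean, sd = float(filt.mean()), float(filt.std())
    else:
        mean, sd = participant_stats
    if sd <= 1e-12:
        raise ValueError("GSR recording has (near-)zero variance; cannot normalize")
    return CleanGSR((filt - mean) / sd, fs, mean, sd)
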