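"""Trial-level and windowed feature extraction.

Eleven features per trial (or per sliding window):

* 3 EEG frontal alpha asymmetry indices AI = ln(P_alpha_right) − ln(P_alpha_left)
  for the pairs FP2/FP1, F4/F3, F8/F7, with alpha power obtained from a
  five-level db8 wavelet-packet decomposition at 128 Hz (2-Hz terminal
  bands; the 8–14 Hz nodes are the closest dyadic cover of the 8–13 Hz
  alpha band),
* 6 HRV indices from the NN series: SDNN, RMSSD (time domain), LF, HF,
  LF/HF (Welch PSD of the 4 Hz cubic-spline-resampled tachogram, bands
  0.04–0.15 / 0.15–0.40 Hz), and sample entropy (m = 2, r = 0.2·SD),
* 2 electrodermal indices: SCL (mean z-scored level) and NS.SCRs
  (trough-to-peak response count, 0.01 μS minimum rise applied in raw μS
  through the stored normalization constants).

The trial-level vector is computed on the full recording; the windowed
sequence (default 60 s windows, 20 s hop → 4 steps over a 120 s trial)
supplies the temporal axis for the sequence classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from fractions import Fraction
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

from .preprocess import (
    CleanEEGEpoch,
    CleanGSR,
    NNSeries,
    correct_ectopics,
    detect_r_peaks,
    rr_from_peaks,
)
from .synth import EEG_PAIRS, EEG_CHANNELS, TrialRecord

__all__ = [
    "FEATURE_NAMES",
    "Windowing",
    "alpha_power_wpd",
    "alpha_band_signal",
    "asymmetry_index",
    "hrv_time",
    "hrv_freq",
    "sample_entropy",
    "scl",
    "ns_scrs",
    "extract_features",
]

#: fixed feature order used in every table and model input
FEATURE_NAMES = (
    "AI_FP2_FP1",
    "AI_F4_F3",
    "AI_F8_F7",
    "SDNN",
    "RMSSD",
    "LF",
    "HF",
    "LF_HF",
    "SampEn",
    "SCL",
    "NS_SCRs",
)

ALPHA_FS = 128.0
SCR_MIN_RISE_US = 0.01
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class Windowing:
    window_s: float = 60.0
    hop_s: float = 20.0

    def starts(self, duration: float) -> np.ndarray:
        n = int(math.floor((duration - self.window_s) / self.hop_s)) + 1
        if n < 1:
            raise ValueError("trial shorter than one window")
        return np.arange(n) * self.hop_s


# ---------------------------------------------------------------------------
# EEG


def _resample_to(x: np.ndarray, fs: float, target: float = ALPHA_FS) -> np.ndarray:
    if fs == target:
        return np.asarray(x, dtype=float)
    frac = Fraction(target / fs).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def alpha_band_signal(channel: np.ndarray, fs: float) -> np.ndarray:
    """Alpha-band reconstruction of one channel at 128 Hz.

    Level-5 db8 wavelet-packet tree on the 128 Hz resampled signal; the
    frequency-ordered terminal nodes covering 8–14 Hz are kept, all others
    zeroed, and the packet tree inverted.
    """
    x = _resample_to(channel, fs)
    if x.size < 2**5:
        raise ValueError("segment too short for a level-5 wavelet-packet decomposition")
    wp = pywt.WaveletPacket(x, "db8", mode="symmetric", maxlevel=5)
    nodes = wp.get_level(5, order="freq")
    band_hz = (ALPHA_FS / 2) / len(nodes)  # 2 Hz per terminal node
    keep = pywt.WaveletPacket(None, "db8", mode="symmetric", maxlevel=5)
    for i, node in enumerate(nodes):
        lo = i * band_hz
        hi = lo + band_hz
        if hi > 8.0 and lo < 14.0:
            keep[node.path] = node.data
    rec = keep.reconstruct(update=False)
    return np.asarray(rec[: x.size])


def alpha_power_wpd(channel: np.ndarray, fs: float) -> float:
    """Alpha-band power (mean squared amplitude, μV²) of one EEG segment."""
    rec = alpha_band_signal(channel, fs)
    return float(np.mean(rec**2))


def asymmetry_index(p_right: float, p_left: float) -> float:
    """ln(P_right) − ln(P_left); NaN when either power is non-positive."""
    if not (p_right > 0 and p_left > 0):
        return float("nan")
    return math.log(p_right) - math.log(p_left)


# ---------------------------------------------------------------------------
# HRV


def hrv_time(nn: np.ndarray | NNSeries) -> tuple[float, float]:
    """(SDNN, RMSSD) in ms. SDNN uses the n−1 denominator."""
    x = nn.intervals if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    if x.size < 10:
        return float("nan"), float("nan")
    sdnn = float(np.std(x, ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    return sdnn, rmssd


def hrv_freq(
    nn: np.ndarray | NNSeries, *, resample_hz: float = 4.0, min_span_s: float = 45.0
) -> tuple[float, float, float]:
    """(LF, HF, LF/HF) band powers in ms² from the NN tachogram.

    The tachogram (interval value at its end-beat time) is cubic-spline
    resampled at 4 Hz and analysed with Welch (64 s segments or the full
    length if shorter, 50 % overlap). LF/HF is NaN when HF is zero.
    """
    x = nn.intervals if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    if x.size < 4:
        return float("nan"), float("nan"), float("nan")
    t = np.cumsum(x) / 1000.0
    span = t[-1] - t[0]
    if span < min_span_s:
        return float("nan"), float("nan"), float("nan")
    cs = CubicSpline(t, x)
    tt = np.arange(t[0], t[-1], 1.0 / resample_hz)
    y = cs(tt)
    y = y - y.mean()
    nperseg = min(int(64 * resample_hz), y.size)
    freqs, psd = sps.welch(y, fs=resample_hz, nperseg=nperseg, noverlap=nperseg // 2)

    def band_power(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs < hi)
        if not np.any(m):
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    ratio = lf / hf if hf > 0 else float("nan")
    return lf, hf, ratio


def sample_entropy(x: np.ndarray | NNSeries, m: int = 2, r: float | None = None) -> float:
    """Sample entropy −ln(A/B) with Chebyshev distance, self-matches excluded.

    A counts matching template pairs of length m+1, B of length m, both
    over the first n−m templates. Default tolerance r = 0.2 × SD of the
    series. NaN when either count is zero (and the series is not constant).
    """
    x = x.intervals if isinstance(x, NNSeries) else np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return float("nan")
    if r is None:
        r = 0.2 * float(np.std(x))
    elif r < 0:
        raise ValueError("tolerance r must be non-negative")

    def count_matches(mm: int) -> int:
        n_t = n - m  # same template count for both lengths
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_t]
        total = 0
        for i in range(n_t - 1):
            d = np.max(np.abs(emb[i + 1 :] - emb[i]), axis=1)
            total += int(np.count_nonzero(d <= r))
        return total

    b = count_matches(m)
    a = count_matches(m + 1)
    if a == 0 or b == 0:
        return 0.0 if a == b else float("nan")
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# electrodermal


def scl(window: np.ndarray) -> float:
    """Skin conductance level: mean of the z-scored signal over the window."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return float(w.mean())


def ns_scrs(
    gsr: CleanGSR | np.ndarray,
    fs: float | None = None,
    *,
    sd_us: float = 1.0,
    min_rise_us: float = SCR_MIN_RISE_US,
) -> int:
    """Count non-specific skin conductance responses in a window.

    Trough-to-peak detection on the phasic component (signal minus a 4-s
    moving median): a response is a local minimum followed within 5 s by a
    local maximum with a rise of at least ``min_rise_us`` (applied in raw
    μS via the stored normalization SD). Detection runs on a ~20 Hz
    decimated copy — SCRs live well below 1 Hz after the 0.3 Hz low-pass.
    """
    if isinstance(gsr, CleanGSR):
        x, fs, sd_us = gsr.samples, gsr.fs, gsr.participant_sd
    else:
        x = np.asarray(gsr, dtype=float)
        if fs is None:
            raise ValueError("fs required for plain-array input")
    if x.size < 10 * fs:
        raise ValueError("window must cover at least 10 s")

    step = max(1, int(fs // 20))
    xd = x[::step]
    fsd = fs / step
    half_win = int(round(2.0 * fsd))
    phasic = xd - median_filter(xd, size=2 * half_win + 1, mode="nearest")

    thr = min_rise_us / sd_us  # threshold in z units
    d = np.diff(phasic)
    sign = np.sign(d)
    # the median baseline tracks the signal exactly over monotone
    # stretches, leaving long flat-zero runs; treat flats as falling so
    # that a rise out of a quiet baseline still registers a trough
    sign[sign == 0] = -1
    turn = np.diff(sign)
    troughs = np.flatnonzero(turn > 0) + 1
    peaks = np.flatnonzero(turn < 0) + 1
    cands: list[tuple[int, float]] = []
    for ti in troughs:
        nxt = peaks[peaks > ti]
        if nxt.size == 0:
            continue
        pi = int(nxt[0])
        rise = float(phasic[pi] - phasic[ti])
        # a response peak must also stand above the running baseline;
        # this drops the flat "peaks" where a dip merely recovers to zero
        if rise >= thr and phasic[pi] >= 0.5 * thr and (pi - ti) <= 5.0 * fsd:
            cands.append((int(ti), rise))
    # the median baseline dips just ahead of a large response, which can
    # turn the acausal foot of a large response (the zero-phase low-pass
    # smears it backward) into a small spurious trough/peak pair: suppress
    # a candidate when a larger one follows within 7 s
    count = 0
    for k, (ti, rise) in enumerate(cands):
        shadowed = any(
            0 < tj - ti <= 7.0 * fsd and rj >= 1.5 * rise
            for tj, rj in cands[k + 1 :]
        )
        if not shadowed:
            count += 1
    return count


# ---------------------------------------------------------------------------
# per-trial assembly


def extract_features(
    trial: TrialRecord,
    clean_eeg: CleanEEGEpoch,
    nn: NNSeries,
    clean_gsr: CleanGSR,
    windowing: Windowing = Windowing(),
) -> tuple[dict[str, float], list[dict[str, float]]]:
    """Compute the trial-level vector and the windowed feature sequence.

    Returns ``(trial_features, [window_features...])`` as plain dicts keyed
    by :data:`FEATURE_NAMES`. The alpha band is reconstructed once per
    channel on the full trial and sliced per window (the power of a slice
    of the reconstruction), which matches :func:`alpha_power_wpd` on the
    full trial exactly and avoids re-running the packet transform per
    window. Raises when the EEG epoch was rejected.
    """
    if clean_eeg.rejected:
        raise ValueError(f"trial {trial.trial_id}: EEG epoch rejected")
    duration = clean_eeg.channels.shape[1] / clean_eeg.fs

    alpha = {
        ch: alpha_band_signal(clean_eeg.channels[i], clean_eeg.fs)
        for i, ch in enumerate(EEG_CHANNELS)
    }
    nn_t = np.cumsum(nn.intervals) / 1000.0  # end-beat times, s

    def window_vector(t0: float, t1: float) -> dict[str, float]:
        out: dict[str, float] = {}
        a0, a1 = int(t0 * ALPHA_FS), int(t1 * ALPHA_FS)
        for (right, left), name in zip(EEG_PAIRS, FEATURE_NAMES[:3]):
            pr = float(np.mean(alpha[right][a0:a1] ** 2))
            pl = float(np.mean(alpha[left][a0:a1] ** 2))
            out[name] = asymmetry_index(pr, pl)
        sel = (nn_t > t0) & (nn_t <= t1)
        nn_w = nn.intervals[sel]
        out["SDNN"], out["RMSSD"] = hrv_time(nn_w)
        out["LF"], out["HF"], out["LF_HF"] = hrv_freq(nn_w)
        out["SampEn"] = sample_entropy(nn_w)
        g0, g1 = int(t0 * clean_gsr.fs), int(t1 * clean_gsr.fs)
        gw = clean_gsr.samples[g0:g1]
        out["SCL"] = scl(gw)
        out["NS_SCRs"] = float(
            ns_scrs(gw, clean_gsr.fs, sd_us=clean_gsr.participant_sd)
        )
        return out

    trial_vec = window_vector(0.0, duration)
    seq = [
        window_vector(s, s + windowing.window_s) for s in windowing.starts(duration)
    ]
    return trial_vec, seq


def nn_series_from_ecg(ecg: np.ndarray, fs: float) -> NNSeries:
    """Convenience: Pan-Tompkins detection → RR series → ectopic correction."""
    peaks = detect_r_peaks(ecg, fs)
    rr = rr_from_peaks(peaks)
    return correct_ectopics(rr)
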