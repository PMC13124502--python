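"""Emotion-conditioned synthetic multimodal trial generator.

Produces trials with the statistical structure of a VR emotion-elicitation
study: 6-channel prefrontal EEG whose alpha-band (8–13 Hz) right/left power
ratio encodes the emotional condition, ECG built from an oscillatory RR
model with controllable SDNN and LF/HF, electrodermal activity with a tonic
level plus Poisson-like phasic responses, and SAM self-ratings. Every
injected event (R peak, skin-conductance response, asymmetry offset) is
recorded as ground truth so downstream detectors can be validated.

The default condition profiles encode the qualitative contrasts that
emotional valence produces in these signals: frontal alpha asymmetry
ordered positive > neutral > negative, reduced heart-rate variability and
raised sympathovagal (LF/HF) balance under negative emotion, and highest
skin conductance level / response rate under negative emotion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy import signal as sps

from .stimuli import pooled_sam_profile

__all__ = [
    "EEG_CHANNELS",
    "EEG_PAIRS",
    "EmotionProfile",
    "SynthConfig",
    "TrialRecord",
    "default_profiles",
    "generate_eeg",
    "generate_rr_series",
    "generate_ecg_from_rr",
    "generate_gsr",
    "generate_sam_ratings",
    "generate_experiment",
]

#: channel order used everywhere downstream
EEG_CHANNELS = ("FP1", "FP2", "F3", "F4", "F7", "F8")

#: homologous (right, left) electrode pairs, in asymmetry-feature order
EEG_PAIRS = (("FP2", "FP1"), ("F4", "F3"), ("F8", "F7"))

LABELS = ("positive", "neutral", "negative")


class ConfigurationError(ValueError):
    """Raised for invalid generator settings."""


@dataclass(frozen=True)
class EmotionProfile:
    """Target signal statistics for one emotional condition.

    alpha_asym_shift is the mean asymmetry index ln(P_right) − ln(P_left)
    injected per electrode pair (FP2/FP1, F4/F3, F8/F7). HRV targets are
    expectations of the extracted features: rr_mean and rr_sdnn_target in
    ms, lf_hf_target a power ratio, sampen_target dimensionless (steers
    the stochastic share of RR variance). scr_rate is phasic events per
    minute, scl_level the tonic skin conductance in μS. SAM parameters
    are on the 1–9 rating scale.
    """

    label: str
    alpha_asym_shift: tuple[float, float, float]
    rr_mean: float
    rr_sdnn_target: float
    lf_hf_target: float
    sampen_target: float
    scr_rate: float
    scl_level: float
    sam_valence_mean: float
    sam_valence_sd: float
    sam_arousal_mean: float
    sam_arousal_sd: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ConfigurationError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.rr_mean <= 0 or self.rr_sdnn_target < 0:
            raise ConfigurationError("RR parameters must be positive (SDNN may be 0)")
        if self.lf_hf_target <= 0:
            raise ConfigurationError("lf_hf_target must be > 0")
        if self.scr_rate < 0 or self.scl_level <= 0:
            raise ConfigurationError("electrodermal parameters must be non-negative")
        for m in (self.sam_valence_mean, self.sam_arousal_mean):
            if not 1.0 <= m <= 9.0:
                raise ConfigurationError("SAM means must lie in [1, 9]")


def default_profiles() -> dict[str, EmotionProfile]:
    """Default condition profiles.

    Asymmetry shifts are largest on the dorsolateral pairs (F4/F3, F8/F7)
    and near-zero frontopolar, matching the empirical pattern that the
    frontopolar index carries little valence information. Negative emotion
    gets low SDNN/RMSSD/SampEn, high LF/HF, high SCL and SCR rate.
    """
    sam = {lab: pooled_sam_profile(lab) for lab in LABELS}

    def prof(label, ai, rr, sdnn, lfhf, se, rate, scl):
        s = sam[label]
        return EmotionProfile(
            label=label,
            alpha_asym_shift=ai,
            rr_mean=rr,
            rr_sdnn_target=sdnn,
            lf_hf_target=lfhf,
            sampen_target=se,
            scr_rate=rate,
            scl_level=scl,
            sam_valence_mean=s["valence_mean"],
            sam_valence_sd=s["valence_sd"],
            sam_arousal_mean=s["arousal_mean"],
            sam_arousal_sd=s["arousal_sd"],
        )

    return {
        "positive": prof("positive", (0.05, 0.50, 0.40), 800.0, 55.0, 1.5, 1.8, 3.0, 5.0),
        "neutral": prof("neutral", (0.0, 0.0, 0.0), 820.0, 50.0, 1.8, 1.6, 1.5, 4.0),
        "negative": prof("negative", (-0.05, -0.50, -0.40), 750.0, 30.0, 4.0, 1.0, 6.0, 8.0),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Full experiment design. Defaults reproduce the study layout:

    20 participants × 3 conditions × 6 trials = 360 two-minute trials,
    EEG at 512 Hz, ECG and GSR at 500 Hz.
    """

    n_participants: int = 20
    trials_per_class_per_participant: int = 6
    eeg_fs: float = 512.0
    ecg_fs: float = 500.0
    gsr_fs: float = 500.0
    trial_duration: float = 120.0
    profiles: dict[str, EmotionProfile] = field(default_factory=default_profiles)
    blink_rate_per_min: float = 0.0
    ectopic_prob: float = 0.02
    powerline_amp_uv: float = 2.0
    ecg_noise_mv: float = 0.02
    gsr_noise_us: float = 0.003
    # between-participant trait SDs and within-participant trial jitter;
    # emotional autonomic responses vary a lot from trial to trial, so the
    # HRV/electrodermal targets get multiplicative lognormal trial noise
    ai_participant_sd: float = 0.15
    ai_trial_sd: float = 0.30
    rr_participant_sd: float = 40.0
    rr_trial_sd: float = 25.0
    scl_participant_sd: float = 0.8
    scl_trial_sd: float = 1.4
    sdnn_trial_lognorm_sd: float = 0.38
    lfhf_trial_lognorm_sd: float = 0.50
    scr_rate_trial_lognorm_sd: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.trials_per_class_per_participant <= 0:
            raise ConfigurationError("participant and trial counts must be positive")
        if self.trial_duration <= 0:
            raise ConfigurationError("trial_duration must be positive")
        if min(self.eeg_fs, self.ecg_fs, self.gsr_fs) <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if set(self.profiles) != set(LABELS):
            raise ConfigurationError(f"profiles must cover exactly {LABELS}")


@dataclass
class TrialRecord:
    """One synthetic trial: raw signals, label, self-ratings, ground truth.

    ``eeg`` is a (6, n) array in μV ordered as :data:`EEG_CHANNELS`;
    ``ecg`` in mV, ``gsr`` in μS. ``ground_truth`` holds the injected
    R-peak sample indices, SCR onset times (s) and effective per-pair
    asymmetry offsets.
    """

    participant_id: str
    trial_id: str
    label: str
    eeg: np.ndarray
    ecg: np.ndarray
    gsr: np.ndarray
    eeg_fs: float
    ecg_fs: float
    gsr_fs: float
    sam_valence: float
    sam_arousal: float
    ground_truth: dict


# ---------------------------------------------------------------------------
# modality generators


def _pink_noise(n: int, rms: float, rng: Generator, fs: float = 1.0) -> np.ndarray:
    """1/f-amplitude noise above a 1 Hz knee, scaled to a target RMS.

    The spectrum is flat below the knee: AC-coupled hardware has already
    removed the slow drift, and unbounded 1/f power at millihertz
    frequencies would only feed filter edge transients downstream.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    knee = 1.0
    scale = 1.0 / np.sqrt(np.maximum(freqs, knee) / knee)
    spec *= scale
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def generate_eeg(
    profile: EmotionProfile,
    duration: float,
    fs: float,
    rng: Generator,
    *,
    blink_rate_per_min: float = 0.0,
    powerline_amp_uv: float = 0.0,
    alpha_rms_uv: float = 12.0,
    background_rms_uv: float = 10.0,
) -> np.ndarray:
    """Six-channel prefrontal EEG (μV) with condition-coded alpha asymmetry.

    Each channel is pink-noise background plus a narrowband 8–13 Hz alpha
    component (band-filtered white noise). The shift for pair p is applied
    symmetrically: right power × exp(+s/2), left × exp(−s/2), so the
    expected log power ratio equals ``alpha_asym_shift[p]``. Blinks, when
    enabled, are 100–400 μV slow positive transients on FP1/FP2; a common
    50 Hz component models power-line pickup.
    """
    if fs < 128:
        raise ConfigurationError("EEG sampling rate must be at least 128 Hz")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sos = sps.butter(4, [8.0, 13.0], btype="bandpass", fs=fs, output="sos")

    out = np.empty((6, n))
    pair_of = {"FP2": 0, "FP1": 0, "F4": 1, "F3": 1, "F8": 2, "F7": 2}
    right = {"FP2", "F4", "F8"}
    for ci, ch in enumerate(EEG_CHANNELS):
        s = profile.alpha_asym_shift[pair_of[ch]]
        gain = np.exp(+s / 2.0) if ch in right else np.exp(-s / 2.0)
        alpha = sps.sosfiltfilt(sos, rng.standard_normal(n))
        asd = alpha.std()
        if asd > 0:
            alpha *= alpha_rms_uv * np.sqrt(gain) / asd
        out[ci] = _pink_noise(n, background_rms_uv, rng, fs) + alpha

    if powerline_amp_uv > 0:
        out += powerline_amp_uv * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))

    if blink_rate_per_min > 0:
        n_blinks = rng.poisson(blink_rate_per_min * duration / 60.0)
        for _ in range(n_blinks):
            t0 = rng.uniform(0.5, duration - 0.5)
            amp = rng.uniform(100.0, 400.0)
            shape = amp * np.exp(-0.5 * ((t - t0) / 0.08) ** 2)
            out[0] += shape  # FP1
            out[1] += shape  # FP2
    return out


def _rr_amplitudes(profile: EmotionProfile) -> tuple[float, float, float]:
    """Solve the RR variance partition for (a_lf, a_hf, jitter_sd).

    Total variance SDNN² is split into a white-jitter share (a monotone
    function of the sample-entropy target: more stochastic variance means
    higher entropy) and two sinusoids at 0.1 and 0.25 Hz whose power ratio
    equals the LF/HF target.
    """
    var = profile.rr_sdnn_target**2
    if var == 0:
        return 0.0, 0.0, 0.0
    # entropy is driven by white jitter relative to the matching tolerance
    # r = 0.2*SDNN: jitter_sd/r = sqrt(frac)/0.2 ~ sampen_target keeps the
    # classes on the steep part of the SampEn curve instead of saturating it
    jitter_frac = float(np.clip(0.04 * profile.sampen_target**2, 0.02, 0.8))
    jitter_var = jitter_frac * var
    osc_var = var - jitter_var
    if osc_var < 0:
        raise ConfigurationError("infeasible RR variance partition")
    r = profile.lf_hf_target
    lf_var = osc_var * r / (1.0 + r)
    hf_var = osc_var / (1.0 + r)
    return float(np.sqrt(2 * lf_var)), float(np.sqrt(2 * hf_var)), float(np.sqrt(jitter_var))


def generate_rr_series(
    profile: EmotionProfile,
    duration: float,
    rng: Generator,
    *,
    ectopic_prob: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """RR intervals (ms) and beat times (s, starting at 0) covering ``duration``.

    RR(t) = rr_mean + LF sinusoid (0.1 Hz) + HF sinusoid (0.25 Hz) + white
    jitter. With probability ``ectopic_prob`` an interval is multiplied by
    0.6 or 1.5, guaranteeing a >20 % deviation for the ectopic-correction
    rule to catch. Returns (intervals, beat_times) with
    ``len(beat_times) == len(intervals) + 1``.
    """
    if not 400.0 <= profile.rr_mean <= 1500.0:
        raise ConfigurationError("rr_mean must lie in [400, 1500] ms")
    a_lf, a_hf, jit = _rr_amplitudes(profile)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)

    times = [0.0]
    intervals: list[float] = []
    t = 0.0
    while True:
        rr = (
            profile.rr_mean
            + a_lf * np.sin(2 * np.pi * 0.1 * t + ph1)
            + a_hf * np.sin(2 * np.pi * 0.25 * t + ph2)
            + (jit * rng.standard_normal() if jit > 0 else 0.0)
        )
        if ectopic_prob > 0 and rng.random() < ectopic_prob:
            rr *= rng.choice([0.6, 1.5])
        rr = max(rr, 320.0)
        t_next = t + rr / 1000.0
        if t_next > duration + 1e-9:
            break
        intervals.append(rr)
        times.append(t_next)
        t = t_next
    return np.asarray(intervals), np.asarray(times)


def generate_ecg_from_rr(
    beat_times: np.ndarray,
    fs: float,
    *,
    duration: float | None = None,
    noise_sd_mv: float = 0.0,
    rng: Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic single-lead ECG (mV) from beat times.

    Each beat contributes a PQRST complex of Gaussian deflections with the
    R wave (≈1 mV) centred on the beat time. Returns (signal, ground-truth
    R-peak sample indices). Beat times must be strictly increasing and at
    least 300 ms apart.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        n = int(round((duration or 0.0) * fs))
        return np.zeros(n), np.array([], dtype=int)
    d = np.diff(beat_times)
    if np.any(d <= 0):
        raise ValueError("beat times must be strictly increasing")
    if np.any(d < 0.3):
        raise ValueError("RR interval below 300 ms: complexes would overlap")
    if duration is None:
        duration = float(beat_times[-1]) + 0.5
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    # (amplitude mV, offset s, width s) for P, Q, R, S, T
    waves = [(0.12, -0.20, 0.030), (-0.15, -0.027, 0.010),
             (1.00, 0.0, 0.012), (-0.25, 0.027, 0.010), (0.30, 0.25, 0.045)]
    half = 0.45
    for bt in beat_times:
        lo = max(0, int((bt - half) * fs))
        hi = min(n, int((bt + half) * fs) + 1)
        if lo >= hi:
            continue
        tt = t[lo:hi] - bt
        for a, mu, sd in waves:
            sig[lo:hi] += a * np.exp(-0.5 * ((tt - mu) / sd) ** 2)
    if noise_sd_mv > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd_mv > 0")
        sig = sig + noise_sd_mv * rng.standard_normal(n)
    r_idx = np.round(beat_times * fs).astype(int)
    r_idx = r_idx[(r_idx >= 0) & (r_idx < n)]
    return sig, r_idx


def _scr_kernel(fs: float, tau_rise: float = 1.0, tau_decay: float = 4.0) -> np.ndarray:
    """Biexponential SCR shape, unit peak amplitude, truncated at 20 s."""
    t = np.arange(0, 20.0, 1.0 / fs)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def generate_gsr(
    profile: EmotionProfile,
    duration: float,
    fs: float,
    rng: Generator,
    *,
    noise_sd_us: float = 0.0,
    min_gap_s: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Skin conductance (μS) with tonic level plus phasic responses.

    The tonic part is ``scl_level`` plus a slow sinusoidal drift; phasic
    responses arrive as a renewal process at ``scr_rate`` per minute with
    a refractory gap of ``min_gap_s`` (keeps events resolvable so that
    ground-truth counts are exact for noise-free detection), each a
    biexponential kernel (rise ≈1 s, decay ≈4 s) with amplitude
    0.15 μS + Exp(0.15 μS) — the typical range of spontaneous responses,
    comfortably above the 0.01 μS detection floor even after the 0.3 Hz
    low-pass attenuates the rising edge. Returns (signal, onset times s).
    """
    if profile.scr_rate < 0:
        raise ConfigurationError("scr_rate must be non-negative")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    tonic = profile.scl_level + 0.05 * profile.scl_level * np.sin(
        2 * np.pi * 0.004 * t + rng.uniform(0, 2 * np.pi)
    )
    sig = tonic.copy()
    onsets: list[float] = []
    if profile.scr_rate > 0:
        mean_gap = 60.0 / profile.scr_rate
        exp_mean = max(mean_gap - min_gap_s, 0.1)
        kernel = _scr_kernel(fs)
        t0 = 2.0 + rng.exponential(exp_mean)
        prev_amp, prev_t = 0.0, -np.inf
        # leave room for the rise so the full peak stays inside the trial
        while t0 < duration - 6.0:
            amp = 0.15 + rng.exponential(0.15)
            # resolvability: a response whose maximum rise slope never beats
            # the previous response's decay slope produces no local extremum
            # at all (invisible to any trough-to-peak rule), so its amplitude
            # is floored at the slope-balance point with a 1.4x margin
            g = t0 - prev_t
            floor = prev_amp * max(2.0 * np.exp(-g / 4.0) - 8.1 * np.exp(-g), 0.0)
            amp = max(amp, floor)
            i0 = int(round(t0 * fs))
            seg = min(kernel.size, n - i0)
            sig[i0 : i0 + seg] += amp * kernel[:seg]
            onsets.append(t0)
            prev_amp, prev_t = amp, t0
            t0 += min_gap_s + rng.exponential(exp_mean)
    if noise_sd_us > 0:
        sig = sig + noise_sd_us * rng.standard_normal(n)
    return sig, np.asarray(onsets)


def generate_sam_ratings(profile: EmotionProfile, rng: Generator) -> tuple[float, float]:
    """One (valence, arousal) SAM rating pair, Gaussian, clipped to [1, 9]."""
    v = float(np.clip(rng.normal(profile.sam_valence_mean, profile.sam_valence_sd), 1.0, 9.0))
    a = float(np.clip(rng.normal(profile.sam_arousal_mean, profile.sam_arousal_sd), 1.0, 9.0))
    return v, a


# ---------------------------------------------------------------------------
# experiment assembly


def generate_experiment(config: SynthConfig) -> list[TrialRecord]:
    """Generate the full balanced trial set.

    Exactly ``n_participants × 3 × trials_per_class_per_participant``
    trials, bit-reproducible for a fixed seed. Participants carry random
    trait offsets (baseline asymmetry per pair, mean RR, tonic SCL) and
    each trial adds small jitter, so classes are separable but not
    trivially so.
    """
    trials: list[TrialRecord] = []
    root = SeedSequence(config.seed)
    part_seeds = root.spawn(config.n_participants)
    ecg_margin = 0.4  # keeps the first/last QRS complex fully inside the trial

    for p in range(config.n_participants):
        rng = default_rng(part_seeds[p])
        pid = f"P{p + 1:02d}"
        ai_off = rng.normal(0.0, config.ai_participant_sd, size=3)
        rr_off = rng.normal(0.0, config.rr_participant_sd)
        scl_off = rng.normal(0.0, config.scl_participant_sd)

        labels = [lab for lab in LABELS for _ in range(config.trials_per_class_per_participant)]
        rng.shuffle(labels)

        for ti, label in enumerate(labels):
            base = config.profiles[label]
            eff = replace(
                base,
                alpha_asym_shift=tuple(
                    np.asarray(base.alpha_asym_shift)
                    + ai_off
                    + rng.normal(0.0, config.ai_trial_sd, size=3)
                ),
                rr_mean=float(
                    np.clip(base.rr_mean + rr_off + rng.normal(0.0, config.rr_trial_sd), 420, 1450)
                ),
                rr_sdnn_target=float(
                    base.rr_sdnn_target
                    * np.exp(rng.normal(0.0, config.sdnn_trial_lognorm_sd))
                ),
                lf_hf_target=float(
                    base.lf_hf_target * np.exp(rng.normal(0.0, config.lfhf_trial_lognorm_sd))
                ),
                scr_rate=float(
                    base.scr_rate * np.exp(rng.normal(0.0, config.scr_rate_trial_lognorm_sd))
                ),
                scl_level=float(
                    max(base.scl_level + scl_off + rng.normal(0.0, config.scl_trial_sd), 0.5)
                ),
            )

            eeg = generate_eeg(
                eff,
                config.trial_duration,
                config.eeg_fs,
                rng,
                blink_rate_per_min=config.blink_rate_per_min,
                powerline_amp_uv=config.powerline_amp_uv,
            )
            rr, beat_times = generate_rr_series(
                eff,
                config.trial_duration - 2 * ecg_margin,
                rng,
                ectopic_prob=config.ectopic_prob,
            )
            ecg, r_idx = generate_ecg_from_rr(
                beat_times + ecg_margin,
                config.ecg_fs,
                duration=config.trial_duration,
                noise_sd_mv=config.ecg_noise_mv,
                rng=rng,
            )
            gsr, scr_onsets = generate_gsr(
                eff,
                config.trial_duration,
                config.gsr_fs,
                rng,
                noise_sd_us=config.gsr_noise_us,
            )
            valence, arousal = generate_sam_ratings(eff, rng)

            trials.append(
                TrialRecord(
                    participant_id=pid,
                    trial_id=f"{pid}T{ti + 1:02d}",
                    label=label,
                    eeg=eeg,
                    ecg=ecg,
                    gsr=gsr,
                    eeg_fs=config.eeg_fs,
                    ecg_fs=config.ecg_fs,
                    gsr_fs=config.gsr_fs,
                    sam_valence=valence,
                    sam_arousal=arousal,
                    ground_truth={
                        "r_peak_indices": r_idx,
                        "scr_onsets_s": scr_onsets,
                        "ai_offsets": tuple(eff.alpha_asym_shift),
                        "rr_intervals_ms": rr,
                    },
                )
            )
    return trials
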