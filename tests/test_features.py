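"""Feature-extraction contracts and oracle equivalences."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emofuse.features import (
    FEATURE_NAMES,
    Windowing,
    alpha_power_wpd,
    asymmetry_index,
    extract_features,
    hrv_freq,
    hrv_time,
    ns_scrs,
    sample_entropy,
    scl,
)
from emofuse.preprocess import preprocess_eeg, preprocess_gsr
from emofuse.synth import SynthConfig, default_profiles, generate_experiment, generate_gsr


def sampen_bruteforce(x, m=2, r=None):
    """Naive O(n^2 m) double-loop sample entropy, written independently."""
    x = list(map(float, x))
    n = len(x)
    if r is None:
        mean = sum(x) / n
        r = 0.2 * math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    n_templates = n - m

    def matches(length):
        count = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                if all(abs(x[i + d] - x[j + d]) <= r for d in range(length)):
                    count += 1
        return count

    b = matches(m)
    a = matches(m + 1)
    if a == 0 and b == 0:
        return 0.0
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


class TestAlphaPower:
    def test_in_band_tone_recovered(self):
        t = np.arange(0, 10, 1 / 512)
        p = alpha_power_wpd(5.0 * np.sin(2 * np.pi * 10 * t), 512.0)
        assert abs(p - 12.5) / 12.5 < 0.15

    def test_out_of_band_tone_rejected(self):
        t = np.arange(0, 10, 1 / 512)
        p = alpha_power_wpd(5.0 * np.sin(2 * np.pi * 30 * t), 512.0)
        assert p < 0.05 * 12.5

    def test_zero_signal(self):
        assert alpha_power_wpd(np.zeros(5120), 512.0) == 0.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            alpha_power_wpd(np.zeros(20), 128.0)


class TestAsymmetryIndex:
    def test_equal_powers(self):
        assert asymmetry_index(2.0, 2.0) == 0.0

    def test_log_ratio(self):
        for p in (0.5, 1.0, 7.3):
            assert abs(asymmetry_index(math.e * p, p) - 1.0) < 1e-12

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 10, 2)
            assert asymmetry_index(a, b) == pytest.approx(-asymmetry_index(b, a))

    def test_scale_invariance(self, rng):
        for _ in range(20):
            a, b, c = rng.uniform(0.1, 10, 3)
            assert asymmetry_index(c * a, c * b) == pytest.approx(
                asymmetry_index(a, b), abs=1e-12
            )

    def test_nonpositive_power_flagged(self):
        assert math.isnan(asymmetry_index(0.0, 1.0))
        assert math.isnan(asymmetry_index(1.0, -2.0))


class TestHRVTime:
    def test_constant_series(self):
        sdnn, rmssd = hrv_time(np.full(12, 800.0))
        assert sdnn == 0.0 and rmssd == 0.0

    def test_rmssd_example(self):
        x = np.array([800.0, 810.0] * 6)  # successive differences all +-10
        _, rmssd = hrv_time(x)
        assert rmssd == pytest.approx(10.0)

    def test_sdnn_sample_sd(self):
        x = np.array([790.0, 800.0, 810.0])
        sdnn = float(np.std(x, ddof=1))
        assert sdnn == pytest.approx(10.0)
        # hrv_time requires >= 10 intervals; replicate the pattern
        big = np.array([790.0, 800.0, 810.0] * 4)
        assert hrv_time(big)[0] == pytest.approx(float(np.std(big, ddof=1)))

    def test_shift_invariance_and_homogeneity(self, rng):
        x = 800 + 30 * rng.standard_normal(40)
        s0, r0 = hrv_time(x)
        s1, r1 = hrv_time(x + 123.0)
        s2, r2 = hrv_time(3.0 * x)
        assert (s1, r1) == (pytest.approx(s0), pytest.approx(r0))
        assert s2 == pytest.approx(3 * s0) and r2 == pytest.approx(3 * r0)

    def test_too_few_intervals(self):
        sdnn, rmssd = hrv_time(np.array([800.0] * 5))
        assert math.isnan(sdnn) and math.isnan(rmssd)


class TestHRVFreq:
    def _series(self, freq, amp=20.0, base=800.0, duration=120.0):
        rr, t = [], 0.0
        while t < duration:
            v = base + amp * math.sin(2 * math.pi * freq * t)
            rr.append(v)
            t += v / 1000.0
        return np.array(rr)

    def test_lf_tone(self):
        lf, hf, ratio = hrv_freq(self._series(0.10))
        assert ratio > 5

    def test_hf_tone(self):
        lf, hf, ratio = hrv_freq(self._series(0.25))
        assert ratio < 0.5

    def test_constant_series_undefined_ratio(self):
        lf, hf, ratio = hrv_freq(np.full(150, 800.0))
        assert lf == pytest.approx(0.0, abs=1e-9)
        assert hf == pytest.approx(0.0, abs=1e-9)
        assert math.isnan(ratio)

    def test_short_series_flagged(self):
        assert all(math.isnan(v) for v in hrv_freq(np.full(20, 800.0)))


class TestSampleEntropy:
    def test_constant_series(self):
        assert sample_entropy(np.full(30, 800.0)) == 0.0

    def test_oracle_on_random_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 31))
            x = 800 + 40 * rng.standard_normal(n)
            got = sample_entropy(x)
            want = sampen_bruteforce(x)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert abs(got - want) < 1e-12

    def test_alternating_series_matches_oracle(self):
        x = np.array([800.0, 900.0] * 15)
        got = sample_entropy(x, m=2)
        want = sampen_bruteforce(x, m=2)
        assert (math.isnan(got) and math.isnan(want)) or abs(got - want) < 1e-12

    def test_custom_tolerance(self, rng):
        x = 800 + 40 * rng.standard_normal(25)
        assert abs(sample_entropy(x, r=15.0) - sampen_bruteforce(x, r=15.0)) < 1e-12

    def test_too_short(self):
        assert math.isnan(sample_entropy(np.array([1.0, 2.0, 3.0])))


class TestElectrodermal:
    def test_scl_trivials(self):
        assert scl(np.zeros(100)) == 0.0
        assert scl(np.full(100, 0.5)) == 0.5
        with pytest.raises(ValueError):
            scl(np.array([]))

    def test_flat_signal_no_responses(self):
        x = np.zeros(60 * 100)
        assert ns_scrs(x, 100.0, sd_us=1.0) == 0

    def test_injected_events_counted_exactly(self):
        prof = replace(default_profiles()["negative"], scr_rate=6.0)
        for i in range(5):
            rng = np.random.default_rng(40 + i)
            sig, onsets = generate_gsr(prof, 120.0, 500.0, rng)
            clean = preprocess_gsr(sig, 500.0)
            assert ns_scrs(clean) == onsets.size

    def test_subthreshold_events_ignored(self):
        # biexponential events well below the 0.01 uS floor
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        sig = np.full(t.size, 5.0)
        kern = np.exp(-np.arange(0, 20, 1 / fs) / 4) - np.exp(-np.arange(0, 20, 1 / fs) / 1)
        kern /= kern.max()
        for onset in (10, 30, 50, 70, 90):
            i0 = int(onset * fs)
            sig[i0 : i0 + kern.size] += 0.002 * kern[: t.size - i0]
        z = (sig - sig.mean()) / sig.std()
        assert ns_scrs(z, fs, sd_us=float(sig.std())) == 0

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            ns_scrs(np.zeros(100), 100.0)


@pytest.fixture(scope="module")
def one_trial():
    trials = generate_experiment(SynthConfig(n_participants=1, seed=5))
    tr = trials[0]
    clean_eeg = preprocess_eeg(tr.eeg, tr.eeg_fs)
    from emofuse.features import nn_series_from_ecg

    nn = nn_series_from_ecg(tr.ecg, tr.ecg_fs)
    clean_gsr = preprocess_gsr(tr.gsr, tr.gsr_fs)
    return tr, clean_eeg, nn, clean_gsr


class TestExtractFeatures:
    def test_default_sequence_length(self, one_trial):
        _, seq = extract_features(*one_trial)
        assert len(seq) == 4  # floor((120-60)/20)+1

    def test_single_window_equals_trial_vector(self, one_trial):
        trial_vec, seq = extract_features(
            *one_trial, windowing=Windowing(window_s=120.0, hop_s=120.0)
        )
        assert len(seq) == 1
        for name in FEATURE_NAMES:
            a, b = trial_vec[name], seq[0][name]
            if math.isnan(a):
                assert math.isnan(b)
            else:
                assert a == pytest.approx(b, rel=1e-9)

    def test_feature_order_fixed(self, one_trial):
        trial_vec, _ = extract_features(*one_trial)
        assert tuple(trial_vec.keys()) == FEATURE_NAMES

    def test_rejected_epoch_raises(self, one_trial):
        tr, clean_eeg, nn, clean_gsr = one_trial
        bad = replace_rejected(clean_eeg)
        with pytest.raises(ValueError):
            extract_features(tr, bad, nn, clean_gsr)


def replace_rejected(clean_eeg):
    import copy

    bad = copy.copy(clean_eeg)
    bad.rejected = True
    return bad
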