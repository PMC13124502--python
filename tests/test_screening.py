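"""RM-ANOVA, Tukey HSD, feature screening and stimulus categorization."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from emofuse.features import FEATURE_NAMES
from emofuse.screening import (
    build_design_matrix,
    categorize_video,
    rm_anova,
    screen_features,
    tukey_hsd_rm,
)
from emofuse.stimuli import video_norms


class TestRMAnova:
    def test_no_condition_effect(self):
        # participants differ, conditions identical within participant
        y = np.tile(np.arange(8.0)[:, None], (1, 3))
        res = rm_anova(y)
        assert res.F == 0.0

    def test_perfect_effect_is_degenerate(self):
        y = np.zeros((5, 3)) + np.array([0.0, 1.0, 2.0])
        res = rm_anova(y)
        assert not res.defined and math.isnan(res.F)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for rep in range(5):
            y = rng.normal(0, 1, (10, 3)) + rng.normal(0, 0.5, (1, 3))
            res = rm_anova(y)
            df = pd.DataFrame(
                {
                    "y": y.ravel(),
                    "subj": np.repeat(np.arange(10), 3),
                    "cond": list("abc") * 10,
                }
            )
            ref = pg.rm_anova(data=df, dv="y", within="cond", subject="subj",
                              correction=True)
            assert abs(res.F - ref["F"].iloc[0]) < 1e-8
            assert abs(res.p_uncorrected - ref["p_unc"].iloc[0]) < 1e-8
            assert abs(res.epsilon_gg - ref["eps"].iloc[0]) < 1e-8
            assert abs(res.p_gg - ref["p_GG_corr"].iloc[0]) < 1e-8

    def test_invariant_to_subject_offsets(self, rng):
        y = rng.normal(0, 1, (12, 3))
        shifted = y + rng.normal(0, 5, (12, 1))
        a, b = rm_anova(y), rm_anova(shifted)
        assert abs(a.F - b.F) < 1e-10

    def test_epsilon_bounds(self, rng):
        for _ in range(50):
            res = rm_anova(rng.normal(0, 1, (8, 3)))
            assert 0.5 - 1e-12 <= res.epsilon_gg <= 1.0 + 1e-12

    def test_compound_symmetry_gives_epsilon_one(self):
        # exact compound symmetry: equal variances and covariances
        rng = np.random.default_rng(0)
        subj = rng.normal(0, 2, (2000, 1))
        y = subj + rng.normal(0, 1, (2000, 3))
        res = rm_anova(y)
        assert res.epsilon_gg > 0.99

    def test_partial_eta_squared_range(self, rng):
        for _ in range(20):
            y = rng.normal(0, 1, (10, 3)) + np.array([0, 0.3, 0.6])
            res = rm_anova(y)
            assert 0.0 <= res.eta_sq <= 1.0


class TestTukey:
    def test_equal_means(self):
        y = np.tile(np.arange(6.0)[:, None], (1, 3))
        table = tukey_hsd_rm(y, ms_error=1.0, df_error=10.0)
        assert np.allclose(table["q"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_q_scales_with_difference(self, rng):
        y = rng.normal(0, 1, (6, 3))
        t1 = tukey_hsd_rm(y, 2.0, 10.0)
        t2 = tukey_hsd_rm(y * 2, 2.0, 10.0)
        np.testing.assert_allclose(t2["q"], 2 * t1["q"], rtol=1e-12)

    @staticmethod
    def _sf_studentized_range(q, k, df):
        """Survival function by direct double integration of the
        studentized-range density (independent of scipy's implementation)."""
        from scipy import integrate
        from scipy.special import gammaln
        from scipy.stats import norm

        def inner(s):
            def f(z):
                return norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q * s)) ** (k - 1)

            val, _ = integrate.quad(f, -8, 8, limit=200)
            return k * val

        log_c = (df / 2) * np.log(df) - gammaln(df / 2) - (df / 2 - 1) * np.log(2)

        def outer(s):
            return np.exp(log_c + (df - 1) * np.log(s) - df * s * s / 2) * inner(s)

        cdf, _ = integrate.quad(outer, 1e-8, 10, limit=200)
        return 1.0 - cdf

    def test_matches_independent_studentized_range(self, rng):
        y = rng.normal(0, 1, (6, 3)) + np.array([0.0, 0.8, 1.6])
        res = rm_anova(y)
        table = tukey_hsd_rm(y, res.ms_error, res.df2)
        means = y.mean(axis=0)
        # independent q computation
        expected_q = [
            abs(means[i] - means[j]) / np.sqrt(res.ms_error / 6)
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        np.testing.assert_allclose(table["q"], expected_q, atol=1e-12)
        for q, p in zip(table["q"], table["p"]):
            ref = self._sf_studentized_range(q, 3, res.df2)
            assert abs(p - ref) < 1e-6


class TestScreenFeatures:
    @staticmethod
    def _null_table(rng, n_participants=12, trials=4):
        rows = []
        for p in range(n_participants):
            for lab in ("positive", "neutral", "negative"):
                for _ in range(trials):
                    rows.append(
                        {
                            "participant": f"P{p}",
                            "label": lab,
                            **{f: rng.normal() for f in FEATURE_NAMES},
                        }
                    )
        return pd.DataFrame(rows)

    def test_alpha_one_selects_everything(self, rng):
        table = self._null_table(rng)
        res = screen_features(table, alpha=1.0)
        assert res.selected == list(FEATURE_NAMES)

    def test_injected_effects_selected(self, default_tables):
        trial_table, _, _ = default_tables
        res = screen_features(trial_table, alpha=0.05)
        assert {"AI_F4_F3", "SDNN", "SCL"}.issubset(set(res.selected))

    def test_fallback_on_pure_noise(self):
        rng = np.random.default_rng(77)
        # tiny sample: almost surely nothing passes, fallback to 3 smallest p
        table = self._null_table(rng, n_participants=4, trials=2)
        res = screen_features(table, alpha=1e-6)
        assert res.fallback_used and len(res.selected) == 3

    def test_missing_condition_raises(self, rng):
        table = self._null_table(rng)
        with pytest.raises(ValueError):
            screen_features(table[table["label"] != "neutral"])

    def test_participant_with_missing_cell_dropped(self, rng):
        table = self._null_table(rng)
        mask = ~((table["participant"] == "P0") & (table["label"] == "neutral"))
        res = screen_features(table[mask])
        assert "P0" in res.dropped_participants


class TestDesignMatrix:
    def test_aggregates_trials_to_means(self):
        table = pd.DataFrame(
            {
                "participant": ["A"] * 6 + ["B"] * 6 + ["C"] * 6,
                "label": ["positive", "neutral", "negative"] * 6,
                "SDNN": np.arange(18.0),
            }
        )
        design, ids, dropped = build_design_matrix(table, "SDNN")
        assert design.shape == (3, 3)
        assert not dropped
        a_pos = table[(table.participant == "A") & (table.label == "positive")]["SDNN"].mean()
        assert design[0, 0] == a_pos


class TestCategorizeVideo:
    @pytest.mark.parametrize(
        "v, a, want",
        [
            (7.8, 7.2, "positive"),
            (2.5, 7.8, "negative"),
            (5.1, 3.2, "neutral"),
            (6.5, 5.0, "none"),
            (7.5, 5.0, "none"),  # high valence but insufficient arousal
            (4.0, 3.9, "neutral"),  # boundary: valence 4 included, arousal < 4
            (7.0, 7.0, "none"),  # valence threshold is strict
        ],
    )
    def test_rules(self, v, a, want):
        assert categorize_video(v, a) == want

    def test_out_of_scale_raises(self):
        with pytest.raises(ValueError):
            categorize_video(0.5, 5.0)

    def test_all_norm_table_rows_match_their_category(self):
        norms = video_norms()
        got = [
            categorize_video(r.valence_mean, r.arousal_mean)
            for r in norms.itertuples()
        ]
        assert got == norms["category"].tolist()
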