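"""Coarticulation slope estimators, mixed model, descriptive tests."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from coartic import (
    fit_pooled_lmm,
    pearson_r,
    per_speaker_slopes,
    pooled_consonant_slopes,
    slope_ols,
    welch_t,
)
from coartic.models import DegenerateFitError, InsufficientDataError

from conftest import exact_blend_table


class TestSlopeOLS:
    def test_identity_pairs(self):
        pairs = [(v, v) for v in (0.0, 0.3, 0.7, 1.0)]
        fit = slope_ols(pairs)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)

    def test_constant_consonant_position(self):
        fit = slope_ols([(0.1, 0.4), (0.5, 0.4), (0.9, 0.4)])
        assert fit.slope == pytest.approx(0.0)
        assert fit.intercept == pytest.approx(0.4)

    def test_collinear_points(self):
        fit = slope_ols([(0.0, 0.10), (0.5, 0.35), (1.0, 0.60)])
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(0.10)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            slope_ols([(0, 0), (1, 1)])
        with pytest.raises(DegenerateFitError):
            slope_ols([(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)])

    def test_matches_normal_equations_oracle(self):
        # independent route: solve [1 v] beta = c by lstsq
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 12)
            v = rng.normal(size=n)
            if np.ptp(v) == 0:
                continue
            c = rng.normal(size=n)
            fit = slope_ols(np.column_stack([v, c]))
            beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), v]), c, rcond=None)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
            assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 1, 20)
        c = 0.2 + 0.6 * v + rng.normal(0, 0.05, 20)
        base = slope_ols(np.column_stack([v, c]))
        shifted = slope_ols(np.column_stack([v, c + 5.0]))
        assert shifted.slope == pytest.approx(base.slope, abs=1e-12)
        assert shifted.intercept == pytest.approx(base.intercept + 5.0, abs=1e-12)
        scaled = slope_ols(np.column_stack([3.0 * v, c]))
        assert scaled.slope == pytest.approx(base.slope / 3.0, abs=1e-12)

    def test_per_speaker_minimum_tokens(self):
        df = pd.DataFrame(
            {
                "speaker_id": ["a"] * 2 + ["b"] * 4,
                "consonant": "b",
                "peak_v_x": [0, 1, 0, 0.4, 0.6, 1],
                "peak_c_x": [0, 1, 0.1, 0.3, 0.5, 0.9],
            }
        )
        out = per_speaker_slopes(df, min_tokens=3)
        assert set(out["speaker_id"]) == {"b"}


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # equal variances 1, means 2 vs 3: t = -1/sqrt(2/3), WS df = 4
        res = welch_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.224745, abs=1e-6)
        assert res.df == pytest.approx(4.0, abs=1e-9)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.1, 4.0], [2.0, 2.2, 5.5]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_zero_variance_cases(self):
        assert welch_t([2, 2], [2, 2]).statistic == 0.0
        with pytest.raises(DegenerateFitError):
            welch_t([2, 2], [3, 3])


class TestPearsonR:
    def test_perfect_linear(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_direct_formula_example(self):
        res = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)

    def test_zero_variance_error(self):
        with pytest.raises(DegenerateFitError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPooledLMM:
    def test_fixed_slope_matches_ols_on_exact_data(self):
        """No noise, no random-effect variance: GLS collapses to OLS."""
        tab = exact_blend_table()
        res = fit_pooled_lmm(tab)
        fe = dict(zip(res.fixed_effects.term, res.fixed_effects.estimate))
        ref = tab[tab.consonant == "b"]
        ols = slope_ols(np.column_stack([ref.peak_v_x, ref.peak_c_x]))
        assert fe["peak_v_x"] == pytest.approx(ols.slope, abs=1e-6)

    def test_contrast_linearity(self, default_table):
        res = fit_pooled_lmm(default_table)
        con = res.age_contrasts.set_index("comparison")["estimate"]
        assert con["P1-K1"] - con["K2-K1"] == pytest.approx(con["P1-K2"], abs=1e-8)

    def test_null_age_contrasts_on_default_data(self, default_table):
        # default config gives every cohort the same weights
        res = fit_pooled_lmm(default_table)
        assert (res.age_contrasts["p"] > 0.05).all()

    def test_consonant_ordering_and_d_vs_b_sign(self, default_table):
        res = fit_pooled_lmm(default_table)
        con = res.consonant_contrasts.set_index("comparison")["estimate"]
        assert con["d-b"] < 0  # alveolar resists vocalic anticipation most

    def test_injected_cohort_effect_recovered(self):
        tab = exact_blend_table(
            cohort_speakers=(("K1", 3), ("K2", 3), ("P1", 3)),
            slope_shift_by_cohort={"P1": 0.2},
        )
        rng = np.random.default_rng(0)
        tab["peak_c_x"] = tab["peak_c_x"] + rng.normal(0, 0.01, len(tab))
        res = fit_pooled_lmm(tab)
        con = res.age_contrasts.set_index("comparison")["estimate"]
        assert con["P1-K1"] == pytest.approx(0.2, abs=0.05)
        assert con["P1-K2"] == pytest.approx(0.2, abs=0.05)
        assert con["K2-K1"] == pytest.approx(0.0, abs=0.05)

    def test_single_cohort_gives_empty_age_contrasts(self):
        tab = exact_blend_table(cohort_speakers=(("P1", 4),))
        rng = np.random.default_rng(1)
        tab["peak_c_x"] += rng.normal(0, 0.01, len(tab))
        res = fit_pooled_lmm(tab)
        assert res.age_contrasts.empty

    def test_pooled_slope_recovery(self, default_table, default_dataset):
        pooled = pooled_consonant_slopes(default_table).set_index("consonant")["slope"]
        truth = default_dataset.truth["config"]["base_weights"]
        for c, w in truth.items():
            assert pooled[c] == pytest.approx(w, abs=0.05)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestAgainstLme4:
    def test_fixed_effects_match_lmer(self, tmp_path, small_table):
        """Independent oracle: the same model specification in lme4."""
        df = small_table.copy()
        for c in ("b", "d", "g"):
            df[f"v_{c}"] = df["peak_v_x"] * (df["consonant"] == c)
        csv = tmp_path / "tab.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "fe.csv"
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$consonant <- relevel(factor(d$consonant), ref="b")
        d$cohort <- relevel(factor(d$cohort), ref="K1")
        m <- lmer(peak_c_x ~ peak_v_x*consonant + peak_v_x*cohort +
                  (0 + v_b | speaker_id) + (0 + v_d | speaker_id) +
                  (0 + v_g | speaker_id) + (0 + peak_v_x | word_id),
                  data=d, REML=TRUE,
                  control=lmerControl(check.conv.singular="ignore"))
        fe <- fixef(m)
        write.csv(data.frame(term=names(fe), estimate=unname(fe)), "{out}", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        r_fe = pd.read_csv(out).set_index("term")["estimate"]
        res = fit_pooled_lmm(small_table)
        fe = dict(zip(res.fixed_effects.term, res.fixed_effects.estimate))
        pairs = {
            "peak_v_x": "peak_v_x",
            "peak_v_x:C[d]": "peak_v_x:consonantd",
            "peak_v_x:C[g]": "peak_v_x:consonantg",
            "peak_v_x:cohort[K2]": "peak_v_x:cohortK2",
            "peak_v_x:cohort[P1]": "peak_v_x:cohortP1",
        }
        for ours, theirs in pairs.items():
            assert fe[ours] == pytest.approx(r_fe[theirs], abs=0.02), ours
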