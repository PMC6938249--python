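"""Tensor-product smooths: edf behavior, grids, oracle cross-checks."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from coartic import (
    GesturalConfig,
    build_analysis_table,
    fit_te_smooth,
    nonlinearity_report,
    pooled_consonant_slopes,
    predict_grid,
    simulate_cohort,
)
from coartic.smooths import ExtrapolationError, SmoothFit, SmoothFitError


def make_rows(v, y, spk, consonant="b"):
    return pd.DataFrame(
        {"speaker_id": spk, "consonant": consonant, "peak_v_x": v, "peak_c_x": y}
    )


def speaker_scores(spk, scores):
    return pd.Series(dict(zip(spk, scores)))


@pytest.fixture(scope="module")
def linear_rows():
    """Exactly linear in vowel position, no score effect, no noise."""
    rng = np.random.default_rng(0)
    n, n_spk = 600, 30
    spk = np.repeat([f"s{i}" for i in range(n_spk)], n // n_spk)
    score = np.repeat(rng.uniform(0, 24, n_spk), n // n_spk)
    v = rng.uniform(0, 1, n)
    y = 0.3 + 0.5 * v
    return make_rows(v, y, spk), speaker_scores(spk, score)


class TestFitTeSmooth:
    def test_linear_data_shrinks_to_edf_near_one(self, linear_rows):
        rows, scores = linear_rows
        fit = fit_te_smooth(rows, scores, score_name="score")
        assert 1.0 - 1e-6 <= fit.edf <= 1.5

    def test_sigmoid_link_detected_as_nonlinear(self):
        cfg = GesturalConfig(link="sigmoid", skill_effect=0.4)
        ds = simulate_cohort(cfg, seed=5)
        tab = build_analysis_table(ds.contours, ds.tokens)
        fit = fit_te_smooth(tab[tab.consonant == "d"], ds.scores, "composite_pa")
        assert fit.edf > 2.0
        assert fit.p < 0.05
        assert fit.score_p < 0.05

    def test_noise_score_not_significant(self, default_table):
        # skill unrelated to articulation: score direction should be null
        rng = np.random.default_rng(4)
        speakers = default_table["speaker_id"].unique()
        noise = speaker_scores(speakers, rng.uniform(0, 24, len(speakers)))
        fit = fit_te_smooth(default_table[default_table.consonant == "g"], noise, "noise")
        assert fit.score_p > 0.05

    def test_constant_score_refused(self, linear_rows):
        rows, scores = linear_rows
        with pytest.raises(SmoothFitError):
            fit_te_smooth(rows, scores * 0 + 3.0, score_name="score")

    def test_too_few_rows_refused(self, linear_rows):
        rows, scores = linear_rows
        with pytest.raises(SmoothFitError):
            fit_te_smooth(rows.head(40), scores, score_name="score")

    def test_edf_bounded_by_basis_dimension(self, default_table, default_dataset):
        fit = fit_te_smooth(
            default_table[default_table.consonant == "b"],
            default_dataset.scores, "vocabulary",
        )
        assert 1.0 - 1e-6 <= fit.edf <= fit.basis_dims[0] * fit.basis_dims[1] - 1

    def test_determinism(self, default_table, default_dataset):
        args = (default_table[default_table.consonant == "d"], default_dataset.scores, "rhyme")
        f1, f2 = fit_te_smooth(*args), fit_te_smooth(*args)
        assert f1.edf == f2.edf
        assert f1.smoothing_params == f2.smoothing_params
        np.testing.assert_array_equal(f1._beta, f2._beta)


class TestPredictGrid:
    def test_grid_shape(self, linear_rows):
        rows, scores = linear_rows
        fit = fit_te_smooth(rows, scores, score_name="score")
        grid = predict_grid(fit, n_score=5, n_vowel=7)
        assert grid.values.shape == (5, 7)

    def test_full_anticipation_surface_tracks_vowel(self):
        cfg = GesturalConfig(
            noise_sd=0.0, base_weights={"b": 1.0, "d": 1.0, "g": 1.0}, reps=3
        )
        ds = simulate_cohort(cfg, {"K1": 3, "P1": 3}, seed=6)
        tab = build_analysis_table(ds.contours, ds.tokens)
        fit = fit_te_smooth(tab[tab.consonant == "b"], ds.scores, "vocabulary")
        grid = predict_grid(fit, n_score=6, n_vowel=11)
        i02, i08 = 2, 8  # vowel grid points 0.2 and 0.8
        diff = grid.values[:, i08] - grid.values[:, i02]
        np.testing.assert_allclose(diff, 0.6, atol=0.05)

    def test_zero_anticipation_surface_flat_in_vowel(self):
        cfg = GesturalConfig(
            noise_sd=0.0, base_weights={"b": 0.0, "d": 0.0, "g": 0.0}, reps=3
        )
        ds = simulate_cohort(cfg, {"K1": 3, "P1": 3}, seed=6)
        tab = build_analysis_table(ds.contours, ds.tokens)
        fit = fit_te_smooth(tab[tab.consonant == "g"], ds.scores, "vocabulary")
        grid = predict_grid(fit, n_score=4, n_vowel=9)
        assert np.ptp(grid.values, axis=1).max() < 0.05

    def test_extrapolation_refused_then_allowed(self, linear_rows):
        rows, scores = linear_rows
        fit = fit_te_smooth(rows, scores, score_name="score")
        lo, hi = fit.score_range
        with pytest.raises(ExtrapolationError):
            predict_grid(fit, score_range=(lo - 5, hi + 5))
        grid = predict_grid(fit, n_score=3, n_vowel=3,
                            score_range=(lo - 5, hi + 5), allow_extrapolation=True)
        assert np.all(np.isfinite(grid.values))

    def test_vowel_gradient_consistent_with_ols_slope(self, default_table):
        """link=none: mean vowel-direction gradient ~ pooled OLS slope."""
        pooled = pooled_consonant_slopes(default_table).set_index("consonant")["slope"]
        rng = np.random.default_rng(2)
        speakers = default_table["speaker_id"].unique()
        score = speaker_scores(speakers, rng.uniform(0, 24, len(speakers)))
        for consonant in ("b", "d"):
            fit = fit_te_smooth(
                default_table[default_table.consonant == consonant], score, "score"
            )
            grid = predict_grid(fit, n_score=5, n_vowel=21)
            grad = np.gradient(grid.values, grid.vowel_grid, axis=1)
            assert grad.mean() == pytest.approx(pooled[consonant], abs=0.05)


class TestNonlinearityReport:
    def _fit(self, consonant, edf):
        return SmoothFit(
            consonant=consonant, score_name="rhyme", edf=edf, f_stat=1.0, p=0.5,
            score_edf=edf, score_f=1.0, score_p=0.5, smoothing_params={},
            criterion="reml", basis_dims=(5, 5), n_obs=100,
            score_range=(0, 12), vowel_range=(0, 1),
        )

    def test_sorted_by_edf_descending(self):
        rep = nonlinearity_report(
            [self._fit("b", 3.0), self._fit("d", 13.9), self._fit("g", 8.0)]
        )
        assert list(rep["consonant"]) == ["d", "g", "b"]

    def test_ties_stable_by_consonant_label(self):
        rep = nonlinearity_report([self._fit("g", 2.0), self._fit("b", 2.0)])
        assert list(rep["consonant"]) == ["b", "g"]

    def test_single_fit(self):
        rep = nonlinearity_report([self._fit("d", 5.0)])
        assert len(rep) == 1


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestAgainstMgcv:
    def test_surface_predictions_close_to_mgcv_te(self, tmp_path):
        """Independent oracle: mgcv's te() on the same nonlinear data."""
        rng = np.random.default_rng(8)
        n, n_spk = 600, 30
        spk = np.repeat([f"s{i}" for i in range(n_spk)], n // n_spk)
        score = np.repeat(rng.uniform(0, 24, n_spk), n // n_spk)
        v = rng.uniform(0, 1, n)
        y = 0.2 + 0.5 * v + 0.15 * np.sin(np.pi * score / 12) * v + rng.normal(0, 0.05, n)
        rows = make_rows(v, y, spk)
        fit = fit_te_smooth(rows, speaker_scores(spk, score), score_name="score")
        sg = np.linspace(score.min(), score.max(), 8)
        vg = np.linspace(0.05, 0.95, 8)
        S, V = np.meshgrid(sg, vg, indexing="ij")
        ours = fit.predict(S.ravel(), V.ravel())

        csv, out = tmp_path / "d.csv", tmp_path / "pred.csv"
        pd.DataFrame({"score": score, "v": v, "y": y}).to_csv(csv, index=False)
        grid_csv = tmp_path / "grid.csv"
        pd.DataFrame({"score": S.ravel(), "v": V.ravel()}).to_csv(grid_csv, index=False)
        script = f"""
        suppressMessages(library(mgcv))
        d <- read.csv("{csv}")
        g <- read.csv("{grid_csv}")
        m <- gam(y ~ te(score, v, k=c(5,5)), data=d, method="REML")
        write.csv(data.frame(p=predict(m, newdata=g)), "{out}", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        theirs = pd.read_csv(out)["p"].to_numpy()
        rmse = float(np.sqrt(np.mean((ours - theirs) ** 2)))
        assert rmse < 0.03
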