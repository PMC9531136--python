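import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import tomoloc as tl
from tomoloc.dlt import DESIGNS, GeneFitResult, MIN_DISPERSION


def _one_stage_samples(n_reps=3):
    rows = [
        (f"sp_small_r{r}_{s}", "sp", "small", f"r{r}", s)
        for r in range(1, n_reps + 1)
        for s in tl.SECTIONS
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "species", "stage", "replicate", "section"]
    ).set_index("sample_id")


def _two_stage_samples(n_reps=1):
    rows = [
        (f"sp_{st}_r{r}_{s}", "sp", st, f"r{r}", s)
        for st in ("small", "big")
        for r in range(1, n_reps + 1)
        for s in tl.SECTIONS
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "species", "stage", "replicate", "section"]
    ).set_index("sample_id")


class TestDesignMatrix:
    def test_within_stage_treatment_coding(self):
        samples = _one_stage_samples(n_reps=2)
        spec = DESIGNS["within_stage"]
        X, names = tl.build_design_matrix(samples, spec.full_terms, ["small"])
        # intercept + (2-1) replicate + 4 position columns
        assert X.shape == (10, 6)
        assert names[0] == "intercept"
        assert sum(n.startswith("position") for n in names) == 4

    def test_total_between_stages_columns(self):
        samples = _two_stage_samples()
        spec = DESIGNS["total_between_stages"]
        Xf, _ = tl.build_design_matrix(samples, spec.full_terms, ["small", "big"])
        Xr, _ = tl.build_design_matrix(samples, spec.reduced_terms, ["small", "big"])
        assert Xf.shape[1] == 2 and Xr.shape[1] == 1

    def test_interaction_block_size(self):
        samples = _two_stage_samples()
        spec = DESIGNS["profile_across_stages"]
        X, names = tl.build_design_matrix(samples, spec.full_terms, ["small", "big"])
        inter = [n for n in names if ":" in n]
        assert len(inter) == 4  # (2-1) stages x (5-1) positions
        assert X.shape[1] == 1 + 1 + 4 + 4

    def test_stage_levels_follow_declared_order(self):
        samples = _two_stage_samples()
        _, names = tl.build_design_matrix(
            samples, ("intercept", "Size"), ["big", "small"]
        )
        assert names == ["intercept", "Size[small]"]  # 'big' is the reference

    def test_single_level_tested_factor_raises(self):
        samples = _one_stage_samples()
        with pytest.raises(ValueError, match="single level"):
            tl.build_design_matrix(
                samples, ("intercept", "Size"), ["small"], tested_terms=("Size",)
            )

    def test_aliased_columns_dropped_with_warning(self):
        samples = _one_stage_samples(n_reps=2)
        # duplicating the replicate factor makes its columns aliased
        with pytest.warns(UserWarning, match="aliased"):
            X, _ = tl.build_design_matrix(
                samples, ("intercept", "replicate", "replicate", "position"), ["small"]
            )
        assert np.linalg.matrix_rank(X) == X.shape[1]


class TestDispersion:
    def test_exact_fit_floors_dispersion(self):
        X = np.ones((10, 1))
        y = np.full(10, 50.0)
        assert tl.estimate_dispersion(y, X, np.ones(10)) == MIN_DISPERSION

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(100, size=20)
        alpha = tl.estimate_dispersion(y, np.ones((20, 1)), np.ones(20))
        assert alpha < 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        r = 1 / 0.2
        y = rng.negative_binomial(r, r / (r + 100.0), size=200)
        alpha = tl.estimate_dispersion(y, np.ones((200, 1)), np.ones(200))
        assert 0.1 <= alpha <= 0.3

    def test_all_zero_counts_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            alpha = tl.estimate_dispersion(
                np.zeros(10), np.ones((10, 1)), np.ones(10)
            )
        assert alpha == MIN_DISPERSION


class TestNbGlmFit:
    def test_intercept_only_reproduces_sample_mean(self):
        y = np.array([3, 9, 5, 7, 6.0])
        fit = tl.fit_nb_glm(y, np.ones((5, 1)), np.ones(5), alpha=0.1)
        assert fit.converged
        np.testing.assert_allclose(fit.fitted, y.mean(), rtol=1e-8)

    def test_poisson_limit_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        samples = _one_stage_samples()
        X, _ = tl.build_design_matrix(
            samples, DESIGNS["within_stage"].full_terms, ["small"]
        )
        y = rng.poisson(np.exp(X @ np.array([4.0, 0.2, -0.1, 0.5, 0.3, -0.2, 0.1])))
        sf = np.full(len(y), 1.3)
        fit = tl.fit_nb_glm(y, X, sf, alpha=MIN_DISPERSION)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(sf)).fit()
        np.testing.assert_allclose(
            list(fit.coefficients.values()), ref.params, atol=1e-4
        )

    def test_fixed_alpha_matches_statsmodels_nb(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = rng.negative_binomial(5, 5 / (5 + np.exp(3 + 0.5 * X[:, 1])))
        fit = tl.fit_nb_glm(y, X, np.ones(40), alpha=0.2)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=0.2)).fit()
        np.testing.assert_allclose(
            list(fit.coefficients.values()), ref.params, rtol=1e-6
        )
        assert fit.log_likelihood == pytest.approx(ref.llf, rel=1e-6)

    def test_saturated_design_fits_observations(self):
        y = np.array([4, 10, 2, 30, 7.0])
        fit = tl.fit_nb_glm(y, np.eye(5), np.ones(5), alpha=0.1)
        np.testing.assert_allclose(fit.fitted, y, rtol=1e-6)


class TestLrt:
    def _fake(self, ll, k, alpha=0.1):
        return GeneFitResult("g", ll, {f"b{i}": 0.0 for i in range(k)}, alpha, True)

    def test_identical_fits_give_p_one(self):
        stat, p = tl.lrt(self._fake(-10.0, 2), self._fake(-10.0, 1))
        assert stat == 0.0 and p == 1.0

    def test_chi_square_reference_value(self):
        stat, p = tl.lrt(self._fake(-10.0 + 3.84 / 2, 2), self._fake(-10.0, 1))
        assert p == pytest.approx(0.0500, abs=5e-4)

    def test_df_and_dispersion_checks(self):
        with pytest.raises(ValueError, match="df"):
            tl.lrt(self._fake(-9.0, 1), self._fake(-10.0, 1))
        with pytest.raises(ValueError, match="dispersion"):
            tl.lrt(self._fake(-9.0, 2, 0.1), self._fake(-10.0, 1, 0.2))

    def test_statistic_invariant_to_reference_relabeling(self):
        rng = np.random.default_rng(4)
        samples = _one_stage_samples()
        y = rng.poisson(200, size=len(samples))
        sf = np.ones(len(y))
        spec = DESIGNS["within_stage"]

        def stat_for(sample_df):
            Xf, _ = tl.build_design_matrix(sample_df, spec.full_terms, ["small"])
            Xr, _ = tl.build_design_matrix(sample_df, spec.reduced_terms, ["small"])
            alpha = tl.estimate_dispersion(y, Xf, sf)
            return tl.lrt(
                tl.fit_nb_glm(y, Xf, sf, alpha), tl.fit_nb_glm(y, Xr, sf, alpha)
            )[0]

        relabeled = samples.copy()
        relabeled["section"] = relabeled["section"].map(
            {"A": "E", "B": "D", "C": "C", "D": "B", "E": "A"}
        )
        assert stat_for(samples) == pytest.approx(stat_for(relabeled), abs=1e-6)

    def test_nested_model_loglik_monotone(self):
        rng = np.random.default_rng(5)
        samples = _one_stage_samples()
        y = rng.poisson(150, size=len(samples))
        sf = np.ones(len(y))
        spec = DESIGNS["within_stage"]
        Xf, _ = tl.build_design_matrix(samples, spec.full_terms, ["small"])
        Xr, _ = tl.build_design_matrix(samples, spec.reduced_terms, ["small"])
        alpha = tl.estimate_dispersion(y, Xf, sf)
        full = tl.fit_nb_glm(y, Xf, sf, alpha)
        red = tl.fit_nb_glm(y, Xr, sf, alpha)
        assert full.log_likelihood >= red.log_likelihood - 1e-8


class TestDetectDlts:
    def test_count_threshold_vetoes_low_abundance_genes(self):
        # strongly localized but scarce genes (~10 transcripts/oocyte)
        cfg = tl.simulate.SimulationConfig(
            blocks=(tl.GeneBlock(40, "extreme_vegetal"),
                    tl.GeneBlock(60, "uniform")),
            stages=("small",),
            base_abundance_range=(10.0, 10.0),
            dispersion=0.01,
            library_size_factor_range=(1.0, 1.0),
            seed=6,
        )
        scm, truth = tl.generate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = tl.detect_dlts(scm, "within_stage", stage="small")
        significant = res[res["padj"] < 0.1]
        assert len(significant) > 0  # localization is detectable...
        assert not significant["is_dlt"].any()  # ...but below the count floor

    def test_padj_bounds_and_monotonicity(self, null_scm):
        scm, _ = null_scm
        res = tl.detect_dlts(scm, "within_stage", stage="small")
        ok = res.dropna(subset=["padj"])
        assert (ok["padj"] >= ok["p_value"] - 1e-12).all()
        order = ok.sort_values("p_value")
        assert order["padj"].is_monotonic_increasing

    def test_total_test_needs_two_stages(self, null_scm):
        scm, _ = null_scm
        with pytest.raises(ValueError, match="2 stages|single level"):
            tl.detect_dlts(scm, "total_between_stages")

    def test_total_between_stages_detects_degradation(self):
        cfg = tl.simulate.dynamics_benchmark_config(
            seed=8, n_per_group=15, n_background=60
        )
        scm, truth = tl.generate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = tl.detect_dlts(scm, "total_between_stages")
        m = res.merge(truth.reset_index()[["gene_id", "dynamics"]], on="gene_id")
        changed = m[m["dynamics"] != "stable"]
        stable = m[m["dynamics"] == "stable"]
        assert (changed["padj"] < 0.1).mean() >= 0.95
        assert (stable["padj"] < 0.1).mean() <= 0.1
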