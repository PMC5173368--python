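"""LRT machinery and the elimination / interaction-search protocol."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from cavenet import (ModelSpec, SimulationConfig, augment_with_predictor,
                     add_variance_function, backward_eliminate, fit_lmm,
                     interaction_search, lrt, residual_profile,
                     simulate_landscape)
from cavenet.results import LRTResult


class TestLRT:
    def test_identical_models_chi2_zero_p_one(self, small_landscape):
        spec = ModelSpec("richness", "gaussian", fixed_terms=("log(area_m2)",))
        m = fit_lmm(spec, small_landscape)
        res = lrt(m, m)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_chi2_quantile_matches_reference(self):
        # independent CDF check: chi2=3.841, df=1 -> p=0.05
        res = LRTResult.from_logliks(0.0, -3.841 / 2.0, df=1)
        assert res.p == pytest.approx(chi2_dist.sf(3.841, 1), abs=1e-12)
        assert res.p == pytest.approx(0.05, abs=5e-4)

    def test_loglik_monotone_in_terms(self, small_landscape):
        base = ModelSpec("richness", "gaussian", fixed_terms=("log(area_m2)",))
        bigger = ModelSpec("richness", "gaussian",
                           fixed_terms=("log(area_m2)", "guano", "roots"))
        from cavenet.formula import complete_cases

        rows = complete_cases(small_landscape, bigger)
        a = fit_lmm(base, small_landscape, rows=rows)
        b = fit_lmm(bigger, small_landscape, rows=rows)
        assert b.loglik >= a.loglik - 1e-6
        res = lrt(b, a)
        assert res.df == 2 and res.chi2 >= 0

    def test_non_nested_rejected(self, small_landscape):
        a = fit_lmm(ModelSpec("richness", "gaussian", fixed_terms=("guano",)),
                    small_landscape)
        b = fit_lmm(ModelSpec("richness", "gaussian", fixed_terms=("roots",)),
                    small_landscape)
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_differing_rows_rejected(self, small_landscape):
        spec_small = ModelSpec("richness", "gaussian", fixed_terms=("guano",))
        spec_big = ModelSpec("richness", "gaussian", fixed_terms=("guano", "roots"))
        a = fit_lmm(spec_small, small_landscape.iloc[:300])
        b = fit_lmm(spec_big, small_landscape)
        with pytest.raises(ValueError, match="n_obs"):
            lrt(b, a)

    def test_reml_fixed_effect_lrt_rejected(self, small_landscape):
        spec = ModelSpec("richness", "gaussian", fixed_terms=("guano", "roots"),
                         estimation="REML")
        m = fit_lmm(spec, small_landscape)
        r = fit_lmm(spec.drop("roots"), small_landscape)
        with pytest.raises(ValueError, match="ML"):
            lrt(m, r)


class TestBackwardElimination:
    def test_significant_terms_never_dropped(self):
        t = simulate_landscape(SimulationConfig(n_caves=1000, seed=31,
                                                spatial_field_sd=0.0))
        spec = ModelSpec("richness", "gaussian", fixed_terms=("log(area_m2)",))
        trace = backward_eliminate(spec, t)
        assert [s for s in trace.steps if s.action == "drop"] == []
        assert trace.final_spec.fixed_terms == ("log(area_m2)",)

    def test_single_true_predictor_selected(self):
        rng = np.random.default_rng(5)
        n = 1000
        d = pd.DataFrame({
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
            "x3": rng.normal(size=n), "grp": rng.integers(0, 8, n).astype(str),
        })
        d["y"] = 3.0 * d.x1 + rng.normal(size=n)
        spec = ModelSpec("y", "gaussian", fixed_terms=("x1", "x2", "x3"),
                         group="grp")
        trace = backward_eliminate(spec, d)
        assert trace.final_spec.fixed_terms == ("x1",)
        dropped = [s.term for s in trace.steps if s.action == "drop"]
        assert set(dropped) == {"x2", "x3"}
        # every drop step was non-significant, every keep significant
        for s in trace.steps:
            assert (s.lrt.p >= 0.05) if s.action == "drop" else (s.lrt.p < 0.05)

    def test_null_terms_retained_at_alpha_rate(self):
        """Type-I calibration: under all-zero coefficients each term
        survives elimination with probability ~ alpha."""
        rng = np.random.default_rng(6)
        kept = 0
        reps, n = 60, 300
        for _ in range(reps):
            d = pd.DataFrame({
                "x1": rng.normal(size=n), "x2": rng.normal(size=n),
                "y": rng.normal(size=n),
                "grp": rng.integers(0, 5, n).astype(str),
            })
            trace = backward_eliminate(
                ModelSpec("y", "gaussian", fixed_terms=("x1", "x2"), group="grp"), d)
            kept += len(trace.final_spec.fixed_terms)
        rate = kept / (2 * reps)
        assert 0.005 < rate < 0.12  # ~0.05 with binomial noise at 120 trials


class TestInteractionSearch:
    def test_candidate_set_is_pairs_of_retained_mains(self, small_landscape):
        spec = ModelSpec("richness", "gaussian",
                         fixed_terms=("log(area_m2)", "roots", "guano"))
        from cavenet.formula import normalize_interaction
        from itertools import combinations

        cands = {normalize_interaction(p)
                 for p in combinations(spec.fixed_terms, 2)}
        assert cands == {"log(area_m2):roots", "guano:log(area_m2)",
                         "guano:roots"}

    def test_true_interaction_recovered(self):
        t = simulate_landscape(SimulationConfig(n_caves=1000, seed=32,
                                                spatial_field_sd=0.0))
        spec = ModelSpec("richness", "gaussian",
                         fixed_terms=("log(area_m2)", "guano", "water_reservoirs",
                                      "detritus", "roots", "bat_population"))
        trace = interaction_search(backward_eliminate(spec, t), t)
        added = [s.term for s in trace.steps if s.action == "add_interaction"]
        assert "guano:log(area_m2)" in added

    def test_greedy_and_exhaustive_agree_on_clear_signal(self):
        t = simulate_landscape(SimulationConfig(n_caves=800, seed=33,
                                                spatial_field_sd=0.0))
        spec = ModelSpec("richness", "gaussian",
                         fixed_terms=("log(area_m2)", "guano", "roots"))
        base = backward_eliminate(spec, t)
        greedy = interaction_search(base, t)
        exhaustive = interaction_search(base, t, exhaustive=True)
        assert "guano:log(area_m2)" in greedy.final_spec.interactions
        assert "guano:log(area_m2)" in exhaustive.final_spec.interactions


class TestVarianceFunction:
    def test_heteroscedastic_extension_detected(self):
        rng = np.random.default_rng(44)
        n = 800
        strat = rng.integers(0, 2, n)
        grp = rng.integers(0, 6, n)
        d = pd.DataFrame({
            "x": rng.normal(size=n), "stratum": strat.astype(str),
            "grp": grp.astype(str),
        })
        d["y"] = 1.0 + 2.0 * d.x + rng.normal(0, 1.5, 6)[grp] \
            + rng.normal(0, np.where(strat == 1, 4.0, 1.0))
        base = backward_eliminate(
            ModelSpec("y", "gaussian", fixed_terms=("x",), group="grp"), d)
        out = add_variance_function(base, d, strata="stratum")
        step = out.steps[-1]
        assert step.action == "add_variance_function"
        assert step.lrt.p < 0.001
        assert out.final_spec.variance_strata == "stratum"


class TestResidualsAndAugment:
    def test_wellspecified_residuals_show_no_structure(self, model_landscape):
        spec = ModelSpec(
            "richness", "gaussian",
            fixed_terms=("log(area_m2)", "guano", "water_reservoirs",
                         "detritus", "roots", "bat_population"),
            interactions=(("log(area_m2)", "guano"),))
        m = fit_lmm(spec, model_landscape)
        coords = model_landscape.loc[m.row_index, ["x_m", "y_m"]].to_numpy()
        prof = residual_profile(m, coords, n_bands=10)
        pvals = prof.to_frame()["p"].dropna()
        assert (pvals < 0.05).sum() <= 2  # calibration noise only

    def test_omitted_spatial_field_leaves_structure(self):
        t = simulate_landscape(SimulationConfig(
            n_caves=600, seed=35, spatial_field_sd=15.0, spatial_range_m=2000.0))
        spec = ModelSpec("richness", "gaussian", fixed_terms=("log(area_m2)",))
        m = fit_lmm(spec, t)
        coords = t.loc[m.row_index, ["x_m", "y_m"]].to_numpy()
        frame = residual_profile(m, coords, n_bands=10).to_frame()
        # the short-range field survives in the smallest distance bands
        assert (frame["p"].iloc[:3] < 0.05).any()

    def test_augmenting_with_duplicate_term_fails(self, small_landscape):
        spec = ModelSpec("richness", "gaussian", fixed_terms=("guano",))
        with pytest.raises((np.linalg.LinAlgError, ValueError)):
            augment_with_predictor(spec, "guano", small_landscape)

    def test_richness_associated_with_troglobite_richness(self, model_landscape):
        """Adding troglobite richness to the richness model on the subset
        where it is observed yields a positive, significant coefficient
        (simulated troglobite richness is a thinned count of richness)."""
        spec = ModelSpec("richness", "gaussian", fixed_terms=("log(area_m2)",))
        d = model_landscape.copy()
        d["troglobite_richness"] = d["troglobite_richness"].astype("Float64")
        fit, res = augment_with_predictor(spec, "troglobite_richness", d)
        assert fit.coefficients["troglobite_richness"] > 0
        assert res.p < 0.05
        assert fit.n_obs < len(model_landscape)  # subset with data available
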