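import numpy as np
import pandas as pd
import pytest

from clonalmix.ccf_inference import saf_bounds
from clonalmix.sagp_inference import CopyState, fit_all_segments, mean_copy
from clonalmix.simulation import (SimulationConfig, default_state_ratios,
                                  evaluate_ccf, evaluate_sagp, sagp_grid,
                                  simulate_scna_dataset, simulate_snv_dataset,
                                  run_comparison_protocol)


class TestScnaDataset:
    def test_default_counts_and_clone_split(self):
        cfg = SimulationConfig(p_dom=0.9, p_sub=0.4, seed=1)
        segs = simulate_scna_dataset(cfg)
        assert len(segs) == 400
        assert (segs["clone"] == "euploid").sum() == 200
        assert (segs["clone"] == "dominant").sum() == 133
        assert (segs["clone"] == "minor").sum() == 67

    def test_noiseless_observables_are_canonical(self):
        cfg = SimulationConfig(p_dom=0.7, p_sub=0.2, sigma_baf=0.0,
                               sigma_lrr=0.0, seed=2)
        segs = simulate_scna_dataset(cfg)
        for _, s in segs.iterrows():
            st = CopyState(int(s["true_nb"]), int(s["true_nt"]))
            n_bar = mean_copy(st, s["true_p"])
            assert s["med_fbaf"] == pytest.approx(
                abs(0.5 - (s["true_p"] * st.n_b + 1 - s["true_p"]) / n_bar),
                abs=1e-12)
            assert s["med_lrr"] == pytest.approx(np.log2(n_bar) - 1,
                                                 abs=1e-12)

    def test_state_frequencies_match_ratios(self):
        cfg = SimulationConfig(p_dom=0.9, p_sub=0.4, n_scna=10000,
                               n_euploid=0, seed=3)
        segs = simulate_scna_dataset(cfg)
        counts = segs.groupby(["true_nb", "true_nt"]).size()
        for (nb, nt), weight in default_state_ratios().items():
            observed = counts.get((nb, nt), 0) / 10000
            assert observed == pytest.approx(weight, abs=0.02)

    def test_seed_determinism(self):
        cfg = SimulationConfig(p_dom=0.9, p_sub=0.4, seed=4)
        a = simulate_scna_dataset(cfg, np.random.default_rng(4))
        b = simulate_scna_dataset(cfg, np.random.default_rng(4))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_dom=0.4, p_sub=0.5)


class TestSagpGrid:
    def test_default_grid_has_55_pairs(self):
        pairs = sagp_grid()
        assert len(pairs) == 55
        assert all(p_sub < p_dom for p_dom, p_sub in pairs)

    def test_smallest_dominant_contributes_one_pair(self):
        assert [p for p in sagp_grid() if p[0] == pytest.approx(0.1)] \
            == [(0.1, 0.0)]

    def test_coarse_grid(self):
        assert sagp_grid(0.5) == [(0.5, 0.0), (1.0, 0.0), (1.0, 0.5)]


@pytest.fixture(scope="module")
def fitted_tumor():
    cfg = SimulationConfig(p_dom=0.9, p_sub=0.4, seed=9)
    segs = simulate_scna_dataset(cfg, np.random.default_rng(9))
    return cfg, fit_all_segments(segs)


class TestSnvDataset:
    def test_mean_depth_matches_coverage(self, fitted_tumor):
        cfg, fitted = fitted_tumor
        var = simulate_snv_dataset(cfg, fitted, np.random.default_rng(1))
        assert var["n_depth"].mean() == pytest.approx(cfg.coverage, abs=1.0)
        assert (var["n_depth"] >= 1).all()

    def test_euploid_truth_is_twice_saf(self, fitted_tumor):
        cfg, fitted = fitted_tumor
        var = simulate_snv_dataset(cfg, fitted, np.random.default_rng(2))
        eu = var[var["host_kind"] == "euploid"]
        assert len(eu) == pytest.approx(cfg.n_snv / 2, rel=0.15)
        np.testing.assert_allclose(eu["true_ccf"], 2 * eu["true_f"],
                                   atol=1e-12)

    def test_simulated_saf_inside_scenario_zone(self, fitted_tumor):
        cfg, fitted = fitted_tumor
        var = simulate_snv_dataset(cfg, fitted, np.random.default_rng(3))
        sc = var[var["host_kind"] == "scna"]
        for _, v in sc.iterrows():
            lo, hi = saf_bounds(CopyState(int(v["host_nb"]),
                                          int(v["host_nt"])),
                                v["host_p"], v["true_scenario"])
            assert lo - 1e-12 <= v["true_f"] <= hi + 1e-12


class TestEvaluation:
    def test_perfect_estimates_score_perfectly(self, fitted_tumor):
        cfg, fitted = fitted_tumor
        var = simulate_snv_dataset(cfg, fitted, np.random.default_rng(5))
        var["ccf"] = var["true_ccf"]
        m = evaluate_ccf(var)
        assert m["spearman"] == pytest.approx(1.0)
        assert m["mad"] == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_run_has_no_state_errors(self):
        cfg = SimulationConfig(p_dom=0.7, p_sub=0.3, sigma_baf=0.0,
                               sigma_lrr=0.0, seed=6)
        segs = simulate_scna_dataset(cfg, np.random.default_rng(6))
        fitted = fit_all_segments(segs)
        m = evaluate_sagp(fitted)
        assert m["state_error_scna"] == pytest.approx(0.0, abs=1e-12)
        assert m["mad_scna_all"] == pytest.approx(0.0, abs=1e-3)

    def test_sagp_mad_nondecreasing_in_baf_noise(self):
        mads = []
        for sigma in (0.005, 0.02, 0.08):
            cfg = SimulationConfig(p_dom=0.8, p_sub=0.4, sigma_baf=sigma,
                                   seed=8)
            segs = simulate_scna_dataset(cfg, np.random.default_rng(8))
            fitted = fit_all_segments(segs)
            mads.append(evaluate_sagp(fitted)["mad_scna_all"])
        assert mads[0] <= mads[1] + 1e-3 <= mads[2] + 2e-3


class TestNoiseFloor:
    def test_euploid_stratum_rank_correlation_is_binomial_limited(self):
        """For euploid-hosted variants the estimator is exactly 2*S/N, so the
        rank correlation with truth is pinned by binomial read noise: about
        0.93 at mean depth 50, rising with depth."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(0)
        rhos = {}
        for k in (50, 100):
            f = rng.uniform(0, 0.5, 4000)
            n = np.maximum(rng.poisson(k, 4000), 1)
            fh = rng.binomial(n, f) / n
            rhos[k] = spearmanr(2 * f, 2 * fh)[0]
        assert 0.91 < rhos[50] < 0.95
        assert rhos[100] > rhos[50]


class TestComparisonProtocol:
    def test_placement_and_bias_directions(self):
        r = run_comparison_protocol(seed=5)
        v = r["variants"]
        # ~half of the mutations land in sCNA regions (binomial around 0.5)
        assert 0.35 <= r["n_in_scna"] / len(v) <= 0.65
        # mis-specified estimators are worse than the full model where the
        # mutation predates the sCNA (the population they ignore is real)
        a1 = v[(v["true_scenario"] == "A1") & v["ccf"].notna()
               & (v["host_nt"] > 1)]
        full_bias = (a1["ccf"] - a1["true_ccf"]).abs().median()
        naive_bias = (a1["ccf_ignore_r1"] - a1["true_ccf"]).abs().median()
        assert full_bias < naive_bias
        # and the co-occurrence estimator systematically underestimates there
        assert (a1["ccf_ignore_r1"] - a1["true_ccf"]).median() < 0
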