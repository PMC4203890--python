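import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import binom

from clonalmix.ccf_inference import (CCFEstimate, admissible_scenarios,
                                     assign_scenario, ccf_expression,
                                     ccf_point_estimate,
                                     ccf_posterior_moments,
                                     estimate_ccf_for_variant,
                                     estimate_ccf_batch, mean_copy_number,
                                     saf_bounds, scenario_probabilities)
from clonalmix.sagp_inference import CopyState

STATES = [CopyState(0, 1), CopyState(0, 2), CopyState(1, 3), CopyState(2, 4)]


def brute_force_saf_range(state, p, scenario, grid=201):
    """Independent oracle: enumerate the three-population model of each
    scenario on a fine grid and read off the attainable SAF extremes.

    A1/A2: sCNA cells are r2 = p, the mutation-only population r1 ranges over
    [0, 1-p]; mutant copies per r2 cell are n_a (A1) or n_b (A2).
    B: sCNA first, r1 + r2 = p, mutation in r2 of them (one mutant copy).
    C: independent lineages, r2 = p, mutation-only r1 in [0, 1-p].
    """
    n_bar = mean_copy_number(p, state.n_t)
    fs = []
    if scenario in ("A1", "A2"):
        m = state.n_a if scenario == "A1" else state.n_b
        for r1 in np.linspace(0.0, 1.0 - p, grid):
            fs.append((r1 + m * p) / n_bar)
    elif scenario == "B":
        for r2 in np.linspace(0.0, p, grid):
            fs.append(r2 / n_bar)
    elif scenario == "C":
        for r1 in np.linspace(0.0, 1.0 - p, grid):
            fs.append(r1 / n_bar)
    return min(fs), max(fs)


class TestMeanCopyNumber:
    @pytest.mark.parametrize("p,n_t,expected", [
        (0.0, 3, 2.0), (1.0, 3, 3.0), (0.5, 3, 2.5), (0.4, 1, 1.6)])
    def test_values(self, p, n_t, expected):
        assert mean_copy_number(p, n_t) == pytest.approx(expected)


class TestAdmissibleScenarios:
    def test_sets(self):
        assert admissible_scenarios(CopyState(1, 3)) == ("A1", "A2", "B", "C")
        assert admissible_scenarios(CopyState(0, 1)) == ("A1", "A2", "B", "C")
        assert admissible_scenarios(CopyState(0, 2)) == ("A1", "B", "C")
        assert admissible_scenarios(CopyState(2, 4)) == ("A1", "B", "C")

    def test_euploid_rejected(self):
        with pytest.raises(ValueError):
            admissible_scenarios(CopyState(1, 2))


class TestCcfExpression:
    def test_amplification_a1(self):
        assert ccf_expression(0.4, CopyState(1, 3), 0.5, "A1") \
            == pytest.approx(0.4 * 2.5 - 0.5)

    def test_amplification_upper_bound_maps_to_full_ccf(self):
        """At the A1 zone's upper SAF limit every cell carries the mutation."""
        for p in np.arange(0.05, 1.0, 0.05):
            f_h = (1 + p) / (2 + p)
            assert ccf_expression(f_h, CopyState(1, 3), p, "A1") \
                == pytest.approx(1.0, abs=1e-12)

    def test_cnloh_and_deletion_specials(self):
        assert ccf_expression(0.6, CopyState(0, 2), 0.4, "A1") \
            == pytest.approx(2 * 0.6 - 0.4)
        assert ccf_expression(0.6, CopyState(0, 2), 0.4, "B") \
            == pytest.approx(1.2)
        for scen in ("A1", "A2", "B", "C"):
            assert ccf_expression(0.5, CopyState(0, 1), 0.6, scen) \
                == pytest.approx(0.5 * 1.4)

    def test_general_form_matches_specials_for_het_amplification(self):
        """For n_b >= 1 the per-type formulas and the general n_bar-based
        expressions are identical over the (f, p) grid."""
        for f, p in itertools.product(np.linspace(0.05, 0.95, 7),
                                      np.linspace(0.1, 0.9, 7)):
            n_bar = mean_copy_number(p, 3)
            assert ccf_expression(f, CopyState(1, 3), p, "A1") \
                == pytest.approx(f * (2 + p) - p, abs=1e-12)
            assert ccf_expression(f, CopyState(1, 3), p, "A2") \
                == pytest.approx(f * (2 + p), abs=1e-12)
            assert n_bar == pytest.approx(2 + p)


class TestSafBounds:
    @pytest.mark.parametrize("state,p,scenario,expected", [
        (CopyState(1, 3), 0.5, "A1", (0.4, 0.6)),
        (CopyState(1, 3), 0.5, "A2", (0.2, 0.4)),
        (CopyState(1, 3), 0.5, "B", (0.0, 0.2)),
        (CopyState(0, 2), 0.4, "C", (0.0, 0.3)),
        (CopyState(0, 2), 0.4, "A1", (0.4, 0.7)),
        (CopyState(0, 1), 0.5, "A1", (1 / 3, 2 / 3)),
    ])
    def test_known_intervals(self, state, p, scenario, expected):
        assert saf_bounds(state, p, scenario) == pytest.approx(expected)

    def test_zone_oracle_equivalence(self):
        """Analytic bounds equal the brute-force population-model extremes."""
        for state in STATES:
            for p in np.arange(0.1, 1.0, 0.1):
                for scen in admissible_scenarios(state):
                    lo, hi = saf_bounds(state, p, scen)
                    blo, bhi = brute_force_saf_range(state, p, scen)
                    assert lo == pytest.approx(blo, abs=1e-9), (state, p, scen)
                    assert hi == pytest.approx(bhi, abs=1e-9), (state, p, scen)

    def test_ccf_in_unit_interval_inside_zone(self):
        """Pre-clip CCF stays within [0, 1] whenever (f, p) lies inside the
        scenario's admissible zone."""
        for state in STATES:
            for p in np.arange(0.1, 1.0, 0.2):
                for scen in admissible_scenarios(state):
                    lo, hi = saf_bounds(state, p, scen)
                    for f in np.linspace(lo, hi, 11):
                        ccf = ccf_expression(f, state, p, scen)
                        assert -1e-9 <= ccf <= 1 + 1e-9, (state, p, scen, f)


class TestScenarioProbabilities:
    def test_matches_quadrature(self):
        """Closed-form incomplete-beta zone masses equal direct quadrature."""
        cases = [(CopyState(1, 3), 0.5, 50, 100),
                 (CopyState(1, 3), 0.5, 10, 100),
                 (CopyState(0, 2), 0.7, 30, 60),
                 (CopyState(0, 1), 0.9, 20, 20)]
        for state, p, s, n in cases:
            probs, flag = scenario_probabilities(s, n, state, p)
            assert not flag
            raw = {}
            for scen in admissible_scenarios(state):
                lo, hi = saf_bounds(state, p, scen)
                raw[scen] = quad(lambda f: binom.pmf(s, n, f), lo, hi,
                                 epsabs=1e-13, limit=200)[0]
            total = sum(raw.values())
            for scen, val in probs.items():
                assert val == pytest.approx(raw[scen] / total, abs=1e-8)

    def test_mid_zone_read_is_dominantly_a1(self):
        probs, _ = scenario_probabilities(50, 100, CopyState(1, 3), 0.5)
        assert probs["A1"] > 0.95

    def test_equal_intervals_split_evenly(self):
        # f_hat = 0.1 sits inside both B [0, 0.2] and C [0, 0.2] at p = 0.5
        probs, _ = scenario_probabilities(10, 100, CopyState(1, 3), 0.5)
        assert probs["B"] == pytest.approx(probs["C"], abs=1e-12)
        assert probs["B"] == pytest.approx(0.5, abs=0.02)
        assert probs["A1"] < 1e-6

    def test_deletion_high_saf_concentrates_on_a1(self):
        probs, _ = scenario_probabilities(20, 20, CopyState(0, 1), 0.9)
        assert max(probs, key=probs.get) == "A1"
        assert probs["A1"] > 0.8

    def test_out_of_zone_flag(self):
        # amplification zones at p=0.5 cover f <= 0.6; an observed f_hat of
        # 0.9 at extreme depth underflows every zone integral
        probs, flag = scenario_probabilities(90000, 100000, CopyState(1, 3),
                                             0.5)
        assert flag
        assert sum(probs.values()) == pytest.approx(1.0)


class TestAssignScenario:
    @pytest.mark.parametrize("probs,expected", [
        ({"A1": 0.97, "A2": 0.01, "B": 0.01, "C": 0.01}, ("A1",)),
        ({"A1": 0.50, "A2": 0.02, "B": 0.24, "C": 0.24}, ("A1", "B", "C")),
        ({"A1": 0.25, "A2": 0.25, "B": 0.25, "C": 0.25},
         ("A1", "A2", "B", "C")),
    ])
    def test_smallest_qualifying_combination(self, probs, expected):
        assert assign_scenario(probs) == expected

    def test_search_space_is_fifteen_combinations(self):
        combos = [c for size in range(1, 5)
                  for c in itertools.combinations(("A1", "A2", "B", "C"),
                                                  size)]
        assert len(combos) == 15


class TestCcfPointEstimate:
    def test_shared_expression_evaluates(self):
        ccf, raw, _ = ccf_point_estimate(0.2, CopyState(1, 3), 0.5, ("B", "C"))
        assert ccf == pytest.approx(0.5)

    def test_conflicting_expressions_missing(self):
        ccf, raw, candidates = ccf_point_estimate(0.4, CopyState(1, 3), 0.5,
                                                  ("A1", "C"))
        assert ccf is None
        assert sorted(candidates) == pytest.approx(
            sorted([0.4 * 2.5 - 0.5, 0.4 * 2.5]))

    def test_deletion_always_estimable(self):
        ccf, _, _ = ccf_point_estimate(0.5, CopyState(0, 1), 0.6,
                                       ("A1", "A2", "B", "C"))
        assert ccf == pytest.approx(0.5 * 1.4)


class TestPosteriorMoments:
    def test_diploid_expectation_converges(self):
        ex, var, bad = ccf_posterior_moments(250, 1000, None, 0.0, "diploid")
        assert not bad
        assert abs(ex - 0.5) < 0.01

    def test_variance_shrinks_with_depth(self):
        _, v100, _ = ccf_posterior_moments(25, 100, CopyState(1, 3), 0.5, "B")
        _, v1000, _ = ccf_posterior_moments(250, 1000, CopyState(1, 3), 0.5,
                                            "B")
        assert v100 > v1000 > 0

    def test_expectation_converges_to_point_formula(self):
        """At very high depth the posterior mean approaches the plug-in
        CCF expression."""
        n = 10 ** 4
        for state, p, scen, f in [(CopyState(1, 3), 0.5, "A1", 0.5),
                                  (CopyState(0, 1), 0.6, "B", 0.2),
                                  (CopyState(0, 2), 0.4, "C", 0.2)]:
            s = int(round(f * n))
            ex, _, _ = ccf_posterior_moments(s, n, state, p, scen)
            assert ex == pytest.approx(ccf_expression(f, state, p, scen),
                                       abs=5e-3)

    def test_degenerate_inverse_flagged(self):
        # A1 at p high enough that the implied SAF saturates at 1 everywhere
        ex, var, bad = ccf_posterior_moments(5, 10, CopyState(0, 6), 0.999,
                                             "B")
        assert not bad  # sanity: normal case not flagged
        assert np.isfinite(ex)


class TestEstimateForVariant:
    def test_euploid_region_doubles_saf(self):
        est = estimate_ccf_for_variant(25, 100, None, None)
        assert est.ccf == pytest.approx(0.5)
        assert est.flag == "euploid"

    def test_host_with_missing_sagp_gives_missing_ccf(self):
        est = estimate_ccf_for_variant(25, 100, CopyState(0, 1), np.nan)
        assert est.ccf is None
        assert est.flag == "host_sagp_missing"

    def test_full_scenario_path(self):
        est = estimate_ccf_for_variant(50, 100, CopyState(1, 3), 0.5)
        assert est.scenario_set == ("A1",)
        assert est.ccf == pytest.approx(0.5 * 2.5 - 0.5, abs=1e-9)
        assert est.ccf_var > 0

    def test_batch_segment_lookup(self, simulated_tumor):
        import pandas as pd

        from clonalmix.sagp_inference import fit_all_segments

        fitted = fit_all_segments(simulated_tumor)
        seg = fitted[(fitted["n_t"] == 3) & (fitted["sagp"] > 0.5)].iloc[0]
        pos = (seg["start"] + seg["end"]) // 2
        variants = pd.DataFrame([
            {"chrom": seg["chrom"], "pos": pos, "s_count": 50,
             "n_depth": 100, "saf": 0.5},
            {"chrom": "unplaced", "pos": 1, "s_count": 10, "n_depth": 100,
             "saf": 0.1},
        ])
        out = estimate_ccf_batch(variants, fitted)
        assert len(out) == 2
        assert out.iloc[1]["flag"] == "euploid"  # off-segment -> SAF x 2
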