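from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from cenckit import (GeneSet, bootstrap_null, expected_overlap, hypergeom_tail,
                     run_enrichment_scenarios, simulate_overlaps, overlap_test)


def enumeration_tails(N: int, n_a: int, n_b: int) -> dict[int, tuple[Fraction, Fraction]]:
    """Exact tails by counting n_a-subsets of {0..N-1} against {0..n_b-1}.

    Returns {k: (P(X>=k), P(X<=k))} as exact rationals.
    """
    total = comb(N, n_a)
    pmf = {k: Fraction(comb(n_b, k) * comb(N - n_b, n_a - k), total)
           for k in range(max(0, n_a + n_b - N), min(n_a, n_b) + 1)}
    ks = sorted(pmf)
    out = {}
    for k in ks:
        out[k] = (sum(pmf[j] for j in ks if j >= k), sum(pmf[j] for j in ks if j <= k))
    return out


def test_counting_formula_agrees_with_literal_subset_enumeration():
    """The combinatorial pmf equals brute-force iteration over all subsets."""
    for (N, n_a, n_b) in [(6, 3, 2), (8, 4, 5), (9, 2, 7), (10, 5, 4)]:
        ref = set(range(n_b))
        counts: dict[int, int] = {}
        for subset in combinations(range(N), n_a):
            k = len(ref & set(subset))
            counts[k] = counts.get(k, 0) + 1
        total = comb(N, n_a)
        for k, c in counts.items():
            assert Fraction(c, total) == Fraction(
                comb(n_b, k) * comb(N - n_b, n_a - k), total)


class TestHypergeomTail:
    def test_worked_example_six_over_252(self):
        assert hypergeom_tail(10, 5, 4, 4, "upper") == pytest.approx(6 / 252, abs=1e-12)
        assert hypergeom_tail(10, 5, 4, 0, "lower") == pytest.approx(6 / 252, abs=1e-12)

    def test_whole_support_has_probability_one(self):
        for (N, n_a, n_b) in [(10, 5, 4), (10, 7, 8), (20, 0, 5)]:
            k_lo = max(0, n_a + n_b - N)
            assert hypergeom_tail(N, n_a, n_b, k_lo, "upper") == pytest.approx(1.0)

    def test_matches_enumeration_on_a_grid(self):
        for (N, n_a, n_b) in [(7, 3, 4), (12, 6, 5), (15, 8, 8)]:
            for k, (up, lo) in enumeration_tails(N, n_a, n_b).items():
                assert hypergeom_tail(N, n_a, n_b, k, "upper") == pytest.approx(
                    float(up), abs=1e-12)
                assert hypergeom_tail(N, n_a, n_b, k, "lower") == pytest.approx(
                    float(lo), abs=1e-12)

    def test_symmetric_in_set_sizes(self):
        assert hypergeom_tail(30, 10, 7, 4, "upper") == pytest.approx(
            hypergeom_tail(30, 7, 10, 4, "upper"), abs=1e-15)

    def test_infeasible_k_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            hypergeom_tail(10, 5, 4, 5, "upper")
        with pytest.raises(ValueError):
            hypergeom_tail(10, 12, 4, 0, "upper")


class TestExpectedOverlap:
    def test_closed_forms(self):
        mean, sd = expected_overlap(10, 5, 4)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2 / 3), abs=1e-12)

    def test_empty_reference(self):
        assert expected_overlap(10, 5, 0) == (0.0, 0.0)

    def test_matches_enumeration_moments(self):
        N, n_a, n_b = 12, 5, 6
        ref = set(range(n_b))
        ks = [len(ref & set(s)) for s in combinations(range(N), n_a)]
        mean, sd = expected_overlap(N, n_a, n_b)
        assert mean == pytest.approx(np.mean(ks), abs=1e-12)
        assert sd == pytest.approx(np.std(ks), abs=1e-12)

    def test_tiny_universe_rejected(self):
        with pytest.raises(ValueError):
            expected_overlap(1, 1, 1)


class TestBootstrap:
    def test_empirical_p_near_exact_tail(self):
        boot = bootstrap_null(10, 5, 4, k_obs=4, r=20_000, seed=0)
        assert boot["p_boot_empirical"] == pytest.approx(6 / 252, abs=0.005)
        mean, _ = expected_overlap(10, 5, 4)
        assert boot["boot_mean"] == pytest.approx(mean, abs=0.05)

    def test_zero_overlap_is_never_significant(self):
        boot = bootstrap_null(100, 30, 20, k_obs=0, r=1000, seed=1)
        assert boot["p_boot_empirical"] == 1.0
        assert boot["p_boot_normal"] > 0.5

    def test_small_iteration_count_rejected(self):
        with pytest.raises(ValueError, match="stable"):
            bootstrap_null(10, 5, 4, 2, r=99)

    def test_degenerate_null_reports_empirical_only(self, caplog):
        # n_a = N forces every simulated overlap to equal n_b exactly
        with caplog.at_level("WARNING", logger="cenckit.enrichment"):
            boot = bootstrap_null(10, 10, 4, k_obs=4, r=200, seed=0)
        assert boot["p_boot_normal"] is None
        assert boot["p_boot_empirical"] == 1.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_seed_reproducibility(self):
        a = bootstrap_null(50, 10, 10, 4, r=500, seed=9)
        b = bootstrap_null(50, 10, 10, 4, r=500, seed=9)
        assert a == b

    def test_simulated_counts_have_hypergeometric_moments(self):
        rng = np.random.default_rng(4)
        sims = simulate_overlaps(200, 40, 30, 40_000, rng)
        mean, sd = expected_overlap(200, 40, 30)
        assert sims.mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(40_000))
        assert sims.min() >= 0 and sims.max() <= 30


class TestScenarios:
    def _sets(self):
        genes = [f"g{i}" for i in range(60)]
        universe = GeneSet("universe", genes)
        up = GeneSet("up", genes[:20])
        down = GeneSet("down", genes[20:35])
        sig_epc = GeneSet("epc", genes[:10] + genes[50:55])  # heavy up overlap
        sig_enc = GeneSet("enc", genes[20:28] + genes[55:58])  # heavy down overlap
        return up, down, sig_epc, sig_enc, universe

    def test_four_scenarios_in_canonical_order(self):
        up, down, sig_epc, sig_enc, universe = self._sets()
        res = run_enrichment_scenarios(up, down, sig_epc, sig_enc, universe,
                                       r=2000, seed=0)
        assert [r.name for r in res] == ["down_in_enc", "up_in_epc",
                                         "up_in_enc", "down_in_epc"]
        by = {r.name: r for r in res}
        assert by["up_in_epc"].k_obs == 10
        assert by["down_in_enc"].k_obs == 8
        assert by["up_in_epc"].call == "enriched"
        assert by["down_in_enc"].call == "enriched"

    def test_query_and_reference_are_exchangeable(self):
        up, down, sig_epc, sig_enc, universe = self._sets()
        a = overlap_test("x", up, sig_epc, universe, r=1000, seed=5)
        b = overlap_test("x", sig_epc, up, universe, r=1000, seed=5)
        assert a.p_hyper_enrich == pytest.approx(b.p_hyper_enrich, abs=1e-15)
        assert a.p_boot_empirical == pytest.approx(b.p_boot_empirical, abs=1e-15)

    def test_query_equal_to_universe_is_degenerate_certainty(self):
        up, down, sig_epc, sig_enc, universe = self._sets()
        res = overlap_test("all", universe, sig_epc, universe, r=500, seed=0)
        assert res.k_obs == len(sig_epc)
        assert res.p_hyper_enrich == pytest.approx(1.0)
        assert res.call != "enriched"

    def test_sets_outside_universe_rejected(self):
        universe = GeneSet("u", ["a", "b"])
        rogue = GeneSet("q", ["a", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            overlap_test("x", rogue, GeneSet("r", ["b"]), universe, r=200)

    def test_tail_probabilities_share_point_mass(self):
        up, down, sig_epc, sig_enc, universe = self._sets()
        res = overlap_test("x", up, sig_enc, universe, r=500, seed=2)
        assert res.p_hyper_enrich + res.p_hyper_deplete >= 1.0 - 1e-12
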