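from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cenckit import (PROFILES, SimulationConfig, ThresholdProfile, apply_de_filters,
                     bh_adjust, compute_gene_stats, de_gene_sets, simulate_compendium)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestGeneStats:
    def test_welch_t_closed_form_and_permutation_extremity(self, tiny_compendium):
        # log2 values A=[1,2,3], B=[4,5,6]: t = -3/sqrt(2/3), df = 4, p ~ 0.021
        tpm = pd.DataFrame(
            {"a1": [1.0], "a2": [3.0], "a3": [7.0],
             "b1": [15.0], "b2": [31.0], "b3": [63.0]},
            index=["g"])  # log2(TPM+1) = 1,2,3 and 4,5,6
        sheet = pd.DataFrame({"sample_id": tpm.columns,
                              "group": ["a"] * 3 + ["b"] * 3, "clone": [""] * 6})
        from cenckit import ExpressionCompendium
        comp = ExpressionCompendium(tpm=tpm, sample_sheet=sheet)
        stats = compute_gene_stats(comp, "a", "b")
        from scipy import stats as sps
        t_expected = -3.0 / np.sqrt(2.0 / 3.0)
        p_expected = 2 * sps.t.sf(abs(t_expected), 4)
        assert p_expected == pytest.approx(0.0212, abs=5e-4)
        assert stats.p[0] == pytest.approx(p_expected, rel=1e-9)

        # the observed split attains the most extreme |t| of all 20 assignments
        vals = np.array([1.0, 2, 3, 4, 5, 6])

        def welch_t(ia):
            ib = [i for i in range(6) if i not in ia]
            a, b = vals[list(ia)], vals[ib]
            se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
            return abs((a.mean() - b.mean()) / se)

        all_t = [welch_t(ia) for ia in combinations(range(6), 3)]
        assert max(all_t) == pytest.approx(abs(t_expected))
        assert sum(t >= abs(t_expected) - 1e-12 for t in all_t) == 2  # split + mirror

    def test_identical_groups_give_p_one(self, tiny_compendium):
        stats = compute_gene_stats(tiny_compendium, "a", "b")
        flat = stats.set_index("gene_id").loc[["flat_low", "flat_high"]]
        assert (flat.p == 1.0).all()
        assert (flat.fc == 1.0).all()

    def test_fold_change_uses_pseudocounted_linear_means(self, tiny_compendium):
        stats = compute_gene_stats(tiny_compendium, "a", "b").set_index("gene_id")
        assert stats.loc["up_gene", "fc"] == pytest.approx(30.5 / 10.5)
        assert stats.loc["up_gene", "fc_max"] == pytest.approx(30.5 / 10.5)
        assert stats.loc["up_gene", "direction"] == "up"
        assert stats.loc["down_gene", "fc"] == pytest.approx(10.5 / 30.5)
        assert stats.loc["down_gene", "direction"] == "down"

    def test_missing_or_small_groups_rejected(self, tiny_compendium):
        with pytest.raises(ValueError, match="'c'"):
            compute_gene_stats(tiny_compendium, "c", "b")
        solo = tiny_compendium
        solo.sample_sheet.loc[0, "group"] = "solo"
        with pytest.raises(ValueError, match="solo"):
            compute_gene_stats(solo, "solo", "b")


class TestBH:
    def test_hand_worked_examples(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_after_sorting_by_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


FIXTURE = pd.DataFrame({
    "gene_id": [f"g{i}" for i in range(1, 7)],
    "fc_max": [3.0, 2.0, 4.0, 10.0, 2.5, 1.2],
    "mean_tpm_a": [20.0, 50.0, 15.0, 100.0, 16.0, 1000.0],
    "mean_tpm_b": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
    "direction": ["up", "up", "up", "down", "up", "down"],
    "q": [0.10, 0.01, 0.05, 0.30, 0.29, 1e-6],
})


class TestFilters:
    def test_six_gene_fixture_exactly_two_pass(self):
        table = apply_de_filters(FIXTURE, PROFILES["ppcd"])
        passing = list(table.table.loc[table.table["pass"], "gene_id"])
        assert passing == ["g1", "g5"]

    @pytest.mark.parametrize("profile,row,reason", [
        ("ppcd", dict(fc_max=2.0, mean_tpm_a=100.0, mean_tpm_b=1.0, q=0.01), "fc at bound"),
        ("ppcd", dict(fc_max=5.0, mean_tpm_a=15.0, mean_tpm_b=1.0, q=0.01), "tpm at bound"),
        ("ppcd", dict(fc_max=5.0, mean_tpm_a=100.0, mean_tpm_b=1.0, q=0.3), "q at bound"),
        ("cellline", dict(fc_max=5.0, mean_tpm_a=100.0, mean_tpm_b=1.0, q=0.05), "q at bound"),
    ])
    def test_boundary_values_fail_under_strict_inequalities(self, profile, row, reason):
        df = pd.DataFrame([{"gene_id": "g", "direction": "up", **row}])
        table = apply_de_filters(df, PROFILES[profile])
        assert not table.table["pass"].any(), reason

    def test_filter_idempotent(self):
        t1 = apply_de_filters(FIXTURE, PROFILES["ppcd"])
        t2 = apply_de_filters(t1.table, PROFILES["ppcd"])
        assert t1.table["pass"].equals(t2.table["pass"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(1.0, 5.0), st.floats(0.0, 50.0), st.floats(0.01, 1.0))
    def test_loosening_any_threshold_never_drops_a_gene(self, fc, tpm, q):
        strict = apply_de_filters(FIXTURE, ThresholdProfile("s", fc, tpm, q))
        for loose in (ThresholdProfile("l", max(1.0, fc - 0.5), tpm, q),
                      ThresholdProfile("l", fc, max(0.0, tpm - 5), q),
                      ThresholdProfile("l", fc, tpm, min(1.0, q + 0.1))):
            loosened = apply_de_filters(FIXTURE, loose)
            assert (loosened.table["pass"] | ~strict.table["pass"]).all()


class TestDEGeneSets:
    def test_empty_table_gives_empty_sets(self):
        empty = FIXTURE.assign(q=1.0)  # q=1 fails every profile
        up, down = de_gene_sets(apply_de_filters(empty, PROFILES["ppcd"]))
        assert len(up) == 0 and len(down) == 0

    def test_fixture_partition(self):
        up, down = de_gene_sets(apply_de_filters(FIXTURE, PROFILES["ppcd"]))
        assert up.members | down.members == {"g1", "g5"}
        assert not up.members & down.members

    def test_no_noise_recovery_matches_truth_exactly(self):
        cfg = SimulationConfig(
            universe_size=800, n_up=40, n_down=30, sig_epc_size=30, sig_enc_size=20,
            planted_up_in_epc=10, planted_down_in_enc=8,
            planted_up_in_enc=1, planted_down_in_epc=1,
            noise_log_sd=0.0, fold_up=4.0, fold_down=4.0,
            baseline_log_mean=7.0, baseline_log_sd=0.5, seed=2)
        comp, truth, _, _ = simulate_compendium(cfg)
        stats = compute_gene_stats(comp, "disease", "control")
        table = apply_de_filters(stats, PROFILES["ppcd"])
        up, down = de_gene_sets(table)
        assert up.members == truth.genes("up")
        assert down.members == truth.genes("down")
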