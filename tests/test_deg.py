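"""NB exact test, dispersion estimation, BH correction and DEG calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from whorlspec import (SimConfig, Thresholds, bh_adjust, call_degs,
                       estimate_dispersion, exact_nb_test, overlap_analysis,
                       simulate_expression)

from conftest import make_matrix


def binomial_split_oracle(sum_a: int, total: int, n_a: int, n_b: int) -> float:
    """Exhaustive two-sided binomial test of the A-share of the total."""
    probs = binom.pmf(np.arange(total + 1), total, n_a / (n_a + n_b))
    return float(probs[probs <= probs[sum_a] * (1 + 1e-12)].sum())


class TestExactNbTest:
    def test_identical_groups_p_one(self):
        assert exact_nb_test([5, 5, 5], [5, 5, 5], 0.1) == pytest.approx(1.0)

    @pytest.mark.parametrize("total", [1, 3, 10, 47, 120, 200])
    def test_poisson_limit_matches_binomial_oracle(self, total):
        for sum_a in {0, total // 4, total // 2, total}:
            p_mine = exact_nb_test([sum_a, 0, 0], [total - sum_a, 0, 0], 0.0)
            p_oracle = binomial_split_oracle(sum_a, total, 3, 3)
            assert p_mine == pytest.approx(p_oracle, abs=1e-10)

    def test_strong_separation_is_significant(self):
        assert exact_nb_test([0, 0, 0], [50, 60, 55], 0.1) < 1e-3

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 50, size=3)
            b = rng.integers(0, 50, size=3)
            phi = float(rng.uniform(0, 0.5))
            assert exact_nb_test(a, b, phi) == pytest.approx(
                exact_nb_test(b, a, phi), rel=1e-12)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 100, size=3)
            b = rng.integers(0, 100, size=3)
            p = exact_nb_test(a, b, 0.2)
            assert 0 < p <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test([-1, 2], [3, 4], 0.1)


class TestBhAdjust:
    def test_step_up_hand_oracle(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            assert np.allclose(bh_adjust(p),
                               multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDispersion:
    def test_constant_gene_floored_at_zero(self):
        m = make_matrix({"a1": [5, 9], "a2": [5, 9], "b1": [5, 9], "b2": [5, 9]},
                        lengths=[100, 100],
                        organs=["x", "x", "y", "y"])
        groups = pd.Series(["A", "A", "B", "B"], index=["a1", "a2", "b1", "b2"])
        est = estimate_dispersion(m, groups)
        assert (est.per_gene == 0).all()

    def test_single_replicate_group_instructs_pooling(self):
        m = make_matrix({"a1": [5, 9], "a2": [6, 8], "b1": [5, 9]},
                        lengths=[100, 100], organs=["x", "x", "y"])
        groups = pd.Series(["A", "A", "B"], index=["a1", "a2", "b1"])
        with pytest.raises(ValueError, match="pool dispersion"):
            estimate_dispersion(m, groups)

    def test_poisson_counts_give_small_estimates(self):
        config = SimConfig(n_genes=2000, organs=("a", "b"), cultivars=("w",),
                           n_replicates=5, dispersion=0.0, frac_specific=0.0,
                           seed=11)
        m, _ = simulate_expression(config)
        est = estimate_dispersion(m, m.group_key())
        assert np.median(est.per_gene) < 0.02
        assert est.common < 0.02

    def test_common_dispersion_recovers_truth(self):
        config = SimConfig(n_genes=2000, organs=("a", "b"), cultivars=("w",),
                           n_replicates=3, dispersion=0.4, frac_specific=0.0,
                           seed=12)
        m, _ = simulate_expression(config)
        est = estimate_dispersion(m, m.group_key())
        assert est.common == pytest.approx(0.4, rel=0.25)


class TestCallDegs:
    def _planted(self, seed=14):
        config = SimConfig(n_genes=600, organs=("a", "b"), cultivars=("w",),
                           n_replicates=3, dispersion=0.1, frac_specific=0.1,
                           specificity_fold=8.0, seed=seed)
        return simulate_expression(config)

    def test_triple_rule_and_direction(self):
        m, truth = self._planted()
        table = call_degs(m, m.samples_for("a"), m.samples_for("b"))
        called = table[table["call"] != "ns"]
        assert (called["log2_ratio"].abs() >= 1).all()
        assert (called["pvalue"] < 0.05).all()
        assert (called["fdr"] < 0.001).all()
        up = called[called["call"] == "up"]
        assert (up["log2_ratio"] > 0).all()
        # planted genes specific to organ "a" come out up in a-vs-b
        a_specific = {g for g, o in truth.specific_gene_map.items() if o == "a"}
        up = set(table.index[table["call"] == "up"])
        assert len(a_specific & up) / len(a_specific) >= 0.9

    def test_fold_change_gate_blocks_small_ratios(self):
        # a 1.5-fold shift with enormous counts: tiny p but |log2 ratio| < 1
        m = make_matrix({"a1": [30000, 50, 10 ** 6], "a2": [30000, 50, 10 ** 6],
                         "b1": [20000, 50, 10 ** 6], "b2": [20000, 50, 10 ** 6]},
                        lengths=[1000, 1000, 1000], organs=["x", "x", "y", "y"])
        table = call_degs(m, ["a1", "a2"], ["b1", "b2"], dispersion=0.0)
        assert table.loc["g0", "pvalue"] < 1e-6
        assert abs(table.loc["g0", "log2_ratio"]) < 1.0
        assert table.loc["g0", "call"] == "ns"

    def test_fdr_gate_blocks_despite_raw_p(self):
        m, _ = self._planted()
        strict = Thresholds(log2fc=1.0, pval=0.05, fdr=1e-12)
        table = call_degs(m, m.samples_for("a"), m.samples_for("b"),
                          thresholds=strict)
        loose = call_degs(m, m.samples_for("a"), m.samples_for("b"))
        blocked = (loose["call"] != "ns") & (table["call"] == "ns")
        assert blocked.any()
        assert (table.loc[table["call"] != "ns", "fdr"] < 1e-12).all()

    def test_empty_group_rejected(self, small_sim):
        _, matrix, _ = small_sim
        with pytest.raises(ValueError):
            call_degs(matrix, [], matrix.samples_for("petal"))


class TestOverlap:
    def _table(self, calls):
        genes = [f"g{i}" for i in range(len(calls))]
        return pd.DataFrame({"call": calls}, index=genes)

    def test_identical_tables(self):
        t = self._table(["up", "down", "ns", "up"])
        s = overlap_analysis(t, t)
        assert s.shared == 3 and s.private_x == s.private_y == 0
        assert s.concordance == 1.0

    def test_disjoint_deg_sets(self):
        x = self._table(["up", "ns", "ns"])
        y = self._table(["ns", "down", "ns"])
        s = overlap_analysis(x, y)
        assert s.shared == 0 and s.private_x == 1 and s.private_y == 1

    def test_six_gene_worked_example_matches_enumeration(self):
        cx = ["up", "up", "down", "ns", "up", "down"]
        cy = ["up", "down", "down", "up", "ns", "down"]
        s = overlap_analysis(self._table(cx), self._table(cy))
        # brute-force enumeration over the 6 genes
        union = [(a, b) for a, b in zip(cx, cy) if (a, b) != ("ns", "ns")]
        expect = {}
        for pair in union:
            expect[pair] = expect.get(pair, 0) + 1
        assert s.partition == expect
        assert s.union_size() == len(union)
        both = [(a, b) for a, b in zip(cx, cy) if a != "ns" and b != "ns"]
        assert s.shared == len(both)
        assert s.concordance == pytest.approx(
            sum(a == b for a, b in both) / len(both))

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        calls = rng.choice(["up", "down", "ns"], size=40)
        calls2 = rng.choice(["up", "down", "ns"], size=40)
        x, y = self._table(list(calls)), self._table(list(calls2))
        perm = list(rng.permutation(x.index))
        s1 = overlap_analysis(x, y)
        s2 = overlap_analysis(x.loc[perm], y.loc[perm])
        assert s1.partition == s2.partition and s1.shared == s2.shared

    def test_disjoint_universes_rejected(self):
        x = self._table(["up"])
        y = self._table(["up"])
        y.index = ["other"]
        with pytest.raises(ValueError):
            overlap_analysis(x, y)
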