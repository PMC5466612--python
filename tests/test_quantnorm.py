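"""Normalization and replicate-QC behaviour."""

import numpy as np
import pandas as pd
import pytest

from whorlspec import mirna_tpm, organ_dendrogram, replicate_qc, rpkm, zscore_rows
from whorlspec.containers import ExpressionMatrix

from conftest import make_matrix


class TestRpkm:
    def test_worked_values(self, tiny_counts):
        out = rpkm(tiny_counts)
        # 10 reads, 1 kb, 1e6 mapped -> 10; 5 reads, 0.5 kb, 2e6 mapped -> 5
        assert out.values.loc["g0", "s1"] == pytest.approx(10.0)
        assert out.values.loc["g2", "s2"] == pytest.approx(5.0)
        assert out.unit == "RPKM"

    def test_zero_reads_zero_rpkm(self):
        m = make_matrix({"s1": [0, 100], "s2": [3, 50]}, lengths=[500, 800],
                        organs=["sepal", "sepal"])
        assert rpkm(m).values.loc["g0", "s1"] == 0.0

    def test_zero_column_sum_names_sample(self):
        m = make_matrix({"s1": [0, 0], "s2": [3, 5]}, lengths=[500, 800],
                        organs=["sepal", "sepal"])
        with pytest.raises(ValueError, match="s1"):
            rpkm(m)

    def test_inversion_recovers_column_proportions(self, small_sim):
        _, matrix, _ = small_sim
        out = rpkm(matrix)
        # summing RPKM * length_kb per column recovers counts / depth factor
        back = out.values.mul(out.lengths / 1000.0, axis=0).sum(axis=0)
        expected = matrix.values.sum(axis=0) / (matrix.values.sum(axis=0) / 1e6)
        assert np.allclose(back, expected)

    def test_rejects_wrong_unit(self, tiny_counts):
        with pytest.raises(ValueError, match="unit"):
            rpkm(rpkm(tiny_counts))


class TestMirnaTpm:
    @pytest.mark.parametrize("counts,total,expected", [
        ([50], 1e7, [5.0]),
        ([0], 1e7, [0.0]),
        ([1, 1], 2e6, [0.5, 0.5]),
    ])
    def test_worked_values(self, counts, total, expected):
        assert np.allclose(mirna_tpm(counts, total), expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            mirna_tpm([1, 2], 0)


class TestZscore:
    def test_constant_row_maps_to_zero(self):
        m = make_matrix({"s1": [7.0], "s2": [7.0], "s3": [7.0]},
                        lengths=[100], organs=["a", "b", "c"], unit="RPKM")
        assert (zscore_rows(m).values.to_numpy() == 0).all()

    def test_population_sd_convention(self):
        m = make_matrix({"s1": [1.0], "s2": [2.0], "s3": [3.0]},
                        lengths=[100], organs=["a", "b", "c"], unit="RPKM")
        out = zscore_rows(m).values.iloc[0].to_numpy()
        assert np.allclose(out, [-1.2247, 0.0, 1.2247], atol=5e-5)

    def test_rows_sum_to_zero(self, small_sim):
        _, matrix, _ = small_sim
        z = zscore_rows(rpkm(matrix))
        assert np.abs(z.values.sum(axis=1)).max() < 1e-9

    def test_single_column_rejected(self):
        m = make_matrix({"s1": [1.0, 2.0]}, lengths=[100, 100], organs=["a"])
        with pytest.raises(ValueError):
            zscore_rows(m)


def _correlated_replicates(corr: np.ndarray, n: int = 4000,
                           seed: int = 0) -> ExpressionMatrix:
    """Three replicates of one organ with a target correlation structure."""
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    x = rng.standard_normal((n, 3)) @ chol.T + 10.0
    df = pd.DataFrame(x, columns=["r1", "r2", "r3"],
                      index=[f"g{i}" for i in range(n)])
    samples = pd.DataFrame({"organ": "sepal", "cultivar": "wild",
                            "replicate": [1, 2, 3]}, index=df.columns)
    return ExpressionMatrix(values=df.clip(lower=0.0),
                            lengths=pd.Series(100.0, index=df.index),
                            samples=samples, unit="RPKM")


class TestReplicateQC:
    def test_outlier_below_both_siblings(self):
        corr = np.array([[1.0, 0.1, 0.1], [0.1, 1.0, 0.9], [0.1, 0.9, 1.0]])
        m = _correlated_replicates(corr)
        report = replicate_qc(m, log_transform=False)
        assert report.outliers == ["r1"]

    def test_identical_replicates_unflagged(self):
        m = make_matrix({"r1": [1, 5, 9], "r2": [1, 5, 9], "r3": [1, 5, 9]},
                        lengths=[100] * 3, organs=["sepal"] * 3, unit="RPKM")
        report = replicate_qc(m, log_transform=False)
        assert report.flagged.empty

    def test_low_agreement_any_sibling_rule(self):
        # sibling correlations (0.95, 0.6): fails the within threshold for one
        # sibling but not the all-siblings outlier rule
        corr = np.array([[1.0, 0.95, 0.6], [0.95, 1.0, 0.75], [0.6, 0.75, 1.0]])
        m = _correlated_replicates(corr, seed=1)
        report = replicate_qc(m, log_transform=False)
        assert "r1" in report.low_agreement
        assert report.outliers == []

    def test_affine_rescaling_invariance(self):
        corr = np.array([[1.0, 0.1, 0.1], [0.1, 1.0, 0.9], [0.1, 0.9, 1.0]])
        m = _correlated_replicates(corr)
        scaled = m.with_values(m.values * 3.0 + 1.0, unit="RPKM")
        a = replicate_qc(m, log_transform=False)
        b = replicate_qc(scaled, log_transform=False)
        assert np.allclose(a.correlations, b.correlations)

    def test_single_replicate_group_rejected(self):
        m = make_matrix({"r1": [1, 2], "r2": [1, 2]}, lengths=[100, 100],
                        organs=["sepal", "petal"], unit="RPKM")
        with pytest.raises(ValueError, match="fewer than 2"):
            replicate_qc(m, log_transform=False)


class TestOrganDendrogram:
    def test_identical_profiles_merge_first_at_zero(self):
        m = make_matrix({"a1": [1, 2], "a2": [1, 2], "b1": [1, 2], "b2": [1, 2],
                         "c1": [9, 9], "c2": [9, 9]},
                        lengths=[100, 100],
                        organs=["sepal", "sepal", "petal", "petal",
                                "stamen", "stamen"],
                        unit="RPKM")
        dendro = organ_dendrogram(m, log_transform=False)
        left, right, h = dendro.merges[0]
        assert set(left) | set(right) == {"sepal|wild", "petal|wild"}
        assert h == pytest.approx(0.0)

    def test_three_profiles_complete_linkage(self):
        # organ mean profiles at mutual distances (ab)=1, (bc)=2, (ac)=3
        m = make_matrix({"a1": [0.0], "a2": [0.0], "b1": [1.0], "b2": [1.0],
                         "c1": [3.0], "c2": [3.0]},
                        lengths=[100],
                        organs=["sa", "sa", "sb", "sb", "sc", "sc"],
                        unit="RPKM")
        dendro = organ_dendrogram(m, log_transform=False)
        (left, right, h1), (_, _, h2) = dendro.merges
        assert set(left) | set(right) == {"sa|wild", "sb|wild"}
        assert h1 == pytest.approx(1.0)
        assert h2 == pytest.approx(3.0)  # complete linkage: furthest pair

    def test_cophenetic_dominates_pairwise(self, small_sim):
        _, matrix, _ = small_sim
        from whorlspec.cluster import euclidean_distance_matrix
        from whorlspec.quantnorm import _correlation_input
        vals = _correlation_input(matrix, True)
        groups = matrix.group_key()
        prof = pd.DataFrame({g: vals[list(groups.index[groups == g])].mean(axis=1)
                             for g in groups.unique()})
        dist = euclidean_distance_matrix(prof)
        dendro = organ_dendrogram(matrix)
        for a in dist.index:
            for b in dist.index:
                if a != b:
                    assert dendro.cophenetic(a, b) >= dist.loc[a, b] - 1e-9
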