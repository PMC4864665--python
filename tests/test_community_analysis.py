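import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from otugrad.community_analysis import (
    alpha_to_dataframe,
    community_alpha,
    hierarchical_cluster,
    horohalinicum_test,
    mantel_test,
    pcoa,
    per_phylum_alpha,
    relative_abundance,
    spearman_dissimilarity,
    subsampled_alpha,
    correlate_axis_with_gradient,
)
from otugrad.core_io import Lineage
from tests._oracles import expected_rarefied_richness
from tests.conftest import small_table


class TestRelativeAbundance:
    def test_columns_sum_to_one(self):
        freqs = relative_abundance(small_table([[2, 1], [2, 3]]))
        assert np.allclose(freqs.sum(axis=0), 1.0)
        assert freqs.iloc[0, 0] == pytest.approx(0.5)

    def test_single_otu(self):
        freqs = relative_abundance(small_table([[7]]))
        assert freqs.iloc[0, 0] == 1.0

    def test_zero_sum_sample_errors(self):
        with pytest.raises(ValueError, match="S2"):
            relative_abundance(small_table([[1, 0], [1, 0]]))


class TestSpearmanDissimilarity:
    def test_identical_samples_zero(self):
        freqs = relative_abundance(small_table([[2, 2], [1, 1], [5, 5]]))
        dm = spearman_dissimilarity(freqs)
        assert dm[0, 1] == pytest.approx(0.0)

    def test_antiranked_samples_two(self):
        freqs = pd.DataFrame({"S1": [0.1, 0.2, 0.3, 0.4], "S2": [0.4, 0.3, 0.2, 0.1]})
        dm = spearman_dissimilarity(freqs)
        assert dm[0, 1] == pytest.approx(2.0)

    def test_hand_computed_rho(self):
        freqs = pd.DataFrame({"S1": [1, 2, 3, 4], "S2": [1, 3, 2, 4]}, dtype=float)
        dm = spearman_dissimilarity(freqs)
        assert dm[0, 1] == pytest.approx(0.2)  # rho = 0.8

    def test_constant_sample_errors(self):
        freqs = pd.DataFrame({"S1": [0.25, 0.25, 0.25, 0.25], "S2": [0.1, 0.2, 0.3, 0.4]})
        with pytest.raises(ValueError, match="S1"):
            spearman_dissimilarity(freqs)


class TestPcoa:
    def test_collinear_three_points(self):
        dm = DistanceMatrix(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=["a", "b", "c"]
        )
        ordination = pcoa(dm)
        assert ordination.variance_explained[0] == pytest.approx(1.0)
        coords = ordination.coordinates[:, 0]
        assert coords == pytest.approx([-1.0, 0.0, 1.0]) or coords == pytest.approx(
            [1.0, 0.0, -1.0]
        )

    def test_euclidean_recovery_to_1e9(self, rng):
        points = rng.normal(size=(7, 2))
        d = squareform(pdist(points))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(7)])
        ordination = pcoa(dm)
        recovered = squareform(pdist(ordination.coordinates))
        assert np.abs(recovered - d).max() < 1e-9

    def test_duplicate_sample_identical_coordinates(self, rng):
        points = np.vstack([rng.normal(size=(4, 2)), [[0, 0], [0, 0]]])
        d = squareform(pdist(points))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        ordination = pcoa(dm)
        assert np.allclose(ordination.coordinates[4], ordination.coordinates[5], atol=1e-9)

    def test_matches_skbio_eigenvalues(self, rng):
        points = rng.normal(size=(6, 3))
        d = squareform(pdist(points))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        ours = pcoa(dm)
        theirs = skbio_pcoa(dm, number_of_dimensions=3)
        assert np.allclose(
            ours.eigenvalues[:3], theirs.eigvals.to_numpy()[:3], atol=1e-8
        )

    def test_axes_ordered_by_eigenvalue(self, rng):
        points = rng.normal(size=(8, 3)) * [5, 2, 1]
        d = squareform(pdist(points))
        ordination = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(8)]))
        assert (np.diff(ordination.eigenvalues) <= 1e-9).all()
        assert ordination.variance_explained.sum() == pytest.approx(1.0)


class TestGradientCorrelation:
    def _meta(self, sal):
        return pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(sal))], "salinity": sal,
             "temperature": 15.0}
        ).set_index("sample_id")

    def test_perfect_correlation(self):
        from otugrad.community_analysis import Ordination

        sal = np.linspace(2, 30, 10)
        ordination = Ordination(
            [f"s{i}" for i in range(10)], sal[:, None], np.array([1.0]), np.array([1.0])
        )
        rho, p = correlate_axis_with_gradient(ordination, self._meta(sal), n_perm=199, rng=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_independent_noise_not_significant(self):
        from otugrad.community_analysis import Ordination

        rng = np.random.default_rng(5)
        sal = np.linspace(2, 30, 21)
        ps = []
        for i in range(20):
            coords = rng.normal(size=(21, 1))
            ordination = Ordination(
                [f"s{i}" for i in range(21)], coords, np.array([1.0]), np.array([1.0])
            )
            _, p = correlate_axis_with_gradient(
                ordination, self._meta(sal), n_perm=199, rng=rng
            )
            ps.append(p)
        assert np.mean(ps) > 0.2  # roughly uniform under the null

    def test_missing_salinity_errors(self):
        from otugrad.community_analysis import Ordination

        ordination = Ordination(["s0", "s99"], np.zeros((2, 1)), np.ones(1), np.ones(1))
        with pytest.raises(KeyError):
            correlate_axis_with_gradient(ordination, self._meta([1.0, 2.0]), n_perm=9)


class TestHierarchicalClustering:
    def test_two_samples_single_merge(self):
        dm = DistanceMatrix([[0, 0.3], [0.3, 0]], ids=["a", "b"])
        z, newick = hierarchical_cluster(dm)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(0.3)
        assert "a" in newick and "b" in newick

    def test_average_linkage_three_points(self):
        dm = DistanceMatrix(
            [[0, 0.1, 1.0], [0.1, 0, 1.0], [1.0, 1.0, 0]], ids=["A", "B", "C"]
        )
        z, _ = hierarchical_cluster(dm, "average")
        assert z[0, 2] == pytest.approx(0.1)  # A-B first
        assert z[1, 2] == pytest.approx(1.0)  # then C at average height 1.0

    def test_duplicate_sample_merges_at_zero(self):
        dm = DistanceMatrix(
            [[0, 0.0, 0.8], [0.0, 0, 0.8], [0.8, 0.8, 0]], ids=["A", "B", "C"]
        )
        z, _ = hierarchical_cluster(dm)
        assert z[0, 2] == pytest.approx(0.0)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(DistanceMatrix([[0.0]], ids=["a"]))


class TestMantel:
    def _random_dm(self, rng, n=10):
        d = squareform(pdist(rng.normal(size=(n, 2))))
        return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])

    def test_self_comparison(self, rng):
        dm = self._random_dm(rng)
        rho, p = mantel_test(dm, dm, n_perm=99, rng=1)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_monotone_scaling_invariance(self, rng):
        dm = self._random_dm(rng)
        dm2 = DistanceMatrix(dm.data * 2.0, ids=list(dm.ids))
        rho, _ = mantel_test(dm, dm2, n_perm=49, rng=1)
        assert rho == pytest.approx(1.0)

    def test_independent_matrices_usually_null(self, rng):
        ps = [
            mantel_test(self._random_dm(rng), self._random_dm(rng), n_perm=99, rng=rng)[1]
            for _ in range(20)
        ]
        assert np.mean(np.array(ps) <= 0.05) < 0.25

    def test_null_pvalue_superuniform(self, rng):
        """Under the null, P(p <= 0.05) should not exceed 0.05 by much."""
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            p = mantel_test(self._random_dm(rng, 8), self._random_dm(rng, 8), n_perm=59, rng=rng)[1]
            hits += p <= 0.05
        assert hits / n_rep <= 0.09  # 0.05 + 3 binomial SE

    def test_agrees_with_skbio(self, rng):
        from skbio.stats.distance import mantel as skbio_mantel

        d1, d2 = self._random_dm(rng), self._random_dm(rng)
        rho, _ = mantel_test(d1, d2, n_perm=9, rng=0)
        theirs = skbio_mantel(d1, d2, method="spearman", permutations=9)
        assert rho == pytest.approx(theirs[0])

    def test_dimension_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            mantel_test(self._random_dm(rng, 5), self._random_dm(rng, 6))


class TestSubsampledAlpha:
    def test_full_depth_exact(self):
        table = small_table([[5], [5]])
        est = subsampled_alpha(table, "S1", 10, reps=100, rng=0)
        assert est.mean_richness == 2.0 and est.sd_richness == 0.0
        assert est.mean_shannon == pytest.approx(np.log(2))

    def test_depth_one_richness_one(self):
        table = small_table([[5], [5]])
        est = subsampled_alpha(table, "S1", 1, reps=50, rng=0)
        assert est.mean_richness == 1.0

    def test_hypergeometric_expectation(self):
        table = small_table([[5], [5]])
        est = subsampled_alpha(table, "S1", 5, reps=1000, rng=0)
        expected = expected_rarefied_richness([5, 5], 5)  # 2*(1 - 1/252)
        assert expected == pytest.approx(1.9920634920634921)
        se = est.sd_richness / np.sqrt(est.replicates)
        assert abs(est.mean_richness - expected) <= 3 * se + 1e-12

    def test_mean_richness_monotone_in_depth(self, rng):
        counts = rng.integers(1, 40, size=12)[:, None]
        table = small_table(counts)
        exact = [expected_rarefied_richness(counts[:, 0].tolist(), n)
                 for n in (5, 15, 30)]
        assert exact == sorted(exact)
        means = [
            subsampled_alpha(table, "S1", n, reps=400, rng=rng).mean_richness
            for n in (5, 15, 30)
        ]
        for m, e in zip(means, exact):
            assert abs(m - e) < 0.25

    def test_depth_exceeding_total_errors(self):
        with pytest.raises(ValueError):
            subsampled_alpha(small_table([[3]]), "S1", 4)


class TestPerPhylumAlpha:
    def _table(self):
        lineages = [
            Lineage.from_string("Euk;SG;Ochrophyta;CL1"),
            Lineage.from_string("Euk;SG;Ochrophyta;CL2"),
            Lineage.from_string("Euk;SG;Chlorophyta;CL3"),
        ]
        return small_table(
            [[600, 1500], [500, 900], [2000, 50]], otu_lineages=lineages, marker="18S"
        )

    def test_low_count_sample_excluded(self):
        est = per_phylum_alpha(self._table(), "Ochrophyta", min_reads=1200)
        assert [e.sample_id for e in est] == ["S2"]

    def test_all_samples_kept_at_min_total(self):
        est = per_phylum_alpha(self._table(), "Ochrophyta", min_reads=1000)
        assert [e.sample_id for e in est] == ["S1", "S2"]
        assert {e.depth for e in est} == {1100}

    def test_single_otu_phylum_zero_shannon(self):
        est = per_phylum_alpha(self._table(), "Chlorophyta", min_reads=40)
        assert all(e.mean_richness == 1.0 and e.mean_shannon == 0.0 for e in est)

    def test_unknown_phylum_empty(self):
        assert per_phylum_alpha(self._table(), "Dinophyta") == []


class TestHorohalinicum:
    def _alpha(self, values_in, values_out):
        rows = []
        for i, v in enumerate(values_in):
            rows.append({"phylum": "P", "sample_id": f"in{i}",
                         "mean_richness": v, "mean_shannon": v / 10})
        for i, v in enumerate(values_out):
            rows.append({"phylum": "P", "sample_id": f"out{i}",
                         "mean_richness": v, "mean_shannon": v / 10})
        return pd.DataFrame(rows)

    def _meta(self, n_in, n_out):
        rows = [{"sample_id": f"in{i}", "salinity": 6.0, "temperature": 15.0}
                for i in range(n_in)]
        rows += [{"sample_id": f"out{i}", "salinity": 20.0, "temperature": 15.0}
                 for i in range(n_out)]
        return pd.DataFrame(rows).set_index("sample_id")

    def test_identical_groups_p_one(self):
        res = horohalinicum_test(self._alpha([5, 5, 5], [5, 5, 5]), self._meta(3, 3))
        assert (res["p"] == 1.0).all()

    def test_fully_separated_exact_p(self):
        res = horohalinicum_test(
            self._alpha([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]), self._meta(5, 5)
        )
        assert res["p"].iloc[0] == pytest.approx(2 / 252)  # 2 / C(10,5)

    def test_bh_adjustment_smallest_p(self):
        alpha = pd.concat(
            [
                self._alpha([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]).assign(phylum="P1"),
                self._alpha([5, 6, 5, 6, 5], [5, 6, 5, 6, 6]).assign(phylum="P2"),
            ],
            ignore_index=True,
        )
        res = horohalinicum_test(alpha, self._meta(5, 5))
        rich = res[res["metric"] == "richness"].sort_values("p")
        assert rich["q"].iloc[0] == pytest.approx(rich["p"].iloc[0] * 2)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match=r"\[5.0, 8.0\]"):
            horohalinicum_test(self._alpha([1, 2], []), self._meta(2, 0))


def test_community_alpha_uses_min_depth():
    table = small_table([[30, 5], [10, 5]])
    ests = community_alpha(table, reps=50, rng=0)
    assert {e.depth for e in ests} == {10}
    df = alpha_to_dataframe(ests)
    assert set(df["sample_id"]) == {"S1", "S2"}
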