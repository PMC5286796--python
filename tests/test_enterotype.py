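"""Jensen-Shannon distance, PAM, CH model selection, PCoA, Fisher association."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from htnbiome.enterotype import (DistanceMatrix, enterotype_association,
                                 genus_cooccurrence, jsd_distance, optimal_k,
                                 pam, pcoa)
from htnbiome.profiles import CohortMetadata
from .conftest import profile_from_array


class TestJsdDistance:
    def test_self_distance_zero_and_symmetric(self):
        rng = np.random.default_rng(0)
        prof = profile_from_array(rng.dirichlet(np.ones(5), size=4).T)
        d = jsd_distance(prof)
        assert np.allclose(np.diag(d.d), 0)
        assert np.allclose(d.d, d.d.T)

    def test_disjoint_support_is_sqrt_ln2(self):
        prof = profile_from_array([[1.0, 0.0], [0.0, 1.0]])
        d = jsd_distance(prof)
        assert d.d[0, 1] == pytest.approx(np.sqrt(np.log(2)))

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            prof = profile_from_array(rng.dirichlet(np.ones(6), size=3).T)
            d = jsd_distance(prof).d
            for i, j, k in itertools.permutations(range(3)):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_taxon_permutation_invariance(self):
        rng = np.random.default_rng(2)
        arr = rng.dirichlet(np.ones(6), size=4).T
        perm = rng.permutation(6)
        d1 = jsd_distance(profile_from_array(arr)).d
        d2 = jsd_distance(profile_from_array(arr[perm])).d
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            jsd_distance(profile_from_array([[-0.1], [1.1]]))


def _two_clouds(n_per=6, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 0.5, size=(n_per, 2)),
                     rng.normal(sep, 0.5, size=(n_per, 2))])
    d = squareform(pdist(pts))
    ids = [f"s{i}" for i in range(2 * n_per)]
    return DistanceMatrix(ids, d, metric="euclidean"), pts


class TestPam:
    def test_separated_clouds_split_perfectly(self):
        dist, _ = _two_clouds()
        assignment, medoids = pam(dist, k=2)
        left = set(assignment.iloc[:6])
        right = set(assignment.iloc[6:])
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_objective_matches_exhaustive_search_n8(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            pts = rng.normal(size=(8, 2))
            d = squareform(pdist(pts))
            dist = DistanceMatrix([f"s{i}" for i in range(8)], d)
            _, medoids = pam(dist, k=2)
            got = d[[dist.sample_ids.index(m) for m in medoids]].min(axis=0).sum()
            best = min(d[list(pair)].min(axis=0).sum()
                       for pair in itertools.combinations(range(8), 2))
            assert got == pytest.approx(best)

    def test_duplicate_of_medoid_joins_its_cluster(self):
        dist, pts = _two_clouds()
        assignment, medoids = pam(dist, k=2)
        m = medoids[0]
        dup = assignment.index.get_loc(m)
        # duplicate row: distance profile identical to the medoid's
        assert assignment.loc[m] == assignment.iloc[dup]

    def test_k_bounds(self):
        dist, _ = _two_clouds(n_per=3)
        with pytest.raises(ValueError):
            pam(dist, k=6)


class TestPcoa:
    def test_points_on_line_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        coords, eig, _ = pcoa(DistanceMatrix(list("abcd"), d), n_axes=1)
        got = coords.values[:, 0]
        got = (got - got.mean())
        want = x - x.mean()
        err = min(np.abs(got - want).max(), np.abs(-got - want).max())
        assert err < 1e-8

    def test_equilateral_three_points_two_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        _, eig, _ = pcoa(DistanceMatrix(list("abc"), d), n_axes=2)
        pos = np.sort(eig[eig > 1e-12])
        assert pos[0] == pytest.approx(pos[1])

    def test_euclidean_input_reproduces_pca(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3))
        d = squareform(pdist(pts))
        coords, _, _ = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d), n_axes=2)
        from sklearn.decomposition import PCA
        pc = PCA(n_components=2).fit_transform(pts)
        for axis in range(2):
            r = abs(np.corrcoef(coords.values[:, axis], pc[:, axis])[0, 1])
            assert r > 1 - 1e-8


class TestOptimalK:
    def test_two_mode_cohort_selects_k2(self, small_cohort):
        from htnbiome.profiles import filter_taxa, taxon_profile
        prof = filter_taxa(taxon_profile(small_cohort.genes,
                                         small_cohort.gene_annotation["taxon"]))
        model = optimal_k(jsd_distance(prof), prof, k_range=range(2, 7), seed=0)
        assert model.k == 2
        assert model.ch_by_k[2] > model.ch_by_k[3]
        assert model.dominant_taxon[1] != model.dominant_taxon[2]
        assert set(model.dominant_taxon.values()) == {"Prevotella", "Bacteroides"}

    def test_three_equidistant_singletons_no_crash(self):
        d = np.ones((3, 3)) - np.eye(3)
        model = optimal_k(DistanceMatrix(list("abc"), d), k_range=range(2, 3))
        assert np.isfinite(model.ch_by_k[2])

    def test_empty_k_range_errors(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            optimal_k(DistanceMatrix(list("abc"), d), k_range=range(5, 5))


class TestAssociation:
    def _meta(self, groups):
        return CohortMetadata(pd.DataFrame(
            {"group": groups}, index=[f"s{i}" for i in range(len(groups))]))

    def test_balanced_table_or_one_p_one(self):
        meta = self._meta(["C"] * 10 + ["H"] * 10)
        assignment = pd.Series([1, 2] * 10, index=meta.sample_ids)
        table, or_mle, or_sample, p = enterotype_association(assignment, meta)
        assert or_sample == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association_hypergeometric_p(self):
        from math import comb
        meta = self._meta(["C"] * 10 + ["H"] * 10)
        assignment = pd.Series([1] * 10 + [2] * 10, index=meta.sample_ids)
        _, _, _, p = enterotype_association(assignment, meta)
        assert p == pytest.approx(2 / comb(20, 10))

    def test_matches_enumeration_on_small_tables(self):
        """Fisher p equals exhaustive hypergeometric enumeration, n <= 12."""
        for a, b, c, d in [(3, 2, 1, 4), (2, 2, 4, 4), (5, 1, 0, 6), (1, 3, 3, 1)]:
            n1, n2 = a + b, c + d
            col1 = a + c
            n = n1 + n2
            probs = {}
            for x in range(max(0, col1 - n2), min(n1, col1) + 1):
                probs[x] = stats.hypergeom.pmf(x, n, n1, col1)
            p_enum = sum(v for v in probs.values() if v <= probs[a] * (1 + 1e-9))
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(p_enum, rel=1e-8)

    def test_empty_margin_errors(self):
        meta = self._meta(["C"] * 4 + ["H"] * 4)
        assignment = pd.Series([1] * 8, index=meta.sample_ids)
        with pytest.raises(ValueError):
            enterotype_association(assignment, meta)


class TestGenusCooccurrence:
    def test_monotone_transforms_of_one_factor_form_clique(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=20)
        arr = np.vstack([np.exp(z), np.exp(2 * z), stats.rankdata(z), z - z.min() + 1])
        prof = profile_from_array(arr)
        net = genus_cooccurrence(prof, list(prof.sample_ids))
        assert net.graph.number_of_edges() == 6
        assert all(d["sign"] == 1 for _, _, d in net.graph.edges(data=True))

    def test_negative_anchor_edges_keep_sign(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=20)
        arr = np.vstack([-z + 0.01 * rng.normal(size=20), z, z + 0.01 * rng.normal(size=20)])
        prof = profile_from_array(arr, taxa=["anchor", "a", "b"])
        net = genus_cooccurrence(prof, list(prof.sample_ids), anchor_taxon="anchor")
        signs = {frozenset((u, v)): d["sign"] for u, v, d in net.graph.edges(data=True)}
        assert signs[frozenset(("anchor", "a"))] == -1
        assert signs[frozenset(("anchor", "b"))] == -1
        assert net.graph.nodes["anchor"]["anchor"] is True

    def test_too_few_samples_rejected(self):
        prof = profile_from_array(np.random.default_rng(0).random((3, 5)))
        with pytest.raises(ValueError):
            genus_cooccurrence(prof, list(prof.sample_ids))
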