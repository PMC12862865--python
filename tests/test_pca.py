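"""Centering, pairwise-complete similarity, and its eigendecomposition."""
import numpy as np
import pytest

import haplopop as hp
from conftest import make_dataset

M = hp.MISSING


class TestCentering:
    def test_direct_arithmetic(self):
        centred = hp.center_genotypes(np.array([[0], [1], [1]]))
        np.testing.assert_allclose(centred[:, 0], [-2 / 3, 1 / 3, 1 / 3])

    def test_observed_values_sum_to_zero(self):
        rng = np.random.default_rng(51)
        calls = rng.choice([0, 1, M], size=(10, 30), p=[0.4, 0.4, 0.2])
        calls[0] = 0  # guard against all-missing columns
        centred = hp.center_genotypes(calls)
        sums = np.nansum(centred, axis=0)
        np.testing.assert_allclose(sums, 0.0, atol=1e-12)

    def test_monomorphic_column_zeroed(self):
        centred = hp.center_genotypes(np.ones((4, 2), dtype=int))
        np.testing.assert_array_equal(centred, 0.0)

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError, match="all-missing"):
            hp.center_genotypes(np.full((3, 1), M))


class TestSimilarityMatrix:
    def test_complete_data_equals_dense_product(self):
        rng = np.random.default_rng(52)
        calls = rng.choice([0, 1], size=(6, 40))
        centred = hp.center_genotypes(calls)
        sim = hp.similarity_matrix(centred, min_pairs=1)
        np.testing.assert_allclose(sim.values, centred @ centred.T / 40, atol=1e-12)
        assert (sim.n_pairs == 40).all()

    def test_duplicate_rows_give_equal_rows(self):
        rng = np.random.default_rng(53)
        calls = rng.choice([0, 1], size=(5, 30))
        calls[2] = calls[0]
        sim = hp.similarity_matrix(hp.center_genotypes(calls), min_pairs=1)
        np.testing.assert_allclose(sim.values[0], sim.values[2], atol=1e-12)

    def test_holes_match_triple_loop_brute_force(self):
        rng = np.random.default_rng(54)
        calls = rng.choice([0, 1, M], size=(4, 6), p=[0.4, 0.4, 0.2])
        calls[0] = [0, 1, 0, 1, 1, 0]  # keep every column observed somewhere
        centred = hp.center_genotypes(calls)
        sim = hp.similarity_matrix(centred, min_pairs=1)
        for i in range(4):
            for k in range(4):
                prods = [centred[i, j] * centred[k, j] for j in range(6)
                         if not (np.isnan(centred[i, j]) or np.isnan(centred[k, j]))]
                if prods:
                    assert sim.values[i, k] == pytest.approx(np.mean(prods), abs=1e-12)
                    assert sim.n_pairs[i, k] == len(prods)
                else:
                    assert np.isnan(sim.values[i, k])

    def test_diagonal_pair_counts_equal_call_counts(self, toy_dataset):
        centred = hp.center_genotypes(toy_dataset.calls)
        sim = hp.similarity_matrix(centred, ids=toy_dataset.sample_ids, min_pairs=1)
        np.testing.assert_array_equal(np.diag(sim.n_pairs),
                                      toy_dataset.samples["n_calls"])


class TestEigenPca:
    def test_rank_one_matrix_closed_form(self):
        v = np.array([3.0, 0.0, 4.0])
        sim = hp.SimilarityMatrix(["a", "b", "c"], np.outer(v, v),
                                  np.full((3, 3), 10), min_pairs=1)
        res = hp.eigen_pca(sim, n_components=3)
        assert res.eigenvalues[0] == pytest.approx(25.0)
        np.testing.assert_allclose(res.eigenvalues[1:], 0.0, atol=1e-10)
        np.testing.assert_allclose(np.abs(res.coordinates[:, 0]), np.abs(v / 5))

    def test_asymmetric_rejected(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        sim = hp.SimilarityMatrix(["a", "b"], bad, np.full((2, 2), 10))
        with pytest.raises(ValueError, match="asymmetric"):
            hp.eigen_pca(sim)

    def test_pc1_separates_two_populations(self, two_pop_dataset):
        ds, truth = two_pop_dataset
        res, _ = hp.pca(ds, n_components=2)
        pc1 = res.coordinates[:, 0]
        labels = ds.samples["group"].to_numpy()
        side = pc1 > 0
        # sign-based assignment must be perfect for F = 0.1 at 5000 SNPs
        assert len({(l, s) for l, s in zip(labels, side)}) == 2

    def test_zero_missingness_equals_standard_pca(self):
        rng = np.random.default_rng(55)
        calls = rng.choice([0, 1], size=(20, 200))
        centred = hp.center_genotypes(calls)
        res = hp.eigen_pca(hp.similarity_matrix(centred, min_pairs=1),
                           n_components=20)
        ref_eigval = np.linalg.eigvalsh(centred @ centred.T / 200)[::-1]
        np.testing.assert_allclose(res.eigenvalues, ref_eigval, atol=1e-8)
        # spectral reconstruction of the similarity matrix
        lam = res.eigenvalues
        vec = hp.eigen_pca(hp.similarity_matrix(centred, min_pairs=1),
                           n_components=20).coordinates
        recon = (vec * lam) @ vec.T
        np.testing.assert_allclose(recon, centred @ centred.T / 200, atol=1e-8)

    def test_variance_explained_over_positive_eigenvalues(self):
        vals = np.array([[2.0, 0.0], [0.0, -1.0]])
        sim = hp.SimilarityMatrix(["a", "b"], vals, np.full((2, 2), 10))
        res = hp.eigen_pca(sim, n_components=2)
        assert res.variance_explained[0] == pytest.approx(1.0)
        assert res.variance_explained[1] == 0.0


class TestSubsetPca:
    def test_full_subset_identical(self, toy_dataset):
        res, sim = hp.pca(toy_dataset, n_components=4, min_pairs=1)
        sub = hp.subset_pca(sim, toy_dataset.sample_ids, n_components=4)
        np.testing.assert_allclose(sub.coordinates, res.coordinates)

    def test_distances_preserved_after_dropping_duplicate(self):
        # scaled full-rank coordinates reproduce the similarity Gram matrix,
        # so pairwise distances of the kept individuals are unchanged
        rng = np.random.default_rng(56)
        calls = rng.choice([0, 1], size=(8, 100))
        calls[3] = calls[0]
        ds = make_dataset(calls.tolist())
        res, sim = hp.pca(ds, n_components=8, min_pairs=1)
        keep = [s for s in ds.sample_ids if s != "i3"]
        sub = hp.subset_pca(sim, keep, n_components=7, scaled=True)
        full = hp.eigen_pca(sim, n_components=8, scaled=True)
        kept_idx = [ds.sample_ids.index(s) for s in keep]

        def dists(coords):
            d = coords[:, None, :] - coords[None, :, :]
            return np.sqrt((d ** 2).sum(-1))

        np.testing.assert_allclose(dists(sub.coordinates),
                                   dists(full.coordinates[kept_idx]), atol=1e-8)

    def test_group_removal_keeps_spectrum_clean(self, two_pop_dataset):
        ds, _ = two_pop_dataset
        res, sim = hp.pca(ds, n_components=5)
        keep = ds.samples[ds.samples["group"] == "P1"]["sample_id"].tolist()
        sub = hp.subset_pca(sim, keep, n_components=5)
        assert not np.isnan(sub.eigenvalues).any()
        assert (np.diff(sub.eigenvalues) <= 1e-9).all()

    def test_unknown_id_rejected(self, toy_dataset):
        _, sim = hp.pca(toy_dataset, n_components=2, min_pairs=1)
        with pytest.raises(KeyError, match="ghost"):
            hp.subset_pca(sim, ["i0", "ghost"])


class TestMigrantPlacement:
    def test_migrants_fall_in_source_hull(self):
        # planted migrants land inside their source population's convex hull
        # on (PC1, PC2) in >= 90% of replicates; the source sample is large
        # because a pure-source migrant is exchangeable with source members,
        # so hull inclusion itself is only ~(1 - vertices/n) probable
        from scipy.spatial import Delaunay
        hits = total = 0
        for seed in range(20):
            cfg = hp.SimConfig(n_pops=2, n_snps=5000, pop_F=(0.1, 0.1),
                               sample_sizes=(20, 150), missing_rate=0.2,
                               migrants=[("P1", "P2", 1)], seed=200 + seed)
            ds, truth = hp.build_dataset(cfg)
            res, _ = hp.pca(ds, n_components=2)
            coords = res.coordinates[:, :2]
            mig = truth.migrants(ds.samples)["sample_id"].iloc[0]
            labels = ds.samples["group"].to_numpy()
            ids = np.asarray(ds.sample_ids)
            source_pts = coords[(labels == "P2")]
            hull = Delaunay(source_pts)
            total += 1
            if hull.find_simplex(coords[ids == mig][0]) >= 0:
                hits += 1
        assert hits / total >= 0.9
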