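import math

import numpy as np
import pytest

from prism import (
    DistanceMatrix,
    PrismError,
    ZipfianCoSpectrum,
    cluster_projection_distances,
    euclidean_distances,
    pairwise,
    zipfian_distance,
    zipfian_distance_matrix,
)


def make_z(model_id, bins, h, ranks=None, k=2, total=100):
    order = np.argsort(h, kind="stable")
    bins = [bins[i] for i in order]
    h = np.asarray(h, dtype=float)[order]
    ranks = (np.arange(1, len(bins) + 1) if ranks is None
             else np.asarray(ranks)[order])
    return ZipfianCoSpectrum(model_id, k=k, total=total,
                             ranks=np.asarray(ranks), h=h, bins=bins)


class TestEuclidean:
    def test_identical_vectors(self):
        d = euclidean_distances(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d.d[0, 1] == 0.0

    def test_3_4_5(self):
        d = euclidean_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d.d[0, 1] == pytest.approx(5.0)

    def test_matches_summation_oracle(self, rng):
        x = rng.normal(size=(6, 10))
        d = euclidean_distances(x)
        for i in range(6):
            for j in range(6):
                oracle = math.sqrt(sum((x[i, c] - x[j, c]) ** 2
                                       for c in range(10)))
                assert d.d[i, j] == pytest.approx(oracle, abs=1e-9)

    def test_pairwise_complete_rescales(self):
        x = np.array([[1.0, 5.0, 0.0], [1.0, 5.0, 9.0]])
        flags = np.array([[False, False, True], [False, False, False]])
        d = euclidean_distances(x, flags=flags,
                                missing_policy="pairwise-complete")
        assert d.d[0, 1] == 0.0  # shared coords agree exactly
        y = np.array([[1.0, 5.0, 0.0], [2.0, 6.0, 9.0]])
        d2 = euclidean_distances(y, flags=flags,
                                 missing_policy="pairwise-complete")
        assert d2.d[0, 1] == pytest.approx(math.sqrt(2.0 * 3 / 2))

    def test_no_overlap(self):
        flags = np.array([[True, False], [False, True]])
        with pytest.raises(PrismError, match="no-overlap"):
            euclidean_distances(np.ones((2, 2)), flags=flags,
                                missing_policy="pairwise-complete")


class TestZipfianDistance:
    def test_identity(self, small_profile):
        from prism import zipfian_from_profile

        z = zipfian_from_profile(small_profile, "m")
        assert zipfian_distance(z, z) == 0.0

    def test_hand_summation(self):
        a = make_z("a", ["AA", "AC"], [1.0, 2.0])
        b = make_z("b", ["AA", "AC"], [1.0, 3.0])
        # only bin AC differs: (2-3)^2 / mean-rank 2 = 1/2
        assert zipfian_distance(a, b) == pytest.approx(math.sqrt(0.5))

    def test_symmetry(self):
        a = make_z("a", ["AA", "AC"], [1.0, 2.0])
        b = make_z("b", ["AA", "AC"], [1.5, 3.0])
        assert zipfian_distance(a, b) == zipfian_distance(b, a)

    def test_missing_bin_uses_pseudocount_at_rank_d_plus_1(self):
        from prism import unobserved_self_information

        a = make_z("a", ["AA", "AC"], [1.0, 2.0], total=10)
        b = make_z("b", ["AA"], [0.5], total=20)
        h_un = unobserved_self_information(20)
        expected = math.sqrt((1.0 - 0.5) ** 2 / 1.0
                             + (2.0 - h_un) ** 2 / ((2 + 2) / 2))
        assert zipfian_distance(a, b) == pytest.approx(expected)

    def test_k_mismatch(self):
        a = make_z("a", ["AA"], [0.0], k=2)
        b = make_z("b", ["AAA"], [0.0], k=3)
        with pytest.raises(PrismError, match="incompatible-spectra"):
            zipfian_distance(a, b)

    def test_bin_relabeling_invariance(self, rng):
        h = np.sort(rng.uniform(0, 5, size=8))
        a1 = make_z("a", [f"w{i}" for i in range(8)], list(h))
        b1 = make_z("b", [f"w{i}" for i in range(8)], list(h + 0.3))
        a2 = make_z("a", [f"x{i}" for i in range(8)], list(h))
        b2 = make_z("b", [f"x{i}" for i in range(8)], list(h + 0.3))
        assert zipfian_distance(a1, b1) == pytest.approx(
            zipfian_distance(a2, b2))

    def test_matrix_equals_pairwise_calls(self, rng):
        zs = []
        for t in range(5):
            h = np.sort(rng.uniform(0.5, 6.0, size=12))
            keep = rng.random(12) < 0.8
            zs.append(make_z(
                f"z{t}", [f"w{i:02d}" for i in np.flatnonzero(keep)],
                list(h[keep])))
        dm = zipfian_distance_matrix(zs)
        dp = pairwise(zs, "zipfian")
        assert np.allclose(dm.d, dp.d, atol=1e-12)


class TestClusterProjection:
    def test_singleton_clusters_equal_euclidean(self, rng):
        x = rng.normal(size=(12, 5))
        d1 = cluster_projection_distances(x, n_clusters=12, seed=0)
        d2 = euclidean_distances(x.T)
        assert np.allclose(d1.d, d2.d, atol=1e-9)

    def test_duplicated_column_distance_zero(self, rng):
        x = rng.normal(size=(20, 4))
        x[:, 3] = x[:, 0]
        d = cluster_projection_distances(x, n_clusters=4, seed=1)
        assert d.d[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_two_blob_closed_form(self, rng):
        # two well-separated spectrum blobs; projection = per-blob col means
        a = rng.normal(0.0, 0.05, size=(15, 3))
        b = rng.normal(10.0, 0.05, size=(10, 3))
        x = np.vstack([a, b])
        d = cluster_projection_distances(x, n_clusters=2, seed=0)
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        oracle = euclidean_distances(np.stack([ma, mb]).T)
        assert np.allclose(np.sort(d.d.ravel()), np.sort(oracle.d.ravel()),
                           atol=1e-9)

    def test_too_many_clusters(self, rng):
        with pytest.raises(PrismError, match="invalid-clusters"):
            cluster_projection_distances(rng.normal(size=(3, 2)), 5)


class TestAxiomsAndPlumbing:
    def test_pairwise_unknown_metric(self):
        with pytest.raises(PrismError, match="unknown-metric"):
            pairwise([1, 2], "mahalanobis")

    def test_pairwise_single_item(self):
        d = pairwise([np.zeros(3)], "euclidean")
        assert d.d.shape == (1, 1) and d.d[0, 0] == 0.0

    def test_distance_matrix_invariants_enforced(self):
        with pytest.raises(PrismError, match="asymmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(PrismError, match="nonzero-diagonal"):
            DistanceMatrix(["a"], np.array([[1.0]]))

    def test_triangle_inequality_all_metrics(self, rng):
        # euclidean
        x = rng.normal(size=(30, 6))
        de = euclidean_distances(x).d
        # cluster projection
        dc = cluster_projection_distances(rng.normal(size=(25, 9)),
                                          n_clusters=5, seed=0).d
        # zipfian over random sparse co-spectra
        zs = []
        for t in range(12):
            h = np.sort(rng.uniform(0.5, 6.0, size=15))
            keep = rng.random(15) < 0.8
            zs.append(make_z(
                f"z{t}", [f"w{i:02d}" for i in np.flatnonzero(keep)],
                list(h[keep])))
        dz = zipfian_distance_matrix(zs).d
        for d in (de, dc, dz):
            n = d.shape[0]
            triples = rng.integers(0, n, size=(120, 3))
            for i, j, k in triples:
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_phylip_and_tsv_roundtrip(self, tmp_path, rng):
        d = euclidean_distances(rng.normal(size=(4, 3)),
                                item_ids=list("abcd"))
        d.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert np.allclose(back.d, d.d, atol=1e-6)
        d.to_phylip(tmp_path / "d.phy")
        lines = (tmp_path / "d.phy").read_text().splitlines()
        assert lines[0].strip() == "4" and len(lines) == 5
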