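"""Global / short-range / long-range FCD mapping."""

import networkx as nx
import numpy as np
import pytest

from fcdmap.fcd import (compute_fcd, compute_global_fcd,
                        compute_long_range_fcd, compute_short_range_fcd,
                        correlation_matrix, zscore_and_smooth, zscore_map)
from fcdmap.qc import BoldMatrix
from fcdmap.surface import SurfaceMesh, build_adjacency


def _bold(values):
    return BoldMatrix(values=np.asarray(values, float))


def _random_patchy_bold(mesh, rng, n_patches=8, r=0.5):
    """Patch-correlated noise giving a nontrivial suprathreshold graph."""
    labels = np.arange(mesh.n_vertices) % n_patches
    sig = rng.standard_normal((n_patches, 60))
    alpha = np.sqrt(r / (1 - r))
    x = alpha * sig[labels] + rng.standard_normal((mesh.n_vertices, 60))
    return BoldMatrix(values=x)


class TestGlobalFcd:
    def test_identical_series_connect_to_everyone(self, triangle_mesh):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(50)
        counts, ok = compute_global_fcd(_bold(np.tile(s, (3, 1))))
        assert (counts == 2).all()

    def test_white_noise_has_no_connections(self):
        rng = np.random.default_rng(1)
        counts, _ = compute_global_fcd(_bold(rng.standard_normal((60, 250))))
        assert counts.sum() == 0

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 40))
        x[10:15] += 2.0 * rng.standard_normal(40)       # correlated block
        counts, ok = compute_global_fcd(_bold(x), threshold_r=0.6)
        oracle = np.zeros(30, dtype=int)
        for u in range(30):
            for v in range(30):
                if u != v and np.corrcoef(x[u], x[v])[0, 1] > 0.6:
                    oracle[u] += 1
        np.testing.assert_array_equal(counts, oracle)

    def test_blockwise_bit_identical(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((101, 50))
        x[::3] += rng.standard_normal(50)
        full, _ = compute_global_fcd(_bold(x))
        for bs in (7, 32, 101, 1000):
            blocked, _ = compute_global_fcd(_bold(x), block_size=bs)
            np.testing.assert_array_equal(full, blocked)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((40, 30)) + rng.standard_normal(30) * 0.8
        lo, _ = compute_global_fcd(_bold(x), threshold_r=0.3)
        hi, _ = compute_global_fcd(_bold(x), threshold_r=0.7)
        assert (hi <= lo).all()

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_global_fcd(_bold(np.ones((5, 10))))


class TestShortRangeFcd:
    def test_fully_correlated_connected_mesh(self, icosahedron):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(40)
        bold = _bold(np.tile(s, (icosahedron.n_vertices, 1))
                     + 1e-6 * rng.standard_normal((icosahedron.n_vertices,
                                                   40)))
        g, _ = compute_global_fcd(bold)
        sr, _ = compute_short_range_fcd(bold, icosahedron)
        n = icosahedron.n_vertices
        assert (sr == n - 1).all()
        np.testing.assert_array_equal(compute_long_range_fcd(g, sr), 0)

    def test_distant_patch_counts_as_long_range(self, icosphere2):
        """Seed correlated only with a non-adjacent patch: growth never
        starts, so all its connections are long-range."""
        mesh = icosphere2
        rng = np.random.default_rng(6)
        n = mesh.n_vertices
        seed = 0
        coords = mesh.vertex_coords
        far = np.argsort(((coords - coords[seed]) ** 2).sum(1))[-6:]
        adj = build_adjacency(mesh)
        assert not set(far).intersection(adj[seed])
        x = rng.standard_normal((n, 80))
        shared = rng.standard_normal(80)
        x[seed] = shared + 0.1 * rng.standard_normal(80)
        x[far] = shared + 0.1 * rng.standard_normal((6, 80))
        bold = _bold(x)
        g, _ = compute_global_fcd(bold)
        sr, _ = compute_short_range_fcd(bold, mesh)
        lr = compute_long_range_fcd(g, sr)
        assert sr[seed] == 0
        assert lr[seed] == g[seed] == 6

    def test_matches_independent_graph_oracle(self, icosphere3):
        """Growing algorithm equals connected components (networkx) of the
        mesh subgraph induced on each seed's suprathreshold set."""
        mesh = icosphere3
        rng = np.random.default_rng(7)
        bold = _random_patchy_bold(mesh, rng, r=0.55)
        R, ok = correlation_matrix(bold)
        sr, _ = compute_short_range_fcd(bold, mesh)
        G = nx.Graph()
        G.add_nodes_from(range(mesh.n_vertices))
        G.add_edges_from(mesh.edges.tolist())
        for seed in rng.choice(mesh.n_vertices, 60, replace=False):
            keep = set(np.flatnonzero(R[seed] > 0.6)) | {seed}
            sub = G.subgraph(keep)
            expected = len(nx.node_connected_component(sub, int(seed))) - 1
            assert sr[seed] == expected

    def test_bfs_and_vectorized_agree(self, icosphere2):
        rng = np.random.default_rng(8)
        bold = _random_patchy_bold(icosphere2, rng, r=0.6)
        a, _ = compute_short_range_fcd(bold, icosphere2, method="vectorized")
        b, _ = compute_short_range_fcd(bold, icosphere2, method="bfs")
        np.testing.assert_array_equal(a, b)


class TestConservationAndInvariance:
    def test_sum_rule_exact(self, icosphere2):
        rng = np.random.default_rng(9)
        for trial in range(3):
            bold = _random_patchy_bold(icosphere2, rng, r=0.5 + 0.1 * trial)
            res = compute_fcd(bold, icosphere2, smooth=False)
            np.testing.assert_array_equal(
                res.short_range_fcd + res.long_range_fcd, res.global_fcd)

    def test_negative_difference_rejected(self):
        with pytest.raises(ValueError, match="growing"):
            compute_long_range_fcd(np.array([3, 1]), np.array([1, 2]))

    def test_permutation_equivariance(self, icosahedron):
        rng = np.random.default_rng(10)
        mesh = icosahedron
        bold = _random_patchy_bold(mesh, rng, n_patches=4, r=0.6)
        res = compute_fcd(bold, mesh, smooth=False)
        perm = rng.permutation(mesh.n_vertices)
        inv = np.argsort(perm)
        mesh_p = SurfaceMesh(vertex_coords=mesh.vertex_coords[perm],
                             triangles=inv[mesh.triangles])
        bold_p = _bold(bold.values[perm])
        res_p = compute_fcd(bold_p, mesh_p, smooth=False)
        np.testing.assert_array_equal(res_p.global_fcd, res.global_fcd[perm])
        np.testing.assert_array_equal(res_p.short_range_fcd,
                                      res.short_range_fcd[perm])


class TestZscoreAndSmooth:
    def test_closed_form_zscore(self):
        z = zscore_map(np.array([0.0, 2.0, 4.0]), np.ones(3, dtype=bool))
        np.testing.assert_allclose(z, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_map(np.ones(5), np.ones(5, dtype=bool))

    def test_smoothed_z_mean_stays_zero(self, icosphere2):
        rng = np.random.default_rng(11)
        vals = rng.poisson(10, icosphere2.n_vertices).astype(float)
        mask = np.ones(icosphere2.n_vertices, dtype=bool)
        raw, smoothed = zscore_and_smooth({"m": vals}, icosphere2, mask)
        assert abs(raw["m"].mean()) < 1e-12
        assert abs(np.nanmean(smoothed["m"].values)) < 1e-6
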