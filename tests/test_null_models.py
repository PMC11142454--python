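"""Null-model randomizations, geometric distances, movement rules, generators."""

import numpy as np
import pytest
from scipy import stats

from tnulls import GeometricParams, HyperbolicParams, TemporalGraph, generate
from tnulls.null_models import (
    _reflect_unit,
    geometric_snapshot,
    hyperbolic_distance,
    move_hyperbolic,
    move_square,
    move_torus,
    permuted_times,
    radial_cdf,
    radial_inverse_cdf,
    randomized_edges,
    sample_hyperbolic_positions,
    sample_square_positions,
    torus_distance,
)

from .conftest import random_temporal_graph


def contact_stats(g):
    contacts = g.to_contacts()
    pairs = sorted((u, v) for u, v, _ in contacts)
    times = sorted(t for _, _, t in contacts)
    return len(contacts), pairs, times


def hyperboloid_distance(p, q, zeta=1.0):
    """Geodesic via explicit hyperboloid embedding and the Minkowski inner product."""

    def embed(r, theta):
        return np.array(
            [np.cosh(zeta * r), np.sinh(zeta * r) * np.cos(theta),
             np.sinh(zeta * r) * np.sin(theta)]
        ) / zeta

    x, y = embed(*p), embed(*q)
    minkowski = -x[0] * y[0] + x[1] * y[1] + x[2] * y[2]
    return np.arccosh(max(-(zeta**2) * minkowski, 1.0)) / zeta


class TestPermutedTimes:
    def test_edgeless_input(self):
        g = TemporalGraph.from_contacts([], 4, 3)
        assert permuted_times(g, 0) == g

    def test_degenerate_timestamp_multiset(self):
        g = TemporalGraph.from_contacts([(0, 1, 1), (2, 3, 1)], 4, 3)
        assert permuted_times(g, 5) == g  # all timestamps equal: nothing can move

    def test_conserves_pairs_times_and_degree(self):
        g = random_temporal_graph(10, 6, 0.3, 0)
        count, pairs, times = contact_stats(g)
        for seed in range(20):
            h = permuted_times(g, seed)
            hcount, hpairs, htimes = contact_stats(h)
            assert (hcount, hpairs, htimes) == (count, pairs, times)
            assert h.average_degree() == pytest.approx(g.average_degree())

    def test_snapshot_mode_reorders_whole_slices(self):
        g = random_temporal_graph(8, 5, 0.3, 1)
        h = permuted_times(g, 3, mode="snapshots")
        originals = {g.tensor[t].tobytes() for t in range(5)}
        assert {h.tensor[t].tobytes() for t in range(5)} == originals

    def test_shuffle_actually_moves_contacts(self):
        g = random_temporal_graph(10, 6, 0.3, 0)
        assert any(permuted_times(g, s) != g for s in range(5))


class TestRandomizedEdges:
    def test_edgeless_input(self):
        g = TemporalGraph.from_contacts([], 5, 3)
        assert randomized_edges(g, 0) == g

    def test_identity_permutation_is_noop(self):
        g = random_temporal_graph(6, 4, 0.4, 2)
        identity = [np.arange(6)] * 4
        assert randomized_edges(g, 0, permutations=identity) == g

    def test_never_grows_and_never_self_loops(self):
        g = random_temporal_graph(6, 4, 0.4, 7)
        before = [int(g.tensor[t].sum()) // 2 for t in range(4)]
        for seed in range(50):
            h = randomized_edges(g, seed)
            for t in range(4):
                assert int(h.tensor[t].sum()) // 2 <= before[t]
                assert np.diagonal(h.tensor[t]).sum() == 0
                assert (h.tensor[t] == h.tensor[t].T).all()


class TestSquareTorusGeometry:
    def test_uniform_positions(self):
        pos = sample_square_positions(100_000, 0)
        assert pos.shape == (100_000, 2)
        assert (pos >= 0).all() and (pos <= 1).all()
        # mean within 3 standard errors of (1/2, 1/2)
        se = np.sqrt(1 / 12 / 100_000)
        assert np.abs(pos.mean(axis=0) - 0.5).max() < 3 * se
        assert stats.kstest(pos[:10_000, 0], "uniform").pvalue > 0.01

    def test_torus_distance_examples(self):
        assert torus_distance([0.3, 0.7], [0.3, 0.7]) == 0.0
        assert torus_distance([0.05, 0.5], [0.95, 0.5]) == pytest.approx(0.1)

    def test_torus_distance_matches_nine_image_minimum(self):
        rng = np.random.default_rng(0)
        p, q = rng.random((2, 300, 2))
        shifts = np.array([(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)])
        brute = np.min(
            [np.linalg.norm(p - (q + s), axis=1) for s in shifts], axis=0
        )
        assert np.allclose(torus_distance(p, q), brute)

    def test_snapshot_limits(self):
        pos = sample_square_positions(20, 1)
        assert geometric_snapshot(pos, np.sqrt(2) * 1.001, "square").sum() == 20 * 19
        assert geometric_snapshot(pos, 1e-12, "square").sum() == 0

    def test_square_vs_torus_corner_contrast(self):
        pos = np.array([[0.02, 0.02], [0.98, 0.98]])
        assert geometric_snapshot(pos, 0.1, "square")[0, 1] == 0
        assert geometric_snapshot(pos, 0.1, "torus")[0, 1] == 1

    def test_zero_speed_is_identity(self):
        pos = sample_square_positions(50, 2)
        assert (move_square(pos, 0.0, 3) == pos).all()
        assert (move_torus(pos, 0.0, 3) == pos).all()

    def test_reflection_rule(self):
        # overshooting 1 by delta lands at 1 - delta
        assert _reflect_unit(np.array([1.02]))[0] == pytest.approx(0.98)
        assert _reflect_unit(np.array([-0.1]))[0] == pytest.approx(0.1)
        assert _reflect_unit(np.array([2.3]))[0] == pytest.approx(0.3)

    def test_torus_wraps(self):
        moved = np.mod(np.array([[0.98, 0.5]]) + np.array([[0.05, 0.0]]), 1.0)
        assert moved[0, 0] == pytest.approx(0.03)


class TestHyperbolicGeometry:
    def test_inverse_cdf_endpoints_and_median(self):
        assert radial_inverse_cdf(0.0, 1.0, 4.5) == 0.0
        assert radial_inverse_cdf(1.0, 1.0, 4.5) == pytest.approx(4.5)
        expected_median = np.arccosh(1 + 0.5 * (np.cosh(4.5) - 1))
        assert radial_inverse_cdf(0.5, 1.0, 4.5) == pytest.approx(expected_median)
        assert expected_median == pytest.approx(3.8285, abs=1e-4)
        params = HyperbolicParams(n_nodes=100_000, n_steps=1, alpha=1.0, R=4.5)
        pos = sample_hyperbolic_positions(params, 0)
        assert np.median(pos[:, 0]) == pytest.approx(expected_median, rel=0.01)

    def test_radial_density_chi_square(self):
        params = HyperbolicParams(n_nodes=100_000, n_steps=1, alpha=0.8, R=4.5)
        r = sample_hyperbolic_positions(params, 1)[:, 0]
        edges = radial_inverse_cdf(np.linspace(0, 1, 21), 0.8, 4.5)
        observed, _ = np.histogram(r, bins=edges)
        assert stats.chisquare(observed).pvalue > 0.01  # equiprobable bins

    def test_distance_identities(self):
        assert hyperbolic_distance([2.0, 1.3], [2.0, 1.3]) == 0.0
        # collinear points: distance is the radial gap
        assert hyperbolic_distance([3.0, 0.7], [1.2, 0.7]) == pytest.approx(1.8)
        # antipodal at equal radius 2: acosh(cosh^2 2 + sinh^2 2) = acosh(cosh 4) = 4
        assert hyperbolic_distance([2.0, 0.0], [2.0, np.pi]) == pytest.approx(4.0)

    def test_distance_matches_hyperboloid_model(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = [rng.uniform(0, 6), rng.uniform(0, 2 * np.pi)]
            q = [rng.uniform(0, 6), rng.uniform(0, 2 * np.pi)]
            zeta = rng.uniform(0.5, 2.0)
            a = hyperbolic_distance(p, q, zeta)
            b = hyperboloid_distance(p, q, zeta)
            assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_zero_speed_is_identity(self):
        params = HyperbolicParams(n_nodes=50, n_steps=1, alpha=0.75, R=4.5)
        pos = sample_hyperbolic_positions(params, 4)
        moved = move_hyperbolic(pos, 0.0, params, 5)
        assert np.allclose(moved, pos)

    def test_radial_update_in_cdf_space_is_stationary(self):
        params = HyperbolicParams(n_nodes=20_000, n_steps=1, alpha=0.75, R=4.5, v=0.5)
        pos = sample_hyperbolic_positions(params, 6)
        rng = np.random.default_rng(7)
        for _ in range(50):
            pos = move_hyperbolic(pos, 0.5, params, rng)
        u = radial_cdf(pos[:, 0], 0.75, 4.5)
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestGenerate:
    def test_zero_speed_freezes_snapshots(self):
        for model, params in [
            ("rts", GeometricParams(n_nodes=40, n_steps=5, r=0.2, v=0.0)),
            ("rtt", GeometricParams(n_nodes=40, n_steps=5, r=0.2, v=0.0)),
            ("rth", HyperbolicParams(n_nodes=40, n_steps=5, alpha=0.8, R=4.0, v=0.0)),
        ]:
            g = generate(model, params, 0)
            assert all((g.tensor[t] == g.tensor[0]).all() for t in range(5))

    def test_deterministic_per_seed(self):
        params = HyperbolicParams(n_nodes=60, n_steps=6, alpha=0.7, R=4.5, v=0.5)
        assert generate("rth", params, 9) == generate("rth", params, 9)
        assert generate("rth", params, 9) != generate("rth", params, 10)

    def test_snapshot_is_function_of_positions(self):
        pos = sample_square_positions(30, 8)
        a = geometric_snapshot(pos, 0.3, "torus")
        b = geometric_snapshot(pos.copy(), 0.3, "torus")
        assert (a == b).all()

    def test_rth_degree_decreases_with_R(self):
        degs = []
        for R in (3.0, 4.5, 6.0):
            params = HyperbolicParams(n_nodes=200, n_steps=4, alpha=1.2, R=R, v=0.9)
            degs.append(
                np.mean([generate("rth", params, s).average_degree() for s in range(5)])
            )
        assert degs[0] > degs[1] > degs[2]

    def test_output_satisfies_graph_invariants(self):
        params = GeometricParams(n_nodes=30, n_steps=4, r=0.25, v=0.3)
        g = generate("rtt", params, 11)
        TemporalGraph(g.tensor)  # re-validate symmetry / binarity / zero diagonal
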