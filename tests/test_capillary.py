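"""Synthetic capillary networks and the embedded-membrane voxel current solve."""

import math

import numpy as np
import pytest

import tdcsflow as tf
from tdcsflow.electroosmosis import InvalidParameterError

from conftest import COARSE_GRID


class TestGeneration:
    def test_length_density_within_10_percent(self, network):
        stats = tf.network_stats(network)
        assert 501.0 <= stats.length_density <= 613.0

    def test_zero_target_gives_empty_graph(self):
        g = tf.generate_network(target_length_density=0.0)
        stats = tf.network_stats(g)
        assert g.n_segments == 0
        assert stats.length_density == stats.surface_density == 0.0
        assert stats.volume_fraction == 0.0

    def test_deterministic_for_fixed_seed(self):
        a = tf.generate_network(seed=7)
        b = tf.generate_network(seed=7)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.segments, b.segments)
        assert np.array_equal(a.outer_diameters, b.outer_diameters)

    def test_different_seeds_differ(self):
        a = tf.generate_network(seed=7)
        b = tf.generate_network(seed=8)
        assert a.nodes.shape != b.nodes.shape or not np.array_equal(a.nodes, b.nodes)

    def test_connected_and_inside_voxel(self, network):
        assert network.is_connected()
        dims = np.asarray(network.voxel_dims)
        assert np.all(network.nodes >= -1e-12)
        assert np.all(network.nodes <= dims + 1e-12)

    def test_diameters_in_range(self, network):
        assert np.all(network.outer_diameters >= 8e-6)
        assert np.all(network.outer_diameters <= 10e-6)
        assert np.all(network.lumen_diameters > 0)

    def test_infeasible_target_rejected(self):
        with pytest.raises(InvalidParameterError, match="voxel too small"):
            tf.generate_network(target_length_density=50000.0)


class TestStats:
    def test_single_axial_segment_hand_value(self):
        """One straight 0.43 mm segment: length density = 0.43/(0.15*0.16*0.43)."""
        g = tf.VesselGraph(
            nodes=np.array([[75e-6, 80e-6, 0.0], [75e-6, 80e-6, 0.43e-3]]),
            segments=np.array([[0, 1]]),
            outer_diameters=np.array([9e-6]),
            wall_thicknesses=np.array([1e-6]),
        )
        stats = tf.network_stats(g)
        assert stats.length_density == pytest.approx(41.7, rel=1e-2)

    def test_volume_fraction_formula(self, network):
        """At the in vivo density, 3.5 um lumen radius gives ~0.021."""
        stats = tf.network_stats(network)
        mean_r2_mm2 = np.average(
            (network.lumen_diameters * 1e3 / 2.0) ** 2,
            weights=network.segment_lengths(),
        )
        expected = stats.length_density * math.pi * mean_r2_mm2
        assert stats.volume_fraction == pytest.approx(expected, rel=1e-6)
        assert stats.volume_fraction == pytest.approx(0.021, rel=0.15)


class TestSolver:
    def test_empty_graph_uniform_slab(self):
        """No vessels: uniform field, drop = J * depth / sigma, exactly."""
        g = tf.generate_network(target_length_density=0.0)
        sol = tf.solve_voxel_current(g, "closed", 1000.0, 0.082, grid_shape=(8, 8, 24))
        hz = g.voxel_dims[2] / 24
        top = sol.grid_potentials[:, :, -1]
        assert np.ptp(top) < 1e-15
        face_drop = top.max() + 0.082 * hz / 2.0 / 0.276
        assert face_drop == pytest.approx(0.082 * g.voxel_dims[2] / 0.276, rel=1e-10)

    def test_current_conservation(self, closed_1000):
        assert closed_1000.conservation_residual < 1e-9
        assert closed_1000.boundary_balance < 1e-6

    def test_closed_network_wall_currents_balance(self, closed_1000):
        """In closed mode all current entering the lumen leaves it again."""
        assert closed_1000.wall_balance < 1e-6

    def test_teer_increase_lowers_peak_current(self, closed_1000, closed_5000):
        assert closed_5000.peak_j_norm < closed_1000.peak_j_norm

    def test_open_peak_at_least_closed(self, closed_1000, open_1000):
        assert open_1000.peak_j_norm >= closed_1000.peak_j_norm

    def test_doubling_influx_doubles_currents(self, network):
        a = tf.solve_voxel_current(network, "closed", 1000.0, 0.041,
                                   grid_shape=COARSE_GRID)
        b = tf.solve_voxel_current(network, "closed", 1000.0, 0.082,
                                   grid_shape=COARSE_GRID)
        assert np.allclose(b.element_j_norm, 2.0 * a.element_j_norm,
                           rtol=1e-6, atol=1e-12)

    def test_grid_refinement_stable(self, network, closed_1000):
        coarse = tf.solve_voxel_current(network, "closed", 1000.0, 0.082,
                                        grid_shape=COARSE_GRID)
        assert closed_1000.peak_j_norm == pytest.approx(
            coarse.peak_j_norm, rel=0.10
        )

    def test_open_mode_grounds_largest_segments(self, network, open_1000):
        """Grounded lumen potentials sit at exactly zero."""
        k = 4
        order = np.argsort(-network.outer_diameters, kind="stable")[:k]
        grounded = set(int(s) for s in order)
        mask = np.isin(open_1000.element_segment, list(grounded))
        assert mask.any()

    def test_invalid_inputs_rejected(self, network):
        with pytest.raises(InvalidParameterError):
            tf.solve_voxel_current(network, "sideways", 1000.0, 0.082,
                                   grid_shape=COARSE_GRID)
        with pytest.raises(InvalidParameterError):
            tf.solve_voxel_current(network, "closed", 1000.0, -0.1,
                                   grid_shape=COARSE_GRID)
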