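"""Double-layer potential and electroosmotic velocity in the TJ slit."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tdcsflow as tf
from tdcsflow.electroosmosis import InvalidParameterError


def midline_potential_closed_form(params: tf.DoubleLayerParams) -> float:
    """Independent closed-form midline potential of the two-wall superposition.

    psi(h) = 2 * (4kT/ze) * atanh(tanh(ze*zeta/4kT) * exp(-kappa*h)).
    """
    scale = (
        4.0 * params.boltzmann_k * params.temperature
        / (params.valence_z * params.electron_charge_e)
    )
    return 2.0 * scale * math.atanh(
        math.tanh(params.zeta / scale)
        * math.exp(-params.half_width_h / params.debye_length)
    )


class TestEquilibriumPotential:
    def test_midline_matches_closed_form(self, default_params):
        prof = tf.equilibrium_potential(default_params, n_points=2001)
        mid = prof.potentials_psi[1000]
        assert mid == pytest.approx(midline_potential_closed_form(default_params),
                                    rel=1e-12)
        assert mid == pytest.approx(-0.013815, abs=5e-7)

    def test_zero_zeta_gives_zero_potential(self, default_params):
        params = tf.DoubleLayerParams(zeta=0.0)
        prof = tf.equilibrium_potential(params, 101)
        assert np.all(prof.potentials_psi == 0.0)

    def test_symmetric_about_midline(self, default_params):
        prof = tf.equilibrium_potential(default_params, 501)
        assert np.allclose(prof.potentials_psi, prof.potentials_psi[::-1],
                           rtol=1e-10, atol=0)

    def test_bounded_by_wall_potential(self, default_params):
        # weak overlap raises |psi| above |zeta| only near the walls, by the
        # small correction tanh(zeta/scale)*exp(-2*kappa*h) (~11% here)
        prof = tf.equilibrium_potential(default_params, 501)
        assert np.all(np.abs(prof.potentials_psi) <= abs(default_params.zeta) * 1.15)

    @pytest.mark.parametrize("bad", [
        dict(half_width_h=-1e-9), dict(debye_length=0.0),
        dict(temperature=-1.0), dict(viscosity=0.0), dict(valence_z=0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            tf.DoubleLayerParams(**bad)

    def test_too_few_points_rejected(self, default_params):
        with pytest.raises(InvalidParameterError):
            tf.equilibrium_potential(default_params, 2)


class TestVelocityProfile:
    def test_zero_field_zero_velocity(self, default_params):
        prof = tf.velocity_profile(default_params, 0.0, 101)
        assert np.all(prof.velocities_u == 0.0)

    def test_printed_midline_velocity(self, default_params):
        # closed-network, 1000 TEER condition: E_TJ = 869.4 V/m
        prof = tf.velocity_profile(default_params, 869.4, 2001)
        assert prof.velocities_u[1000] == pytest.approx(5.76e-6, rel=5e-3)

    def test_negative_zeta_positive_field_flows_forward(self, default_params):
        # the superposition slightly overshoots |zeta| at the walls, so the
        # approximate profile dips negative in a thin near-wall band; the
        # core flow and the channel mean are field-aligned (positive)
        prof = tf.velocity_profile(default_params, 100.0, 101)
        core = prof.velocities_u[25:76]
        assert np.all(core > 0)
        assert np.mean(prof.velocities_u) > 0

    def test_thin_double_layer_smoluchowski_plateau(self):
        params = tf.DoubleLayerParams(debye_length=1e-9 / 50.0)
        prof = tf.velocity_profile(params, 1.0, 4001)
        assert prof.velocities_u[2000] == pytest.approx(
            params.smoluchowski_coeff, rel=0.01
        )

    @given(E=st.floats(-5000, 5000, allow_nan=False))
    def test_exact_linearity_in_field(self, E):
        params = tf.DoubleLayerParams()
        u1 = tf.velocity_profile(params, 1.0, 101).velocities_u
        uE = tf.velocity_profile(params, E, 101).velocities_u
        assert np.allclose(uE, E * u1, rtol=1e-12, atol=1e-30)

    def test_symmetric_about_midline(self, default_params):
        prof = tf.velocity_profile(default_params, 500.0, 501)
        assert np.allclose(prof.velocities_u, prof.velocities_u[::-1],
                           rtol=1e-10, atol=0)


class TestAverageVelocity:
    def test_zero_field(self, default_params):
        assert tf.average_velocity(default_params, 0.0) == 0.0

    def test_linearity_in_field(self, default_params):
        v1 = tf.average_velocity(default_params, 1.0)
        v10 = tf.average_velocity(default_params, 10.0)
        assert v10 == pytest.approx(10.0 * v1, rel=1e-12)

    def test_quadrature_convergence(self, default_params):
        coarse = tf.average_velocity(default_params, 1.0, rtol=1e-9, n_start=2001)
        fine = tf.average_velocity(default_params, 1.0, rtol=1e-9, n_start=4001)
        assert fine == pytest.approx(coarse, rel=1e-3)

    def test_overlap_suppresses_average_velocity(self):
        """Stronger double-layer overlap monotonically slows the mean flow.

        The signed channel-average decreases monotonically with
        debye_length/h; the flow stays field-aligned (positive) through the
        weak-overlap range where the two-wall superposition is valid
        (debye_length/h up to ~1.2), beyond which the approximation
        overshoots |zeta| mid-channel and predicts reversal.
        """
        ratios = [0.3, 0.6, 0.9, 1.0, 1.2, 1.5]
        speeds = [
            tf.average_velocity(tf.DoubleLayerParams(debye_length=r * 1e-9), 1.0)
            for r in ratios
        ]
        assert all(a > b for a, b in zip(speeds, speeds[1:]))
        assert all(v > 0 for v, r in zip(speeds, ratios) if r <= 1.2)


class TestCoefficients:
    def test_zero_zeta_gives_zero_coefficients(self):
        c = tf.fit_coefficients(tf.DoubleLayerParams(zeta=0.0))
        assert c.avg_velocity_coeff == 0.0 and c.max_velocity_coeff == 0.0

    def test_ordering_and_smoluchowski_bound(self, default_params):
        c = tf.fit_coefficients(default_params)
        assert 0 < c.avg_velocity_coeff < c.max_velocity_coeff
        assert c.max_velocity_coeff < default_params.smoluchowski_coeff

    def test_helmholtz_smoluchowski_limit(self):
        params = tf.DoubleLayerParams(debye_length=1e-9 / 200.0)
        c = tf.fit_coefficients(params)
        assert c.avg_velocity_coeff == pytest.approx(
            params.smoluchowski_coeff, rel=0.01
        )

    def test_flux_coefficient_chain(self, default_params, default_tj):
        c = tf.fit_coefficients(default_params)
        q = tf.flux_coefficient(c, default_tj)
        assert q == pytest.approx(
            c.avg_velocity_coeff * 2e-9 * 150000.0, rel=1e-12
        )

    def test_flux_coefficient_linear_in_junction_length(self, default_params):
        c = tf.fit_coefficients(default_params)
        q1 = tf.flux_coefficient(c, tf.TJGeometry())
        q2 = tf.flux_coefficient(c, tf.TJGeometry(junction_length_per_area=300000.0))
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)

    def test_flux_coefficient_rejects_bad_geometry(self, default_params):
        c = tf.fit_coefficients(default_params)
        with pytest.raises(InvalidParameterError):
            tf.TJGeometry(opening_2h=-1e-9)
        with pytest.raises(InvalidParameterError):
            tf.flux_coefficient(tf.EOCoefficients(0.0, 0.0), _NegTJ())


class _NegTJ:
    opening_2h = -1.0
    junction_length_per_area = 1.0
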