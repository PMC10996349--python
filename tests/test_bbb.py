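"""Wall-current to TJ-field coupling: lookup constants and the reduced model."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

import tdcsflow as tf
from tdcsflow.electroosmosis import InvalidParameterError


class TestLookup:
    @pytest.mark.parametrize("teer, expected", [(1000.0, 2.73e6), (5000.0, 3.83e6)])
    def test_tabulated_constants(self, teer, expected):
        assert tf.coupling_constant(teer=teer).C == pytest.approx(expected)

    def test_unsupported_teer_lists_available(self):
        with pytest.raises(InvalidParameterError, match="1000"):
            tf.coupling_constant(teer=2000.0)


class TestReducedModel:
    @pytest.mark.parametrize("teer, printed", [(1000.0, 2.73e6), (5000.0, 3.83e6)])
    def test_within_30_percent_of_lookup(self, teer, printed):
        c = tf.coupling_constant(mode="model", teer=teer)
        assert abs(c.C - printed) / printed < 0.30

    def test_transcellular_shunting_lowers_coupling(self):
        base = tf.UltrastructureModel()
        leaky = dataclasses.replace(base, sigma_transcellular=1e-4)
        c_base = tf.coupling_constant(base, 5000.0, "model").C
        c_leaky = tf.coupling_constant(leaky, 5000.0, "model").C
        assert c_leaky < c_base

    def test_more_tight_junctions_raise_paracellular_fraction(self):
        base = tf.UltrastructureModel()
        multi = dataclasses.replace(base, n_tight_junctions=3)
        spec = tf.TEERSpec(1000.0)
        assert multi.paracellular_conductance(spec) == pytest.approx(
            3.0 * base.paracellular_conductance(spec), rel=1e-12
        )

    def test_works_at_untabulated_teer(self):
        c = tf.coupling_constant(mode="model", teer=2500.0)
        assert c.C > 0 and c.mode == "model"


class TestFieldFromCurrent:
    def test_printed_closed_1000_condition(self):
        c = tf.coupling_constant(teer=1000.0)
        assert tf.tj_field_from_wall_current(3.2e-4, c) == pytest.approx(
            869.4, rel=0.01
        )

    def test_printed_closed_5000_condition(self):
        c = tf.coupling_constant(teer=5000.0)
        assert tf.tj_field_from_wall_current(9.1e-5, c) == pytest.approx(
            348.3, rel=0.01
        )

    def test_zero_current_zero_field(self):
        c = tf.coupling_constant(teer=1000.0)
        assert tf.tj_field_from_wall_current(0.0, c) == 0.0

    @given(st.floats(-1e-2, 1e-2, allow_nan=False))
    def test_linear_and_odd(self, j):
        c = tf.coupling_constant(teer=1000.0)
        assert tf.tj_field_from_wall_current(-j, c) == pytest.approx(
            -tf.tj_field_from_wall_current(j, c), abs=1e-30
        )
        assert tf.tj_field_from_wall_current(2 * j, c) == pytest.approx(
            2 * tf.tj_field_from_wall_current(j, c), abs=1e-30
        )


def test_invalid_ultrastructure_rejected():
    with pytest.raises(InvalidParameterError):
        tf.UltrastructureModel(area_correction=0.5)
    with pytest.raises(InvalidParameterError):
        tf.UltrastructureModel(n_tight_junctions=0)
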