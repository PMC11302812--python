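"""Displacement-to-delay conversion and the beam-off matching algorithm."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatelag import (
    BeamGeometry,
    DelayMeasurement,
    InvalidInputError,
    SimScenario,
    beam_off_delay,
    beam_off_objective,
    beam_on_delay,
    delay_from_displacement,
    displacement_isocenter,
    render_pair,
    round2,
)

from conftest import PX_MS, off_pair, on_pair


class TestDisplacementIsocenter:
    def test_back_projection(self, geometry):
        # 11.408 mm at the detector = 7.130 mm at the isocenter (M = 1.6)
        assert displacement_isocenter(11.408, 0.0, geometry) == pytest.approx(7.130)

    def test_identity(self, geometry):
        assert displacement_isocenter(2.5, 2.5, geometry) == 0.0

    def test_sign_preserved(self, geometry):
        assert displacement_isocenter(0.0, 1.6, geometry) == pytest.approx(-1.0)


class TestDelayFromDisplacement:
    @pytest.mark.parametrize(
        "delta_x,velocity,expected",
        [(7.13, 24.0, 297.08), (7.41, 24.0, 308.75), (2.40, 24.0, 100.00)],
    )
    def test_table_values(self, delta_x, velocity, expected):
        assert round2(delay_from_displacement(delta_x, velocity)) == expected

    def test_zero_displacement(self):
        assert delay_from_displacement(0.0, 17.0) == 0.0

    def test_negative_displacement_not_clamped(self):
        assert delay_from_displacement(-2.4, 24.0) == pytest.approx(-100.0)

    def test_nonpositive_velocity_rejected(self):
        with pytest.raises(InvalidInputError):
            delay_from_displacement(1.0, 0.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        delta=st.floats(0.01, 20.0),
        v=st.floats(1.0, 100.0),
        k=st.floats(1.1, 10.0),
    )
    def test_inverse_velocity_scaling(self, delta, v, k):
        assert delay_from_displacement(delta, v * k) * k == pytest.approx(
            delay_from_displacement(delta, v)
        )


class TestDelayMeasurementInvariant:
    def test_inconsistent_delay_rejected(self):
        with pytest.raises(InvalidInputError):
            DelayMeasurement(delta_x=2.4, velocity=24.0, delay=90.0, phase="beam_on")

    def test_consistent_delay_accepted(self):
        m = DelayMeasurement(delta_x=2.4, velocity=24.0, delay=100.0, phase="beam_on")
        assert m.delay == pytest.approx(m.delta_x / m.velocity * 1000.0)


class TestBeamOnDelay:
    def test_motion_equals_reference_gives_zero(self, geometry):
        ref, _ = on_pair(0.0)
        assert beam_on_delay(ref, ref, geometry, 24.0).delay == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_within_pixel(self, geometry):
        ref, mot = on_pair(100.0)
        m = beam_on_delay(ref, mot, geometry, 24.0)
        assert m.delay == pytest.approx(100.0, abs=PX_MS)

    def test_linearity_in_true_delay(self, geometry):
        d1 = beam_on_delay(*on_pair(150.0), geometry, 24.0).delay
        d2 = beam_on_delay(*on_pair(300.0), geometry, 24.0).delay
        assert d2 == pytest.approx(2 * d1, abs=2 * PX_MS)

    def test_declared_velocity_rescales_delay(self, geometry):
        ref, mot = on_pair(200.0)
        d24 = beam_on_delay(ref, mot, geometry, 24.0).delay
        d48 = beam_on_delay(ref, mot, geometry, 48.0).delay
        assert d24 == pytest.approx(2 * d48)

    def test_five_noisy_repeats_recover_truth(self, geometry):
        delays = []
        for seed in range(5):
            ref, mot = on_pair(300.0, noise_sigma=160.0, seed=seed)
            delays.append(beam_on_delay(ref, mot, geometry, 24.0).delay)
        assert np.mean(delays) == pytest.approx(300.0, abs=10.0)
        assert np.std(delays, ddof=1) < 10.0

    def test_sid_extension_does_not_change_result(self):
        geom = BeamGeometry(sid=3200.0)
        ref, mot = render_pair(
            SimScenario(geometry=geom, true_delay=150.0, phase="beam_on")
        )
        m = beam_on_delay(ref, mot, geom, 24.0)
        # one detector pixel at M=3.2 is worth 0.34/3.2/24 s
        assert m.delay == pytest.approx(150.0, abs=0.34 / 3.2 / 24.0 * 1000.0)


class TestBeamOffDelay:
    def test_zero_delay_alignment(self, geometry):
        ref, trace = off_pair(0.0)
        m = beam_off_delay(ref, trace, geometry, 24.0)
        assert m.delay == pytest.approx(0.0, abs=0.5 * PX_MS)

    def test_catalyst_scale_round_trip(self, geometry):
        ref, trace = off_pair(97.69)
        m = beam_off_delay(ref, trace, geometry, 24.0)
        assert m.delay == pytest.approx(97.69, abs=PX_MS)

    def test_grid_matches_brute_force_argmin(self, geometry):
        # exhaustive 0.01 px brute force over the whole search range
        for delay in [60.0, 230.0]:
            ref, trace = off_pair(delay)
            obj, _ = beam_off_objective(ref, trace, geometry)
            step = 0.01 * geometry.pixel_pitch / geometry.magnification
            grid = np.arange(0.0, 15.0, step)
            brute = grid[int(np.argmin([obj(d) for d in grid]))]
            m = beam_off_delay(ref, trace, geometry, 24.0)
            assert abs(m.delta_x - brute) <= 0.05 * geometry.pixel_pitch / geometry.magnification

    def test_direction_flip_symmetry(self, geometry):
        kw = dict(noise_sigma=0.0, seed=0)
        ref_d, tr_d = off_pair(150.0, direction="descending", **kw)
        ref_a, tr_a = off_pair(150.0, direction="ascending", **kw)
        m_d = beam_off_delay(ref_d, tr_d, geometry, 24.0, direction="descending")
        m_a = beam_off_delay(ref_a, tr_a, geometry, 24.0, direction="ascending")
        assert m_a.delay == pytest.approx(m_d.delay, abs=0.5 * PX_MS)

    def test_search_range_exhausted_raises(self, geometry):
        from gatelag import SearchRangeError

        ref, trace = off_pair(300.0)  # 7.2 mm displacement
        with pytest.raises(SearchRangeError):
            beam_off_delay(ref, trace, geometry, 24.0, search=(0.0, 3.0))
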