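"""Synthetic portal-image renderer: geometry, determinism, trace shape."""

import numpy as np
import pytest

from gatelag import (
    BallSpec,
    BeamGeometry,
    GeometryError,
    SimScenario,
    extract_profile,
    locate_ball_center,
    locate_trace_edges,
    render_beam_off_trace,
    render_beam_on_snapshot,
    render_reference,
)

from conftest import com_oracle_px, true_center_px


class TestRenderReference:
    def test_centered_ball_centroid_at_image_center(self):
        img = render_reference(SimScenario(reference_position=0.0))
        n = img.pixels.shape[1]
        assert com_oracle_px(img) == pytest.approx((n - 1) / 2, abs=1e-6)

    def test_magnified_offset_in_pixels(self):
        # 2 mm at isocenter, M=1.6, pitch 0.34 -> 9.412 px from center
        img0 = render_reference(SimScenario(reference_position=0.0))
        img2 = render_reference(SimScenario(reference_position=2.0))
        offset = com_oracle_px(img2) - com_oracle_px(img0)
        assert offset == pytest.approx(2.0 * 1.6 / 0.34, abs=0.05)

    def test_seeded_determinism(self):
        a = render_reference(SimScenario(noise_sigma=50.0, seed=11))
        b = render_reference(SimScenario(noise_sigma=50.0, seed=11))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_footprint_outside_image_raises(self):
        with pytest.raises(GeometryError):
            render_reference(SimScenario(reference_position=60.0))

    def test_flux_conservation_across_positions(self):
        # total attenuated flux of a noise-free snapshot is position-independent
        ball = BallSpec()
        totals = []
        for pos in [0.0, 0.13, -2.7, 5.05]:
            img = render_reference(SimScenario(reference_position=pos))
            totals.append(np.sum(ball.background_level - img.pixels))
        assert np.ptp(totals) / np.mean(totals) < 1e-3


class TestRenderSnapshot:
    def test_zero_delay_identical_to_reference(self):
        sc = SimScenario(true_delay=0.0, phase="beam_on")
        np.testing.assert_array_equal(
            render_beam_on_snapshot(sc).pixels, render_reference(sc).pixels
        )

    def test_delay_displacement_at_detector(self):
        # 100 ms at 24 mm/s, M=1.6 -> 3.84 mm at the detector plane
        sc = SimScenario(true_delay=100.0, phase="beam_on")
        ref = render_reference(sc)
        mot = render_beam_on_snapshot(sc)
        shift_mm = (com_oracle_px(mot) - com_oracle_px(ref)) * 0.34
        assert abs(shift_mm) == pytest.approx(3.84, abs=0.02)

    def test_reference_scale_displacement(self):
        # 297.08 ms at 24 mm/s -> 7.13 mm at the isocenter plane
        sc = SimScenario(true_delay=297.08, phase="beam_on")
        mot = render_beam_on_snapshot(sc)
        det = locate_ball_center(mot)
        assert abs(det.center) / 1.6 == pytest.approx(7.13, abs=0.01)


class TestRenderTrace:
    def test_trace_extent_geometry(self):
        # extent = (diameter + v * duration) * M, within 1 px
        sc = SimScenario(true_delay=100.0, phase="beam_off", beam_duration=0.8)
        lead, stop = locate_trace_edges(render_beam_off_trace(sc), "descending")
        expected = (6.0 + 24.0 * 0.8) * 1.6
        assert abs(lead - stop) == pytest.approx(expected, abs=0.34)

    def test_zero_delay_stop_edge_matches_reference_edge(self):
        sc = SimScenario(true_delay=0.0, phase="beam_off")
        _, stop = locate_trace_edges(render_beam_off_trace(sc), "descending")
        # reference ball's stop-side (descending: low-position) edge
        ref = render_reference(sc)
        prof = extract_profile(ref, band_halfwidth=2)
        attn = np.median(prof.intensities) - prof.intensities
        above = np.flatnonzero(attn >= 0.5 * attn.max())
        i = above[0]
        level = 0.5 * attn.max()
        frac = (level - attn[i - 1]) / (attn[i] - attn[i - 1])
        ref_edge = prof.positions[i - 1] + frac * 0.34
        assert stop == pytest.approx(ref_edge, abs=0.5 * 0.34)

    def test_reference_scale_stop_position(self):
        # 97.69 ms at 24 mm/s -> stop 2.344 mm past the beam-off reference
        sc = SimScenario(true_delay=97.69, phase="beam_off")
        _, stop = locate_trace_edges(render_beam_off_trace(sc), "descending")
        radius_det = 3.0 * 1.6
        stop_center_iso = (stop + radius_det) / 1.6  # descending: edge below center
        assert stop_center_iso == pytest.approx(-2.344, abs=0.2)

    def test_stop_edge_profile_matches_static_ball_after_shift(self):
        # constant-intensity segment: trace stop edge == shifted static edge
        shift_px = 10  # exact integer-pixel displacement
        delay = 10 * 0.34 / 1.6 / 24.0 * 1000.0
        sc = SimScenario(true_delay=delay, phase="beam_off")
        trace = render_beam_off_trace(sc)
        ref = render_reference(sc)
        band = 13
        p_t = extract_profile(trace, band_halfwidth=band)
        p_r = extract_profile(ref, band_halfwidth=band)
        attn_t = np.median(p_t.intensities) - p_t.intensities
        attn_r = np.median(p_r.intensities) - p_r.intensities
        attn_t /= attn_t.max()
        attn_r /= attn_r.max()
        # stop center sits shift_px below the reference center (descending)
        c_ref = int(np.argmax(attn_r))
        c_stop = c_ref - shift_px
        # compare the stop-side halves (1 px in from the plateau boundary)
        width = 20
        seg_t = attn_t[c_stop - width : c_stop - 1]
        seg_r = attn_r[c_ref - width : c_ref - 1]
        assert np.max(np.abs(seg_t - seg_r)) < 0.01

    def test_doubling_sid_doubles_detector_displacement(self):
        for sid, expect in [(1600.0, 1.6), (3200.0, 3.2)]:
            geom = BeamGeometry(sid=sid)
            sc = SimScenario(geometry=geom, true_delay=100.0, phase="beam_on")
            shift = (
                com_oracle_px(render_beam_on_snapshot(sc))
                - com_oracle_px(render_reference(sc))
            ) * 0.34
            assert abs(shift) == pytest.approx(2.4 * expect, abs=0.02)

    def test_ramp_blurs_stop_edge(self):
        sharp = render_beam_off_trace(SimScenario(true_delay=100.0, phase="beam_off"))
        soft = render_beam_off_trace(
            SimScenario(true_delay=100.0, phase="beam_off", ramp_time=80.0)
        )
        # ramp-down removes attenuated flux near the stop edge
        assert soft.pixels.sum() > sharp.pixels.sum()

    def test_too_short_travel_rejected(self):
        with pytest.raises(Exception):
            SimScenario(phase="beam_off", beam_duration=0.1, velocity=24.0)


def test_snapshot_centroid_tracks_subpixel_truth():
    for frac in [0.0, 0.25, 0.5, 0.75]:
        pos = frac * 0.34 / 1.6
        img = render_reference(SimScenario(reference_position=pos))
        assert com_oracle_px(img) == pytest.approx(
            true_center_px(img, pos), abs=0.05
        )
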