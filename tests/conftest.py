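import numpy as np
import pytest

from gatelag import BallSpec, BeamGeometry, SimScenario, render_pair

# detector-pixel equivalent delay at v=24 mm/s, M=1.6, pitch 0.34 mm
PX_MS = 0.34 / 1.6 / 24.0 * 1000.0  # 8.854 ms
DEPTH = BallSpec().contrast * BallSpec().background_level  # attenuation depth, counts


@pytest.fixture(scope="session")
def geometry() -> BeamGeometry:
    return BeamGeometry()


def on_pair(true_delay, noise_sigma=0.0, seed=0, **kw):
    """(reference, snapshot) pair for a beam-on scenario."""
    return render_pair(
        SimScenario(true_delay=true_delay, phase="beam_on",
                    noise_sigma=noise_sigma, seed=seed, **kw)
    )


def off_pair(true_delay, noise_sigma=0.0, seed=0, **kw):
    """(reference, trace) pair for a beam-off scenario."""
    return render_pair(
        SimScenario(true_delay=true_delay, phase="beam_off",
                    noise_sigma=noise_sigma, seed=seed, **kw)
    )


def true_center_px(image, pos_iso_mm, geometry=BeamGeometry()):
    return image.mm_to_px(pos_iso_mm * geometry.magnification)


def com_oracle_px(image):
    """Independent oracle: exhaustive 2-D thresholded center of mass.

    Works directly on the full 2-D attenuation image (no band averaging,
    no profile or run analysis): attenuation-weighted centroid over the
    columns whose pixels reach 50% of the maximum depth, padded by 3
    columns so the antialiased edge tails contribute.
    """
    attn = np.median(image.pixels) - image.pixels
    cols_above = np.flatnonzero((attn >= 0.5 * attn.max()).any(axis=0))
    lo = max(cols_above[0] - 3, 0)
    hi = min(cols_above[-1] + 3, attn.shape[1] - 1)
    w = np.clip(attn[:, lo : hi + 1], 0.0, None)
    cols = np.arange(lo, hi + 1, dtype=float)
    return float(w.sum(axis=0) @ cols / w.sum())
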