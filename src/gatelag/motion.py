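"""Phantom motion model: waveform velocity fit and gate-window geometry.

The motion phantom traverses the gating window at (nominally) constant
speed.  The traversal velocity is estimated by an ordinary least-squares
line through (time, position) samples restricted to an explicit time
window; the window must be chosen by the operator to cover the linear
segment of the breathing waveform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InvalidInputError

Direction = Literal["descending", "ascending"]


def direction_sign(direction: Direction) -> float:
    """Sign of the phantom velocity on the position axis.

    ``descending`` means positions decrease with time (e.g. 20 mm -> 0 mm),
    hence sign -1; ``ascending`` is +1.
    """
    if direction == "descending":
        return -1.0
    if direction == "ascending":
        return 1.0
    raise InvalidInputError(f"direction must be 'descending' or 'ascending', got {direction!r}")


@dataclass(frozen=True)
class VelocityFit:
    """Result of the constant-velocity least-squares fit.

    ``speed`` is the absolute slope in mm/s; ``signed_slope`` keeps the
    direction; ``r_squared`` is the coefficient of determination and
    ``p_value`` the two-sided t-test on the slope (n-2 degrees of freedom).
    """

    speed: float
    signed_slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


@dataclass(frozen=True)
class GateConfig:
    """Gating window: a position band of ``center +/- halfwidth`` mm.

    ``direction`` declares which way the phantom moves through the window;
    it determines which band edge is the beam-on reference (entry) and
    which is the beam-off reference (exit).
    """

    center: float
    halfwidth: float = 1.0
    direction: Direction = "descending"

    def __post_init__(self) -> None:
        if self.halfwidth < 0:
            raise InvalidInputError(f"halfwidth must be >= 0, got {self.halfwidth}")
        direction_sign(self.direction)  # validates


def _as_time_position(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, pd.DataFrame):
        t = samples["time_s"].to_numpy(dtype=float)
        p = samples["position_mm"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(samples) if isinstance(samples, Iterable) else samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidInputError("samples must be (time, position) pairs")
        t, p = arr[:, 0], arr[:, 1]
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
        raise InvalidInputError("waveform samples must be finite")
    return t, p


def fit_velocity(samples, window: tuple[float, float] | None = None) -> VelocityFit:
    """Least-squares constant-velocity fit over an explicit time window.

    Parameters
    ----------
    samples : DataFrame with ``time_s``/``position_mm`` columns, or a
        sequence of (time_s, position_mm) pairs.
    window : (t_min, t_max) or None
        Inclusive time interval to fit over; None uses all samples.

    Returns
    -------
    VelocityFit
    """
    t, p = _as_time_position(samples)
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, p = t[mask], p[mask]
    n = t.size
    if n < 2:
        raise InvalidInputError(f"need >= 2 samples inside the window, got {n}")
    if np.ptp(t) == 0:
        raise DegenerateFitError("zero time variance: cannot fit a velocity")
    res = stats.linregress(t, p)
    r2 = float(res.rvalue**2)
    if n == 2:
        # zero residual degrees of freedom: the two-point line is exact
        p_value = 0.0
    else:
        p_value = float(res.pvalue)
    slope = float(res.slope)
    return VelocityFit(
        speed=abs(slope),
        signed_slope=slope,
        intercept=float(res.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        p_value=p_value,
        n_points=int(n),
    )


def gate_reference_positions(gate: GateConfig) -> tuple[float, float]:
    """Reference positions (beam_on_ref, beam_off_ref) for a gate window.

    The beam turns on when the phantom enters the window and off when it
    leaves, so for descending motion the entry edge is ``center + halfwidth``
    and the exit edge ``center - halfwidth``; mirrored for ascending motion.
    """
    s = direction_sign(gate.direction)
    beam_on_ref = gate.center - s * gate.halfwidth
    beam_off_ref = gate.center + s * gate.halfwidth
    return beam_on_ref, beam_off_ref


def read_waveform(path: str | Path) -> pd.DataFrame:
    """Read a waveform CSV with header columns ``time_s,position_mm``."""
    df = pd.read_csv(path)
    required = {"time_s", "position_mm"}
    if not required.issubset(df.columns):
        raise InvalidInputError(
            f"{path}: waveform CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError(f"{path}: time_s must be strictly increasing")
    if not np.all(np.isfinite(df["position_mm"].to_numpy(dtype=float))):
        raise InvalidInputError(f"{path}: positions must be finite")
    return df[["time_s", "position_mm"]]
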