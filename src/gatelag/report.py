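"""Aggregation of repeat measurements and QA report output.

Two distinct standard-deviation conventions are used deliberately:

* within a beam mode, the SD over the (typically five) repeats is the
  *sample* standard deviation (divisor n - 1), the usual choice for
  repeated measurements of one quantity;
* across beam modes, the system-level spread is the *population*
  standard deviation (divisor N) of the per-mode mean delays — the modes
  measured are the modes of interest, not a sample from a larger pool.

Both conventions are recorded in the report metadata.  Printed values
are rounded half-up to 2 decimals (ms and mm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .delay import DelayMeasurement
from .errors import InvalidInputError

REPORT_COLUMNS = [
    "system",
    "phase",
    "beam_mode",
    "n_repeats",
    "mdd_mm",
    "mean_delay_ms",
    "sd_ms",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (matches table/abstract formatting)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BeamModeResult:
    """Aggregated repeats for one beam mode (energy + dose rate).

    ``mdd`` is the mean distance discrepancy: the average displacement
    delta_x (mm, isocenter plane) over the repeats.  ``sd`` is the sample
    standard deviation of the per-repeat delays.
    """

    beam_mode: str
    phase: Literal["beam_on", "beam_off"]
    mdd: float
    mean_delay: float
    sd: float
    n_repeats: int
    velocity: float = 24.0


@dataclass(frozen=True)
class SystemSummary:
    """Cross-energy summary for one gating system and phase.

    ``mean`` and ``sd`` (population divisor over per-mode mean delays)
    are rounded to 2 decimals for display.
    """

    system: str
    phase: Literal["beam_on", "beam_off"]
    mean: float
    sd: float
    modes_included: tuple[str, ...]


@dataclass(frozen=True)
class ToleranceCheck:
    """TG-142-style action-level check: pass iff measured <= threshold."""

    threshold: float
    measured: float
    passed: bool


def aggregate_repeats(measurements: Sequence[DelayMeasurement]) -> BeamModeResult:
    """Aggregate repeated measurements of one beam mode.

    All measurements must share beam mode, phase, and velocity.  With a
    single repeat the SD is 0 and a warning is emitted.
    """
    if len(measurements) == 0:
        raise InvalidInputError("no measurements to aggregate")
    modes = {m.beam_mode for m in measurements}
    phases = {m.phase for m in measurements}
    velocities = {m.velocity for m in measurements}
    if len(modes) > 1 or len(phases) > 1 or len(velocities) > 1:
        raise InvalidInputError(
            f"mixed inputs: beam_modes={modes}, phases={phases}, velocities={velocities}"
        )
    delays = np.array([m.delay for m in measurements])
    deltas = np.array([m.delta_x for m in measurements])
    if len(measurements) == 1:
        warnings.warn("single repeat: SD reported as 0", UserWarning, stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(delays, ddof=1))
    return BeamModeResult(
        beam_mode=measurements[0].beam_mode,
        phase=measurements[0].phase,
        mdd=float(deltas.mean()),
        mean_delay=float(delays.mean()),
        sd=sd,
        n_repeats=len(measurements),
        velocity=measurements[0].velocity,
    )


def summarize_system(
    results: Sequence[BeamModeResult],
    system: str = "",
    ddof: int = 0,
) -> SystemSummary:
    """Cross-energy mean +/- SD over per-mode mean delays.

    ``ddof=0`` (population SD, the default) is the convention used for
    system-level summaries; both outputs are rounded to 2 decimals.
    """
    if len(results) == 0:
        raise InvalidInputError("no per-mode results to summarize")
    phases = {r.phase for r in results}
    if len(phases) > 1:
        raise InvalidInputError(f"mixed phases in summary: {phases}")
    means = np.array([r.mean_delay for r in results])
    return SystemSummary(
        system=system,
        phase=results[0].phase,
        mean=round2(float(means.mean())),
        sd=round2(float(np.std(means, ddof=ddof))),
        modes_included=tuple(r.beam_mode for r in results),
    )


def check_tolerance(summary: SystemSummary, threshold: float) -> ToleranceCheck:
    """Action-level check of the system mean delay against a configured threshold."""
    if not threshold > 0:
        raise InvalidInputError(f"threshold must be positive, got {threshold}")
    return ToleranceCheck(
        threshold=float(threshold),
        measured=summary.mean,
        passed=summary.mean <= threshold,
    )


def results_frame(results: Iterable[BeamModeResult], system: str = "") -> pd.DataFrame:
    """Tabulate per-mode results at printed precision (2 decimals)."""
    rows = [
        {
            "system": system,
            "phase": r.phase,
            "beam_mode": r.beam_mode,
            "n_repeats": r.n_repeats,
            "mdd_mm": round2(r.mdd),
            "mean_delay_ms": round2(r.mean_delay),
            "sd_ms": round2(r.sd),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report_csv(
    results: Iterable[BeamModeResult], path: str | Path, system: str = ""
) -> Path:
    path = Path(path)
    results_frame(results, system).to_csv(path, index=False, float_format="%.2f")
    return path


def read_report_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: report CSV missing columns {sorted(missing)}")
    return df


def write_summary_json(
    summary: SystemSummary,
    path: str | Path,
    tolerance: ToleranceCheck | None = None,
) -> Path:
    path = Path(path)
    payload = {
        "system": summary.system,
        "phase": summary.phase,
        "mean_ms": summary.mean,
        "sd_ms": summary.sd,
        "modes_included": list(summary.modes_included),
        "conventions": {
            "within_mode_sd": "sample (n-1)",
            "cross_energy_sd": "population (N)",
        },
    }
    if tolerance is not None:
        payload["tolerance"] = {
            "threshold_ms": tolerance.threshold,
            "pass": tolerance.passed,
        }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def measurement_record(measurement: DelayMeasurement, system: str = "") -> dict:
    """JSON-serializable per-repeat record (raw delays are retained for audit)."""
    rec = asdict(measurement)
    rec["system"] = system
    return rec
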