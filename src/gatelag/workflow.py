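"""Manifest-driven end-to-end analysis: detection -> delay -> report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .delay import DelayMeasurement, beam_off_delay, beam_on_delay
from .errors import GatelagError, InvalidInputError
from .images import read_image
from .report import (
    BeamModeResult,
    aggregate_repeats,
    check_tolerance,
    measurement_record,
    summarize_system,
    write_report_csv,
    write_summary_json,
)

logger = logging.getLogger("gatelag")

MANIFEST_COLUMNS = {"path", "role", "beam_mode", "repeat"}
_ROLES = {"reference", "motion", "trace"}


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"beam_mode": str})
    missing = MANIFEST_COLUMNS - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: manifest missing columns {sorted(missing)}")
    bad = set(df["role"]) - _ROLES
    if bad:
        raise InvalidInputError(f"{path}: unknown roles {sorted(bad)}")
    df["beam_mode"] = df["beam_mode"].fillna("")
    return df


def _load(path: str, config: RunConfig):
    return read_image(path, pixel_pitch=config.geometry.pixel_pitch)


def run_end_to_end(
    manifest_path: str | Path,
    config: RunConfig,
    out_dir: str | Path,
    tolerance_ms: float | None = None,
) -> dict:
    """Execute detection, delay conversion, aggregation, and reporting.

    The manifest CSV lists images with columns ``path,role,beam_mode,repeat``
    (roles: reference / motion / trace; paths relative to the manifest).
    Per-file failures are logged and the file skipped as long as at least
    one repeat of the mode survives; otherwise the run fails.

    Returns a dict with the per-mode results, summaries, and output paths.
    """
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = read_manifest(manifest_path)
    base = manifest_path.parent

    def resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    refs = df[df["role"] == "reference"]
    mode_results: list[BeamModeResult] = []
    records: list[dict] = []
    results_by_phase: dict[str, list[BeamModeResult]] = {}

    for beam_mode, group in df[df["role"] != "reference"].groupby("beam_mode", sort=True):
        ref_rows = refs[refs["beam_mode"].isin([beam_mode, ""])]
        if ref_rows.empty:
            raise InvalidInputError(f"no reference image for beam mode {beam_mode!r}")
        reference = _load(str(resolve(ref_rows.iloc[0]["path"])), config)
        for role, phase in (("motion", "beam_on"), ("trace", "beam_off")):
            rows = group[group["role"] == role]
            if rows.empty:
                continue
            measurements: list[DelayMeasurement] = []
            for _, row in rows.sort_values("repeat").iterrows():
                img_path = resolve(row["path"])
                try:
                    image = _load(str(img_path), config)
                    if phase == "beam_on":
                        m = beam_on_delay(
                            reference,
                            image,
                            config.geometry,
                            config.velocity,
                            config.gate.direction,
                            repeat_index=int(row["repeat"]),
                            beam_mode=str(beam_mode),
                        )
                    else:
                        m = beam_off_delay(
                            reference,
                            image,
                            config.geometry,
                            config.velocity,
                            config.gate.direction,
                            repeat_index=int(row["repeat"]),
                            beam_mode=str(beam_mode),
                        )
                except (GatelagError, OSError, ValueError, RuntimeError) as exc:
                    logger.warning("skipping %s: %s", img_path, exc)
                    continue
                logger.info(
                    "%s %s repeat %d: delta_x=%.3f mm delay=%.2f ms",
                    beam_mode, phase, m.repeat_index, m.delta_x, m.delay,
                )
                measurements.append(m)
                records.append(measurement_record(m, config.system_label))
            if not measurements:
                raise InvalidInputError(
                    f"all repeats failed for beam mode {beam_mode!r} ({phase})"
                )
            result = aggregate_repeats(measurements)
            mode_results.append(result)
            results_by_phase.setdefault(phase, []).append(result)

    if not mode_results:
        raise InvalidInputError("manifest contains no motion or trace images")

    outputs: dict = {"results": mode_results, "summaries": {}, "paths": {}}
    report_path = write_report_csv(mode_results, out_dir / "report.csv", config.system_label)
    outputs["paths"]["report_csv"] = report_path
    (out_dir / "measurements.json").write_text(json.dumps(records, indent=2) + "\n")
    outputs["paths"]["measurements_json"] = out_dir / "measurements.json"

    for phase, results in results_by_phase.items():
        summary = summarize_system(results, system=config.system_label)
        tol = check_tolerance(summary, tolerance_ms) if tolerance_ms else None
        spath = out_dir / f"summary_{phase}.json"
        write_summary_json(summary, spath, tol)
        outputs["summaries"][phase] = summary
        outputs["paths"][f"summary_{phase}"] = spath
    return outputs
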