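"""Run configuration: TOML loading with strict key validation."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .geometry import BeamGeometry
from .errors import InvalidInputError
from .motion import GateConfig

_GEOMETRY_KEYS = {"sad_mm", "sid_mm", "pixel_pitch_mm", "rows", "cols"}
_GATE_KEYS = {"center_mm", "halfwidth_mm", "direction"}
_TOP_KEYS = {
    "velocity_mm_s",
    "system_label",
    "beam_mode",
    "seed",
    "log_level",
    "geometry",
    "gate",
}
_LOG_LEVELS = {"DEBUG", "INFO", "WARNING", "ERROR"}


@dataclass(frozen=True)
class RunConfig:
    """Validated, defaulted run configuration."""

    geometry: BeamGeometry = field(default_factory=BeamGeometry)
    gate: GateConfig = field(default_factory=lambda: GateConfig(center=1.0))
    velocity: float = 24.0
    system_label: str = ""
    beam_mode: str = ""
    seed: int | None = None
    log_level: str = "INFO"


def _check_unknown(mapping: dict, allowed: set[str], prefix: str = "") -> None:
    for key in mapping:
        if key not in allowed:
            path = f"{prefix}{key}"
            raise ConfigError(f"unknown config key: {path}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a TOML config; missing keys take defaults.

    Defaults: SAD 1000 mm, SID 1600 mm, pixel pitch 0.34 mm, gate
    halfwidth 1.0 mm, velocity 24 mm/s.  Unknown keys raise
    :class:`ConfigError` naming the offending key path.
    """
    if path is None:
        data: dict = {}
    else:
        path = Path(path)
        if not path.is_file():
            raise ConfigError(f"config file not found: {path}")
        try:
            data = tomllib.loads(path.read_text())
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: invalid TOML: {exc}") from exc

    _check_unknown(data, _TOP_KEYS)
    geo = data.get("geometry", {})
    gate = data.get("gate", {})
    if not isinstance(geo, dict):
        raise ConfigError("geometry: expected a table")
    if not isinstance(gate, dict):
        raise ConfigError("gate: expected a table")
    _check_unknown(geo, _GEOMETRY_KEYS, "geometry.")
    _check_unknown(gate, _GATE_KEYS, "gate.")

    try:
        geometry = BeamGeometry(
            sad=float(geo.get("sad_mm", 1000.0)),
            sid=float(geo.get("sid_mm", 1600.0)),
            pixel_pitch=float(geo.get("pixel_pitch_mm", 0.34)),
            image_shape=(int(geo.get("rows", 192)), int(geo.get("cols", 512))),
        )
        gate_cfg = GateConfig(
            center=float(gate.get("center_mm", 1.0)),
            halfwidth=float(gate.get("halfwidth_mm", 1.0)),
            direction=gate.get("direction", "descending"),
        )
    except InvalidInputError as exc:
        raise ConfigError(str(exc)) from exc

    velocity = float(data.get("velocity_mm_s", 24.0))
    if not velocity > 0:
        raise ConfigError(f"velocity_mm_s must be positive, got {velocity}")
    log_level = str(data.get("log_level", "INFO")).upper()
    if log_level not in _LOG_LEVELS:
        raise ConfigError(f"log_level must be one of {sorted(_LOG_LEVELS)}")
    seed = data.get("seed")
    if seed is not None:
        seed = int(seed)

    return RunConfig(
        geometry=geometry,
        gate=gate_cfg,
        velocity=velocity,
        system_label=str(data.get("system_label", "")),
        beam_mode=str(data.get("beam_mode", "")),
        seed=seed,
        log_level=log_level,
    )
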