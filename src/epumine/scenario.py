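"""Declarative description of a synthetic single-particle acquisition session.

A :class:`Scenario` enumerates everything a session encodes — instrument
and optics configuration, targeting strategy (squares / foil holes /
shots per hole), acquisition timing, dose fractionation, and the
ground-truth distributions behind the preprocessing results (particle
diameter, pick counts and scores, clustering level, motion profile, CTF
and 2D-class resolutions).  The synthetic generator consumes a Scenario;
the parsers and metrics are later expected to recover its fields.
"""

from __future__ import annotations

import ast
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Tuple

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class PresetSpec(BaseModel):
    """Optical configuration of one magnification preset."""

    model_config = ConfigDict(frozen=True)

    preset_name: str  # atlas | gridsquare | hole | acquisition
    magnification: float = Field(gt=0)
    pixel_size: float = Field(gt=0, description="Å per pixel")
    spot_size: int = 5
    c2_aperture: float = Field(50.0, gt=0, description="µm")
    objective_aperture: float = Field(100.0, gt=0, description="µm")
    beam_diameter: float = Field(1.1, gt=0, description="µm")
    defocus_min: float = -1.0  # µm, signed; negative = underfocus
    defocus_max: float = -3.0
    sensor_pixels: Tuple[int, int] = (5760, 4092)

    @field_validator("preset_name")
    @classmethod
    def _known_preset(cls, v: str) -> str:
        allowed = {"atlas", "gridsquare", "hole", "acquisition"}
        if v not in allowed:
            raise ValueError(f"preset_name must be one of {sorted(allowed)}, got {v!r}")
        return v

    @field_validator("sensor_pixels")
    @classmethod
    def _positive_sensor(cls, v):
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("sensor_pixels must be positive")
        return v


class Scenario(BaseModel):
    """Full description of one synthetic session and its ground truth."""

    model_config = ConfigDict(frozen=True)

    instrument_id: str = "TITAN00000000"
    epu_version: str = "3.0.0"
    session_id: str = "bi00000-1"
    acceleration_voltage: float = Field(300000.0, gt=0, description="volts")
    presets: Tuple[PresetSpec, ...] = ()
    grid_type: str = "HoleyCarbon"
    hole_diameter: float = Field(1.2, gt=0, description="µm")
    hole_spacing: float = Field(1.3, gt=0, description="µm")
    collection_mode: str = "AFIS"
    shots_per_hole: int = Field(2, ge=1)
    n_squares_available: int = Field(62, ge=0)
    n_squares_collected: int = Field(3, ge=0)
    foils_per_square: Tuple[int, ...] = (140, 140, 140)
    n_micrographs: int = Field(254, ge=0)
    acquisition_start: datetime = datetime(2023, 6, 1, 9, 0, 0, tzinfo=timezone.utc)
    acquisition_interval: float = Field(10.0, gt=0, description="seconds")
    fraction_dose: float = Field(0.6, gt=0, description="e⁻ Å⁻² per frame")
    n_frames: int = Field(58, ge=1)
    particle_diameter_true: float = Field(136.0, gt=0, description="Å")
    picks_per_micrograph: Tuple[float, float] = (100.0, 10.0)  # mean, sd
    pick_score: Tuple[float, float] = (0.85, 0.08)  # mean, sd, clipped to [0,1]
    clustered_fraction_true: float = Field(0.2, ge=0.0, le=1.0)
    shot_density_factors: Optional[Tuple[float, ...]] = None
    motion_profile: Tuple[float, ...] = ()  # per-frame drift magnitudes, Å
    ctf_resolution: Tuple[float, float] = (3.8, 0.4)  # mean, sd, Å
    n_2d_classes: int = Field(20, ge=1)
    class_resolution_range: Tuple[float, float] = (7.0, 15.0)  # Å
    seed: int = 0

    @model_validator(mode="after")
    def _check_invariants(self) -> "Scenario":
        if self.n_squares_collected > self.n_squares_available:
            raise ValueError("n_squares_collected exceeds n_squares_available")
        if len(self.foils_per_square) != self.n_squares_collected:
            raise ValueError(
                "foils_per_square must list one count per collected square "
                f"({len(self.foils_per_square)} != {self.n_squares_collected})"
            )
        capacity = sum(f * self.shots_per_hole for f in self.foils_per_square)
        if self.n_micrographs > capacity:
            raise ValueError(
                f"n_micrographs={self.n_micrographs} exceeds targeting capacity "
                f"{capacity} (foil holes × shots_per_hole)"
            )
        if any(f <= 0 for f in self.foils_per_square):
            raise ValueError("foils_per_square entries must be positive")
        if self.shot_density_factors is not None:
            if len(self.shot_density_factors) != self.shots_per_hole:
                raise ValueError("shot_density_factors must have one entry per shot")
            if any(f <= 0 for f in self.shot_density_factors):
                raise ValueError("shot_density_factors must be positive")
        lo, hi = self.class_resolution_range
        if not (0 < lo <= hi):
            raise ValueError("class_resolution_range must satisfy 0 < min <= max")
        if any(m < 0 for m in self.motion_profile):
            raise ValueError("motion_profile drift magnitudes must be non-negative")
        return self

    @property
    def acquisition_preset(self) -> PresetSpec:
        for p in self.presets:
            if p.preset_name == "acquisition":
                return p
        raise ValueError("scenario has no acquisition preset")

    @property
    def total_dose(self) -> float:
        return self.n_frames * self.fraction_dose

    def effective_motion_profile(self) -> Tuple[float, ...]:
        """Per-frame drift magnitudes, defaulting to a decaying profile."""
        if self.motion_profile:
            if len(self.motion_profile) != self.n_frames:
                raise ValueError("motion_profile length must equal n_frames")
            return self.motion_profile
        # Beam-induced motion is fastest at the start of the exposure.
        return tuple(3.0 / (1.0 + 0.35 * i) for i in range(self.n_frames))


def default_presets(
    magnification: float = 81000.0,
    pixel_size: float = 2.3,
    sensor_pixels: Tuple[int, int] = (5760, 4092),
    defocus_min: float = -1.0,
    defocus_max: float = -3.0,
    beam_diameter: float = 1.1,
    spot_size: int = 5,
    c2_aperture: float = 50.0,
    objective_aperture: float = 100.0,
) -> Tuple[PresetSpec, ...]:
    """The four-level preset ladder of a typical Krios AFIS session.

    Low-magnification presets are fixed at representative values; the
    acquisition preset carries the caller's optics.
    """
    common = dict(
        spot_size=spot_size,
        c2_aperture=c2_aperture,
        objective_aperture=objective_aperture,
        sensor_pixels=sensor_pixels,
    )
    return (
        PresetSpec(preset_name="atlas", magnification=64.0, pixel_size=6500.0,
                   beam_diameter=1000.0, defocus_min=-100.0, defocus_max=-100.0, **common),
        PresetSpec(preset_name="gridsquare", magnification=800.0, pixel_size=500.0,
                   beam_diameter=120.0, defocus_min=-50.0, defocus_max=-50.0, **common),
        PresetSpec(preset_name="hole", magnification=6500.0, pixel_size=60.0,
                   beam_diameter=10.0, defocus_min=-10.0, defocus_max=-10.0, **common),
        PresetSpec(preset_name="acquisition", magnification=magnification,
                   pixel_size=pixel_size, beam_diameter=beam_diameter,
                   defocus_min=defocus_min, defocus_max=defocus_max, **common),
    )


def example_scenario(seed: int = 0, **overrides) -> Scenario:
    """A representative 300 kV Krios AFIS session.

    254 micrographs over 3 collected squares (62 available on the atlas),
    140 targeted foil holes per square, 2 shots per hole, 81000×
    magnification at 2.3 Å per pixel, 58 frames of 0.6 e⁻ Å⁻² each, and a
    136 Å particle with ~20% of picks clustered.
    """
    fields = dict(
        instrument_id="TITAN52334150",
        epu_version="3.0.0446.0",
        session_id="bi23047-42",
        presets=default_presets(),
        seed=seed,
    )
    fields.update(overrides)
    return Scenario(**fields)


# --- flat key = value scenario files (CLI surface) -----------------------

_LIST_FIELDS = {"foils_per_square", "motion_profile", "shot_density_factors"}
_PAIR_FIELDS = {"picks_per_micrograph", "pick_score", "ctf_resolution",
                "class_resolution_range"}


def load_scenario(path: Path | str) -> Scenario:
    """Read a scenario from a flat ``key = value`` config file.

    Keys are Scenario field names; lists and pairs are comma-separated;
    ``acquisition_start`` is ISO 8601; ``magnification`` / ``pixel_size``
    and friends configure the acquisition preset.  Unset keys take the
    example-session defaults.
    """
    overrides: dict = {}
    preset_kwargs: dict = {}
    preset_keys = {"magnification", "pixel_size", "defocus_min", "defocus_max",
                   "beam_diameter", "spot_size", "c2_aperture",
                   "objective_aperture"}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ValueError(f"malformed scenario line (expected key = value): {raw!r}")
        key, value = key.strip(), value.strip()
        if key in preset_keys:
            preset_kwargs[key] = ast.literal_eval(value)
        elif key == "sensor_pixels":
            w, h = (int(t) for t in value.split(","))
            preset_kwargs["sensor_pixels"] = (w, h)
        elif key in _LIST_FIELDS or key in _PAIR_FIELDS:
            overrides[key] = tuple(ast.literal_eval(t) for t in value.split(","))
        elif key == "acquisition_start":
            overrides[key] = datetime.fromisoformat(value)
        elif key in Scenario.model_fields:
            field = Scenario.model_fields[key]
            overrides[key] = value if field.annotation is str else ast.literal_eval(value)
        else:
            raise ValueError(f"unknown scenario key: {key!r}")
    if preset_kwargs:
        overrides["presets"] = default_presets(**preset_kwargs)
    return example_scenario(**overrides)
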