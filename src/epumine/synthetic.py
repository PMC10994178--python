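"""Fabricate internally consistent acquisition + preprocessing trees.

Everything downstream (parsers, metrics, analytics, reporting) is
exercised against directory trees produced here from a declarative
:class:`~epumine.scenario.Scenario`.  The generator writes the standard
session layout — an ``atlas/`` subtree with session/atlas ``.dm``
metadata, a ``metadata/.../Images-Disc1`` subtree with one XML per
grid-square, foil-hole and acquisition image, ``raw/`` fraction
placeholders — and a RELION-style preprocessing tree with motion, CTF,
CBOX pick and 2D-class results whose values are drawn from the
scenario's ground-truth distributions.

Determinism contract: the same (scenario, seed) yields byte-identical
trees.  Raw images are zero-byte placeholders; all parsed information
lives in file names and XML/STAR content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .dialect import SYNTHETIC_ADDRESS_MAP, build_xml
from .scenario import PresetSpec, Scenario
from .star import write_star

_TS_FMT = "%Y%m%d_%H%M%S"


class GenerationError(ValueError):
    """A scenario cannot be realised as a directory tree."""


# ---------------------------------------------------------------------------
# deterministic session layout (shared between session + preprocessing trees)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Hole:
    hole_id: int
    stage: Tuple[float, float]  # µm


@dataclass(frozen=True)
class _Square:
    square_id: int
    stage: Tuple[float, float]
    holes: Tuple[_Hole, ...]


@dataclass(frozen=True)
class _Slot:
    square: _Square
    hole: _Hole
    shot_index: int
    acq_id: int
    timestamp: datetime

    @property
    def name(self) -> str:
        return (f"FoilHole_{self.hole.hole_id}_Data_{self.acq_id}_"
                f"{self.timestamp.strftime(_TS_FMT)}")


@dataclass(frozen=True)
class _Plan:
    squares: Tuple[_Square, ...]
    slots: Tuple[_Slot, ...]  # acquisition order


def _layout(scenario: Scenario) -> _Plan:
    """Deterministic targeting plan: squares, holes, acquisition slots.

    Micrograph slots are interleaved across squares so that every
    collected square receives at least one exposure whenever
    ``n_micrographs >= n_squares_collected``.
    """
    rng = np.random.default_rng([scenario.seed, 1])
    n_sq = scenario.n_squares_collected
    n_holes = sum(scenario.foils_per_square)
    square_ids = rng.choice(np.arange(1_000_000, 10_000_000), size=max(n_sq, 1),
                            replace=False)[:n_sq]
    hole_ids = rng.choice(np.arange(10_000_000, 100_000_000), size=max(n_holes, 1),
                          replace=False)[:n_holes]
    squares: List[_Square] = []
    h = 0
    for i in range(n_sq):
        sx, sy = float(90.0 * i), float(45.0 * (i % 2))
        holes = []
        cols = max(1, int(math.ceil(math.sqrt(scenario.foils_per_square[i]))))
        for j in range(scenario.foils_per_square[i]):
            hx = sx + (j % cols) * scenario.hole_spacing
            hy = sy + (j // cols) * scenario.hole_spacing
            holes.append(_Hole(int(hole_ids[h]), (hx, hy)))
            h += 1
        squares.append(_Square(int(square_ids[i]), (sx, sy), tuple(holes)))

    # per-square slot sequences (hole-major), then round-robin interleave
    per_square: List[List[Tuple[_Square, _Hole, int]]] = []
    for sq in squares:
        seq = [(sq, hole, s) for hole in sq.holes for s in range(scenario.shots_per_hole)]
        per_square.append(seq)
    interleaved: List[Tuple[_Square, _Hole, int]] = []
    depth = max((len(s) for s in per_square), default=0)
    for k in range(depth):
        for seq in per_square:
            if k < len(seq):
                interleaved.append(seq[k])

    slots = []
    for m, (sq, hole, shot) in enumerate(interleaved[: scenario.n_micrographs]):
        ts = scenario.acquisition_start + timedelta(
            seconds=m * scenario.acquisition_interval)
        slots.append(_Slot(sq, hole, shot, 20_000_000 + m, ts))
    return _Plan(tuple(squares), tuple(slots))


# ---------------------------------------------------------------------------
# session tree
# ---------------------------------------------------------------------------

def _preset_fields(p: PresetSpec, voltage: float) -> dict:
    a = SYNTHETIC_ADDRESS_MAP.image
    return {
        a["preset_name"]: p.preset_name,
        a["magnification"]: float(p.magnification),
        a["pixel_size"]: float(p.pixel_size),
        a["spot_size"]: p.spot_size,
        a["c2_aperture"]: float(p.c2_aperture),
        a["objective_aperture"]: float(p.objective_aperture),
        a["beam_diameter"]: float(p.beam_diameter),
        a["acceleration_voltage"]: float(voltage),
        a["defocus_min"]: float(p.defocus_min),
        a["defocus_max"]: float(p.defocus_max),
        a["sensor_width"]: p.sensor_pixels[0],
        a["sensor_height"]: p.sensor_pixels[1],
    }


def _write_image_xml(path: Path, preset: PresetSpec, voltage: float,
                     timestamp: datetime, **extra) -> None:
    a = SYNTHETIC_ADDRESS_MAP.image
    values = _preset_fields(preset, voltage)
    values[a["timestamp"]] = timestamp.isoformat()
    for key, val in extra.items():
        values[a[key]] = val
    path.write_bytes(build_xml("MicroscopeImage", values))
    path.with_suffix(".jpg").touch()


def _shot_offset(shot_index: int, n_shots: int, hole_diameter: float) -> Tuple[float, float]:
    """Within-hole beam-shift offset (µm) for one acquisition area.

    Shots are spread on a circle of radius 0.25 × hole diameter starting
    at the top of the hole, so a 2-shot strategy yields a top and a
    bottom exposure.
    """
    r = 0.25 * hole_diameter
    angle = math.pi / 2 - 2 * math.pi * shot_index / max(n_shots, 1)
    return (round(r * math.cos(angle), 6), round(r * math.sin(angle), 6))


def generate_session_tree(scenario: Scenario, out_root: Path | str) -> Path:
    """Write one complete session directory tree; returns the session root."""
    out_root = Path(out_root)
    try:
        out_root.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise GenerationError(f"output root not writable: {out_root}: {exc}") from exc
    root = out_root / scenario.session_id
    root.mkdir(exist_ok=True)

    plan = _layout(scenario)
    t0 = scenario.acquisition_start
    stamp = (t0 - timedelta(hours=2)).strftime(_TS_FMT)
    voltage = scenario.acceleration_voltage
    presets = {p.preset_name: p for p in scenario.presets}
    if "acquisition" not in presets:
        raise GenerationError("scenario must define an acquisition preset")

    # --- atlas subtree ---
    atlas_dir = root / "atlas" / f"Supervisor_{stamp}_{scenario.session_id}_Atlas"
    sample_atlas = atlas_dir / "Sample1" / "Atlas"
    sample_atlas.mkdir(parents=True, exist_ok=True)
    sa = SYNTHETIC_ADDRESS_MAP.screening
    (atlas_dir / "ScreeningSession.dm").write_bytes(build_xml("ScreeningSessionXml", {
        sa["instrument_id"]: scenario.instrument_id,
        sa["epu_version"]: scenario.epu_version,
        sa["session_id"]: scenario.session_id,
        sa["n_grids"]: 1,
    }))
    (atlas_dir / "Sample1" / "Sample.dm").write_bytes(
        build_xml("SampleXml", {"sampleName": "Sample1", "position": 1}))
    aa = SYNTHETIC_ADDRESS_MAP.atlas
    (sample_atlas / "Atlas.dm").write_bytes(build_xml("AtlasSessionXml", {
        aa["atlas_id"]: f"{scenario.session_id}_atlas",
        aa["n_squares_available"]: scenario.n_squares_available,
    }))
    if "atlas" in presets:
        _write_image_xml(sample_atlas / "Atlas.xml", presets["atlas"], voltage,
                         t0 - timedelta(hours=2))

    # --- session-level metadata ---
    epu_dir = root / "metadata" / f"Supervisor_{stamp}_{scenario.session_id}_EPU"
    disc = epu_dir / "Images-Disc1"
    disc.mkdir(parents=True, exist_ok=True)
    se = SYNTHETIC_ADDRESS_MAP.session
    (epu_dir / "EpuSession.dm").write_bytes(build_xml("EpuSessionXml", {
        se["session_id"]: scenario.session_id,
        se["epu_version"]: scenario.epu_version,
        se["instrument_id"]: scenario.instrument_id,
        se["grid_type"]: scenario.grid_type,
        se["hole_diameter"]: float(scenario.hole_diameter),
        se["hole_spacing"]: float(scenario.hole_spacing),
        se["shots_per_hole"]: scenario.shots_per_hole,
        se["collection_mode"]: scenario.collection_mode,
        se["fraction_dose"]: float(scenario.fraction_dose),
        se["n_frames"]: scenario.n_frames,
        se["session_date"]: t0.isoformat(),
    }))

    # --- per-square / per-hole / per-acquisition images ---
    defocus_steps = np.linspace(presets["acquisition"].defocus_min,
                                presets["acquisition"].defocus_max, 5)
    hole_counter = 0
    for i, sq in enumerate(plan.squares):
        sq_dir = disc / f"GridSquare_{sq.square_id}"
        (sq_dir / "Data").mkdir(parents=True, exist_ok=True)
        (sq_dir / "FoilHoles").mkdir(exist_ok=True)
        sq_ts = t0 - timedelta(minutes=60) + timedelta(seconds=60 * i)
        if "gridsquare" in presets:
            _write_image_xml(
                sq_dir / f"GridSquare_{sq_ts.strftime(_TS_FMT)}.xml",
                presets["gridsquare"], voltage, sq_ts,
                square_id=f"GridSquare_{sq.square_id}",
                stage_x=sq.stage[0], stage_y=sq.stage[1])
        for hole in sq.holes:
            h_ts = t0 - timedelta(minutes=30) + timedelta(seconds=2 * hole_counter)
            hole_counter += 1
            if "hole" in presets:
                _write_image_xml(
                    sq_dir / "FoilHoles" /
                    f"FoilHoles_{hole.hole_id}_{h_ts.strftime(_TS_FMT)}.xml",
                    presets["hole"], voltage, h_ts,
                    square_id=f"GridSquare_{sq.square_id}",
                    hole_id=f"FoilHole_{hole.hole_id}",
                    stage_x=hole.stage[0], stage_y=hole.stage[1])

    raw_root = root / "raw"
    for m, slot in enumerate(plan.slots):
        sq_dir = disc / f"GridSquare_{slot.square.square_id}"
        shift = _shot_offset(slot.shot_index, scenario.shots_per_hole,
                             scenario.hole_diameter)
        _write_image_xml(
            sq_dir / "Data" / f"{slot.name}.xml",
            presets["acquisition"], voltage, slot.timestamp,
            square_id=f"GridSquare_{slot.square.square_id}",
            hole_id=f"FoilHole_{slot.hole.hole_id}",
            acquisition_area_id=f"Area_{slot.acq_id}",
            shot_index=slot.shot_index,
            applied_defocus=float(defocus_steps[m % len(defocus_steps)]),
            stage_x=slot.hole.stage[0], stage_y=slot.hole.stage[1],
            image_shift_x=shift[0], image_shift_y=shift[1])
        raw_dir = raw_root / f"GridSquare_{slot.square.square_id}" / "Data"
        raw_dir.mkdir(parents=True, exist_ok=True)
        (raw_dir / f"{slot.name}_fractions.mrc").touch()

    gain = root / "processing" / "gain"
    gain.mkdir(parents=True, exist_ok=True)
    (gain / "README").write_text("Facility gain-reference staging area.\n")
    (root / "processed" / "raw").mkdir(parents=True, exist_ok=True)
    return root


# ---------------------------------------------------------------------------
# pick-coordinate ground truth
# ---------------------------------------------------------------------------

def generate_pick_coordinates(
    rng: np.random.Generator,
    n: int,
    diameter_px: float,
    sensor: Tuple[int, int],
    clustered_fraction: float,
    max_attempts: int = 2000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Place ``n`` particle centres (px) with a controlled clustered count.

    A pick is clustered when its nearest neighbour lies closer than 0.8
    diameters.  round(clustered_fraction × n) picks are laid out as pairs
    separated by 0.35-0.75 diameters (one pair extended to a triplet when
    the count is odd); all other picks keep >= 0.84 diameters of clearance
    so they stay unambiguously unclustered.  Returns (centres[n, 2],
    clustered_mask[n]).
    """
    w, h = sensor
    margin = diameter_px
    min_sep = 0.84 * diameter_px  # strict 0.8 threshold plus numerical clearance
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise GenerationError("sensor too small for the particle diameter")

    k = int(round(clustered_fraction * n))
    if k == 1:
        k = 2 if n >= 2 else 0
    k = min(k, n)
    if k % 2 == 1:
        cluster_sizes = [3] + [2] * ((k - 3) // 2)
    else:
        cluster_sizes = [2] * (k // 2)

    points: List[np.ndarray] = []
    clustered: List[bool] = []

    def sample_clear() -> np.ndarray:
        for _ in range(max_attempts):
            p = np.array([rng.uniform(margin, w - margin),
                          rng.uniform(margin, h - margin)])
            if not points or np.min(np.linalg.norm(np.vstack(points) - p, axis=1)) >= min_sep:
                return p
        raise GenerationError(
            "cannot place picks at the requested density without clustering")

    for size in cluster_sizes:
        anchor = sample_clear()
        members = [anchor]
        for _ in range(size - 1):
            for _ in range(max_attempts):
                r = rng.uniform(0.35, 0.75) * diameter_px
                theta = rng.uniform(0, 2 * math.pi)
                p = anchor + [r * math.cos(theta), r * math.sin(theta)]
                others = [q for q in points if not any(q is m for m in members)]
                ok = (margin <= p[0] <= w - margin and margin <= p[1] <= h - margin)
                if ok and others:
                    ok = np.min(np.linalg.norm(np.vstack(others) - p, axis=1)) >= min_sep
                if ok:
                    members.append(p)
                    break
            else:
                raise GenerationError("cannot place clustered partner pick")
        for p in members:
            points.append(p)
            clustered.append(True)

    while len(points) < n:
        points.append(sample_clear())
        clustered.append(False)

    if not points:
        return np.empty((0, 2)), np.empty(0, dtype=bool)
    order = rng.permutation(len(points))
    centres = np.vstack(points)[order]
    mask = np.asarray(clustered, dtype=bool)[order]
    return centres, mask


# ---------------------------------------------------------------------------
# preprocessing tree
# ---------------------------------------------------------------------------

def generate_preprocessing_tree(scenario: Scenario, session_root: Path | str) -> Path:
    """Write a RELION-style preprocessing tree under ``processed/raw/relion``.

    Requires the session tree (micrograph names must match); raises
    :class:`GenerationError` otherwise.
    """
    session_root = Path(session_root)
    if not (session_root / "metadata").is_dir():
        raise GenerationError(
            f"no session metadata under {session_root}; "
            "generate the session tree first")
    proc = session_root / "processed" / "raw" / "relion"
    proc.mkdir(parents=True, exist_ok=True)

    plan = _layout(scenario)
    rng = np.random.default_rng([scenario.seed, 2])
    preset = scenario.acquisition_preset
    apix = preset.pixel_size
    d_px = scenario.particle_diameter_true / apix
    box = int(round(1.2 * d_px))
    profile = np.asarray(scenario.effective_motion_profile())

    # motion: roster table + one per-micrograph table of per-frame shifts
    motion_dir = proc / "MotionCorr" / "job002" / "Micrographs"
    motion_dir.mkdir(parents=True, exist_ok=True)
    roster_rows = []
    ctf_rows = []
    cbox_dir = proc / "AutoPick" / "job004" / "CBOX"
    cbox_dir.mkdir(parents=True, exist_ok=True)
    particle_rows = []
    defocus_steps = np.linspace(preset.defocus_min, preset.defocus_max, 5)
    class_res = np.round(rng.uniform(*scenario.class_resolution_range,
                                     size=scenario.n_2d_classes), 3)

    pick_mean, pick_sd = scenario.picks_per_micrograph
    score_mean, score_sd = scenario.pick_score

    for m, slot in enumerate(plan.slots):
        name = slot.name

        scale = rng.uniform(0.8, 1.2)
        mags = profile * scale
        theta = rng.uniform(0, 2 * math.pi, size=len(mags))
        shifts = pd.DataFrame({
            "rlnMicrographFrameNumber": np.arange(1, len(mags) + 1),
            "rlnMicrographShiftX": np.round(mags * np.cos(theta), 6),
            "rlnMicrographShiftY": np.round(mags * np.sin(theta), 6),
        })
        write_star(motion_dir / f"{name}.star", {
            "general": {
                "rlnMicrographDoseRate": float(scenario.fraction_dose),
                "rlnMicrographOriginalPixelSize": float(apix),
            },
            "global_shift": shifts,
        })
        roster_rows.append({
            "rlnMicrographName": f"Micrographs/{name}.mrc",
            "rlnMicrographMetadata": f"Micrographs/{name}.star",
        })

        ctf_rows.append({
            "rlnMicrographName": f"Micrographs/{name}.mrc",
            "rlnDefocusU": round(abs(defocus_steps[m % 5]) * 1e4
                                 + rng.normal(0, 200), 2),
            "rlnCtfMaxResolution": round(max(
                rng.normal(*scenario.ctf_resolution), 1.5), 4),
        })

        factor = 1.0
        if scenario.shot_density_factors is not None:
            factor = scenario.shot_density_factors[slot.shot_index]
        n_picks = max(0, int(round(rng.normal(pick_mean * factor, pick_sd))))
        centres, _ = generate_pick_coordinates(
            rng, n_picks, d_px, preset.sensor_pixels,
            scenario.clustered_fraction_true)
        est = np.round(rng.normal(d_px, 0.02 * d_px, size=n_picks), 4)
        scores = np.round(np.clip(rng.normal(score_mean, score_sd, size=n_picks),
                                  0.0, 1.0), 6)
        corners = np.round(centres - box / 2.0, 2)
        cbox_table = pd.DataFrame({
            "CoordinateX": corners[:, 0] if n_picks else [],
            "CoordinateY": corners[:, 1] if n_picks else [],
            "Width": np.full(n_picks, box),
            "Height": np.full(n_picks, box),
            "EstWidth": est,
            "EstHeight": est,
            "Confidence": scores,
        })
        write_star(cbox_dir / f"{name}.cbox", {
            "global": {"cbox_format_version": "1.0"},
            "cryolo": cbox_table,
        })

        classes = rng.integers(1, scenario.n_2d_classes + 1, size=n_picks)
        for c in range(n_picks):
            particle_rows.append({
                "rlnMicrographName": f"Micrographs/{name}.mrc",
                "rlnCoordinateX": corners[c, 0],
                "rlnCoordinateY": corners[c, 1],
                "rlnClassNumber": int(classes[c]),
            })

    write_star(motion_dir.parent / "corrected_micrographs.star",
               {"micrographs": pd.DataFrame(
                   roster_rows, columns=["rlnMicrographName", "rlnMicrographMetadata"])})
    ctf_dir = proc / "CtfFind" / "job003"
    ctf_dir.mkdir(parents=True, exist_ok=True)
    write_star(ctf_dir / "micrographs_ctf.star",
               {"micrographs": pd.DataFrame(
                   ctf_rows, columns=["rlnMicrographName", "rlnDefocusU",
                                      "rlnCtfMaxResolution"])})
    cls_dir = proc / "Class2D" / "job008"
    cls_dir.mkdir(parents=True, exist_ok=True)
    write_star(cls_dir / "run_it025_data.star",
               {"particles": pd.DataFrame(
                   particle_rows, columns=["rlnMicrographName", "rlnCoordinateX",
                                           "rlnCoordinateY", "rlnClassNumber"])})
    write_star(cls_dir / "run_it025_model.star",
               {"model_classes": pd.DataFrame({
                   "rlnClassNumber": np.arange(1, scenario.n_2d_classes + 1),
                   "rlnEstimatedResolution": class_res,
               })})

    (proc / "relion_it_options.py").write_text(
        "# pipeline options (synthetic)\n"
        f"angpix = {apix!r}\n"
        f"voltage = {scenario.acceleration_voltage / 1000.0!r}\n"
        f"motioncor_doseperframe = {float(scenario.fraction_dose)!r}\n"
        f"frame_count = {scenario.n_frames}\n"
        f"particle_diameter = {float(scenario.particle_diameter_true)!r}\n"
        f"autopick_LoG_diam_min = {round(0.8 * scenario.particle_diameter_true, 2)!r}\n"
        f"autopick_LoG_diam_max = {round(1.2 * scenario.particle_diameter_true, 2)!r}\n"
        "do_class2d = True\n"
    )
    return proc


# ---------------------------------------------------------------------------
# facility tree
# ---------------------------------------------------------------------------

def generate_facility_tree(scenarios: Sequence[Scenario], root: Path | str,
                           with_preprocessing: bool = True) -> Path:
    """Lay out one visit per scenario as ``root/instrument/year/Data/visit``."""
    if not scenarios:
        raise GenerationError("at least one scenario is required")
    root = Path(root)
    seen = set()
    for sc in scenarios:
        year = sc.acquisition_start.year
        key = (sc.instrument_id, year, sc.session_id)
        if key in seen:
            raise GenerationError(f"duplicate visit identifier: {key}")
        seen.add(key)
        visit_parent = root / sc.instrument_id / str(year) / "Data"
        visit_parent.mkdir(parents=True, exist_ok=True)
        session_root = generate_session_tree(sc, visit_parent)
        if with_preprocessing:
            generate_preprocessing_tree(sc, session_root)
    return root
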