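"""Parse RELION-style preprocessing results and join them to a session.

Reads motion-correction per-frame shift tables, CTF estimation results,
crYOLO CBOX particle coordinates, 2D-classification output and the
``relion_it_options.py`` pipeline-options file.  Micrograph identity is
the basename with the ``_fractions`` suffix and any extension stripped,
so entries join to acquisition records by name regardless of which job
directory or extension produced them.

The options file is parsed as simple ``key = literal`` assignments via
``ast.literal_eval``; no code is ever executed.
"""

from __future__ import annotations

import ast
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .epu import AcquisitionRecord
from .star import read_star

logger = logging.getLogger(__name__)

_SUFFIXES = ("_fractions", "_Fractions", "_EER", "_movie")


class JoinError(ValueError):
    """Session and preprocessing trees could not be matched at all."""


def normalize_micrograph_id(name: str) -> str:
    """Canonical micrograph identity: basename, no extension, no movie suffix."""
    stem = Path(str(name)).name
    # strip at most one extension; micrograph names themselves contain no dots
    stem = stem.split(".", 1)[0]
    for suffix in _SUFFIXES:
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return stem


@dataclass
class MotionTrace:
    """Per-frame beam-induced motion for one micrograph."""

    micrograph_id: str
    per_frame_shift: List[float]  # Å, frame i -> i+1 displacement magnitude
    fraction_dose: Optional[float]  # e⁻ Å⁻² per frame

    @property
    def total_dose(self) -> Optional[float]:
        if self.fraction_dose is None:
            return None
        return self.fraction_dose * len(self.per_frame_shift)


@dataclass
class CtfResult:
    micrograph_id: str
    max_resolution: float  # Å
    defocus_fitted: Optional[float] = None  # µm


@dataclass
class PickSet:
    """crYOLO picks for one micrograph (pixel coordinates, CBOX convention).

    ``picks`` rows are (x_px, y_px, box_w, box_h, est_diameter_px, score);
    x/y are the lower-left box corner, so a particle centre is
    corner + box/2.
    """

    micrograph_id: str
    picks: pd.DataFrame  # columns x, y, box_w, box_h, est_diameter, score
    pixel_size: Optional[float] = None  # Å per pixel

    def __len__(self) -> int:
        return len(self.picks)

    def centres_px(self) -> np.ndarray:
        if self.picks.empty:
            return np.empty((0, 2))
        return np.column_stack([
            self.picks["x"].to_numpy(float) + self.picks["box_w"].to_numpy(float) / 2.0,
            self.picks["y"].to_numpy(float) + self.picks["box_h"].to_numpy(float) / 2.0,
        ])


@dataclass
class ClassAssignment:
    micrograph_id: str
    per_pick_class: List[int]
    class_resolution: Dict[int, float]  # class index -> Å


@dataclass
class PreprocResults:
    """All preprocessing results for one session; iterable as a 5-tuple."""

    motion: List[MotionTrace]
    ctf: List[CtfResult]
    picks: List[PickSet]
    classes: List[ClassAssignment]
    pipeline_options: Dict[str, object]
    n_malformed_rows: int = 0

    def __iter__(self):
        return iter((self.motion, self.ctf, self.picks, self.classes,
                     self.pipeline_options))


def parse_pipeline_options(path: Path) -> Dict[str, object]:
    """Parse ``key = literal`` lines; anything else is ignored with a notice."""
    options: Dict[str, object] = {}
    pattern = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_]*)\s*=\s*(.+?)\s*$")
    for line in path.read_text().splitlines():
        stripped = line.split("#", 1)[0]
        m = pattern.match(stripped)
        if not m:
            continue
        try:
            options[m.group(1)] = ast.literal_eval(m.group(2))
        except (ValueError, SyntaxError):
            logger.info("skipping non-literal option line: %s", line.strip())
    return options


def _loop_block(path: Path, preferred: Optional[str] = None) -> Optional[pd.DataFrame]:
    try:
        blocks = read_star(path)
    except OSError as exc:
        logger.warning("cannot read %s: %s", path, exc)
        return None
    if preferred is not None and isinstance(blocks.get(preferred), pd.DataFrame):
        return blocks[preferred]
    for block in blocks.values():
        if isinstance(block, pd.DataFrame):
            return block
    return None


def _parse_motion(proc_root: Path) -> Tuple[List[MotionTrace], int]:
    traces: List[MotionTrace] = []
    malformed = 0
    star_files = sorted(proc_root.glob("MotionCorr/job*/**/*.star"))
    for path in star_files:
        if path.name == "corrected_micrographs.star":
            continue
        blocks = read_star(path)
        shifts = blocks.get("global_shift")
        if not isinstance(shifts, pd.DataFrame):
            continue
        malformed += shifts.attrs.get("n_skipped", 0)
        general = blocks.get("general", {})
        dose = general.get("rlnMicrographDoseRate") if isinstance(general, dict) else None
        mags = np.hypot(shifts["rlnMicrographShiftX"].to_numpy(float),
                        shifts["rlnMicrographShiftY"].to_numpy(float))
        traces.append(MotionTrace(
            micrograph_id=normalize_micrograph_id(path.name),
            per_frame_shift=[float(v) for v in mags],
            fraction_dose=float(dose) if dose is not None else None,
        ))
    return traces, malformed


def _parse_ctf(proc_root: Path) -> Tuple[List[CtfResult], int]:
    results: List[CtfResult] = []
    malformed = 0
    for path in sorted(proc_root.glob("CtfFind/job*/micrographs_ctf.star")):
        table = _loop_block(path, "micrographs")
        if table is None:
            continue
        malformed += table.attrs.get("n_skipped", 0)
        for row in table.itertuples(index=False):
            d = row._asdict()
            res = d.get("rlnCtfMaxResolution")
            if res is None or not np.isfinite(res) or res <= 0:
                malformed += 1
                continue
            defocus_u = d.get("rlnDefocusU")  # Å in RELION convention
            results.append(CtfResult(
                micrograph_id=normalize_micrograph_id(d["rlnMicrographName"]),
                max_resolution=float(res),
                defocus_fitted=float(defocus_u) / 1e4 if defocus_u is not None else None,
            ))
    return results, malformed


_CBOX_COLUMNS = {
    "CoordinateX": "x", "CoordinateY": "y",
    "Width": "box_w", "Height": "box_h",
    "EstWidth": "est_diameter", "Confidence": "score",
}


def parse_cbox(path: Path, pixel_size: Optional[float] = None) -> PickSet:
    """Read one CBOX coordinate file into a :class:`PickSet`."""
    table = _loop_block(path, "cryolo")
    if table is None:
        table = pd.DataFrame(columns=list(_CBOX_COLUMNS))
    present = {src: dst for src, dst in _CBOX_COLUMNS.items() if src in table.columns}
    picks = table[list(present)].rename(columns=present) if len(table.columns) else \
        pd.DataFrame(columns=list(_CBOX_COLUMNS.values()))
    for dst in _CBOX_COLUMNS.values():
        if dst not in picks.columns:
            picks[dst] = np.nan
    return PickSet(micrograph_id=normalize_micrograph_id(path.name),
                   picks=picks.reset_index(drop=True), pixel_size=pixel_size)


def _parse_picks(proc_root: Path, pixel_size: Optional[float]) -> List[PickSet]:
    return [parse_cbox(p, pixel_size)
            for p in sorted(proc_root.glob("AutoPick/job*/**/*.cbox"))]


def _parse_classes(proc_root: Path) -> List[ClassAssignment]:
    assignments: List[ClassAssignment] = []
    for cls_dir in sorted(proc_root.glob("Class2D/job*")):
        data_stars = sorted(cls_dir.glob("run_*_data.star"))
        model_stars = sorted(cls_dir.glob("run_*_model.star"))
        if not data_stars or not model_stars:
            continue
        particles = _loop_block(data_stars[-1], "particles")
        model = _loop_block(model_stars[-1], "model_classes")
        if particles is None or model is None or particles.empty:
            continue
        resolution = {int(c): float(r) for c, r in zip(
            model["rlnClassNumber"], model["rlnEstimatedResolution"])}
        grouped = particles.groupby(
            particles["rlnMicrographName"].map(normalize_micrograph_id), sort=True)
        for mic_id, group in grouped:
            assignments.append(ClassAssignment(
                micrograph_id=mic_id,
                per_pick_class=[int(c) for c in group["rlnClassNumber"]],
                class_resolution=resolution,
            ))
        break  # one classification job per session
    return assignments


def parse_preprocessing(proc_root: Path | str) -> PreprocResults:
    """Parse a preprocessing tree into per-micrograph result lists.

    A missing result type (e.g. classification not run yet) yields an
    empty list with a logged notice, never an exception.
    """
    proc_root = Path(proc_root)
    if not proc_root.is_dir():
        raise FileNotFoundError(f"preprocessing root does not exist: {proc_root}")

    options: Dict[str, object] = {}
    options_path = proc_root / "relion_it_options.py"
    if options_path.is_file():
        options = parse_pipeline_options(options_path)
    else:
        logger.info("no relion_it_options.py under %s", proc_root)

    pixel_size = options.get("angpix")
    pixel_size = float(pixel_size) if isinstance(pixel_size, (int, float)) else None

    motion, bad_motion = _parse_motion(proc_root)
    ctf, bad_ctf = _parse_ctf(proc_root)
    picks = _parse_picks(proc_root, pixel_size)
    classes = _parse_classes(proc_root)
    for label, results in (("motion", motion), ("CTF", ctf),
                           ("picks", picks), ("2D classes", classes)):
        if not results:
            logger.info("no %s results under %s", label, proc_root)
    return PreprocResults(motion=motion, ctf=ctf, picks=picks, classes=classes,
                          pipeline_options=options,
                          n_malformed_rows=bad_motion + bad_ctf)


@dataclass
class JoinedMicrograph:
    """One acquisition record with its preprocessing results attached."""

    record: AcquisitionRecord
    motion: Optional[MotionTrace] = None
    ctf: Optional[CtfResult] = None
    picks: Optional[PickSet] = None
    classes: Optional[ClassAssignment] = None

    @property
    def micrograph_id(self) -> str:
        return self.record.micrograph_id


@dataclass
class JoinResult:
    """Joined micrograph entries plus unmatched preprocessing identities."""

    entries: List[JoinedMicrograph]
    unmatched: List[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, idx):
        return self.entries[idx]


def join_to_session(records: Sequence[AcquisitionRecord],
                    preproc: PreprocResults) -> JoinResult:
    """Attach preprocessing results to acquisition records by micrograph name.

    The join is injective: each preprocessing row attaches to at most one
    record.  Unmatched preprocessing identities are reported in
    ``JoinResult.unmatched``.  Zero joins with both sides non-empty raises
    :class:`JoinError` (naming-convention mismatch).
    """
    def index(items):
        out: Dict[str, object] = {}
        for item in items:
            key = normalize_micrograph_id(item.micrograph_id)
            if key in out:
                logger.warning("duplicate preprocessing entry for %s", key)
                continue
            out[key] = item
        return out

    motion_by = index(preproc.motion)
    ctf_by = index(preproc.ctf)
    picks_by = index(preproc.picks)
    classes_by = index(preproc.classes)

    entries: List[JoinedMicrograph] = []
    matched: set = set()
    for record in records:
        key = normalize_micrograph_id(record.micrograph_id)
        entry = JoinedMicrograph(
            record=record,
            motion=motion_by.get(key),
            ctf=ctf_by.get(key),
            picks=picks_by.get(key),
            classes=classes_by.get(key),
        )
        if any(x is not None for x in (entry.motion, entry.ctf, entry.picks,
                                       entry.classes)):
            matched.add(key)
        entries.append(entry)

    all_preproc = set(motion_by) | set(ctf_by) | set(picks_by) | set(classes_by)
    unmatched = sorted(all_preproc - {normalize_micrograph_id(r.micrograph_id)
                                      for r in records})
    if records and all_preproc and not matched:
        raise JoinError(
            "no preprocessing entry matched any acquisition record; "
            "check the micrograph naming convention between the trees")
    if unmatched:
        logger.warning("%d preprocessing entries had no matching micrograph",
                       len(unmatched))
    return JoinResult(entries=entries, unmatched=unmatched)
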