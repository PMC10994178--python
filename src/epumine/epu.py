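"""Walk an acquisition session tree and assemble the hierarchical data model.

The session layout is the standard one written by the vendor collection
software: an ``atlas/`` subtree holding screening/atlas ``.dm`` metadata
and a ``metadata/Supervisor_*_EPU/Images-Disc1`` subtree with one XML
per grid-square, foil-hole and acquisition image.  All element lookups
go through a configurable :class:`~epumine.dialect.AddressMap`, so the
parser itself never hard-codes an XML schema.

Identity is taken from the filename grammar
``FoilHole_[Hole-ID]_Data_[Acquisition-ID]_[date]_[time]``: square,
hole and acquisition IDs parsed from names are authoritative, and
XML-embedded IDs are cross-checked (a mismatch logs a warning).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from lxml import etree

from .dialect import AddressMap, SYNTHETIC_ADDRESS_MAP, query_fields

logger = logging.getLogger(__name__)

_DATA_RE = re.compile(
    r"FoilHole_(?P<hole>\d+)_Data_(?P<acq>\d+)_(?P<date>\d{8})_(?P<time>\d{6})$")
_HOLE_RE = re.compile(r"FoilHoles_(?P<hole>\d+)_(?P<date>\d{8})_(?P<time>\d{6})$")
_SQUARE_DIR_RE = re.compile(r"GridSquare_(?P<square>\d+)$")


class SessionStructureError(ValueError):
    """The directory tree is missing a required structural element."""


@dataclass(frozen=True)
class OpticsPreset:
    """Microscope optical configuration for one magnification preset."""

    preset_name: str
    magnification: Optional[float] = None
    pixel_size: Optional[float] = None  # Å per pixel
    spot_size: Optional[int] = None
    c2_aperture: Optional[float] = None  # µm
    objective_aperture: Optional[float] = None  # µm
    beam_diameter: Optional[float] = None  # µm
    defocus_min: Optional[float] = None  # µm, signed as stored
    defocus_max: Optional[float] = None
    acceleration_voltage: Optional[float] = None  # volts
    sensor_pixels: Optional[Tuple[int, int]] = None

    def field_of_view_um2(self) -> Optional[float]:
        """Magnified sensor area in µm² (1 µm = 1e4 Å)."""
        if self.sensor_pixels is None or not self.pixel_size:
            return None
        w, h = self.sensor_pixels
        return (w * self.pixel_size / 1e4) * (h * self.pixel_size / 1e4)


@dataclass
class AcquisitionRecord:
    """One micrograph with its targeting lineage and optics context."""

    micrograph_id: str
    square_id: str
    hole_id: str
    acquisition_area_id: Optional[str]
    timestamp: Optional[datetime]
    applied_defocus: Optional[float] = None  # µm
    stage_position: Optional[Tuple[float, float]] = None  # µm
    image_shift: Optional[Tuple[float, float]] = None  # µm
    shot_index: Optional[int] = None
    xml_path: Optional[Path] = None
    raw_path: Optional[Path] = None


@dataclass
class SessionConfig:
    """Session-level configuration harvested from the ``.dm`` files."""

    instrument_id: Optional[str] = None
    epu_version: Optional[str] = None
    session_id: Optional[str] = None
    grid_type: Optional[str] = None
    hole_diameter: Optional[float] = None  # µm
    hole_spacing: Optional[float] = None  # µm
    shots_per_hole: Optional[int] = None
    collection_mode: Optional[str] = None
    n_squares_available: Optional[int] = None
    n_squares_targeted: Optional[int] = None
    n_squares_collected: Optional[int] = None
    session_date: Optional[datetime] = None
    fraction_dose: Optional[float] = None  # e⁻ Å⁻² per frame
    n_frames: Optional[int] = None


@dataclass
class LineageEntry:
    level: str  # atlas | grid_square | foil_hole | acquisition
    image_path: Optional[Path]
    resolved: bool


@dataclass
class ParsedSession:
    """Everything recovered from one session tree.

    Iterable as the (config, presets, records) triple.
    """

    root: Path
    config: SessionConfig
    presets: List[OpticsPreset]
    records: List[AcquisitionRecord]
    atlas_image: Optional[Path] = None
    square_images: Dict[str, Path] = field(default_factory=dict)
    hole_images: Dict[str, Path] = field(default_factory=dict)
    n_skipped: int = 0

    def __iter__(self):
        return iter((self.config, self.presets, self.records))

    def preset(self, name: str) -> Optional[OpticsPreset]:
        for p in self.presets:
            if p.preset_name == name:
                return p
        return None


def _opt(fields: dict, key: str, cast):
    value = fields.get(key)
    if value is None:
        return None
    try:
        return cast(value)
    except (TypeError, ValueError):
        logger.warning("unparseable value for %s: %r", key, value)
        return None


def _parse_timestamp(text: Optional[str], date: Optional[str] = None,
                     time: Optional[str] = None) -> Optional[datetime]:
    if text:
        try:
            return datetime.fromisoformat(text)
        except ValueError:
            logger.warning("unparseable timestamp %r", text)
    if date and time:
        return datetime.strptime(date + time, "%Y%m%d%H%M%S").replace(
            tzinfo=timezone.utc)
    return None


def _image_fields(path: Path, address_map: AddressMap) -> Optional[dict]:
    try:
        return query_fields(path, address_map.image)
    except (etree.XMLSyntaxError, OSError) as exc:
        logger.warning("skipping unparseable XML %s: %s", path, exc)
        return None


def _preset_from_fields(fields: dict, fallback_name: str) -> OpticsPreset:
    w = _opt(fields, "sensor_width", int)
    h = _opt(fields, "sensor_height", int)
    return OpticsPreset(
        preset_name=fields.get("preset_name") or fallback_name,
        magnification=_opt(fields, "magnification", float),
        pixel_size=_opt(fields, "pixel_size", float),
        spot_size=_opt(fields, "spot_size", int),
        c2_aperture=_opt(fields, "c2_aperture", float),
        objective_aperture=_opt(fields, "objective_aperture", float),
        beam_diameter=_opt(fields, "beam_diameter", float),
        defocus_min=_opt(fields, "defocus_min", float),
        defocus_max=_opt(fields, "defocus_max", float),
        acceleration_voltage=_opt(fields, "acceleration_voltage", float),
        sensor_pixels=(w, h) if w is not None and h is not None else None,
    )


def _pair(fields: dict, xkey: str, ykey: str) -> Optional[Tuple[float, float]]:
    x, y = _opt(fields, xkey, float), _opt(fields, ykey, float)
    if x is None or y is None:
        return None
    return (x, y)


def find_epu_dir(session_root: Path) -> Path:
    meta = session_root / "metadata"
    if not meta.is_dir():
        raise SessionStructureError(f"missing 'metadata' subtree under {session_root}")
    candidates = sorted(meta.glob("Supervisor_*_EPU"))
    if not candidates:
        raise SessionStructureError(
            f"missing 'metadata/Supervisor_*_EPU' directory under {session_root}")
    return candidates[0]


def parse_session(session_root: Path | str,
                  address_map: AddressMap = SYNTHETIC_ADDRESS_MAP) -> ParsedSession:
    """Parse one session tree into (SessionConfig, presets, records).

    Unparseable image XML files are skipped with a warning and counted in
    ``ParsedSession.n_skipped``; missing addresses yield ``None`` fields.
    A missing structural element (no ``metadata`` or ``atlas`` subtree)
    raises :class:`SessionStructureError`.
    """
    root = Path(session_root)
    if not root.is_dir():
        raise SessionStructureError(f"session root does not exist: {root}")
    epu_dir = find_epu_dir(root)
    atlas_root = root / "atlas"
    if not atlas_root.is_dir():
        raise SessionStructureError(f"missing 'atlas' subtree under {root}")

    config = SessionConfig()
    dm = epu_dir / "EpuSession.dm"
    if dm.is_file():
        f = query_fields(dm, address_map.session)
        config.session_id = f.get("session_id")
        config.epu_version = f.get("epu_version")
        config.instrument_id = f.get("instrument_id")
        config.grid_type = f.get("grid_type")
        config.hole_diameter = _opt(f, "hole_diameter", float)
        config.hole_spacing = _opt(f, "hole_spacing", float)
        config.shots_per_hole = _opt(f, "shots_per_hole", int)
        config.collection_mode = f.get("collection_mode")
        config.fraction_dose = _opt(f, "fraction_dose", float)
        config.n_frames = _opt(f, "n_frames", int)
        config.session_date = _parse_timestamp(f.get("session_date"))
    else:
        logger.warning("no EpuSession.dm under %s", epu_dir)

    screening = sorted(atlas_root.glob("Supervisor_*_Atlas/ScreeningSession.dm"))
    if screening:
        f = query_fields(screening[0], address_map.screening)
        config.instrument_id = config.instrument_id or f.get("instrument_id")
        config.epu_version = config.epu_version or f.get("epu_version")
        config.session_id = config.session_id or f.get("session_id")

    presets: Dict[str, OpticsPreset] = {}
    atlas_image: Optional[Path] = None
    atlas_dm = sorted(atlas_root.glob("Supervisor_*_Atlas/Sample*/Atlas/Atlas.dm"))
    if atlas_dm:
        f = query_fields(atlas_dm[0], address_map.atlas)
        config.n_squares_available = _opt(f, "n_squares_available", int)
        atlas_xml = atlas_dm[0].with_name("Atlas.xml")
        if atlas_xml.is_file():
            fields = _image_fields(atlas_xml, address_map)
            if fields is not None:
                presets.setdefault("atlas", _preset_from_fields(fields, "atlas"))
                atlas_image = atlas_xml

    disc = epu_dir / "Images-Disc1"
    square_images: Dict[str, Path] = {}
    hole_images: Dict[str, Path] = {}
    records: List[AcquisitionRecord] = []
    n_skipped = 0
    squares_targeted: set = set()
    squares_collected: set = set()

    for sq_dir in sorted(p for p in disc.glob("GridSquare_*") if p.is_dir()):
        m = _SQUARE_DIR_RE.match(sq_dir.name)
        if not m:
            continue
        square_id = sq_dir.name

        for sq_xml in sorted(sq_dir.glob("GridSquare_*.xml")):
            fields = _image_fields(sq_xml, address_map)
            if fields is None:
                n_skipped += 1
                continue
            presets.setdefault("gridsquare",
                               _preset_from_fields(fields, "gridsquare"))
            square_images.setdefault(square_id, sq_xml)

        for hole_xml in sorted((sq_dir / "FoilHoles").glob("FoilHoles_*.xml")):
            hm = _HOLE_RE.match(hole_xml.stem)
            if not hm:
                continue
            fields = _image_fields(hole_xml, address_map)
            if fields is None:
                n_skipped += 1
                continue
            presets.setdefault("hole", _preset_from_fields(fields, "hole"))
            hole_images.setdefault(f"FoilHole_{hm.group('hole')}", hole_xml)
            squares_targeted.add(square_id)

        for data_xml in sorted((sq_dir / "Data").glob("FoilHole_*.xml")):
            dm_match = _DATA_RE.match(data_xml.stem)
            if not dm_match:
                continue
            fields = _image_fields(data_xml, address_map)
            if fields is None:
                n_skipped += 1
                continue
            presets.setdefault("acquisition",
                               _preset_from_fields(fields, "acquisition"))
            hole_id = f"FoilHole_{dm_match.group('hole')}"
            for key, expected in (("square_id", square_id), ("hole_id", hole_id)):
                embedded = fields.get(key)
                if embedded is not None and embedded != expected:
                    logger.warning("%s: XML %s %r disagrees with filename %r",
                                   data_xml.name, key, embedded, expected)
            raw = (root / "raw" / square_id / "Data" /
                   f"{data_xml.stem}_fractions.mrc")
            records.append(AcquisitionRecord(
                micrograph_id=data_xml.stem,
                square_id=square_id,
                hole_id=hole_id,
                acquisition_area_id=fields.get("acquisition_area_id")
                or f"Area_{dm_match.group('acq')}",
                timestamp=_parse_timestamp(fields.get("timestamp"),
                                           dm_match.group("date"),
                                           dm_match.group("time")),
                applied_defocus=_opt(fields, "applied_defocus", float),
                stage_position=_pair(fields, "stage_x", "stage_y"),
                image_shift=_pair(fields, "image_shift_x", "image_shift_y"),
                shot_index=_opt(fields, "shot_index", int),
                xml_path=data_xml,
                raw_path=raw if raw.is_file() else None,
            ))
            squares_collected.add(square_id)

    records.sort(key=lambda r: (r.timestamp or datetime.max.replace(
        tzinfo=timezone.utc), r.micrograph_id))
    config.n_squares_targeted = len(squares_targeted)
    config.n_squares_collected = len(squares_collected)

    preset_order = ["atlas", "gridsquare", "hole", "acquisition"]
    ordered = [presets[k] for k in preset_order if k in presets]
    ordered += [v for k, v in presets.items() if k not in preset_order]

    return ParsedSession(root=root, config=config, presets=ordered,
                         records=records, atlas_image=atlas_image,
                         square_images=square_images, hole_images=hole_images,
                         n_skipped=n_skipped)


def _image_for(xml_path: Optional[Path]) -> Optional[Path]:
    if xml_path is None:
        return None
    jpg = xml_path.with_suffix(".jpg")
    return jpg if jpg.is_file() else xml_path


def lineage(record: AcquisitionRecord, session: ParsedSession) -> List[LineageEntry]:
    """The [atlas, grid square, foil hole, acquisition] image chain.

    Unknown square/hole IDs yield entries flagged unresolved rather than
    raising, so degraded trees remain analysable.
    """
    atlas = session.atlas_image
    square = session.square_images.get(record.square_id)
    hole = session.hole_images.get(record.hole_id)
    acq = record.xml_path
    return [
        LineageEntry("atlas", _image_for(atlas), atlas is not None),
        LineageEntry("grid_square", _image_for(square), square is not None),
        LineageEntry("foil_hole", _image_for(hole), hole is not None),
        LineageEntry("acquisition", _image_for(acq),
                     acq is not None and acq.is_file()),
    ]
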