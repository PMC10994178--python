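"""The synthetic acquisition-metadata XML dialect and its address map.

Vendor acquisition software stores per-image metadata in XML files and
session-level metadata in ``.dm`` files (also XML), but the element
layout is an implementation detail of the vendor software and varies
between versions.  The parser therefore never hard-codes element paths:
it queries an :class:`AddressMap` that maps semantic field names to
slash-separated element paths.  One map ships for the synthetic dialect
written by :mod:`epumine.synthetic`; supporting a real dialect means
supplying an alternative map (``AddressMap.from_json``), not changing
parser code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from lxml import etree


@dataclass(frozen=True)
class AddressMap:
    """Semantic field -> element path, per file kind.

    ``image`` addresses apply to every per-image XML (atlas, grid
    square, foil hole, acquisition); ``session`` to EpuSession.dm;
    ``screening`` to ScreeningSession.dm; ``atlas`` to Atlas.dm.
    """

    image: Mapping[str, str] = field(default_factory=dict)
    session: Mapping[str, str] = field(default_factory=dict)
    screening: Mapping[str, str] = field(default_factory=dict)
    atlas: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: Path | str) -> "AddressMap":
        data = json.loads(Path(path).read_text())
        return cls(**{k: data.get(k, {}) for k in ("image", "session", "screening", "atlas")})


SYNTHETIC_ADDRESS_MAP = AddressMap(
    image={
        "preset_name": "optics/presetName",
        "magnification": "optics/magnification",
        "pixel_size": "optics/pixelSizeAngstrom",
        "spot_size": "optics/spotSize",
        "c2_aperture": "optics/c2ApertureMicron",
        "objective_aperture": "optics/objectiveApertureMicron",
        "beam_diameter": "optics/beamDiameterMicron",
        "acceleration_voltage": "optics/accelerationVoltage",
        "defocus_min": "optics/nominalDefocusMinMicron",
        "defocus_max": "optics/nominalDefocusMaxMicron",
        "sensor_width": "optics/sensor/widthPixels",
        "sensor_height": "optics/sensor/heightPixels",
        "timestamp": "acquisition/dateTime",
        "applied_defocus": "acquisition/appliedDefocusMicron",
        "stage_x": "stage/positionXMicron",
        "stage_y": "stage/positionYMicron",
        "image_shift_x": "beamShift/xMicron",
        "image_shift_y": "beamShift/yMicron",
        "square_id": "context/gridSquareId",
        "hole_id": "context/foilHoleId",
        "acquisition_area_id": "context/acquisitionAreaId",
        "shot_index": "context/shotIndex",
    },
    session={
        "session_id": "name",
        "epu_version": "softwareVersion",
        "instrument_id": "instrumentId",
        "grid_type": "sample/gridType",
        "hole_diameter": "sample/holeDiameterMicron",
        "hole_spacing": "sample/holeSpacingMicron",
        "shots_per_hole": "strategy/shotsPerHole",
        "collection_mode": "strategy/collectionMode",
        "fraction_dose": "dose/fractionDosePerAngstrom2",
        "n_frames": "dose/numberOfFrames",
        "session_date": "startDateTime",
    },
    screening={
        "instrument_id": "instrumentId",
        "epu_version": "softwareVersion",
        "session_id": "sessionName",
        "n_grids": "gridInventory/count",
    },
    atlas={
        "atlas_id": "atlasId",
        "n_squares_available": "squares/totalCount",
    },
)


def build_xml(root_tag: str, values: Mapping[str, object]) -> bytes:
    """Serialize ``{element path: value}`` into nested XML bytes.

    Paths are slash-separated tag names below the root; shared prefixes
    share elements.  Values are written as text (floats via ``repr`` so
    the round trip is exact; None entries are skipped).
    """
    root = etree.Element(root_tag)
    for path, value in values.items():
        if value is None:
            continue
        node = root
        for tag in path.split("/"):
            child = node.find(tag)
            if child is None:
                child = etree.SubElement(node, tag)
            node = child
        node.text = repr(value) if isinstance(value, float) else str(value)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def query(tree: etree._ElementTree | etree._Element, path: str) -> Optional[str]:
    """Look up one address; None when the element is absent or empty."""
    root = tree.getroot() if hasattr(tree, "getroot") else tree
    node = root.find(path)
    if node is None or node.text is None:
        return None
    return node.text.strip()


def query_fields(path_or_tree, addresses: Mapping[str, str]) -> dict[str, Optional[str]]:
    """Query every address in a map against one XML file or element."""
    if isinstance(path_or_tree, (str, Path)):
        tree = etree.parse(str(path_or_tree))
    else:
        tree = path_or_tree
    return {name: query(tree, addr) for name, addr in addresses.items()}
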