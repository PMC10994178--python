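"""Collated CSV outputs, PDF reports, and the checksummed deposition JSON.

Four CSVs collate a session: ``*_datastructure.csv`` (per-micrograph
lineage and quality metrics), ``*_optics.csv`` (one row per optics
preset), ``*_processed.csv`` (per-micrograph preprocessing outcomes) and
``*_session.csv`` (one summary row).  The deposition JSON carries the
mandatory microscopy metadata of an archive deposition, written
canonically (sorted keys, fixed float formatting) with a SHA-256
sidecar checksum so integrity can be verified later.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .analytics import REDUCED_METRICS, SessionSummary
from .epu import OpticsPreset, ParsedSession, SessionConfig, lineage
from .metrics import MetricParameters, MicrographQuality, label_clustered
from .preproc import JoinedMicrograph

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class DepositionError(ValueError):
    """A mandatory deposition field could not be resolved."""


class DepositionRecord(BaseModel):
    """Mandatory microscopy metadata for an archive deposition.

    Field names follow the deposition-file convention verbatim
    (mixed case included) for archive compatibility.
    """

    model_config = ConfigDict(frozen=True)

    microscope: str
    epuversion: str
    date: str  # YYYY/MM/DD
    eV: float
    Mag: float
    Apix: float
    nominal_defocus_min_microns: float
    nominal_defocus_max_microns: float
    spot_size: int
    C2_micron: float
    Objective_micron: float
    beam_diameter_micron: float
    Collection: str
    number_of_images: int
    grid_type: str
    available_squares: int
    collected_squares: int
    average_foils_per_square: int
    hole_size_micron: float
    hole_space_micron: float
    shots_per_hole: int
    total_dose_eA2: float
    fraction_dose_eA2: float


# ---------------------------------------------------------------------------
# collated CSVs
# ---------------------------------------------------------------------------

def _lineage_names(session: ParsedSession, entry: JoinedMicrograph) -> dict:
    chain = lineage(entry.record, session)
    return {f"{lvl.level}_image": (lvl.image_path.name if lvl.image_path else "")
            for lvl in chain}


def _quality_columns(q: Optional[MicrographQuality]) -> dict:
    keys = ("motion_early", "motion_late", "motion_total", "ctf_max_resolution",
            "particle_diameter", "n_picks", "n_picks_accepted", "density",
            "clustered_fraction", "mean_class_resolution")
    return {k: (getattr(q, k) if q is not None else None) for k in keys}


def write_collated_csvs(session: ParsedSession,
                        entries: Sequence[JoinedMicrograph],
                        qualities: Mapping[str, MicrographQuality],
                        summary: SessionSummary,
                        out_prefix: Path | str,
                        have_preprocessing: bool = True) -> List[Path]:
    """Write the four collated CSVs; returns the paths written.

    Without preprocessing the ``*_processed.csv`` file is skipped with a
    notice and three paths are returned.  Absent values are written as
    empty fields; floats use 6 significant digits.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []

    rows = []
    for entry in entries:
        r = entry.record
        row = {
            "micrograph_id": r.micrograph_id,
            "square_id": r.square_id,
            "hole_id": r.hole_id,
            "acquisition_area_id": r.acquisition_area_id,
            "timestamp": r.timestamp.isoformat() if r.timestamp else "",
        }
        row.update(_lineage_names(session, entry))
        row.update(_quality_columns(qualities.get(entry.micrograph_id)))
        rows.append(row)
    datastructure = out_prefix.parent / f"{out_prefix.name}_datastructure.csv"
    pd.DataFrame(rows).to_csv(datastructure, index=False, float_format=_FLOAT_FMT)
    paths.append(datastructure)

    optics_rows = []
    for p in session.presets:
        optics_rows.append({
            "preset_name": p.preset_name,
            "magnification": p.magnification,
            "pixel_size_angstrom": p.pixel_size,
            "spot_size": p.spot_size,
            "c2_aperture_micron": p.c2_aperture,
            "objective_aperture_micron": p.objective_aperture,
            "beam_diameter_micron": p.beam_diameter,
            "defocus_min_micron": p.defocus_min,
            "defocus_max_micron": p.defocus_max,
            "acceleration_voltage": p.acceleration_voltage,
            "sensor_width_px": p.sensor_pixels[0] if p.sensor_pixels else None,
            "sensor_height_px": p.sensor_pixels[1] if p.sensor_pixels else None,
        })
    optics = out_prefix.parent / f"{out_prefix.name}_optics.csv"
    pd.DataFrame(optics_rows).to_csv(optics, index=False, float_format=_FLOAT_FMT)
    paths.append(optics)

    if have_preprocessing:
        proc_rows = []
        for entry in entries:
            q = qualities.get(entry.micrograph_id)
            row = {"micrograph_id": entry.micrograph_id,
                   "has_motion": entry.motion is not None,
                   "has_ctf": entry.ctf is not None,
                   "has_picks": entry.picks is not None,
                   "has_classes": entry.classes is not None}
            row.update(_quality_columns(q))
            proc_rows.append(row)
        processed = out_prefix.parent / f"{out_prefix.name}_processed.csv"
        pd.DataFrame(proc_rows).to_csv(processed, index=False,
                                       float_format=_FLOAT_FMT)
        paths.append(processed)
    else:
        logger.info("no preprocessing results; skipping _processed.csv")

    from .analytics import summary_to_row
    session_csv = out_prefix.parent / f"{out_prefix.name}_session.csv"
    srow = summary_to_row(summary)
    srow.update({
        "instrument_id": session.config.instrument_id,
        "epu_version": session.config.epu_version,
        "grid_type": session.config.grid_type,
        "hole_diameter_micron": session.config.hole_diameter,
        "hole_spacing_micron": session.config.hole_spacing,
        "shots_per_hole": session.config.shots_per_hole,
        "collection_mode": session.config.collection_mode,
    })
    pd.DataFrame([srow]).to_csv(session_csv, index=False, float_format=_FLOAT_FMT)
    paths.append(session_csv)
    return paths


# ---------------------------------------------------------------------------
# deposition JSON + checksum
# ---------------------------------------------------------------------------

def _ordered_defocus(preset: OpticsPreset) -> tuple:
    """Nominal defocus as (smaller magnitude, larger magnitude), signs kept."""
    values = [v for v in (preset.defocus_min, preset.defocus_max) if v is not None]
    if len(values) < 2:
        raise DepositionError("nominal defocus range incomplete")
    lo, hi = sorted(values, key=abs)
    return lo, hi


def build_deposition(summary: SessionSummary, config: SessionConfig,
                     presets: Sequence[OpticsPreset],
                     allow_partial: bool = False) -> DepositionRecord:
    """Assemble the deposition record from parsed and derived session data.

    ``total_dose_eA2`` is the frame count times the per-frame dose.  Any
    unresolvable mandatory field raises :class:`DepositionError` listing
    the missing names, unless ``allow_partial`` substitutes neutral
    placeholders (empty strings / -1).
    """
    acq = next((p for p in presets if p.preset_name == "acquisition"), None)
    missing: List[str] = []

    def need(value, name, default):
        if value is None:
            missing.append(name)
            return default
        return value

    if acq is None:
        missing.append("acquisition preset")
        acq = OpticsPreset(preset_name="acquisition")

    try:
        defocus_min, defocus_max = _ordered_defocus(acq)
    except DepositionError:
        missing.append("nominal_defocus_min/max_microns")
        defocus_min = defocus_max = -1.0

    date = config.session_date or summary.first_acquisition
    fraction_dose = config.fraction_dose
    n_frames = config.n_frames
    total_dose = (fraction_dose * n_frames
                  if fraction_dose is not None and n_frames is not None else None)

    record = dict(
        microscope=need(config.instrument_id, "microscope", ""),
        epuversion=need(config.epu_version, "epuversion", ""),
        date=date.strftime("%Y/%m/%d") if date is not None else need(None, "date", ""),
        eV=float(need(acq.acceleration_voltage, "eV", -1)),
        Mag=float(need(acq.magnification, "Mag", -1)),
        Apix=float(need(acq.pixel_size, "Apix", -1)),
        nominal_defocus_min_microns=float(defocus_min),
        nominal_defocus_max_microns=float(defocus_max),
        spot_size=int(need(acq.spot_size, "spot_size", -1)),
        C2_micron=float(need(acq.c2_aperture, "C2_micron", -1)),
        Objective_micron=float(need(acq.objective_aperture, "Objective_micron", -1)),
        beam_diameter_micron=float(need(acq.beam_diameter, "beam_diameter_micron", -1)),
        Collection=need(config.collection_mode, "Collection", ""),
        number_of_images=int(summary.n_micrographs),
        grid_type=need(config.grid_type, "grid_type", ""),
        available_squares=int(need(summary.n_squares_available, "available_squares", -1)),
        collected_squares=int(need(summary.n_squares_collected, "collected_squares", -1)),
        average_foils_per_square=int(need(summary.average_foils_per_square,
                                          "average_foils_per_square", -1)),
        hole_size_micron=float(need(config.hole_diameter, "hole_size_micron", -1)),
        hole_space_micron=float(need(config.hole_spacing, "hole_space_micron", -1)),
        shots_per_hole=int(need(config.shots_per_hole, "shots_per_hole", -1)),
        total_dose_eA2=float(need(total_dose, "total_dose_eA2", -1)),
        fraction_dose_eA2=float(need(fraction_dose, "fraction_dose_eA2", -1)),
    )
    if missing and not allow_partial:
        raise DepositionError(
            "cannot build deposition record; missing mandatory fields: "
            + ", ".join(missing))
    return DepositionRecord(**record)


def _canonical_json(record: DepositionRecord) -> bytes:
    payload = record.model_dump()

    def default(o):
        raise TypeError(o)

    text = json.dumps(payload, sort_keys=True, indent=1, ensure_ascii=False,
                      default=default)
    return (text + "\n").encode("utf-8")


def write_deposition_json(record: DepositionRecord,
                          out: Path | str) -> tuple[Path, Path]:
    """Write canonical JSON plus a ``<digest>  <filename>`` SHA-256 sidecar."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    data = _canonical_json(record)
    out.write_bytes(data)
    digest = hashlib.sha256(data).hexdigest()
    checksum_path = out.with_suffix(out.suffix + ".sha256")
    checksum_path.write_text(f"{digest}  {out.name}\n")
    return out, checksum_path


@dataclass
class VerificationResult:
    ok: bool
    expected: str
    actual: str
    json_path: Path


def verify_deposition_json(json_path: Path | str,
                           checksum_path: Optional[Path | str] = None,
                           ) -> VerificationResult:
    """Recompute the SHA-256 digest and compare with the sidecar."""
    json_path = Path(json_path)
    if checksum_path is None:
        checksum_path = json_path.with_suffix(json_path.suffix + ".sha256")
    expected = Path(checksum_path).read_text().split()[0]
    actual = hashlib.sha256(json_path.read_bytes()).hexdigest()
    return VerificationResult(ok=(expected == actual), expected=expected,
                              actual=actual, json_path=json_path)


# ---------------------------------------------------------------------------
# PDF reports
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    """Rendered report paths plus the text items placed in each document."""

    session_pdf: Optional[Path]
    processed_pdf: Optional[Path]
    content: Dict[str, List[str]] = field(default_factory=dict)


def _fmt_value(v) -> str:
    if v is None:
        return "-"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def render_reports(session: ParsedSession,
                   entries: Sequence[JoinedMicrograph],
                   qualities: Mapping[str, MicrographQuality],
                   summary: SessionSummary,
                   out_prefix: Path | str,
                   params: MetricParameters = MetricParameters()) -> ReportBundle:
    """Render the session and processed PDF reports.

    The session report carries the configuration, optics table, targeting
    statistics and rates; the processed report shows the six metric
    distributions (early/late motion, density, clustering, CTF
    resolution, class resolution) and a representative pick-overlay
    figure with clustered picks highlighted.  Without any computed
    metrics the processed report is skipped with a notice.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    config = session.config
    content: Dict[str, List[str]] = {"session": [], "processed": []}

    session_pdf = out_prefix.parent / f"{out_prefix.name}_session.pdf"
    session_lines = [
        ("Session", _fmt_value(config.session_id)),
        ("Instrument", _fmt_value(config.instrument_id)),
        ("Acquisition software version", _fmt_value(config.epu_version)),
        ("Collection mode", _fmt_value(config.collection_mode)),
        ("Grid type", _fmt_value(config.grid_type)),
        ("Hole size / spacing (um)",
         f"{_fmt_value(config.hole_diameter)} / {_fmt_value(config.hole_spacing)}"),
        ("Shots per hole", _fmt_value(config.shots_per_hole)),
        ("Available / targeted / collected squares",
         f"{_fmt_value(summary.n_squares_available)} / "
         f"{_fmt_value(summary.n_squares_targeted)} / "
         f"{_fmt_value(summary.n_squares_collected)}"),
        ("Average foil holes per square",
         _fmt_value(summary.average_foils_per_square)),
        ("Collected images", _fmt_value(summary.n_micrographs)),
        ("Rate (micrographs/h)", _fmt_value(summary.rate_micrographs_per_hour)),
        ("Rate (um^2/h)", _fmt_value(summary.rate_area_per_hour)),
        ("Collected area (um^2)", _fmt_value(summary.collected_area)),
        ("First acquisition", _fmt_value(
            summary.first_acquisition.isoformat() if summary.first_acquisition else None)),
        ("Last acquisition", _fmt_value(
            summary.last_acquisition.isoformat() if summary.last_acquisition else None)),
    ]
    with PdfPages(session_pdf) as pdf:
        fig, ax = plt.subplots(figsize=(8.27, 11.69))
        ax.axis("off")
        ax.set_title("Data-collection session report", loc="left", fontsize=14)
        y = 0.95
        for label, value in session_lines:
            text = f"{label}: {value}"
            ax.text(0.02, y, text, transform=ax.transAxes, fontsize=10,
                    family="monospace")
            content["session"].append(text)
            y -= 0.025
        pdf.savefig(fig)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(8.27, 11.69))
        ax.axis("off")
        ax.set_title("Optics presets", loc="left", fontsize=14)
        cols = ["preset", "magnification", "pixel size (A)", "beam (um)",
                "defocus (um)"]
        cell_rows = [[p.preset_name, _fmt_value(p.magnification),
                      _fmt_value(p.pixel_size), _fmt_value(p.beam_diameter),
                      f"{_fmt_value(p.defocus_min)}..{_fmt_value(p.defocus_max)}"]
                     for p in session.presets]
        if cell_rows:
            table = ax.table(cellText=cell_rows, colLabels=cols, loc="upper left")
            table.scale(1, 1.4)
            for row in cell_rows:
                content["session"].append(" ".join(row))
        pdf.savefig(fig)
        plt.close(fig)

    metric_values: Dict[str, List[float]] = {}
    for q in qualities.values():
        for metric in ("motion_early", "motion_late", "density",
                       "clustered_fraction", "ctf_max_resolution",
                       "mean_class_resolution"):
            v = getattr(q, metric)
            if v is not None and np.isfinite(v):
                metric_values.setdefault(metric, []).append(float(v))

    processed_pdf: Optional[Path] = None
    if metric_values:
        processed_pdf = out_prefix.parent / f"{out_prefix.name}_processed.pdf"
        panel_labels = {
            "motion_early": "Early motion (A)",
            "motion_late": "Late motion (A)",
            "density": "Normalized particle density",
            "clustered_fraction": "Clustered particle fraction",
            "ctf_max_resolution": "CTF max resolution (A)",
            "mean_class_resolution": "Mean 2D-class resolution (A)",
        }
        with PdfPages(processed_pdf) as pdf:
            fig, axes = plt.subplots(3, 2, figsize=(8.27, 11.69))
            for ax, (metric, label) in zip(axes.ravel(), panel_labels.items()):
                values = metric_values.get(metric, [])
                if values:
                    ax.hist(values, bins=min(30, max(5, len(values) // 5)),
                            color="#4878cf", edgecolor="black", linewidth=0.4)
                ax.set_xlabel(label, fontsize=8)
                ax.set_ylabel("micrographs", fontsize=8)
                ax.tick_params(labelsize=7)
                content["processed"].append(label)
            fig.suptitle("Preprocessing outcome distributions")
            fig.tight_layout(rect=(0, 0, 1, 0.97))
            pdf.savefig(fig)
            plt.close(fig)

            overlay = _best_pick_overlay(entries, params)
            if overlay is not None:
                entry, centres, flags = overlay
                fig, ax = plt.subplots(figsize=(7, 5))
                ax.scatter(centres[~flags, 0], centres[~flags, 1], s=12,
                           facecolors="none", edgecolors="#4878cf",
                           label="picks")
                if flags.any():
                    ax.scatter(centres[flags, 0], centres[flags, 1], s=12,
                               facecolors="none", edgecolors="red",
                               label="clustered")
                title = f"Particle picks: {entry.micrograph_id}"
                ax.set_title(title, fontsize=9)
                ax.set_xlabel("x (px)")
                ax.set_ylabel("y (px)")
                ax.legend(fontsize=7)
                ax.set_aspect("equal")
                content["processed"].append(title)
                pdf.savefig(fig)
                plt.close(fig)
    else:
        logger.info("no metrics available; skipping processed report")

    return ReportBundle(session_pdf=session_pdf, processed_pdf=processed_pdf,
                        content=content)


def _best_pick_overlay(entries: Sequence[JoinedMicrograph],
                       params: MetricParameters):
    """The pickset with the most picks, with centres and clustered flags."""
    from .metrics import mean_particle_diameter

    best = None
    for entry in entries:
        if entry.picks is not None and len(entry.picks) > 0:
            if best is None or len(entry.picks) > len(best.picks):
                best = entry
    if best is None:
        return None
    diameter = mean_particle_diameter(best.picks)
    if diameter is None or best.picks.pixel_size is None:
        return None
    flags = label_clustered(best.picks, diameter, params)
    return best, best.picks.centres_px(), flags
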