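"""Session-level statistics, location-based grouping, facility aggregation.

Reduces per-micrograph quality metrics to a single summary per session
(collection rates, targeting statistics, mean/min/max of every metric),
splits the same reductions by specimen location (grid square or shot
position within a foil hole), and aggregates summaries across the
facility-wide ``instrument/year/Data/visit`` tree with per-metric
histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .epu import OpticsPreset, ParsedSession, SessionConfig, parse_session
from .metrics import MetricParameters, MicrographQuality, compute_all_qualities
from .preproc import JoinedMicrograph, join_to_session, parse_preprocessing

logger = logging.getLogger(__name__)

REDUCED_METRICS = ("motion_total", "ctf_max_resolution", "density",
                   "clustered_fraction", "mean_class_resolution")

Reduction = Tuple[float, float, float]  # mean, min, max


class AnalyticsError(ValueError):
    pass


@dataclass
class SessionSummary:
    session_id: Optional[str]
    n_micrographs: int
    first_acquisition: Optional[datetime] = None
    last_acquisition: Optional[datetime] = None
    rate_micrographs_per_hour: Optional[float] = None
    rate_area_per_hour: Optional[float] = None  # µm² h⁻¹
    collected_area: Optional[float] = None  # µm²
    n_squares_available: Optional[int] = None
    n_squares_targeted: Optional[int] = None
    n_squares_collected: Optional[int] = None
    average_foils_per_square: Optional[int] = None
    reductions: Dict[str, Reduction] = field(default_factory=dict)


@dataclass
class LocationGroupStats:
    grouping: str  # atlas | grid_square | hole_position
    group_key: str
    n_micrographs: int
    reductions: Dict[str, Reduction] = field(default_factory=dict)


def _reduce(qualities: Sequence[MicrographQuality]) -> Dict[str, Reduction]:
    """mean/min/max per metric over the micrographs where it is present."""
    out: Dict[str, Reduction] = {}
    for metric in REDUCED_METRICS:
        values = [getattr(q, metric) for q in qualities]
        values = [v for v in values if v is not None and np.isfinite(v)]
        if values:
            arr = np.asarray(values, dtype=float)
            out[metric] = (float(arr.mean()), float(arr.min()), float(arr.max()))
    return out


def summarize_session(entries: Sequence[JoinedMicrograph],
                      config: SessionConfig,
                      preset: Optional[OpticsPreset],
                      qualities: Optional[Mapping[str, MicrographQuality]] = None,
                      n_targeted_holes: Optional[int] = None) -> SessionSummary:
    """Reduce a session to one row of rates, targeting stats and metrics.

    The micrograph rate is (N − 1) / span where span is the time between
    the first and last acquisition (the inter-acquisition span, not wall
    clock including setup); the area rate multiplies it by the
    field-of-view area of the acquisition preset.  With fewer than two
    timestamped micrographs the rates are absent.
    """
    timestamps = sorted(e.record.timestamp for e in entries
                        if e.record.timestamp is not None)
    n = len(entries)
    summary = SessionSummary(session_id=config.session_id, n_micrographs=n)
    summary.n_squares_available = config.n_squares_available
    summary.n_squares_targeted = config.n_squares_targeted
    summary.n_squares_collected = config.n_squares_collected

    fov = preset.field_of_view_um2() if preset is not None else None
    if timestamps:
        summary.first_acquisition = timestamps[0]
        summary.last_acquisition = timestamps[-1]
    if len(timestamps) >= 2:
        span_hours = (timestamps[-1] - timestamps[0]).total_seconds() / 3600.0
        if span_hours <= 0:
            raise AnalyticsError(
                "acquisition timestamps span zero time across >=2 micrographs")
        summary.rate_micrographs_per_hour = (len(timestamps) - 1) / span_hours
        if fov is not None:
            summary.rate_area_per_hour = summary.rate_micrographs_per_hour * fov
    else:
        logger.info("fewer than two timestamped micrographs; rates absent")
    if fov is not None:
        summary.collected_area = n * fov

    if n_targeted_holes is None:
        holes = {e.record.hole_id for e in entries if e.record.hole_id}
        n_targeted_holes = len(holes) if holes else None
    if n_targeted_holes and config.n_squares_collected:
        summary.average_foils_per_square = int(round(
            n_targeted_holes / config.n_squares_collected))

    if qualities:
        summary.reductions = _reduce([qualities[e.micrograph_id] for e in entries
                                      if e.micrograph_id in qualities])
    return summary


def _hole_position_label(entry: JoinedMicrograph,
                         shots_per_hole: Optional[int]) -> Optional[str]:
    """Shot-position label within the foil hole.

    For the common 2-shot strategy the within-hole beam-shift offset
    gives a geometric top/bottom label (positive y = top); otherwise the
    template shot index is used.
    """
    record = entry.record
    if shots_per_hole == 2 and record.image_shift is not None:
        return "top" if record.image_shift[1] >= 0 else "bottom"
    if record.shot_index is not None:
        return f"shot_{record.shot_index}"
    if record.image_shift is not None:
        return "top" if record.image_shift[1] >= 0 else "bottom"
    return None


def group_by_location(entries: Sequence[JoinedMicrograph],
                      grouping: str,
                      qualities: Mapping[str, MicrographQuality],
                      shots_per_hole: Optional[int] = None,
                      ) -> List[LocationGroupStats]:
    """Partition micrographs by specimen location and reduce each group.

    ``grouping`` is one of ``atlas`` (one group: the whole grid),
    ``grid_square`` or ``hole_position``.  Groups are disjoint and cover
    every entry; an entry whose location cannot be resolved falls into an
    ``unresolved`` group, and more than 50% unresolved raises
    :class:`AnalyticsError`.
    """
    if grouping not in {"atlas", "grid_square", "hole_position"}:
        raise ValueError(f"unknown grouping: {grouping!r}")
    buckets: Dict[str, List[JoinedMicrograph]] = {}
    n_unresolved = 0
    for entry in entries:
        if grouping == "atlas":
            key = "atlas"
        elif grouping == "grid_square":
            key = entry.record.square_id or None
        else:
            key = _hole_position_label(entry, shots_per_hole)
        if key is None:
            key = "unresolved"
            n_unresolved += 1
        buckets.setdefault(key, []).append(entry)
    if entries and n_unresolved > 0.5 * len(entries):
        raise AnalyticsError(
            f"{n_unresolved}/{len(entries)} micrographs have no resolvable "
            f"{grouping} location; repair the lineage metadata first")
    stats = []
    for key in sorted(buckets):
        members = buckets[key]
        stats.append(LocationGroupStats(
            grouping=grouping, group_key=key, n_micrographs=len(members),
            reductions=_reduce([qualities[e.micrograph_id] for e in members
                                if e.micrograph_id in qualities])))
    return stats


# ---------------------------------------------------------------------------
# facility aggregation
# ---------------------------------------------------------------------------

def summary_to_row(summary: SessionSummary, instrument: Optional[str] = None,
                   year: Optional[int] = None, visit: Optional[str] = None) -> dict:
    row = {
        "instrument": instrument,
        "year": year,
        "visit": visit,
        "session_id": summary.session_id,
        "n_micrographs": summary.n_micrographs,
        "rate_micrographs_per_hour": summary.rate_micrographs_per_hour,
        "rate_area_um2_per_hour": summary.rate_area_per_hour,
        "collected_area_um2": summary.collected_area,
        "n_squares_available": summary.n_squares_available,
        "n_squares_targeted": summary.n_squares_targeted,
        "n_squares_collected": summary.n_squares_collected,
        "average_foils_per_square": summary.average_foils_per_square,
        "first_acquisition": summary.first_acquisition,
        "last_acquisition": summary.last_acquisition,
    }
    for metric in REDUCED_METRICS:
        red = summary.reductions.get(metric)
        row[f"{metric}_mean"] = red[0] if red else None
        row[f"{metric}_min"] = red[1] if red else None
        row[f"{metric}_max"] = red[2] if red else None
    return row


HISTOGRAM_METRICS = ("rate_micrographs_per_hour", "rate_area_um2_per_hour",
                     "motion_total_mean", "ctf_max_resolution_mean",
                     "density_mean", "clustered_fraction_mean",
                     "mean_class_resolution_mean")


@dataclass
class AggregateResult:
    table: pd.DataFrame  # one row per parseable visit
    failures: List[Tuple[str, str]]  # (visit path, reason)
    histogram_paths: List[Path] = field(default_factory=list)


def analyze_one_visit(visit_dir: Path,
                      params: MetricParameters = MetricParameters(),
                      ) -> SessionSummary:
    """Parse, join and summarize a single visit directory."""
    session = parse_session(visit_dir)
    proc_root = visit_dir / "processed" / "raw" / "relion"
    entries: Sequence[JoinedMicrograph]
    qualities: Dict[str, MicrographQuality] = {}
    preset = session.preset("acquisition")
    if proc_root.is_dir() and any(proc_root.iterdir()):
        preproc = parse_preprocessing(proc_root)
        joined = join_to_session(session.records, preproc)
        entries = joined.entries
        qualities = compute_all_qualities(entries, preset, params)
    else:
        entries = [JoinedMicrograph(record=r) for r in session.records]
    return summarize_session(entries, session.config, preset, qualities,
                             n_targeted_holes=len(session.hole_images) or None)


def aggregate_visits(facility_root: Path | str,
                     filters: Optional[Mapping[str, object]] = None,
                     out_dir: Optional[Path | str] = None,
                     params: MetricParameters = MetricParameters(),
                     ) -> AggregateResult:
    """Summarize every visit under ``instrument/year/Data/visit``.

    ``filters`` may restrict ``instrument`` (exact), ``year`` (int) and
    ``since`` (ISO date; keeps visits whose first acquisition is on or
    after it).  When ``out_dir`` is given a PNG histogram is written for
    each reduced metric using Freedman-Diaconis binning.
    """
    root = Path(facility_root)
    filters = dict(filters or {})
    rows: List[dict] = []
    failures: List[Tuple[str, str]] = []
    visit_dirs: List[Tuple[str, int, Path]] = []
    for instrument_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        if filters.get("instrument") not in (None, instrument_dir.name):
            continue
        for year_dir in sorted(p for p in instrument_dir.iterdir() if p.is_dir()):
            try:
                year = int(year_dir.name)
            except ValueError:
                continue
            if filters.get("year") not in (None, year):
                continue
            data_dir = year_dir / "Data"
            if not data_dir.is_dir():
                continue
            for visit in sorted(p for p in data_dir.iterdir() if p.is_dir()):
                visit_dirs.append((instrument_dir.name, year, visit))
    if not visit_dirs:
        raise AnalyticsError(
            f"no visits found under {root}; expected the layout "
            "<instrument>/<year>/Data/<visit>/<session tree>")

    since = filters.get("since")
    if isinstance(since, str):
        since = datetime.fromisoformat(since)
    for instrument, year, visit in visit_dirs:
        try:
            summary = analyze_one_visit(visit, params)
        except Exception as exc:  # any per-visit failure is reported, not fatal
            failures.append((str(visit), str(exc)))
            continue
        if since is not None and summary.first_acquisition is not None:
            first = summary.first_acquisition
            ref = since if since.tzinfo else since.replace(tzinfo=first.tzinfo)
            if first < ref:
                continue
        rows.append(summary_to_row(summary, instrument, year, visit.name))

    table = pd.DataFrame(rows)
    result = AggregateResult(table=table, failures=failures)
    if out_dir is not None and not table.empty:
        result.histogram_paths = write_metric_histograms(table, Path(out_dir))
    return result


def freedman_diaconis_bins(values: np.ndarray) -> int:
    """Bin count by the Freedman-Diaconis rule (>= 1, capped at 200)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        return 1
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    if iqr <= 0:
        return 1
    width = 2.0 * iqr / values.size ** (1.0 / 3.0)
    span = float(values.max() - values.min())
    if span <= 0 or width <= 0:
        return 1
    return int(np.clip(np.ceil(span / width), 1, 200))


def write_metric_histograms(table: pd.DataFrame, out_dir: Path) -> List[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for metric in HISTOGRAM_METRICS:
        if metric not in table.columns:
            continue
        values = pd.to_numeric(table[metric], errors="coerce").dropna().to_numpy()
        if values.size == 0:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(values, bins=freedman_diaconis_bins(values),
                color="#4878cf", edgecolor="black", linewidth=0.4)
        ax.set_xlabel(metric)
        ax.set_ylabel("sessions")
        fig.tight_layout()
        path = out_dir / f"hist_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
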