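"""Per-micrograph quality metrics.

For each micrograph the preprocessing results are reduced to a compact
quality description: beam-induced motion partitioned into early and late
components at a cumulative-dose boundary, CTF maximum resolution, the
mean picked-particle diameter, a particle density normalised so that 1
is ideal packing of the field of view, the fraction of particles whose
nearest neighbour sits closer than a set fraction of the particle
diameter ("clustered"), and the pick-weighted mean resolution of the 2D
classes the particles fall into.

Conventions
-----------
* Density counts only picks whose confidence score is strictly above the
  score threshold (default 0.3), excluding likely false positives; the
  same filter is applied to clustering by default (configurable).
* Ideal packing approximates each particle by a square of side equal to
  its circular diameter: density = N · d² / A_fov.  Values above 1 are
  reported as-is (over-dense picking is a diagnostic signal).
* A movie frame belongs to the early partition when its end-of-frame
  cumulative dose is ≤ the dose boundary (default 4 e⁻ Å⁻²), so with
  1 e⁻ Å⁻² frames the early motion covers exactly the first 4 frames.
* All distances are computed in Å (pixel coordinates × pixel size), so
  thresholds are magnification-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .epu import OpticsPreset
from .preproc import ClassAssignment, JoinedMicrograph, MotionTrace, PickSet

_DOSE_EPS = 1e-9  # absorb float noise at the early/late dose boundary


@dataclass(frozen=True)
class MetricParameters:
    """Tunable thresholds for the quality metrics."""

    score_threshold: float = 0.3  # picks must score strictly above this
    clustering_factor: float = 0.8  # fraction of the diameter
    early_dose_threshold: float = 4.0  # e⁻ Å⁻²
    filter_clustering_by_score: bool = True

    def __post_init__(self):
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")
        if not 0.0 < self.clustering_factor <= 1.0:
            raise ValueError("clustering_factor must be in (0, 1]")
        if self.early_dose_threshold <= 0:
            raise ValueError("early_dose_threshold must be positive")


@dataclass
class MicrographQuality:
    """Derived quality metrics for one micrograph; absent metrics are None."""

    micrograph_id: str
    motion_early: Optional[float] = None  # Å
    motion_late: Optional[float] = None
    motion_total: Optional[float] = None
    ctf_max_resolution: Optional[float] = None  # Å
    particle_diameter: Optional[float] = None  # Å
    n_picks: Optional[int] = None
    n_picks_accepted: Optional[int] = None
    density: Optional[float] = None  # 1 = ideal packing
    clustered_fraction: Optional[float] = None
    mean_class_resolution: Optional[float] = None  # Å


def accepted_mask(pickset: PickSet, params: MetricParameters) -> np.ndarray:
    """Boolean mask of picks scoring strictly above the threshold."""
    if pickset.picks.empty:
        return np.zeros(0, dtype=bool)
    scores = pickset.picks["score"].to_numpy(float)
    return scores > params.score_threshold


def mean_particle_diameter(pickset: PickSet) -> Optional[float]:
    """Arithmetic mean of per-pick estimated diameters, in Å.

    Returns None (never zero) when there are no picks, so downstream
    density/clustering propagate as absent.
    """
    if pickset.picks.empty:
        return None
    if pickset.pixel_size is None:
        raise ValueError("pixel size required to express the diameter in Å")
    est = pickset.picks["est_diameter"].to_numpy(float)
    est = est[np.isfinite(est)]
    if est.size == 0:
        return None
    return float(np.mean(est) * pickset.pixel_size)


def clustering_threshold(diameter: float, params: MetricParameters = MetricParameters()) -> float:
    """Distance below which two particles count as clustered, in Å."""
    if diameter is None or diameter <= 0:
        raise ValueError("particle diameter must be positive")
    return params.clustering_factor * diameter


def label_clustered(pickset: PickSet, diameter: float,
                    params: MetricParameters = MetricParameters()) -> np.ndarray:
    """Flag each pick whose nearest-neighbour distance is below threshold.

    Distances are Euclidean in Å between particle centres.  With fewer
    than two (score-accepted) picks all flags are False.  The returned
    array is aligned with the pickset rows; score-rejected picks are
    False when the score filter is enabled.
    """
    n = len(pickset.picks)
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    if pickset.pixel_size is None:
        raise ValueError("pixel size required for distances in Å")
    mask = accepted_mask(pickset, params) if params.filter_clustering_by_score \
        else np.ones(n, dtype=bool)
    centres = pickset.centres_px()[mask] * pickset.pixel_size
    if len(centres) < 2:
        return flags
    threshold = clustering_threshold(diameter, params)
    tree = cKDTree(centres)
    dist, _ = tree.query(centres, k=2)
    flags[np.flatnonzero(mask)] = dist[:, 1] < threshold
    return flags


def particle_density(pickset: PickSet, diameter: float, preset: OpticsPreset,
                     params: MetricParameters = MetricParameters()) -> float:
    """Pick density normalised to ideal packing of the field of view.

    density = N_accepted / (A_fov / d²) where A_fov is the magnified
    sensor area in Å² and d the measured particle diameter in Å.
    """
    if diameter is None or diameter <= 0:
        raise ValueError("particle diameter must be positive")
    if preset.sensor_pixels is None or not preset.pixel_size:
        raise ValueError("sensor geometry required for the field-of-view area")
    w_px, h_px = preset.sensor_pixels
    area = (w_px * preset.pixel_size) * (h_px * preset.pixel_size)
    if area <= 0:
        raise ValueError("field-of-view area must be positive")
    n_accepted = int(accepted_mask(pickset, params).sum())
    return n_accepted * diameter ** 2 / area


def split_motion(trace: MotionTrace,
                 params: MetricParameters = MetricParameters(),
                 ) -> Tuple[float, float, float]:
    """Partition total motion into (early, late, total) at the dose boundary.

    Frame i (1-based) contributes to the early partition iff its
    end-of-frame cumulative dose i × fraction_dose is ≤ the boundary;
    early + late = total exactly since the partitions are disjoint.
    """
    if trace.fraction_dose is None or trace.fraction_dose <= 0:
        raise ValueError("fraction dose must be positive to partition motion")
    shifts = np.asarray(trace.per_frame_shift, dtype=float)
    if shifts.size == 0:
        raise ValueError("motion trace has no frames")
    frame_end_dose = np.arange(1, shifts.size + 1) * trace.fraction_dose
    early_mask = frame_end_dose <= params.early_dose_threshold + _DOSE_EPS
    early = float(shifts[early_mask].sum())
    late = float(shifts[~early_mask].sum())
    return early, late, early + late


def mean_class_resolution(assignment: ClassAssignment) -> Optional[float]:
    """Pick-weighted mean resolution of the classes the picks fall into."""
    if not assignment.per_pick_class:
        return None
    try:
        values = [assignment.class_resolution[c] for c in assignment.per_pick_class]
    except KeyError as exc:
        raise ValueError(f"class {exc.args[0]} has no resolution entry") from exc
    return float(np.mean(values))


def compute_quality(entry: JoinedMicrograph, preset: Optional[OpticsPreset],
                    params: MetricParameters = MetricParameters()) -> MicrographQuality:
    """Reduce one joined micrograph to its :class:`MicrographQuality`."""
    q = MicrographQuality(micrograph_id=entry.micrograph_id)
    if entry.motion is not None and entry.motion.per_frame_shift:
        q.motion_early, q.motion_late, q.motion_total = split_motion(
            entry.motion, params)
    if entry.ctf is not None:
        q.ctf_max_resolution = entry.ctf.max_resolution
    if entry.picks is not None:
        q.n_picks = len(entry.picks)
        q.n_picks_accepted = int(accepted_mask(entry.picks, params).sum())
        diameter = mean_particle_diameter(entry.picks)
        q.particle_diameter = diameter
        if diameter is not None:
            if preset is not None and preset.sensor_pixels is not None:
                q.density = particle_density(entry.picks, diameter, preset, params)
            flags = label_clustered(entry.picks, diameter, params)
            considered = accepted_mask(entry.picks, params) \
                if params.filter_clustering_by_score else np.ones(len(flags), bool)
            if considered.any():
                q.clustered_fraction = float(flags[considered].mean())
    if entry.classes is not None:
        q.mean_class_resolution = mean_class_resolution(entry.classes)
    return q


def compute_all_qualities(entries: Sequence[JoinedMicrograph],
                          preset: Optional[OpticsPreset],
                          params: MetricParameters = MetricParameters(),
                          ) -> Dict[str, MicrographQuality]:
    """Quality metrics for every entry, keyed by micrograph id."""
    return {e.micrograph_id: compute_quality(e, preset, params) for e in entries}
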