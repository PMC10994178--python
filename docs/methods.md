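# Methods

`epumine` mines metadata from single-particle cryoEM data-collection
sessions. This note records the models and conventions behind each
computation, the choices made where the problem was genuinely open, and
what the synthetic-data generator does and does not emulate.

## The session data model

A single-particle acquisition is a targeting exercise over a hierarchy
of progressively higher-magnification images: one **atlas** of the whole
grid, **grid-square** images, **foil-hole** images, and finally the
high-magnification **acquisition** exposures (micrographs), each saved
as a movie of dose-fractionated frames. The collection software writes
one XML metadata file per image and session-level XML (`.dm`) files:
`ScreeningSession.dm` (instrument, software version, grid inventory),
`EpuSession.dm` (grid type, hole geometry, shot strategy, dose
settings) and `Atlas.dm` (total squares available on the atlas).

Micrograph identity is taken from the filename grammar
`FoilHole_[Hole-ID]_Data_[Acquisition-ID]_[date]_[time]`; square IDs
come from the enclosing `GridSquare_[Square-ID]` directory. Filenames
are authoritative for IDs; XML-embedded IDs are cross-checked and a
mismatch is logged, not fatal. Timestamps are read from the XML when
present and fall back to the filename `[date]_[time]` (interpreted as
UTC).

Because the vendor XML schema is version-dependent and undocumented,
every element lookup goes through an **address map** (semantic field →
slash-separated element path). The package ships one map for its own
synthetic dialect (`epumine.dialect.SYNTHETIC_ADDRESS_MAP`); adapting
to a real dialect means supplying an alternative JSON map
(`--address-map`), not changing code.

Derived targeting counts are defined as:

* `n_squares_targeted` — squares with at least one targeted foil-hole
  image;
* `n_squares_collected` — squares with at least one acquired
  micrograph;
* `average_foils_per_square` — distinct targeted foil holes divided by
  collected squares, rounded to the nearest integer. Collected (not
  available) squares are the denominator; that is the only reading
  under which a session with 62 available squares, 3 collected and
  140 foils per square is internally consistent at ordinary session
  sizes.

## Per-micrograph quality metrics

**Motion split.** Beam-induced motion is summed from per-frame shift
magnitudes (Å). Frame *i* (1-based) belongs to the *early* partition
iff its end-of-frame cumulative dose `i × fraction_dose` is ≤ the dose
boundary (default 4 e⁻ Å⁻², the convention used by common motion
correction pipelines); all later frames are *late*. The boundary is
closed so that with 1 e⁻ Å⁻² frames the early window covers exactly
frames 1–4; a 1e-9 e⁻ Å⁻² tolerance absorbs float noise at an exactly
divisible boundary. Early + late = total holds exactly because the
partitions are disjoint sums.

**Particle diameter.** The arithmetic mean of the per-pick estimated
diameters reported by the crYOLO picker in its CBOX files, converted
to Å with the acquisition pixel size. No picks → the diameter is
*absent* (never zero), and density/clustering propagate as absent.

**Density.** Picks whose confidence score is *strictly above* the
score threshold (default 0.3, the usual false-positive cutoff for
crYOLO) are counted; a score of exactly 0.3 is excluded. The particle
is approximated by a square of side equal to its circular diameter
*d*, so ideal packing of the magnified sensor area `A_fov` holds
`A_fov / d²` particles, and

```
density = N_accepted · d² / A_fov,        A_fov = (w_px·apix)(h_px·apix) Å².
```

Density is deliberately not clamped at 1: values above 1 flag
over-dense picking.

**Clustering.** A pick is *clustered* when the Euclidean distance to
its nearest neighbouring pick is below `clustering_factor × d`
(default 0.8, i.e. 80% of the measured diameter; for d = 136 Å that is
108.8 ≈ 109 Å). Distances are computed between particle centres
(CBOX corner + box/2) in Å, making the threshold
magnification-independent. The nearest-neighbour search uses a k-d
tree; the contract is exactness, and the test suite checks equality
against an O(n²) all-pairs oracle. By default the same 0.3 score
filter applies before clustering (configurable via
`filter_clustering_by_score`): whether the upstream tool filters
before clustering is not documented, so the package makes one choice
and exposes the switch. Note the picker itself already suppresses some
overlapping picks, so measured clustering can underestimate true
aggregation; this is a measurement caveat, not something the package
corrects.

**Class resolution.** The mean over *picks* (not over classes) of the
estimated resolution of the 2D class each pick was assigned to, so
well-populated classes dominate, matching the intent of a per-
micrograph particle-quality score.

## Session statistics

* Rate (micrographs h⁻¹) = `(N − 1) / span` with span the time between
  the first and last acquisition. This is the inter-acquisition rate;
  setup time before the first exposure is deliberately excluded since
  the quantity measures collection performance. N ≤ 1 → rates absent;
  a zero span with N ≥ 2 is treated as timestamp pathology and raises.
* Area rate (µm² h⁻¹) = rate × field of view of the acquisition preset;
  collected area = N × field of view. All acquired micrographs count,
  whether or not they survive downstream filtering.
* Metric reductions report (mean, min, max) over the micrographs where
  the metric is present; absent metrics are excluded, never imputed.

**Location grouping.** Metrics can be partitioned by grid square or by
shot position within the foil hole. For the common 2-shot strategy the
within-hole beam-shift offset labels exposures *top*/*bottom* (sign of
the y-offset); otherwise the template shot index is used. Groups are
disjoint and cover the session; >50% unresolvable locations raises an
error recommending lineage repair.

**Facility aggregation** walks the `instrument/year/Data/visit` layout,
summarizes each visit independently (failures are reported per visit,
never fatal) and writes per-metric histograms with Freedman–Diaconis
binning (capped at 200 bins).

## Outputs

Four CSVs per session (`*_datastructure.csv` per-micrograph lineage +
quality, `*_optics.csv` one row per preset, `*_processed.csv`
preprocessing outcomes, `*_session.csv` one summary row); comma
separated, UTF-8, header row, absent values as empty fields, floats at
6 significant digits.

The deposition JSON carries the mandatory microscopy metadata
(microscope, software version, optics, targeting statistics, dose)
with archive-convention field names (`eV`, `Mag`, `Apix`,
`total_dose_eA2`, ...). `total_dose_eA2` is defined as
`n_frames × fraction_dose`. Nominal defocus is stored signed (negative
= underfocus) with min = the smaller magnitude. The JSON is canonical
— sorted keys, fixed float formatting, UTF-8, trailing newline — so
identical inputs give byte-identical files, and a sidecar
`<sha256>  <filename>` checksum supports later integrity verification
(`epumine verify`, exit code 2 on failure).

PDF reports (session configuration/outcome and preprocessing
distributions with a pick-overlay figure, clustered picks in red) are
rendered with matplotlib's PDF backend. Layout is unspecified by
design; the content contract is the list of text items returned in
`ReportBundle.content`, which the tests assert against.

## The synthetic-session generator

`epumine.synthetic` fabricates complete session + preprocessing trees
from a `Scenario`. Default scenario values describe a representative
300 kV Krios AFIS session: 254 images over 3 collected squares of 62
available, 140 targeted foil holes per square, 2 shots per hole,
81000× at 2.3 Å/px on a 5760×4092 sensor, −1 to −3 µm nominal
defocus, 58 frames of 0.6 e⁻ Å⁻², a 136 Å particle, ~100 picks per
micrograph with scores ~N(0.85, 0.08) clipped to [0, 1] (picker
scores skew high), 20% clustered picks, and CTF max resolution
~N(3.8, 0.4) Å. Where a value is not dictated by the session
configuration it was chosen once as typical of facility practice.

Construction details that the tests rely on:

* **Determinism** — all randomness derives from `Scenario.seed`
  (separate streams for layout and preprocessing content); identical
  scenarios give byte-identical trees.
* **Slot interleaving** — micrograph slots are interleaved across
  squares so every collected square receives exposures.
* **Clustering ground truth** — `round(clustered_fraction × n)` picks
  are placed as pairs 0.35–0.75 diameters apart (a triplet absorbs an
  odd count); all other picks keep ≥ 0.84 diameters of clearance, so
  the measured clustered fraction matches the request to within
  per-micrograph rounding.
* **Motion** — a per-scenario drift profile (default: decaying
  3/(1+0.35·i) Å per frame), scaled per micrograph by U(0.8, 1.2) and
  given a random direction per frame; written as per-frame shift
  deltas in Å in per-micrograph STAR tables.
* Raw `.mrc` and `.jpg` files are zero-byte placeholders: nothing
  downstream reads pixels.

What the generator does **not** emulate: real image content (so no
carbon/ice-contamination pathologies in picking), vendor binary
quirks, multi-grid autoloader inventories (one grid per session),
AFIS calibration drift, or gaps/restarts in the acquisition timeline.
Passing tests therefore demonstrate correct metadata mining and metric
computation under clean, internally consistent inputs — not robustness
to every corruption a production facility produces, beyond the
explicit degradation cases tested (corrupt XML, deleted images,
missing result types, malformed table rows).

## Problem sizes and numerical choices

The test suite runs on compact sessions (≈ 24 micrographs, ~40 picks
each) chosen to keep the full suite around a minute while leaving
every code path exercised; the acceptance script regenerates the full
254-image reference session. Clustering oracle-equivalence is checked
on 100 random picksets up to n = 2000 against the O(n²) brute force.
Parameter recovery is asserted within 3 standard errors over 5 seeds
of 30-micrograph sessions, with the acceptance probability of the
score filter computed analytically from the clipped-normal score
model. STAR/CBOX floats are written via `repr` and XML floats
likewise, so round trips are exact to 1e-6 relative or better.
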