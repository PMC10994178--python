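# epumine

Systematic mining of metadata from single-particle cryoEM
data-collection sessions.

A single-particle acquisition leaves behind a hierarchical trail of
metadata: per-image XML written by the collection software for every
atlas, grid-square, foil-hole and high-magnification exposure,
session-level `.dm` files describing the grid and shot strategy, and a
RELION-style preprocessing directory with motion-correction, CTF,
particle-picking (crYOLO CBOX) and 2D-classification results. None of
it is practically human-readable. `epumine` parses both trees, joins
them micrograph-by-micrograph, computes quality metrics, and emits
collated CSVs, PDF reports, and a checksummed deposition-ready JSON.
It is aimed at microscope operators (concise session reports), facility
managers (multi-visit aggregation and instrument-performance trends)
and depositors (automatic harvesting of the mandatory microscopy
metadata of an archive entry).

## Metrics at the core

For each micrograph with preprocessing results:

* **Early/late motion** — per-frame shifts (Å) are partitioned at a
  cumulative dose of 4 e⁻ Å⁻²: frame *i* is *early* iff
  `i · fraction_dose ≤ 4`; early + late = total exactly.
* **Particle diameter** — mean of the picker's per-particle diameter
  estimates, in Å.
* **Normalized density** — `N · d² / A_fov` for the `N` picks scoring
  strictly above 0.3, where `A_fov` is the magnified sensor area;
  1 = ideal packing of particles of diameter `d`, values > 1 flag
  over-picking.
* **Clustered fraction** — fraction of picks whose nearest neighbour
  lies closer than 0.8 × d (e.g. 109 Å for a 136 Å particle), via an
  exact k-d-tree nearest-neighbour search in Å.
* **CTF max resolution** and the pick-weighted **mean 2D-class
  resolution**.

Sessions reduce to rates (`(N−1)/span` micrographs h⁻¹ and µm² h⁻¹),
targeting statistics (available/targeted/collected squares, foil holes
per square) and mean/min/max of every metric, optionally grouped by
grid square or by shot position inside the foil hole (top/bottom).
A synthetic-session generator (`epumine.synthetic`) fabricates
complete, internally consistent session + preprocessing trees from a
declarative scenario, so the whole pipeline is testable without
microscope data. See `docs/methods.md` for definitions and
conventions.

## Worked example

```python
import epumine as em

sc = em.example_scenario(seed=1, n_micrographs=24, n_squares_collected=3,
                         foils_per_square=(5, 5, 4),
                         picks_per_micrograph=(40.0, 5.0))
root = em.generate_session_tree(sc, "demo")
em.generate_preprocessing_tree(sc, root)

a = em.analyze_session(root)
s = a.summary
print(f"rate        : {s.rate_micrographs_per_hour:.1f} mic/h")
for m, (mean, lo, hi) in s.reductions.items():
    print(f"{m:22s} mean {mean:8.4f}  min {lo:8.4f}  max {hi:8.4f}")
```

prints

```
rate        : 360.0 mic/h
motion_total           mean  28.2416  min  23.9782  max  33.2716
ctf_max_resolution     mean   3.7978  min   3.1098  max   4.5300
density                mean   0.0057  min   0.0044  max   0.0079
clustered_fraction     mean   0.1991  min   0.1875  max   0.2105
mean_class_resolution  mean   10.7325  min  10.3572  max  11.2519
```

One exposure every 10 s is 360 micrographs per hour; total motion
averages 28 Å over the 34.8 e⁻ Å⁻² exposure; CTF fits reach ~3.8 Å;
about 0.6% of ideal packing density with ~20% of particles clustered —
the scenario's generating values (motion profile, CTF ~N(3.8, 0.4),
clustered fraction 0.2) recovered from the files on disk.

The same flow from the shell:

```sh
epumine synth --out demo --seed 1            # generate the example session
epumine session demo/bi23047-42 --out out/run   # 4 CSVs + 2 PDF reports
epumine deposit demo/bi23047-42 --out dep.json  # deposition JSON + .sha256
epumine verify dep.json                          # integrity check (exit 2 on tamper)
epumine aggregate facility_root --out agg        # multi-visit table + histograms
```

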