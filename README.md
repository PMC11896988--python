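# ivimon

Interaction-vertex-imaging (IVI) simulation and 4D range/motion monitoring
for scanned carbon-ion delivery on a moving lung-tumor phantom.

The package implements the full chain as one reproducible synthetic study:

- **phantom** — PMMA aquarium + lung-like foam + PMMA cylinder with a
  spherical proximal end; material, path-segment and water-equivalent-depth
  queries for arbitrary rays, with the whole phantom displaceable along the
  motion axis.
- **motion** — Lujan-type respiratory trace `x(t) = A sin^(2n)(pi t / tau)`
  (default 20 mm / 3 s / n = 2), three amplitude phases
  ([0,3), [3,17), [17,20] mm), motor logfiles with the trigger-start
  convention.
- **plan** — spherical-target scanned plan (iso-energy layers from a
  two-point power-law range model, serpentine lateral grids), delivery
  timeline, nozzle-style spot logfiles (scanner settings, MWPC centroids and
  widths) and a 100 kHz FPGA synchronization log.
- **fragsim** — seeded forward simulator: per-ion transport with
  density-scaled exponential fragmentation sampling, forward-peaked proton
  emission, Highland multiple-Coulomb-scattering kicks per traversed layer,
  and cluster observations on four 3-sensor CMOS tracker arms
  (±10.5°, ±21°, 248 mm, 186.5 µs frames).
- **trackrec** — straight-line track fitting with greedy combinatorial
  cluster matching, rigid sensor alignment from a no-target run, and
  frame-to-spot association via the timing logs (midpoint rule).
- **vertexrec** — primary tracks (method *a*: MWPC-averaged centroid with
  scanner-pivot slopes; method *b*: additionally randomised by beam width
  and upstream scattering), closest-approach vertexing, per-spot vertex
  distributions and computed vertices (means in x/y, empirical quantile in
  z, 50-vertex validity threshold, quantile chosen where the static
  in/out difference is maximal).
- **monitor** — repeat-based 2·RMS thresholds, delivered-as-planned
  classification with efficiency against the motor-logfile truth over a
  `pos_m` grid, spherical-edge spot selection, and the four-case motion
  phase assignment with confusion matrices.
- **study / cli** — configuration, orchestration and reporting.

## Command line

```sh
# end-to-end study (simulate + reconstruct + analyze) with the default
# desk-scale configuration (3 cases x 5 repeats, ~550 spots)
ivimon run --out out/study --seed 1

# stages can be composed separately
ivimon simulate  --config cfg.yaml --case moving --plan layer:170 --out out/s
ivimon reconstruct --run out/s/runs/moving/rep0 --method a
ivimon analyze   --study out/s
ivimon report    --study out/study
```

All parameters live in one YAML config (see the `study.StudyConfig`
defaults; `ivimon run` writes the resolved config next to its outputs).
Every output is plain CSV/JSON; rerunning with the same config and seed
reproduces the outputs byte for byte.

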