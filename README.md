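# nucshape

Automated quantification of nuclear shape and blebbing from fluorescence
microscopy.

Abnormal nuclear shape — blebs, lobes and invaginations of the nuclear
envelope — is the cellular hallmark of laminopathies such as
Hutchinson–Gilford progeria syndrome (HGPS) and is traditionally scored by
eye as a binary "blebbed / not blebbed" call. `nucshape` replaces that
with a reproducible, continuous measurement for anyone analyzing anti-lamin
A/C (or similar rim-stained) images of nuclei: cell biologists screening
compounds that rescue nuclear shape, labs comparing patient-derived lines,
or methodologists benchmarking segmentation.

The pipeline:

1. **Boundary extraction** — CLAHE (8 × 8 tiles, clip limit 0.02, Rayleigh
   target), Otsu binarization, hole filling, removal of border-touching and
   < 800 px² regions, per-region convex hulls (erode 3 / dilate 6 for the
   outer limit, a further erode 2 for the initialization), near-binarization
   of the nucleus image (0.7 T / 1.3 T band around the Otsu threshold), and
   a **gradient-vector-flow (GVF) active contour** (80 GVF iterations,
   α = 0.02, β = 0.05, γ = 1, κ = 0.6, batches of 75 deformations, area
   tolerance 10 px², at most 50,025 deformations) that outputs a closed
   sub-pixel polygon with constant 0.5 px sides.
2. **Shape measures** — signed boundary curvature κᵢ by circle fitting
   through vertices i ± 25 (convex > 0, concave < 0), and per nucleus the
   **mean negative curvature**

   MNC = | mean{ κᵢ : κᵢ < 0 } |,

   plus invagination count (maximal runs of negative curvature), area,
   perimeter, moment-ellipse eccentricity, solidity (area / convex-hull
   area), tortuosity (perimeter / convex-hull perimeter), and
   intensity statistics.
3. **Population analysis** — MNC-sorted curvature heat maps (each column a
   straightened, arc-length-normalized boundary), box-plot summaries,
   one-tailed Welch t-tests between groups, and hierarchical clustering of
   the measure panel (1 − |r| distance, average linkage).
4. **Synthetic data** — a generator of lamin-rim-like 16-bit images with
   analytic ground-truth boundaries and controllable bleb count/depth, so
   the whole pipeline is testable without microscopy data.

## Worked example

Simulate 40 blebbed nuclei (mean bleb depth 0.2 of the radius), then run
the full pipeline:

```bash
nucshape simulate --out frames --n 40 --seed 7 --bleb-depth 0.2
nucshape run --input frames --out results
```

which prints the run manifest

```json
{
  "version": 1,
  "config_hash": "61e4468adf73812c",
  "images": 40,
  "unreadable": {},
  "nuclei": 40
}
```

and writes `contours.json`, `metrics.csv`, `heatmap.csv`, `summary.csv`
and `run.json` into `results/`. The first metric rows:

```
  image_id      mnc  invaginations        area  eccentricity  solidity
frame_0000 0.000000              0 2287.361059      0.371990  0.998259
frame_0001 0.011796              3 2071.767737      0.411422  0.976405
frame_0002 0.015382              2 1584.079618      0.642313  0.969566
frame_0003 0.009440              1 3185.329153      0.647563  0.995034
frame_0004 0.000000              0 2035.886678      0.602899  0.999870
```

Reading a row: `frame_0002` is a ~45 px-wide nucleus (area 1584 px²) with
two detected invaginations; its boundary's concave stretches average
0.0154 px⁻¹ of curvature (MNC), and carving has lowered its solidity to
0.97. `frame_0000` drew a shallow bleb that the 12.5 px curvature window
legitimately smooths away: MNC 0 means "no measurable concavity", the same
reading an unblebbed control nucleus would get. Across the population the
mean MNC is 0.0078 px⁻¹; comparing such populations (e.g. treated vs mock)
is a one-liner:

```bash
nucshape compare --metrics results/metrics.csv --metric mnc --direction less
```

Other subcommands: `extract`, `metrics`, `heatmap` (PNG + CSV matrix),
`cluster`, `init-config` (write the default YAML; every numeric parameter
above is configurable). See `docs/methods.md` for the model, parameter
meanings, generator realism and limitations.

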