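# Methods

## Problem and approach

Nuclear blebbing — protrusions and invaginations of the nuclear envelope —
is the cellular hallmark of laminopathies such as Hutchinson–Gilford
progeria syndrome (HGPS) and is classically scored by eye, which is slow,
binary and rater-dependent. `nucshape` automates the measurement: it
extracts each nucleus boundary from an anti-lamin A/C immunofluorescence
image at sub-pixel resolution with a gradient-vector-flow (GVF) active
contour, computes signed boundary curvature by circle fitting, and reduces
blebbing to a continuous statistic, the **mean negative curvature (MNC)**:
the absolute value of the mean of all concave (negative) curvatures on the
boundary. A convex nucleus has MNC 0; the deeper and more numerous the
invaginations, the larger the MNC.

## Boundary extraction

1. **CLAHE.** Contrast-limited adaptive histogram equalization over an
   8 × 8 tile grid, clip limit 0.02, mapping each tile's clipped CDF through
   the inverse CDF of a Rayleigh distribution (scale σ = 0.4, truncated to
   the intensity range), with bilinear blending between neighboring tile
   mappings. The histogram resolution is 64 bins by default: the clip limit
   only suppresses a background-noise tile if the noise occupies few enough
   bins that their counts exceed the clip, and at 256 bins a noise standard
   deviation of a few percent of the dynamic range slips under the limit —
   the background is then stretched to full range and thresholding fails.
   64 bins keeps the contrast limit effective against realistic background
   noise while leaving genuine rim contrast untouched (`preprocess.n_bins`,
   configurable).
2. **Thresholding and region cleanup.** Otsu's threshold (between-class
   variance maximization on a 256-level histogram; tied maxima across empty
   histogram gaps resolved to the plateau midpoint, as in MATLAB's
   `graythresh`) binarizes the equalized image; holes are filled
   (8-connected foreground / 4-connected background), regions touching the
   image border or smaller than 800 px² are removed.
3. **Hulls.** Each region is eroded by a Euclidean disk of radius 3 px and
   dilated by radius 6 px; the convex hull of the result is the *outer
   hull*, a hard limit for the snake. Eroding the smoothed, enlarged region
   by a further 2 px and taking the convex hull gives the *inner hull*, the
   snake's initialization. The second erosion applies to the already
   smoothed/enlarged region, so the inner hull still sits slightly outside
   the original region.
4. **Near-binarization.** The raw image is contrast-stretched (1%
   saturation at each end), pixels outside the outer hull are zeroed, the
   crop is stretched again, and the Otsu threshold T is computed but not
   applied: pixels below 0.7 T go to the minimum intensity, above 1.3 T to
   the maximum, and the band between is stretched linearly between those
   anchors. Gray-scale holes (the dark nuclear interior enclosed by the
   bright rim) are filled by morphological reconstruction by erosion.
5. **GVF snake.** The GVF field of the near-binarized image (edge map =
   normalized gradient magnitude) is diffused for 80 iterations with
   regularization μ = 0.2 (the standard value of the cited formulation; the
   explicit scheme requires μ ≤ 0.25). The snake starts on the inner hull
   and evolves semi-implicitly, (I + γA) xₜ₊₁ = xₜ + γκ F(xₜ), with tension
   α = 0.02, rigidity β = 0.05, step γ = 1, external weight κ = 0.6; the
   circulant pentadiagonal system is solved exactly per step by FFT.
   Deformations run in batches of 75; between batches the polygon is
   re-interpolated to keep side lengths within [d_min, d_max] = [0.5, 2] px
   (long sides split at midpoints, short runs merged — retained vertices are
   not moved, preserving boundary detail) and vertices outside the outer
   hull are projected orthogonally back onto it. Evolution stops when the
   enclosed (shoelace) area changes by ≤ 10 px² between batches, or after
   50,025 total deformations (667 batches). The final contour is resampled
   by arc length to constant side length d_min = 0.5 px and oriented
   counter-clockwise. Extraction contains no randomness: identical image
   and configuration give bit-identical vertices.

Curation is file-driven rather than interactive: an exclusion list of
(image, point) records removes every contour containing a point.

## Shape measures

- **Curvature**: for each vertex i, the circle through vertices i−25, i,
  i+25 (cyclic) gives |κ| = 1/R; the sign is positive for convex (left)
  turns, negative in concavities, zero for collinear triples. Index 0 of
  each profile is the vertex farthest from the polygon centroid. The offset
  of 25 vertices at 0.5 px spacing means curvature is measured over a
  ±12.5 px arc: structure much narrower than that window is smoothed away,
  so MNC values are comparable only at a fixed pixel size and offset (the
  calibration caveat of the underlying method). A physical pixel size can
  be configured and multiplies lengths/areas and divides curvatures.
- **MNC** = |mean{κᵢ : κᵢ < 0}| (0 if none); **neg_curv_std** is the
  standard deviation of the negative curvatures; **invaginations** is the
  number of maximal cyclic runs of strictly negative curvature (zeros
  interrupt runs).
- **Eccentricity** of the moment-equivalent ellipse, from exact polygon
  moment integrals (Green's theorem); 0 for a circle, 1 for a line
  segment. Zero-area (collinear) inputs fall back to point moments with a
  warning, which yields exactly 1 for a segment.
- **Solidity** = area / convex-hull area; **tortuosity** = perimeter /
  convex-hull perimeter (≥ 1, scale-invariant; chosen as the package's
  definition of boundary waviness since it co-varies with blebbing but not
  with size). Area is the shoelace area, perimeter the polygon arc length;
  intensity mean/SD are taken over pixels inside the polygon.

## Population analysis

Heat maps cut each boundary at its farthest-from-centroid point, straighten
it, resample the signed-curvature profile to 200 positions by normalized
arc length, clip magnitudes at 0.15 px⁻¹ (display only — MNC uses unclipped
values) and order columns by increasing MNC. Group comparisons use the
one-tailed Welch (unequal-variance) t-test with Welch–Satterthwaite degrees
of freedom; p ≤ 0.05 is the significance convention and raw p-values are
reported without multiple-comparison correction. The measure panel is
clustered agglomeratively with distance 1 − |Pearson r| and average linkage
(Spearman available); constant columns are excluded.

## Synthetic data: what it emulates, what it does not

Shapes are star-convex polar curves r(θ) = r_ell(θ)(1 − Σ depth·g(θ)): an
ellipse radial profile (axis ratio up to ~1.6, geometric-mean radius
preserved) carved by smooth periodic Gaussian bumps that model blebs as
inward invaginations (outward protrusions behind a flag — both score as
blebbed, protrusions via their flanking concavities). Defaults emulate
cultured fibroblast nuclei at ~0.3 µm/px: mean radius 28 px (≈ 17 µm
diameter, SD 3 px), 1–4 blebs of angular width σ = 0.25 rad (wide lobes,
comparable to the ±12.5 px curvature window), bleb depth ~N(0.12, 0.05)
clipped to [0, 0.45) as the severity dial. Rendering emulates lamin-rim
staining: a 2.5 px rim band just *inside* the analytic boundary (the lamina
underlies the envelope, and this makes the true boundary the outer rim
edge), interior at 35% of the rim intensity (nucleoplasmic lamin), rim
40,000 on a background of 2,000 with seeded Gaussian noise (SD 800 by
default) on a 16-bit range, with ~1 px linear anti-aliased edge profiles so
the intensity-gradient ridge falls exactly on the true boundary.

Not modeled: optics (PSF convolution, depth blur), photobleaching, uneven
illumination, autofluorescent debris, touching/overlapping nuclei,
chromatin texture. Passing tests therefore demonstrate correctness of the
geometry pipeline and statistics under idealized imaging, not robustness to
every artifact of real microscopy; on real data the curation step exists
precisely to remove what the generator does not model.

Populations draw each nucleus from a counter-derived substream of the
population seed (`default_rng([seed, counter])`), so a population is
reproducible and can be extended without reshuffling earlier nuclei.
Multi-nucleus frames place nuclei on a jittered grid with guaranteed
separation; the ground-truth table stores the drawn parameters and the
shape measures computed on the analytic contour (720 vertices).

## Numerical choices and degenerate inputs

- Pixel centers sit at integer coordinates; polygons are (x, y) =
  (column, row); "lowest/highest intensity" is the dtype range (8- or
  16-bit processed natively).
- Structuring elements are rasterized Euclidean disks (pixel included iff
  center distance ≤ radius).
- Otsu on a constant image raises; a constant patch inside a hull skips
  that nucleus with a warning; a snake collapsing below a 3·d_min perimeter
  rejects the nucleus with a warning; a region eroded away during hull
  construction is dropped with a warning. Warnings name image and nucleus.
- Farthest-vertex ties in profile alignment break to the lowest original
  index. Heat-map column sorting is stable.
- Quartiles use linear interpolation; whiskers the 1.5·IQR rule.

## Validation experiment sizes

The test suite validates the pipeline end to end on synthetic data at desk
scale: disk-recovery across radii 20–60 px at 0 and 5% rim noise; detection
power with 20 replicate pairs of 100-nucleus populations whose mean bleb
depth differs 2-fold (one-tailed Welch p < 0.001 expected in ≥ 90%);
density robustness with the same 100-nucleus shape population imaged at 1,
4 and 9 nuclei per frame over 10 replicates (shape draws are shared across
density conditions so the comparison isolates density effects on
extraction; no pairwise difference expected). These sizes mirror the
~100-nuclei-per-condition design of the original study.

## Known limitations

- MNC depends on pixel size, vertex spacing and the circle-fit offset;
  values are comparable only within one calibration (solidity is the
  scale-robust alternative).
- Touching nuclei are not split; they are removed by curation (or survive
  as merged contours if uncurated).
- The snake cannot enter invaginations much narrower than the GVF
  diffusion scale (√(μ·iterations) ≈ 4 px) or sharper than its rigidity
  allows; very narrow, deep blebs are under-measured by construction.
- Star-convexity is assumed by the renderer (not by the extraction or
  metrics stages).
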