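# Methods

This note documents the models, conventions and numerical choices behind
`spotfuse`, in the order the pipeline runs them.

## Input models and frames

**Visium.** A sample is a Space Ranger-style bundle: a features × barcodes
sparse matrix (10x HDF5 feature-barcode schema), per-spot positions, scale
factors and H&E rasters. All spot geometry is kept in *full-resolution
image pixels*; `hires`/`lowres` rasters relate to that frame by the scalar
factors in `scalefactors_json.json`. Both tissue-positions dialects are
read (v1 headerless `tissue_positions_list.csv`, v2 headered
`tissue_positions.csv`); the writer always emits the v2 form. Position
records without a matrix barcode are dropped with a logged count; a
barcode overlap below 50% is treated as a wrong-bundle pairing and is
fatal rather than silently intersected.

**MSI.** A sample is a peak-by-pixel table: `x`, `y` pixel coordinates in
native acquisition units, one numeric column per peak headed by its m/z
value (non-numeric columns become per-pixel metadata). Intensities must be
finite and non-negative; duplicate pixel coordinates are fatal. The pixel
pitch (µm between pixel centres, e.g. 65 µm for a typical DESI raster) is
carried as metadata and used only for the `msi` radius mode.

**Points are (x, y)** with x the column index and y the row index, origin
top-left, in every frame. The tissue-positions table stores (row, col) and
is swapped at the IO boundary. Transforms carry named domain/codomain
frames and refuse composition across mismatched frames.

## MSI preprocessing

* **TIC normalization** divides each pixel by its total ion count, then
  rescales so every pixel sums to the *median pre-normalization total*.
  The median target (rather than 1.0) keeps magnitudes on a raw-like scale
  so user thresholds stay interpretable; `target="unit"` gives plain
  sum-to-one. Zero-total pixels are dropped with a logged count. Many
  vendor exports arrive already TIC-normalized; the step is optional in
  the pipeline config (`tic: false`).
* **Peak deduplication** groups peaks whose m/z agree after rounding to
  `decimals` (default 2) and keeps, per group, only the peak with the
  largest intensity total — summed across all pixels of all samples when a
  list of datasets is passed jointly. Ties go to the lower exact mass.
  The operation never alters a surviving column and is idempotent.
* **Pixel QC** keeps pixels with strictly more than `min_peaks_per_pixel`
  detected peaks (a detected peak is a strictly positive intensity — the
  table carries no separate detection flag) *and* total intensity strictly
  above `min_total_intensity`. Both inequalities are strict, mirroring the
  "more than N peaks / total > T" convention of upstream MSI QC. Because
  thresholds refer to the (vendor-specific, unpublished) scale of the
  normalized export, they are user parameters with permissive defaults of
  0, not opinionated defaults.

## Data-generated image and tissue labels

PCA on the pixel × peak matrix uses mean-centering only; unit-variance
scaling is off by default (flag `scale=True`) so that high-intensity
structural peaks dominate PC1 — that dominance is precisely what makes
tissue boundaries visible. Component signs are fixed by forcing each
component's largest-magnitude loading positive, which makes images and
labels deterministic and invariant to pixel order. Components are clipped
at the (1, 99) percentiles and min-max scaled to [0, 255] per channel.

Tissue/background labels threshold PC1, either at a user value or by
Otsu's criterion on a 256-bin quantized histogram (ties to the lowest
cut). The side of the threshold with the higher mean total ion intensity
is called tissue, regardless of PC1's sign. A threshold putting all
pixels in one class warns and returns the one-label result.

Single-peak images cap intensities at the 99th percentile before scaling
so isolated hot pixels cannot compress the dynamic range.

The raster's affine frame (offsets + per-axis steps, inferred as the
median positive difference of sorted unique coordinates) is exported as a
sidecar JSON next to every PNG so landmark picks in image pixels convert
back to native MSI coordinates exactly.

## Registration

* **Affine**: least-squares fit of the 6 parameters over all pairs
  (normal equations via `lstsq`); requires ≥ 3 non-collinear pairs
  (rank check on the centred source). Deterministic.
* **Thin-plate spline**: exact interpolating spline, kernel
  U(r) = r² log r², zero bending regularization by default (the
  `regularization` parameter adds λI to the kernel block for noisy
  landmarks); requires ≥ 4 not-all-collinear pairs. Every fitted TPS maps
  each control point onto its target within 1e-6 (asserted in tests over
  100 seeded fits; typical residuals ~1e-10).
* **Composition**: affine∘affine collapses to one matrix; any composition
  involving a TPS returns a chained applicator that applies the stages in
  sequence. Two TPS stages are therefore *chained*, not re-fitted as a
  single spline — the two-stage route (data image → microscopy image →
  H&E) evaluates exactly what was fitted at each stage.
* **Image warping** is backward mapping with bilinear interpolation
  (`scipy.ndimage.map_coordinates`); target cells falling outside the
  source raster are zero-filled and flagged. The TPS "inverse" used for
  warping is a spline fitted on the swapped landmark pairs — an
  approximation adequate for mild warps; the coordinate path (the one that
  matters for aggregation) never uses it.

## Aggregation

Radius modes, in full-resolution pixels:

| mode | radius | pixel multiplicity |
|---|---|---|
| `expanded` (default) | half the minimum nearest-neighbour spot distance (k-NN search, global) | ≤ 1 spot per pixel |
| `visium` | `spot_diameter_fullres / 2` (the 55 µm capture spot) | ≤ 1 spot per pixel |
| `msi` | `(pixel_pitch / 55 µm) × spot_diameter_fullres / 2` | one pixel may serve several spots |

The expanded radius is global rather than per-spot because per-spot
maximal non-intersecting radii are underdetermined at array edges. Circles
at half the minimum centre distance leave interstitial gaps; pixels in
those gaps are reported as unassigned (counted in the mapping and the run
manifest) rather than snapped to a spot. In `expanded`/`visium` modes a
pixel within radius of several centres goes to the nearest, with exact
distance ties broken by the lexicographically smallest barcode.

Reductions per spot and peak: `sum`, `mean`, and `weighted_average` with
weights wᵢ = 1 / (dᵢ + ε), ε = 10⁻⁶ × radius. The weight function is a
design choice (inverse distance, bounded at d = 0 by the radius-scaled ε)
and is recorded in the run manifest. Spots with no assigned pixels get
zero rows and an `empty_spots` flag so the barcode set stays 1:1 with the
Visium object. With `sum` in `expanded` mode the grand total of the spot ×
peak matrix equals the total intensity of assigned pixels exactly, and no
pixel is double-counted — both asserted in tests against a brute-force
all-pairs oracle.

The aligned bundle reuses the Visium sample's scale factors and frame so
both modalities overlay without further transformation;
`spot_diameter_fullres` in the MSI bundle is set to the aggregation
diameter actually used. Aggregated intensities are written as float64,
never rounded to integers — TIC-normalized values are continuous and
rounding would break conservation.

## Alignment scoring and benchmark

The MSI-side spot label is the majority vote of the assigned pixels'
tissue labels (ties count as tissue; pixel-less spots are background);
the Visium-side label is the bundle's own tissue flag. Accuracy is
(tissue–tissue + background–background) / all barcodes in the Visium
object — including spots outside the MSI capture area, which is why the
score is sensitive to capture-area differences on real data.

The benchmark crosses transform kind × registration route × k landmarks ×
repeat. Each (k, repeat) cell draws its subset without replacement from a
per-cell RNG stream derived from `(seed, k, repeat)`, so any cell is
individually reproducible and whole tables are bit-identical across runs.
Cells with k below the transform's minimum (3 affine / 4 TPS) are recorded
as failed rather than aborting the table.

## Synthetic data generator

The generator emulates the *geometry* of a consecutive-section experiment:

* Visium: hexagonal lattice (odd rows offset half a spacing, row pitch
  spacing × √3⁄2, so the minimum centre distance equals the spacing);
  `spot_diameter_fullres` = 0.55 × spacing, mirroring the 55 µm spot on a
  100 µm pitch. Default lattice 14 × 12 spots at 100 px spacing. Gene
  counts are negative-binomial (dispersion 0.5, var = µ + 0.5 µ²) with
  tissue-elevated means — realistic over-dispersion without modelling any
  particular transcriptome.
* Tissue mask: an ellipse with two interior holes. The holes give the
  boundary the distinctive features that make landmark placement
  well-posed, the same reason moderate tears help with real sections.
* MSI: a rectilinear raster covering the warped-back Visium extent at
  `resolution_factor` pixels per spot spacing (default 8, ≈ 13 000
  pixels). Peak intensities are baseline + tissue_effect × mask +
  truncated Gaussian noise, *rounded to integers* so that sum-aggregation
  bookkeeping can be asserted exactly; one peak (m/z 550.15724) is
  restricted to hotspot discs (a drug-deposition pattern), one
  (m/z 89.02435) tracks the whole tissue (a structural metabolite).
* Warp: a random-but-seeded affine — ≈ 7° rotation, ≈ 5% scaling and a
  translation of ~3 spot spacings — the magnitude of misalignment seen
  between sections mounted on different slides.
* Landmarks: sampled in the tissue-boundary band (near the ellipse edge
  or a hole), targets = warp(source) + optional Gaussian jitter. Jitter 0
  gives exact pools for recovery tests (affine recovered to ~1e-13).

Everything is byte-reproducible given a seed (HDF5 written without
timestamps).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: non-affine tissue distortion (stretching,
folds, tears *between* sections), landmark-picking error beyond isotropic
Gaussian jitter, chemical noise structure (correlated peaks, matrix
effects, hot pixels), partial capture-area overlap, and H&E image content
beyond a rendered mask. Real-data accuracy is bounded by section quality;
the synthetic scores characterize the pipeline's geometry handling, not
biological attainability.

## Problem sizes and determinism

Default test and acceptance scenarios use the 14 × 12-spot lattice with
~13 000 MSI pixels and 5 + noise peaks — large enough to exercise k-NN
assignment, brute-force oracles and the benchmark factorial while keeping
the full suite under a minute. All randomness flows through
`numpy.random.default_rng` seeded from explicit arguments; the pipeline
itself is deterministic (PCA via SVD with a fixed sign convention, no
stochastic steps), so re-running a config bit-identically reproduces every
output file.

## Known limitations

* The TPS image-warp inverse (swapped-pair fit) is approximate; strong
  non-affine warps can leave visible resampling error in the transformed
  *image* (coordinates are unaffected).
* No intensity-based (landmark-free) registration and no automatic
  landmark detection; landmark quality is the accuracy ceiling.
* `expanded` aggregation discards interstitial pixels by design; datasets
  where MSI pixels are much larger than spots should use `msi` mode,
  accepting one-to-many pixel reuse (conservation then does not hold).
* The accuracy score is a coarse, label-level metric: it saturates once
  tissue outlines overlap and cannot resolve sub-spot misalignment.
  Image-level similarity metrics would complement it but are not
  implemented.
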