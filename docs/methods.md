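# Methods

This note documents the models, conventions and design choices behind
`stroi`, in the spirit of the methods documentation of the established
single-cell toolkits.

## Coordinate conventions

Pixel coordinates are 0-based with `(x, y) = (column, row)`. Spot
positions are carried in full-resolution pixels (`pxl_col_in_fullres`,
`pxl_row_in_fullres` in Space Ranger terms) and mapped to the working
image by multiplying with the hires scale factor; the spot diameter
scales the same way. Rasterizing a floating-point position onto the pixel
grid uses round-half-up (`floor(v + 0.5)`), chosen over banker's rounding
so the convention is deterministic and directly testable. Both
`tissue_positions` dialects (headerless pre-2.0 and headered 2.0+) are
auto-detected; the two differ only in the header line.

## Preprocessing

* **Spot filter.** Off-tissue spots are dropped, and in-tissue spots with
  fewer than 200 transcripts (sum of counts; default, configurable) are
  excluded — a spot with exactly the threshold survives. Filtering on
  transcript totals rather than detected genes is deliberate; the two
  differ for sparse spots.
* **Gene filter.** Genes detected in fewer than 3 spots are dropped
  (configurable, recorded in the manifest). This is the minimal standard
  filter; it is made explicit because downstream ORA universes depend on
  the surviving gene list.
* **Normalization.** Per-spot library-size scaling to a common target sum
  (default 10⁴) followed by natural `log1p`:
  `x_norm[i,j] = ln(1 + x[i,j] · T / totalᵢ)`. Raw counts are retained
  alongside. The conserved quantity `Σⱼ expm1(x_norm[i,j]) = T` per spot
  is a tested invariant.
* **Crop.** The working image is cropped to the bounding box of in-tissue
  spot coordinates expanded by one working spot diameter (inclusive
  integer bounds `floor(min − pad) .. ceil(max + pad)`, clipped to the
  image). This removes fiducials and slide background geometrically, with
  no fiducial detector. Degenerate windows are expanded to at least 2×2
  pixels because downstream rasters need area. Cropping changes only the
  image and the coordinate offset, never counts.
* **Affine alignment.** Image-based platforms are aligned with a 2×3
  affine `(x, y) → (ax + by + t_x, cx + dy + t_y)`; the linear part must
  be non-singular (|det| > 1e-12). Points landing outside the image are
  flagged, not dropped, and become OTHER downstream.

## Segmentation backend contract

A backend exposes `everything(image, threshold)` (whole-image proposals,
each with a confidence score in [0, 1]) and `from_boxes(image, boxes)`
(exactly one mask per rectangle, in order). For SAM-class models the
confidence is the predicted-IoU score, so the threshold has the model's
native semantics; raising it can only shrink the proposal set (a tested
monotonicity property). Overlapping proposals are allowed and are not
de-overlapped — conflicts are resolved at ROI construction instead.

The built-in **reference segmenter** is a deterministic color segmenter:
k-means (seeded, capped iterations) on the distinct RGB colors, labels
mapped back per pixel, 8-connected components per color class, components
of ≥ `min_area_px` pixels becoming masks with score 1.0. The color class
holding the majority of image-border pixels is background and proposes
nothing. Box mode returns the largest non-background component inside the
box (the whole box if it contains only background). Cluster labels are
re-indexed by sorted center coordinates so the labeling is stable across
seeds for well-separated colors. This is a genuine segmenter for
flat-color imagery — the regime of the synthetic fixtures — not an
approximation of a neural model; real histology requires a SAM-class
backend plugged into the same contract.

Masks are ranked by pixel area, largest first, ties keeping proposal
order; `mask_id` is the 1-based rank.

## Spot–mask geometry

* **Containment.** A spot belongs to every mask whose raster is true at
  the spot's rounded center pixel; multiple membership is expected.
* **Co-location proportion.** Everything-mode masks are scored by the
  fraction of mask pixels covered by the union of spot disks (diameter =
  working spot diameter) and removed below 0.01. The mask-area
  denominator makes the threshold scale-free in mask size. The
  alternative reading — the fraction of all in-tissue spots falling
  inside the mask — is selectable (`proportion_def="spots-in-mask"`);
  spots are treated as disks in the primary definition because overlap is
  an area notion. A pixel `(r, c)` is covered by a spot at `(x, y)` when
  `(r − y)² + (c − x)² ≤ (d/2)²`.
* **ROI construction.** ROI 1/ROI 2 are unions of selected masks. A spot
  in masks of both ROIs is EXCLUDED from the contrast (overlapping
  proposals are routine; silent assignment to either side would bias the
  DEG test); excluded counts are reported. An empty ROI 2 triggers
  one-versus-others: every remaining in-tissue spot becomes the
  comparison group. The labels partition the in-tissue spots, a tested
  invariant. Click-selection (for a UI layered on top) toggles the
  smallest containing mask, so nested fine structures stay reachable
  under their parents.

## Statistics

* **Wilcoxon rank-sum DEG.** Per gene, two-sided, between ROI 1 and ROI 2
  spots on the log-normalized matrix. When both groups have ≤ 10
  observations and there are no ties, the p-value comes from the exact
  permutation null of the Mann–Whitney U statistic (computed with the
  standard counting recurrence); otherwise from the normal approximation
  with tie-corrected variance (`var = n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))]`)
  and no continuity correction — the convention of the standard
  single-cell ranking routines, cross-checked against an independent
  implementation in the tests. Genes expressed in neither group get
  p = 1, log2FC = 0 by convention.
* **Fold change.** `log2FC = log2(mean₁ + ε) − log2(mean₂ + ε)` where
  `meanₖ` is the group mean of `expm1(x_norm)` and ε = 1e-9. The
  difference-of-logs form is mathematically identical to the log-ratio
  and exactly antisymmetric under swapping the ROIs in floating point.
* **Multiple testing.** Benjamini–Hochberg step-up, implemented directly
  and verified against an independent closed-form oracle and against
  statsmodels.
* **Classification and top-k.** `up_roi1` requires `log2FC > cutoff` and
  `adj-p < cutoff` (strict; a gene exactly at a cutoff stays `ns`);
  `up_roi2` mirrors. The top-10 list sorts `up_roi1` by fold change
  descending, ties by smaller adj-p then gene id.
* **ORA.** Upper-tail hypergeometric `P(X ≥ k)` per term with
  `k = |query ∩ term ∩ U|`, `K = |term ∩ U|`, `n = |query ∩ U|`,
  `N = |U|`; BH across tested terms; terms with adj-p < 0.05 flagged
  reported, all rows retained. One-sided by design — the question is
  over-representation. The universe `U` defaults to the genes surviving
  preprocessing (what could have been detected), with the library union
  as an option. Gene matching is case-insensitive (GMT libraries are
  uppercase; mouse symbols are not). ORA runs separately on the
  `up_roi1` and `up_roi2` sets, giving each ROI its own enrichment panel.
* **Cell-type proportions.** The spot×cell-type fraction matrix is an
  external deconvolution product consumed by barcode; per-ROI mean
  fraction vectors and spot counts are reported. If input rows sum to 1,
  so do the ROI means.

## Synthetic fixtures

The generator emulates a miniature Visium bundle: solid-color rectangular
or disk regions on white, a square spot lattice (pitch 12 px by default;
Visium's hex lattice adds nothing to the geometric contracts tested
here), in-tissue flags within one pitch of a region, and negative
binomial counts — NB rather than Poisson because spot-level counts are
overdispersed; `var = μ + μ²/θ` with θ = 2 by default. Defaults: 256×256
image, two regions, ~360 in-tissue spots, 2000 genes at baseline mean 0.5
(median ≈ 1000 transcripts/spot, comfortably above the 200 filter), 10
markers per region boosted four-fold (log2FC = 2), 20 decoy gene sets of
10 non-marker genes, per-region Dirichlet cell-type profiles
(concentration 50) over 5 cell types. Off-tissue lattice points carry 10%
ambient signal.

What passing on these fixtures does **not** show: performance on real
H&E texture (the reference segmenter needs flat colors), hex-lattice
geometry, batch effects, segmentation errors at tissue boundaries, or
deconvolution quality (fractions are planted, not estimated).

## Numerical choices and degenerate inputs

Ties in mask areas keep proposal order; equal co-location proportions at
the threshold survive (`≥` keeps, `<` removes); an all-masks-removed
filter result is a valid empty set with a warning, while an ROI with zero
spots is an error. The exact-U branch of the rank-sum test uses a cached
distribution table per group-size pair. p-values are clipped to (0, 1].
CSV column order is stable and runs are pure functions of (inputs,
config, seed), so repeated runs are byte-identical — timestamps are
deliberately kept out of the manifest.

## Problem sizes

The test suite and the acceptance script run on the default fixture
(≈ 440 spots × 2000 genes) and on smaller geometric fixtures (≤ 128×128
rasters for the pixel-exact oracles; 500 genes × 100 spots for the null
calibration) — sizes at which every oracle is exhaustive yet the whole
suite completes in well under a minute.
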