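# stroi

Segmentation-guided region-of-interest (ROI) analysis for spatial
transcriptomics.

Spot-based spatial transcriptomics (e.g. 10x Visium) pairs a gene–spot
count matrix with a histology image. A natural analysis asks: *given a
morphologically distinct structure visible in the image, what is its
expression signature?* `stroi` answers this by aligning image
segmentation masks with capture spots and running the standard downstream
statistics between mask-defined spot groups. It is aimed at computational
biologists who want a scriptable, testable version of this workflow — the
interactive "click on a tissue structure, get DEGs" loop — without a GPU
or a web front-end.

## What it does

1. **Preprocess** a Visium-style bundle (MTX or 10x HDF5 matrix,
   `tissue_positions` CSV in either Space Ranger dialect, scale-factors
   JSON, tissue image): drop off-tissue spots and spots with fewer than
   200 transcripts, library-size log-normalize
   (`x_norm = ln(1 + x · T / total)`, T = 10⁴), scale full-resolution
   spot coordinates into the working image, and crop the image tight
   around the tissue. Image-based platforms (Xenium and similar) are
   supported through a 2×3 affine transform onto a post-experiment image.
2. **Segment** the cropped image through a pluggable backend contract
   with two modes: *everything* (whole-image mask proposals filtered by a
   confidence threshold — for SAM-class models this is the predicted-IoU
   score) and *prompt* (one mask per user-supplied rectangle box). A
   deterministic built-in reference segmenter (color k-means + connected
   components) exercises the full pipeline without model weights; a
   SAM-style backend can be registered under the same contract.
3. **Filter and rank masks**: masks are ranked by area (mask 1 =
   largest), and everything-mode masks whose pixels are insufficiently
   covered by spot capture areas are removed — the co-location proportion
   of a mask is

   `prop(M) = |M ∩ ⋃ᵢ disk(sᵢ, d/2)| / |M|`

   over spot centers `sᵢ` and spot diameter `d`; masks with
   `prop < 0.01` are discarded.
4. **Build ROIs**: ROI 1 and ROI 2 are unions of selected masks; spots
   claimed by both are excluded; an empty ROI 2 means one-versus-others
   against all remaining in-tissue spots.
5. **Analyze**: per-gene two-sided Wilcoxon rank-sum between ROI spot
   groups (exact permutation null for small tie-free groups, otherwise
   normal approximation with tie-corrected variance), log2 fold change of
   de-logged group means, Benjamini–Hochberg adjustment, cutoff
   classification (|log2FC| > 1, adj-p < 0.05 by default) and the top-10
   genes by fold change; hypergeometric over-representation analysis of
   the up-regulated sets against GMT gene-set libraries (terms reported
   at adj-p < 0.05); and mean cell-type proportions per ROI from an
   externally produced spot deconvolution matrix.

A synthetic fixture generator (`stroi make-fixture`) plants colored
regions, negative binomial counts with known marker genes, a gene-set
library with decoy terms, and Dirichlet cell-type profiles, so the whole
workflow can be validated against known truth.

## Worked example

```bash
stroi make-fixture --seed 7 --out fx
cat > run.yaml <<EOF
bundle: fx
roi1: [1]
gmt: [fx/planted.gmt]
fractions: fx/fractions.csv
outdir: out
seed: 7
EOF
stroi run --config run.yaml
```

prints

```
spots kept: 361, masks kept: 2, ROI1/ROI2 spots: 136/225, DEGs up: 10+9
top genes (ROI1): GENE0999, GENE1707, GENE0100, GENE1555, GENE0314, GENE0228, GENE1003, GENE0881, GENE1644, GENE0615
```

Reading: of 441 lattice spots, 361 are in tissue and pass the
200-transcript filter; the reference segmenter recovers both planted
regions as masks 1 and 2 (ranked by area); choosing mask 1 as ROI 1 with
ROI 2 empty contrasts its 136 spots against the other 225. The ten
planted region-1 marker genes (four-fold boost) are exactly the ten
top-fold-change DEGs. The ORA table confirms the planted term and rejects
every decoy:

```
term,k,K,n,N,p_value,p_adj,reported
REGION0_MARKERS,10,10,10,2000,3.62e-27,7.97e-26,True
DECOY00,0,10,10,2000,1.0,1.0,False
```

`out/` also contains `degs.csv` (per-gene log2FC, p, adj-p, group),
`proportions.csv` (mean cell-type fractions per ROI), `labels.csv`
(per-spot ROI labels), `masks.npz`, `overlay.png` and `manifest.json`
recording every parameter of the run.

The same stages are available individually (`stroi preprocess`,
`stroi segment`, `stroi roi`, `stroi analyze`) against cached
intermediates, and as library functions (`stroi.run_pipeline`,
`stroi.stats.wilcoxon_deg`, ...).

## Scope

The tool consumes segmentation models and deconvolution methods, it does
not reimplement them: SAM-class weights plug in behind the backend
contract, and cell-type fractions come from an external deconvolution
(CellDART-style) CSV. Web UI, multi-sample batches, stain normalization,
ligand–receptor and spatial-distance analyses are out of scope.
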