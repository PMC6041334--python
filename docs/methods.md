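# Methods

`qibc` implements cell-cycle-resolved quantitative image-based cytometry
(QIBC): per-nucleus measurements from automated fluorescence microscopy are
treated like flow-cytometry events, but retain image-derived features (areas,
mean vs total intensities, focus counts) that flow cannot provide.  The
package covers the full chain — synthetic ground-truth populations, image
rendering, segmentation, feature extraction, DNA-content staging,
subpopulation-gated quantification, and plate-scale screen scoring — so that
every stage can be validated against known truth without any external data.

## The measurement model

Each nucleus contributes one record with area $A$ (px), total and mean DAPI
intensity, and per-channel mean intensities in camera arbitrary units
(12-bit, non-saturating).  Total DAPI is proportional to DNA content; after
anchoring the G1 mode of the total-DAPI distribution at 2C, normalized
content is

$$C = 2\,\frac{\text{total DAPI}}{\text{G1 mode}} \in [2, 4]$$

for intact interphase nuclei and mitotic figures.  Stage labels are assigned
in a fixed priority: (1) records outside $[2-\mathrm{tol},\,4+\mathrm{tol}]$
(default tol = 0.4 C) are excluded as debris or doublets; (2) mitotic cells
are recognized by H3pS10 positivity or by chromatin condensation — mean DAPI
above 1.8× the interphase median at conserved total DAPI — and sub-labelled
prophase-to-metaphase (C ≥ 3) vs anaphase/telophase (C < 3); (3) EdU-positive
cells are S phase; (4) the rest fall to the DNA anchors G1 (C < 2.35) and G2
(C > 3.65), with EdU-negative intermediate-C records sent to the nearer
anchor under a QC flag.  Without an EdU channel the intermediate window is
called S directly (1D staging).  Cyclin A corroborates but never overrides
DNA/EdU calls; conflicts are QC-flagged, not reassigned.  S cells are binned
early/mid/late at C = 2.67 and 3.33 (thirds of the replication interval).

Marker positivity thresholds (EdU, Cyclin A, H3pS10) come from a
two-component Gaussian mixture on log intensity per batch, cut at the
equal-posterior crossing, with an Otsu fallback when the mixture degenerates.
Normalization and thresholds are per batch because staining intensities are
arbitrary and batch-dependent; multiplying all intensities by a constant
leaves C and every stage label unchanged (tested property).

## Imaging operators

*Background*: grey morphological opening with a disk of radius 50 px (≫
nucleus radius), computed on a 4× block-reduced image and bilinearly
upsampled; negatives clipped.  *Segmentation*: Gaussian smoothing (σ = 1),
global Otsu threshold with a robustness guard (the threshold must exceed the
median + 3 robust σ of the image, so empty fields yield empty results), hole
filling, min-area 80 px, distance-transform watershed with seed suppression
(peaks ≥ 2 px deep, ≥ 12 px apart) and a fragment re-merge when a shared
boundary exceeds half the smaller fragment's perimeter; border-touching
objects are flagged and excluded downstream.  *Foci*: scale-normalized
Laplacian-of-Gaussian (σ = 1.5 px), per-nucleus threshold at 5× the robust
(MAD) response σ.  Both the noise estimate and the peak search run on the
nucleus mask eroded by 3σ: the band-pass response of the nucleus rim
otherwise dominates the MAD and produces rim artefacts.  Features are exact
sums/means over label masks (bit-identical to a per-pixel reference loop).

## Statistics

Condition comparisons use the two-sided Mann–Whitney U test (exact
enumeration for tie-free samples with n₁+n₂ ≤ 20, tie-corrected normal
approximation otherwise), with the rank-biserial correlation
$1 - 2U/(n_1 n_2)$ as effect size; at the working cohort size of 400 cells
per condition the null rejection rate is calibrated (measured 0.0485 at
α = 0.05 over 2,000 null pairs).  Location summaries report the mean
(population averages) with median, s.d. and MAD alongside; Benjamini–
Hochberg FDR is reported next to raw p when families of gates/timepoints are
compared.  "Cell-cycle independence" of PARP trapping is operationalized as
the maximum pairwise fold between per-stage means plus a Kruskal–Wallis test
across stages — the field describes the phenomenon qualitatively, so this
pair of statistics is this package's own formulation.  Screen scoring uses
robust z-scores, $z = (v - \mathrm{median})/(1.4826\,\mathrm{MAD})$, over
per-gene means of S-phase γH2AX well means in the treated arm; median/MAD
rather than mean/s.d. so hits cannot inflate the scale.  A plate whose gene
values are exactly degenerate (MAD = 0) is rejected rather than scored.

## The generator

The synthetic population emulates an asynchronously growing adherent cancer
cell line (U-2-OS-like).  Defaults, chosen once as realistic study
conditions:

| parameter | default | meaning |
|---|---|---|
| stage fractions | .45/.35/.15/.03/.02 | G1/S/G2/M(pro–meta)/M(ana–telo); 5% mitotic |
| dna_cv | 0.06 | staining+measurement CV of total DAPI (table path) |
| G1 nuclear area | 260 px, lognormal σ 0.15 | grows ∝ C through interphase |
| condensation_factor | 0.4 | mitotic area shrinkage at conserved total DAPI |
| γH2AX baseline | lognormal(120, 0.40) | right-skewed, strictly positive |
| EdU | 80/900 (σ .45/.35) | negative vs S-phase level |
| Cyclin A | 60 → 600 | linear ramp 0.2×→1× of G2 level through S |
| H3pS10 | 50 / 1500 | interphase vs mitotic |
| PARP1 (chromatin) | lognormal(250, 0.35) | stage-independent |

Drug effects are multiplicative and stage-gated: γH2AX fold in S (and
optionally M), trapping fold on chromatin-bound PARP1 in *all* stages (only
expressed under pre-extraction), EdU suppression, PAR suppression, and an
S/G2 accumulation shift that moves stage mass out of G1/M.  The literature
reports these responses as scatter plots without numeric effect sizes, so
the default folds used in validation scenarios (γH2AX fold 4–6, trapping
fold 3, screen effect factors 0.3/3) are this package's choices, sized to
the qualitative phenotypes they emulate — they are not measured values.

Rendering places non-overlapping ellipses by rejection sampling (2 px
boundary gap, 1000 retries), gives each nucleus an integrated DAPI of
exactly C × 45,000 a.u. over its mask (so conservation holds to Poisson
noise), adds uniform per-nucleus marker levels and Gaussian focus bumps,
then a planar background gradient (30–60 a.u.), Poisson shot noise and
Gaussian read noise (σ = 3), clipped to [0, 4095].  The feature-table path
(`simulate_features`) skips rendering and applies the measurement noise
directly; it scales to millions of cells and is what plate-scale scenarios
use.

What the generator does **not** model: 3D nuclei, optical PSF and focus
drift, cell crowding/overlap, illumination vignetting beyond a plane,
cell-to-cell DAPI staining variability in the rendered path, mid-S EdU rate
structure, or time-lapse dynamics.  Passing tests therefore demonstrate
correctness of the measurement and inference chain under a faithful but
simplified image model — not segmentation robustness on crowded real
acquisitions.

## Validation sizes and numerical choices

Reference scenarios (in `qibc.scenarios`) use: 5,000 rendered cells across
25 fields of 1024² px for the mitotic DNA anchors; 2,000 null replicate
pairs of 400 cells for Mann–Whitney calibration; 10,000 cells for staging
recovery and the trapping/damage dissociation; 10 fields × 200 cells for
segmentation recovery; 30 nuclei × 7 planted foci for spot recovery; and
100 plates × 22 genes × 3 siRNA wells × 1,000 cells for screen recovery.
Kendall association between S bins and true replication progress uses
Stuart's tau-c (the tau variant appropriate for an ordinal-vs-continuous
pair; tau-b is bounded near 0.82 by tie normalization for three bins).
Degenerate inputs resolve to flagged empties, not errors, wherever a
scientist would expect a well or gate to be simply absent (empty fields,
gates, S-less wells); hard errors are reserved for contract violations
(non-normalized fractions, missing DAPI, non-pre-extracted trapping input,
zero-MAD plates).

## Known limitations

G1-mode anchoring assumes the G1 peak is detectable below the distribution
median; heavily arrested populations with an extreme S/G2 excess can shift
the KDE mode (the secondary-mode QC flag marks suspect batches).  Doublets
of two G1 nuclei carry ~4C DNA and are indistinguishable from G2 by DNA
content alone — the 2C–4C filter removes doublets reliably only when at
least one partner has replicated.  The mean-DAPI mitotic criterion loses
~20% of mitotic cells in rendered images (mask dilation dilutes the
condensation signal); with an H3pS10 channel the recall is limited only by
the positivity threshold.
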