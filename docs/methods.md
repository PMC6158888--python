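# Methods

This note documents the models, parameters and numerical choices behind
`halopet`, and what its synthetic validation does and does not establish.

## The adaptive halo threshold

A lesion's SUV range `[0, top]` is quantized into ten layers, where
`top = (floor(10·SUVmax) + 1) / 10` is the smallest multiple of 0.1
strictly above SUVmax (SUVmax 13.07 → top 13.1). Defining layers as
fractions of `top` rather than of SUVmax itself reproduces the display
window the procedure is defined on and guarantees the hottest voxel falls
in layer 9 rather than above the window; the relative deviation from a true
%SUVmax layering is below `0.1 / SUVmax` (< 4% for the faintest avid
lesions, < 1% for typical ones). Fixed-percentage thresholds reference the
same `top` for consistency.

The peritumoral halo layer is the decile band between tumoral uptake and
background showing an abrupt increase in band thickness. Detection
proceeds:

- **Analysis shell.** The 26-connected component above `0.2·top`
  containing the seed, dilated by `margin_mm` (default 15 mm, metric
  dilation via a Euclidean distance transform), clipped to the user's ROI
  box. The clip matters for faint lesions, where `0.2·top` can fall below
  the background and the supra-threshold component would otherwise swallow
  the field of view.
- **Background decile.** The decile of the median SUV over an annulus
  outside the shell (10 mm thick, starting `margin_mm` from the avid
  component). A median exactly on a layer boundary is assigned to the
  upper layer, consistent with the half-open label intervals.
- **Band thickness.** `t_k = V_k / mean(A_inner, A_outer)` per band inside
  the shell. Interface areas are voxel-face counts scaled by the face area
  and by 2/3 — axis-aligned face counting overestimates an isotropically
  oriented curved surface by 3/2 (the staircase effect). The estimator is
  pinned by an analytic spherical-shell test (2 mm truth recovered within
  15% at 0.5 mm voxels). Bands with fewer than `min_voxels` (default 5)
  voxels are flagged unreliable and cannot carry a detection.
- **Halo selection.** Candidates are bands `b+1 … 8`, strictly between
  background and the hottest core — an interior irregular layer can never
  be selected, because the halo is by definition adjacent to the
  background-connected run. Scanning inward from `b+1`, a band belongs to
  the halo while `t_k ≥ ρ·t_{k+1}` (default ρ = 2.0; the source procedure
  specifies only "abrupt", so ρ is exposed). The innermost such band sets
  the threshold `10·(k+1)` percent. When no band fires the criterion the
  band adjacent to the background is taken (`fallback_adjacent`); this is
  the canonical halo geometry and guarantees a defined answer. The
  threshold is clamped to the observed clinical 20–90% range as a guard,
  although the candidate range already implies it.

The threshold convention is the *inner edge* of the halo. Whether the true
gradient maximum sits at the inner edge, the middle, or the outer edge of
the halo is an open question of the procedure itself; alternatives are not
implemented.

## Metrics

Metabolic tumor length is the inclusive craniocaudal voxel span times the
z spacing (a single-voxel mask has the length of one voxel), reported in
cm — the digital analogue of a straight sagittal ruler measurement along
the esophagus. A principal-axis variant is available behind a flag for
lesions oblique to the scanner axis. MTV is voxel count times voxel
volume (mL); TLG = SUVmean·MTV holds by construction.

The homogeneous/heterogeneous uptake-pattern proxy counts 26-connected
components of the >90% layer within the mask: two or more cores, or a
single core whose centroid is offset from the mask centroid by more than
0.35 equivalent-sphere radii, classify as heterogeneous. The 0.35 cutoff
is this package's proxy constant for what is clinically a visual judgment;
it is configurable and not a published value.

## The phantom generator

The generator emulates an FDG-avid esophageal lesion: a plateau of uptake
`S` over uniform background `B` (default 1.0 SUV, a typical mediastinal
level), shaped as a capsule (cylinder with hemispherical caps; a prolate
spheroid when the requested length does not exceed the diameter), on an
isotropic 2.65 mm grid, convolved with an isotropic Gaussian PSF
(σ = FWHM/2.3548; default FWHM 7 mm, a stated assumption — the scanner
value is not published — and swept in tests), plus seeded additive
Gaussian noise. Optional hot-core perturbations produce heterogeneous
lesions. The exact pre-blur voxel mask is the ground truth, standing in
for the pathologic reference length. Cohorts draw `S` log-uniformly over
[3, 20] and length uniformly over [10, 90] mm, matching the 0.8–9.8 cm
span of measured metabolic lengths in avid esophageal tumors; cohort noise
defaults to SD 0.15 SUV.

What the phantom does **not** model: Poisson counting statistics and
reconstruction (noise is additive Gaussian), spatially varying background,
respiratory motion, and — importantly — the convex, non-plateau uptake
profiles of real tumors. Two consequences follow.

First, on a Gaussian-blurred plateau all decile bands near the edge are
sub-voxel thick at 2.65 mm resolution, so the ρ-ratio criterion never
fires and detection always takes the fallback path. The adaptive behaviour
(threshold falling with SUVmax in percent terms, rising in SUV terms) is
still fully expressed, because it is carried by where the background sits
on the decile ladder.

Second, the fallback threshold — two deciles above the background level —
lies below the ~40–50% partial-volume level at which a blurred plateau
crosses its true edge, so the adaptive method carries a small constant
positive length bias (~1–2 voxels) on these phantoms. Its error *spread*
(Bland–Altman SD) is nonetheless the smallest of the three methods, and
the two fixed methods show their characteristic signed-error correlations
with SUVmax (positive for SUV 2.5, negative for 40%). On this idealized
cohort the fixed SUV 2.5 method attains a smaller *mean absolute* error
than the adaptive method, because 2.5 SUV happens to sit near the ideal
edge level for the mid-range SUVmax that dominates log-uniform sampling —
a property of the plateau-with-uniform-background idealization, not of the
method; passing or failing that ordering on phantoms says little about
clinical images, where backgrounds vary and profiles are not plateaus.

## Statistics

Regression, Spearman correlation (average-rank ties) and the tie-corrected
Kruskal–Wallis test delegate to scipy. Bland–Altman agreement uses the
sample (n−1) SD and fixed 1.96 limits; the proportional-error test is the
Pearson correlation of differences against pairwise means, flagged
undefined when either is (near-)constant. Dunn's pairwise post-hoc z tests
are computed from the standard rank formulas with tie correction,
uncorrected for multiplicity by default (Bonferroni by flag). Weighted
kappa uses disagreement weights `|i−j|/(m−1)` (linear, default) or their
square; both weightings are reported for the published 8×8 inter-observer
table, whose printed value 0.936 is reproduced by the **linear** weighting
(0.9357; quadratic gives 0.9819).

## Numerical conventions

Voxel indexing is 0-based with inclusive boxes; lengths are mm internally,
cm in reports; volumes in mL. The third index axis is craniocaudal;
volumes are reoriented to RAS on load. Connectivity is 26-neighborhood
throughout; SUVmax ties break to the lowest linear index, making every
result deterministic. The `window_top` floor uses a 1e-9 epsilon against
binary-float representations of exact multiples of 0.1. Noise excursions
below zero are clipped so volumes remain valid SUV fields.

## Problem sizes

The default validation sizes keep everything desk-scale: phantoms of
roughly 45×45×80 voxels, a 30-lesion cohort for the accuracy comparison,
five noiseless phantoms for the threshold–SUVmax sweep, and 1000 null
replicates for the Kruskal–Wallis calibration. These choices are the
package's own; larger cohorts change none of the qualitative conclusions.
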