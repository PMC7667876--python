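# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want to know. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## PolyA-site counting (`pasquant`)

Coordinates are 0-based half-open throughout. A cleavage site at position
*p* on the + strand extends to [p − ext5, p + ext3 + 1) with defaults
ext5 = 200, ext3 = 20 (mirrored on the − strand); the cleavage nucleotide is
inside the window so that a read ending exactly at the site is countable,
giving length ext5 + ext3 + 1 = 221 nt. Same-strand windows that overlap
(strictly; touching half-open windows do not) are merged and their gene
associations unioned. A read — reduced to its strand and 3′-most base — is
counted in at most one window (merged windows are disjoint, so a sorted
search assigns it); a window shared by several genes contributes its reads
to each of them, since gene counts are defined as the sum over the gene's
windows and the shared-window case is not resolvable from the annotation.
Strand match between read and window is required by default (the protocol is
strand-specific) and can be relaxed for robustness checks. Dual-species
counting uses one annotation space tagged by species, so no alignment step
is modelled. Reads overlapping no window are tallied as unassigned rather
than dropped silently.

Spike-in scaling divides the per-sample fly/human PAS-read ratio by the cell
mixing ratio (0.25 for 1:4, 1.25 for 5:4); equal capture efficiency gives
1.0 for either mix. Condition-level differences are tested by one-way ANOVA
on the scaled ratios. RPM divides by the per-sample total of PAS-associated
reads (optionally per species — for spiked samples human RPM should be
normalized by human totals) and multiplies by 10⁶.

## Differential expression stand-in (`expression`)

The test is intentionally minimal and is validated by its error-rate
behaviour, not by numeric equality with any production DE tool:

* size factors: plain median-of-ratios — median over genes (expressed in
  every sample) of count / geometric mean, computed in linear space;
* per-gene dispersion α by method of moments from the pooled within-group
  variance, Var(Y) = μ + αμ², floored at 10⁻⁸, no shrinkage;
* log₂ fold change of group means with a 0.5 pseudocount on the normalized
  scale; delta-method standard error; Wald z = LFC/SE referred to a
  **t distribution with n₁ + n₂ − 2 df**. With six replicates per group the
  plug-in dispersion is noisy and the normal reference is anticonservative;
  the t reference restores near-uniform null p-values (checked by KS test in
  the suite). Production tools solve the same problem with empirical-Bayes
  dispersion shrinkage, which is out of scope here;
* Benjamini–Hochberg across tested genes; genes with all-zero counts in the
  contrast are reported untested (NaN) and excluded from the BH family;
* a cross-check test confirms the stand-in's fold changes correlate > 0.99
  with an independent NB-GLM implementation on a common table, with
  consistent significance calls on injected effects.

Time-series standardization uses log₂(normalized + 1) in place of a
regularized log transform: the shrinkage estimator of the latter is
library-specific, while the downstream contract — per-gene mean 0, SD 1
(sample SD, ddof = 1) across timepoints after replicate averaging — does not
depend on the variance stabilizer. Genes constant across timepoints (up to a
relative 10⁻¹⁰ tolerance, which absorbs floating-point dust) have no scale
and are dropped with a record. Note that depth normalization removes any
change shared by all genes; cohort-level patterns are therefore defined
relative to the stable background, which is how the synthetic cohort tests
are constructed.

Half-life binning: genes missing either value are excluded, then genes whose
log₂ half-life is more than 2 SD from the mean log₂ half-life; survivors are
sorted by log₂ fold change and split into 10 equal-sized bins (`array_split`,
earlier bins take the remainder). The Pearson correlation, regression line
and correlation t-test are computed over the 10 bin means — the relationship
is defined at the bin level, where single-gene noise is averaged out.

The nuclear/cytoplasmic scatter classifier drops genes with base mean < 30
(configurable) or no adjusted p in either compartment, labels the rest
nucleus-only / cytoplasm-only / both / neither at padj < 0.05, and reports
the cross-compartment Pearson r of log₂ fold changes.

## Circadian reset (`circadian`)

Baseline detrending subtracts a centered 24 h moving average (odd sample
window, reflected edges). The masked cold window is bridged by linear
interpolation *for the baseline only* and re-masked afterwards; skipping the
gap instead biases the baseline for half a window on either side and was
measurably worse on phantoms. The detrending algorithm of the commercial
package used in plate-reader practice is unpublished, so per-well numeric
equality with it is not claimed anywhere.

Peak landmarks: the detrended signal is smoothed with a 5-sample moving
average; peaks and troughs are detected per contiguous unmasked segment
(nothing can peak inside the gap, and no artificial cliff is introduced at
its edges) with a prominence of 20 % of the pre-anchor amplitude, where that
reference amplitude is the 2.5–97.5 % quantile span of the smoothed
pre-anchor segment (robust to single noise excursions). Each extremum is
then refined by a local quadratic fit of the raw signal over ±6 h (about a
quarter period): the vertex gives sub-sample time and a noise-averaged
height. The fit falls back to the discrete sample if it degenerates or its
vertex leaves the window. Ties between equal candidates resolve to the
earliest sample. The anchor is the cold-window start for short (5 h)
exposures and the window end for day-long ones, matching how the landmark
peak is defined for each design; the landmark is the *second* peak after the
anchor, and its subsequent trough completes the pair.

Phase shift = [(pk + tr)_test − (pk + tr)_ctrl]/(2 × period) × 100, wrapped
into (−50 %, +50 %] because phase is circular; positive = delay. Amplitude
fold change = log₂ of the peak-to-trough ratio; any common attenuation from
smoothing or fitting cancels in the ratio. Variance alignment uses the
Brown–Forsythe (median-centered Levene) test with Holm–Bonferroni adjustment
over the declared family of comparisons. Threshold tests are one-sided
one-sample t-tests in the direction of the observed group mean against
+5 %/−5 % of period (phase) or ±log₂(1.4) (amplitude): strict exceedance, so
a mean sitting exactly on the threshold is never significant. Period and
amplitude of free-running recordings come from the first autocorrelation
maximum in a 16–36 h band with parabolic refinement and mean peak-to-trough
half-excursion; an autocorrelation below 0.2 at the candidate lag is treated
as arrhythmic and raises.

## Chromatin architecture (`nucleome`)

Nuclear mask: Gaussian smoothing (σ = 0.04 µm per axis, at least half a
voxel), then a two-step threshold — Otsu on log intensity to find the
nucleus robustly (log compression keeps Otsu from splitting dim vs dense
chromatin instead of background vs nucleus), then a final cut at the
midpoint between the background median and the lower quartile of the
provisional foreground, which places the boundary halfway up the edge ramp
rather than at its foot — followed by per-slice hole filling and the largest
connected component.

Density classes: a 7-component Gaussian mixture on in-mask voxel intensity.
Means initialize evenly over the 0.5–99.5 % intensity range (a quantile
initialization piles several components into the dominant interchromatin
mode and EM stays there). The variance is tied across components: intensity
spread within a class is dominated by acquisition noise, and with free
variances EM can park one broad component across several modes when class
volumes are very unequal (observed on phantoms with a 60 % class 1).
Components are relabeled by ascending mean so class 1 is always
interchromatin. Optional iterated-conditional-modes sweeps add spatial
smoothing; they default off since the generators produce spatially coherent
fields anyway. The original 7-class classifier is an unpublished
HMM-derived R script; this implementation keeps its contract (7 ordered
density classes over a nuclear mask) and is validated on phantoms, not
against the original's outputs.

Chromatin ratio = volume of classes 2–7 over classes 1–7. Centroids: Otsu
threshold of the marker channel, non-foci voxels zeroed, inverted-intensity
3D watershed from markers at intensity maxima (splits touching foci at their
saddle), intensity-weighted centre of mass per region, converted to µm with
per-axis voxel sizes. Per-centroid quality is taken from a supplied quality
grid (mean over the region) when available — mirroring reconstruction-
confidence maps — otherwise a local-contrast proxy (region mean over
background SD). Filtering drops centroids below threshold and warns if
nothing survives.

Enrichment per class k: log₂[(count_k/total)/(vol_k/vol_total)], with
zero-count classes capped at ±8 log₂ units for display and numeric stability
(a class with zero volume is NaN). Nearest-neighbour analysis: per nucleus,
each source centroid's distance to the nearest destination centroid (k-d
tree; an O(n²) oracle backs it in tests); distances pooled over all nuclei
and conditions; values above pooled mean + 2 SD excluded — one-sided, since
distances are positive and the rule exists to remove large artifacts — then
mean, SEM and n per condition, with Welch's t-test for pairwise comparisons.

## FISH counting (`fishquant`)

Maximum projection over a half-open z-range. Spot detection follows the
noise-tolerance contract: a local maximum counts only if it stands at least
`tolerance` above the highest saddle connecting it to any higher maximum —
implemented with the h-maxima transform, plateaus collapsing to their
centroid. This is a behavioural re-specification, not a pixel-exact clone of
any particular GUI command; it is invariant to adding a constant to the
image, and with tolerance → 0 on a noiseless image it returns every strict
local maximum (checked against a brute-force oracle). Compartment masks come
from Otsu thresholds (manual override available, since interactive
thresholding was the practice) on smoothed DAPI (nucleus) and diffuse FISH
background (cell); the nucleus is forced inside the cell, cytoplasm =
cell − nucleus, and spots on the nuclear boundary belong to the nucleus —
a deterministic tie rule. Per-image densities are counts per compartment
area; conditions are compared with ANOVA-family Tukey HSD.

## Synthetic generators (`synthgen`)

All generators take a single integer seed, derive any sub-streams from it
deterministically, and return ground truth sufficient to score every
downstream operation. Zero-noise / zero-effect settings force exact
downstream recovery, and those identities are tested.

* **Reads**: per gene, counts follow a gamma–Poisson (NB) draw around
  weight × library size (dispersion 0.1 by default; 0 gives an exact
  multinomial). Each read's 3′ end falls uniformly inside the extension
  window of one of the gene's sites, so window geometry is exercised while
  counts stay recoverable; a configurable background fraction lands ≥ 1 Mb
  beyond any window. Defaults: 10,000 human and 2,500 fly reads (the 1:4
  mix). No sequence-level simulation — reads are coordinates, not FASTQs.
* **Plates**: damped cosine A·e^(−λt)·cos 2π(t − φ)/T plus polynomial drift
  and Gaussian noise; defaults T = 24 h, λ = 0.005 h⁻¹ (about a 50 % decay
  over a 6-day recording, typical of dexamethasone-synchronized reporter
  cells), noise SD 0.1 (10 % of unit amplitude), 30-min sampling over 168 h,
  cold window 72–96 h, six groups staggered 4 h apart at offsets
  3, 7, …, 23 h. The offsets deliberately avoid placing a landmark peak
  exactly on the window boundary, where "second peak after the anchor"
  is ill-defined — the staggered-synchronization design avoids the same
  degeneracy. Samples inside the window are missing, not zero, because
  plates physically leave the readers. Post-window wells resume with a
  configurable phase delay (fraction of period), amplitude factor, or a
  full reset to one common phase (the clock-resetting scenario). Paired
  control wells share group and noise statistics but keep recording at
  37 °C.
* **Nuclei**: an ellipsoidal mask (42 % of each grid dimension as radius) on
  a 32×64×64 grid at 0.125×0.04×0.04 µm voxels (SIM-like anisotropy); a
  smoothed Gaussian random field rank-sliced at the configured volume
  fractions gives the class map, so fractions are exact by construction;
  peripheral thickening adds a shell-shaped bump before slicing,
  concentrating dense classes at the rim and pushing interchromatin inward.
  Class intensity means are strictly increasing (20 … 170, SD 4, background
  2). Surface-marker centroids sample the one-voxel rim (NPC-like);
  interior-marker centroids sample voxels with per-class bias weights
  (default: all weight on class 1, hnRNPC-like). Quality scores are
  clipped-normal. No optics: no PSF, no reconstruction artifacts — passing
  tests show the analysis recovers what the phantom encodes, not that it is
  robust to real SIM artifacts.
* **FISH images**: Gaussian spots (σ = 1.5 px) over a textured background,
  rejection-sampled with pairwise separation ≥ 4σ by default — spots closer
  than ~2σ merge into one intensity maximum and are not countable even in
  principle; the scene generator adds a circular cell with a concentric
  nucleus, diffuse cell-outlining background and a DAPI channel.

## Problem sizes

The suite and the acceptance script run at desk scale by choice: 1,000 genes
× 12 samples for DE calibration, 1,000 reads × ~50 windows for the counting
oracle, 10 wells per phase group, 32×64×64-voxel phantoms (16×40×40 for the
40-nucleus group comparison), 10,000 centroids for enrichment nulls, and
200–1,000 Monte-Carlo replicates for error-rate checks. These sizes put
every Monte-Carlo tolerance comfortably above its standard error while the
whole suite stays in the minutes range.

## Known limitations

* The DE stand-in has no dispersion shrinkage, no outlier handling and no
  independent filtering; gene-count tallies from the original study are not
  comparable targets.
* Detrending/amplitude definitions of the commercial rhythm-analysis tool
  are unpublished; only formula-level behaviour is reproduced.
* The 7-class segmentation matches the published contract, not the original
  script's voxel-level output; class boundaries on real SIM data would also
  depend on reconstruction settings.
* The FISH maxima detector mirrors the noise-tolerance semantics, not the
  exact plateau/edge handling of any specific implementation.
* Generators do not model optics (PSF, spherical aberration, bleaching) or
  sequence-level read artifacts; conclusions from synthetic recovery apply
  to the statistical structure, not to instrument-specific failure modes.
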