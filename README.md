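# coldclock

Desk-scale, fully tested re-implementations of the bespoke computations used
to characterize how mammalian cells respond to cooling below the
physiological range (28, 18, 8 °C): cold compacts chromatin, stalls nuclear
export of messenger RNA so that cold-induced transcripts (including the
circadian negative-limb genes *PER*, *CRY*, *REV-ERBα*) accumulate in the
nucleus, and their release into the cytoplasm on rewarming resets the phase
and boosts the amplitude of the cellular circadian clock.

The package is aimed at computational biologists who want the quantitative
machinery behind such a study as an importable, seedable library — each
analysis stage is exercised end to end on synthetic data with known ground
truth, so every statistic it reports is validated by parameter recovery
rather than by visual inspection.

## What it computes

**3′-end read counting with spike-in scaling** (`coldclock.pasquant`).
Annotated polyA sites are extended 200 nt upstream and 20 nt downstream of
the cleavage position (0-based half-open; the cleavage base is included, so
an unmerged window spans ext5 + ext3 + 1 nt), overlapping same-strand windows
are merged with gene unions, and reads narrowed to their 3′-most nucleotide
are counted per window and aggregated per gene. With fly cells mixed into the
human sample at a known cell ratio *m* before lysis, the scaled spike-in
ratio per sample is

    scaled = (fly PAS reads / human PAS reads) / m

which equals 1 under equal capture efficiency; departures across conditions
indicate absolute RNA-level changes. RPM = counts / total PAS reads × 10⁶.

**Differential expression and time-series summaries** (`coldclock.expression`).
A deliberately simple negative-binomial Wald test: median-of-ratios size
factors, per-gene method-of-moments dispersion α with Var(Y) = μ + αμ²,
Wald statistic z = log₂FC / SE referred to a t distribution with
n₁ + n₂ − 2 degrees of freedom, Benjamini–Hochberg adjustment. Plus per-gene
standardization of time series to mean 0 / SD 1, decile binning of log₂ fold
change against log₂ mRNA half-life (2-SD half-life exclusion), and
classification of genes by their nuclear-vs-cytoplasmic significance
pattern after a base-mean ≥ 30 filter.

**Circadian reset quantification** (`coldclock.circadian`). Bioluminescence
well profiles (30-min sampling) are baseline-detrended with a centered 24 h
moving average, scaled to a genotype-matched control mean profile, and the
second peak after the cold window (and its subsequent trough) is located by
prominence-filtered peak detection with local quadratic refinement. Then

    phase shift (%) = [(pk + tr)_test − (pk + tr)_control] / (2 × period) × 100
    amplitude FC    = log₂[(pk − tr)_test / (pk − tr)_control]

with Brown–Forsythe (median-centered Levene) tests for the collapse of
peak-time spread, Holm–Bonferroni adjustment, and one-sided one-sample
t-tests against the ±5 % phase and ±log₂(1.4) amplitude thresholds.

**3D chromatin analysis** (`coldclock.nucleome`). From the DAPI channel: a
nuclear mask (two-step Otsu), a 7-class intensity/density segmentation
(Gaussian mixture with tied variance, classes ordered by mean intensity;
class 1 = interchromatin), the chromatin:nuclear volume ratio (classes 2–7
over 1–7), marker centroid extraction (Otsu + 3D watershed +
intensity-weighted centres of mass), MCNR-style quality filtering, per-class
centroid enrichment log₂[(count_k/total)/(vol_k/vol_total)], and NPC→hnRNPC
nearest-neighbour distances with a pooled mean + 2 SD outlier exclusion.
All geometry in physical µm with anisotropic voxels.

**RNA-FISH spot counting** (`coldclock.fishquant`). Maximum-intensity
projection, nuclear/cell masks from DAPI and diffuse FISH background,
noise-tolerance maxima detection (prominence ≥ tolerance, the ImageJ
Find-Maxima contract), per-compartment transcript densities and Tukey HSD
across conditions.

**Synthetic data with ground truth** (`coldclock.synthgen`). Seeded
generators for every input above: NB-distributed dual-species reads, damped
noisy ~24 h oscillations with a masked cold window and programmable phase
delay / amplitude change / full phase reset, 3D nucleus phantoms with a
7-level density field and peripheral thickening, and Gaussian-spot FISH
scenes.

## Worked example

`examples/03_circadian_reset.py` simulates six phase-staggered groups of
reporter wells, masks a 24 h cold window, injects a 10 %-of-period phase
delay and a 1.5× amplitude gain, and recovers both:

```
wells analyzed: 60 cold + 60 control
recovered phase shift: 10.02% of period (injected 10.0%; positive = delay)
recovered log2 amplitude FC: 0.556 (injected 0.585)
one-sided t-test vs the 5% threshold: p_adj = 3.94e-50 -> significant reset
```

The recovered shift sits within half a sampling interval of the injected
truth, and the amplitude fold change within 0.03 log₂ units; the threshold
test confirms the reset exceeds the 5 %-of-period significance bar. The
other scripts in `examples/` exercise PAS counting, the nuclear-restricted
differential-expression pattern, chromatin class segmentation and FISH
counting in the same style.

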