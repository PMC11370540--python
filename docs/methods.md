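# Methods

`synaptoloc` quantifies input-specific localization of receptor puncta at
single glutamatergic synapses from multichannel punctate fluorescence
images. This note documents the models, the rules the pipeline applies, the
defaults and why they were chosen, and what the synthetic data can and
cannot establish.

## Puncta detection

Each channel is processed independently by a find-maxima style detector
controlled by three intensity parameters (`min_intensity`, `max_intensity`,
`noise_tolerance`) and a dilation radius. A local maximum is reported as a
punctum when its peak lies in the `[min, max]` window and its prominence —
peak minus the highest saddle connecting it to any stronger maximum — is at
least the noise tolerance. Prominence is evaluated with a descending
union-find sweep (persistence pairing): components grow from the brightest
pixels downward, and when two components meet, the weaker peak either
survives as a separate punctum (prominence ≥ tolerance) or merges. Flat
plateaus collapse to a single maximum at their first row-major pixel; a
plateau shoulder that meets a stronger component at its own level has zero
persistence and is never a punctum.

Two implementation details matter for reproducibility:

* The sweep only needs pixels above `min_intensity − noise_tolerance`: any
  saddle capable of disqualifying a maximum whose peak clears
  `min_intensity` lies above that floor, so the restricted sweep is exactly
  equivalent to a full-image sweep while staying fast on large fields. This
  also makes the detected count provably non-increasing in both
  `min_intensity` and `noise_tolerance`.
* A punctum's pixel region is an 8-connected flood from its maximum down to
  `max(min_intensity, peak − noise_tolerance)`, floods running from the
  strongest punctum down so stronger territory blocks weaker floods.

Positions are 0-based `(row, col)` pixel indices referring to pixel
centers; all distances are Euclidean in pixel units × `pixel_size_nm`.
Sub-pixel localization is deliberately out of scope — distances between
puncta are measured maxima-to-maxima, so every distance carries a
half-pixel-scale quantization error (≤ ~35 nm at 50 nm pixels).

## Synapse pairing and input classification

Regions are dilated by a Euclidean disk (2 px default) before overlap
testing; the dilation compensates for juxtaposed pre- and postsynaptic
markers that need not share pixels at ~120 nm optical resolution. The disk
dilation is an explicit, reproducible stand-in for the median-blur-based
dilation used interactively in imaging software, whose effect on small
binary objects is size-dependent and not reproducible from a written
description.

A synapse is one postsynaptic punctum whose dilated region shares at least
one pixel with at least one dilated presynaptic region; it is paired to the
overlapping presynaptic punctum with the smallest maxima distance (ties to
the lower id). The number of overlapping presynaptic regions is retained
(`multi_overlap_count`) as a quality metric; with sane detection parameters
multi-overlap synapses are rare. One synapse per postsynaptic punctum keeps
the synapse count well-defined; a presynaptic terminal may serve several
synapses.

Input classification thresholds the VGLUT1 / VGLUT2 channels and asks
whether the paired presynaptic punctum's dilated region overlaps
suprathreshold signal by at least one pixel. If both channels overlap, the
larger overlapping pixel count wins and exact ties stay unassigned — the
two terminal classes are spatially disjoint in tissue, so a genuine tie is
evidence of ambiguity, not of dual identity. The overlap is tested against
the dilated presynaptic region for consistency with pairing; the raw-region
alternative is one flag away in the code.

## Receptor compartment assignment

Each receptor punctum receives exactly one call. Candidate markers are the
synaptic pre- and postsynaptic puncta whose dilated regions intersect the
receptor's dilated region. The nearest candidate (maxima distance) wins;
exact distance ties resolve to the postsynaptic marker, matching the
empirical observation that the closer marker is postsynaptic in the large
majority of cases. A winning postsynaptic marker farther than 400 nm
demotes the call to `none` — the postsynaptic pool therefore includes both
synaptic and near-synaptic (extrasynaptic) receptors within that radius,
and no attempt is made to split them. Presynaptic calls are overlap-only
with no distance cap. The 400 nm cutoff applies only to postsynaptic
assignment, and the postsynaptic count is non-decreasing in the cutoff.

Summaries report both denominators used in the field: per-synapse rates
(fraction of synapses, overall and per input class, carrying ≥ 1
postsynaptic or presynaptic receptor punctum) and per-receptor rates
(fraction of receptor puncta that are postsynaptic, and at VGLUT1+/VGLUT2+
synapses). Distance distributions are kept per stratum; histograms use
fixed-width bins from 0 (20 nm default — the bin width of the original
frequency plots is not stated, so this is a package choice) with median and
IQR computed on raw values via linear-interpolation quantiles.

## Nearest-neighbor interaction strength

The spatial correlation of two punctate signals is summarized by a Gibbs
step-potential fit to the nearest-neighbor distance distribution. With
q(d) the *context distribution* — NN distances from a dense regular grid
over the region to the reference pattern Y, approximating a uniformly
placed point — the observed NN distances from X to Y are modeled as

    p(d) ∝ q(d) · exp(ε · 1[d < t])

and (ε, t) minimize the summed squared difference between binned model and
observed densities: t by grid search over bin edges up to the 95th
percentile of q, ε by bounded 1-D minimization (|ε| ≤ 8) at each t. ε > 0
means X lies closer to Y than chance placement predicts. The statistic is
computed in nm throughout so it is comparable across pixel sizes; defaults
are grid step 200 nm (4 px at the 50 nm reference pixel) and bin width
50 nm (1 px). These defaults are this package's own: the original analysis
ran an external plugin at unstated defaults, so sign, ordering and null
behavior — not numeric parity — are the contract. Output metadata flags the
defaults accordingly.

Significance references: (1) the 90°-rotated control — rotating one pattern
about the region center preserves its internal structure while destroying
cross-correlation; (2) a Monte-Carlo CSR null — refitting ε for uniformly
resampled X patterns (99 reps by default). Properties verified by the test
suite: ε̂ is invariant under common translation and common rotation of both
patterns; the CSR null is centered on 0 (mean within 3 SE over 200 reps);
the null band widens as n decreases; and data simulated from the step
potential itself (ε₀ = 2, t₀ = 400 nm, n = 1000, 20 seeds) recover ε within
a few percent, well inside the ±20% contract.

Degenerate inputs (all mass in one histogram bin) raise a fit error rather
than returning a meaningless ε.

## FISH quantification

Cell ROIs come from a Gaussian blur (σ = 2 px) of the composite of nuclear
and mRNA channels, a global threshold, 8-connected labeling, and a minimum
area filter (100 px default, to suppress debris; the original protocol
states none). Per-channel particle thresholds are calibrated on negative
controls: the smallest threshold on a `start + k·step` grid at which no
control cell shows more than 3 particles — counts are non-increasing in the
threshold, so the scan terminates and the calibrated threshold satisfies
the criterion by construction. Particles are counted by the same maxima
detector, assigned to the ROI containing the maximum. Multi-plane stacks
are processed plane-by-plane and summed per ROI; no z-linking is attempted
because none is described for the source protocol.

## Reporting

The animal is the experimental unit: per-FOV metrics are averaged
(unweighted, skipping undefined values) per mouse before any comparison.
Rates with zero denominators are reported as undefined, never as zero.
Group comparisons use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom, two-sided p, and the 95% CI of the
mean difference; it accepts raw values or (mean, SD, n) summaries. ANOVA
variants, mixed-effects models and multiple-comparison corrections are
deliberately not reimplemented — the per-FOV and per-mouse CSVs are
structured so standard tools can run them. Puncta densities are normalized
to 25 μm², the reference panel area.

## Synthetic data: what it emulates and what it does not

The generator renders isotropic 2-D Gaussian spots (σ = 120 nm, the scale
of the ~120 nm XY optical resolution) on a 50 nm pixel grid, on a uniform
background (100 counts) with additive Gaussian noise (SD 10) and spot
amplitudes of 800 ± 150 counts. Synapse centers are sampled uniformly with
a minimum spacing of max(4σ, 600 nm) by rejection sampling; the 600 nm
floor keeps the wide VGLUT2 envelopes of sensory terminals from reaching
neighboring CT presynaptic regions, so ground-truth labels stay
unambiguous. The pre marker sits at the center; the post marker is offset
190 ± 30 nm in a random direction; the receptor, when present, is offset
150 ± 40 nm from the post marker in a direction biased away from the
presynaptic side (angular SD 45° about the pre→post axis) — receptors
belong to the postsynaptic membrane, and this bias reproduces the
observation that the nearest marker is postsynaptic in > 95% of cases.
Receptor occupancy is realized as an exact-size random subset
(round(f · n) synapses per input class) rather than i.i.d. coin flips; this
stratified design satisfies the binomial-bound invariant trivially and
keeps occupancy-recovery tests sharp. Sensory terminals render n_sites
(default 4) presynaptic spots — one true release site with its post/receptor
partners plus decoys kept ≥ 600 nm from every true marker — under a single
wide VGLUT2 envelope (σ = 250 nm, amplitude 600); CT terminals render one
VGLUT1 spot co-centered with the presynaptic marker. Negative controls
contain background, noise, and a Poisson-count number of low-amplitude
(35% of the spot mean) spurious spots.

Pipeline-default detection parameters (`default_analysis_config`) are
matched to these rendering conditions: min intensity 350, noise tolerance
150, VGLUT thresholds 300.

Not emulated: 3-D structure (the analysis is single-plane by design),
shot-noise statistics, optical aberrations, tissue autofluorescence,
antibody labeling efficiency, and out-of-plane fluorescence. Consequently,
passing recovery tests shows the *rules* are implemented correctly and are
recoverable under realistic geometry and noise — it does not certify
detection performance on real tissue, where parameter choice per imaging
session remains the user's responsibility.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configuration and seed give
bit-identical images, tables and fits. The recovery analyses use a
2048 × 2048 px FOV (102 × 102 μm at 50 nm pixels) with 440 synapses; NN
analyses use 20 × 20 μm regions with 100–500 points and 99-rep nulls —
sizes chosen to give tight statistical bounds (binomial SE ≤ 2.5 points on
occupancy; ±1 px on median distances) while a full run of every analysis
completes in well under a minute on one core.

## Known limitations

* Maxima-based distances quantize at the pixel scale; medians inherit up to
  ~half a pixel of bias.
* The interaction-strength values are not numerically comparable to the
  original plugin's output, only in sign/ordering/significance.
* One-synapse-per-postsynaptic-punctum cannot represent genuine
  many-to-many contacts; `multi_overlap_count` flags where that assumption
  is stressed.
* Threshold calibration is only as good as the negative controls supplied;
  a control missing a spurious-signal mode will under-threshold.
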