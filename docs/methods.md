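# Methods

`cardiotransit` implements, as tested code, the two computational arms of a
pressure-overload heart-failure study design: quantification of calcium
transients from confocal line-scan recordings of paced hiPSC-derived
cardiomyocytes, and identification of genes with conserved expression
trajectories across a human aortic-stenosis cohort (NF → CH → mHF) and the
mouse TAC model (sham → 1wTAC → 8wTAC).  A synthetic-data module emulates
both data modalities with known ground truth, so every stage of the
analysis can be exercised and validated without external downloads.

## Imaging arm

### Signal model

A line-scan recording is a (lines × pixels) intensity array acquired at
1057.7 lines/s over 512 pixels (45 µm), 20,000 lines per cell, with field
stimulation at 0.25 Hz.  The generator draws each pixel of line *t* as an
independent Poisson count with expectation

    photon_gain · w(t) · profile(x) · exp(−bleach_rate · t),

where `w(t)` is the cell's noiseless fluorescence waveform in photon
units.  The default spatial profile is flat and bleaching is off; both are
exposed as parameters.  Because the rate is constant along a line, the
sampler tabulates the Poisson pmf per line (support λ ± 10√λ + 20,
truncated mass < 1e-20) and draws by alias-method inversion with one
uniform per pixel; this is exact to double precision and roughly an order
of magnitude faster than generic Poisson transforms, which is what makes
full-scale population simulations (≈ 7 × 10⁹ pixel draws) a few minutes'
work on one CPU.

### Waveform

Per pacing epoch (4 s) the waveform rests at F0 for the first fifth of the
epoch, rises along a raised-cosine upstroke, and decays back toward F0.
The three free parameters are anchored exactly to the analyzer's metric
definitions:

* **amplitude** — the peak equals `F0 · amplitude_peak` (amplitude is the
  F/F0 ratio throughout; the study reports unitless amplitudes ≈ 2.5–3.5);
* **rise time** — the upstroke duration is scaled so the interval from the
  15%-of-height crossing to the peak equals `rise_time_ms` (the crossing
  sits at acos(0.7)/π ≈ 25.3% of the upstroke);
* **decay-50** — the decay is `F0 + H · 2^(−φ(t)/d50)` with the time warp
  `φ(t) = k(√(t² + b²) − b)`, which starts with zero slope, satisfies
  `φ(d50) = d50` exactly (so the half-height crossing is at `decay50_ms`),
  and is asymptotically exponential.

The shoulder width `b` is chosen to match the decay-side curvature at the
peak to the upstroke's, making the peak locally symmetric.  This matters:
a strictly exponential decay meets the cosine upstroke with a slope kink,
and the 21-point smoothing filter then displaces the argmax by ~2 line
periods, biasing rise and decay in opposite directions.  With the
curvature-matched shoulder the noiseless end-to-end recovery error is
below 0.4 line periods (0.35 ms) everywhere on the grid amplitude ∈
[1.5, 5], rise ∈ [80, 400] ms, decay-50 ∈ [200, 900] ms.

The 20% resting segment per epoch gives the baseline estimator an
unambiguous resting population (see below).  The decay does not fully
return to F0 before the next stimulus (as in real paced recordings); the
residual at the epoch boundary is ≤ ~2% of transient height for the
preset parameter ranges.

### Population model

A population preset holds group-level means for the three metrics plus
variance components: per-metric batch effects N(0, σ_b) for each of 3
differentiation batches, and between-cell variation N(batch-shifted mean,
CV · group mean), truncated to valid parameters with bounded retries
(limit 100).  Cells are split near-evenly over batches (181 → 61/60/60).
The study does not print variance magnitudes; the defaults CV = 0.2 and
σ_b = 5% of the mean are fixed stand-ins.  Group means are calibrated to
the reported values:

| group | amplitude (F/F0) | rise (ms) | decay-50 (ms) | n cells |
|---|---|---|---|---|
| WT | 2.8 | 169.5 | 603.5 | 181 |
| KO | 3.5 | 199.0 | 460.8 | 183 |
| WT + helothermine | 2.5 | 207.1 | 731.9 | 180 |
| KO + helothermine | 2.8 | 170.0 | 650.2 | 180 |

Cell counts for the treated groups are not reported; 180 is the default.
The generator does not emulate motion artifacts, ratiometric imaging,
spontaneous activity, or cell-to-cell waveform-shape variation beyond the
three metrics — passing tests demonstrate correctness of the measurement
chain under the stated noise model, not robustness to those real-data
phenomena.

### Measurement chain

extract (mean over pixels per line) → smooth → baseline → normalize →
segment → measure → summarize.

* **Smoothing** is Savitzky–Golay with polynomial order 6 over 10
  neighbours each side (window 21 ≈ 19.9 ms); edges are handled by
  evaluating the polynomial fitted to the nearest full window.  This is
  the standard realization of "local polynomial smoothing" of the
  acquisition software; it reproduces degree-≤6 polynomials exactly.
* **Baseline** is the median of samples at or below the 20th percentile
  of the smoothed trace — robust at the ~30% duty cycle of these
  transients and exact on noiseless traces.  Metrics are measured on the
  smoothed, F/F0-normalized trace.
* **Segmentation** cuts contiguous 4-s epochs from the stimulus offset;
  the partial trailing epoch is dropped (18.91 s → 4 epochs, hence the
  per-cell mean of 4 transients).
* **Measurement**: peak = epoch argmax (earliest on ties), onset = last
  upward crossing of baseline + 0.15 · height before the peak, decay-50 =
  first downward crossing of baseline + 0.5 · height after it; crossing
  times are refined by linear interpolation (the 0.95 ms line period is
  at the scale of the metrics' precision).  Epochs with no peak above a
  prominence gate (default 10% of baseline) or no half-decay within the
  epoch are excluded and logged; a cell is kept if at least one epoch
  survives.
* **Summaries** are unweighted per-cell means over the measured epochs.

### Group statistics

Pairwise comparisons use the pooled-variance Student's t-test on per-cell
values (two-tailed, df = nA + nB − 2), matching the study's stated test
and its use of cells as the experimental unit; collapsing to batch means
first is available as an option.  Nested variability is quantified by a
one-way random-effects (Model II) ANOVA over differentiation batches via
expected mean squares: σ²_w = MS_within, σ²_b = max(0, (MS_between −
MS_within)/n₀) with the standard unbalanced-design coefficient n₀, and F =
MS ratio.  No multiple-testing correction is applied across the three
metrics (none is applied in the study).  The helothermine rescue flag per
metric is: treated-KO vs WT non-significant AND treated-WT vs WT
significant, at α = 0.05.  The ddCt utility implements ΔCt against the
mean of the reference genes and fold change 2^(−ΔΔCt).

Note a statistical caveat documented deliberately: with batch effects of
5% of the mean and only 3 batches per group, per-cell t-tests between
groups with equal true means are anticonservative (the batch term does
not average out), so "non-significant" rescue outcomes at n ≈ 180 carry
real type-I inflation.  This mirrors the pseudoreplication inherent in
the study's per-cell testing; the random-effects ANOVA is provided
precisely to expose the batch variance component.

## Transcriptomics arm

### Count model and simulation

Counts are negative binomial with Var = µ + α µ², gene-wise baseline
means lognormal (median 150, log-SD 1), per-sample size factors uniform
on [0.7, 1.4], and α = 0.05 by default.  The paired-species preset
simulates 20,000 1:1 ortholog pairs with human design NF(4)/CH(5)/mHF(5)
and mouse sham(4)/1wTAC(4)/8wTAC(5).  Twenty-five planted concordant
progressive genes carry per-stage log2 effects: gene 0 reproduces the
CRISPLD1 profile (human 1.6/2.6, mouse 1.5/2.3); the others draw early
magnitudes from U(1.8, 2.4) with a progressive late-stage increment
U(0.5, 1.0), alternating sign, mouse magnitudes shrunk by up to 0.2.
Planted baselines are anchored at U(200, 800) so recovery is
power-limited by dispersion, not depth.

### Differential expression

The engine is self-contained and implements the study's stated
statistical core — normalization, NB GLM likelihood-ratio test, BH-FDR —
without the surrounding machinery of full DE packages (no Cook's
filtering, no LFC shrinkage); it matches those packages qualitatively,
not numerically.

* **Size factors**: median-of-ratios against the per-gene geometric mean
  over samples, using genes expressed in all samples; reported unscaled.
* **Fold change**: log2 of the ratio of mean normalized counts
  (treatment over control) with a pseudocount of 1 to keep estimates
  finite.
* **Test**: per-gene NB dispersion by method of moments on normalized
  counts pooled across the two groups, then stabilised by
  empirical-Bayes shrinkage toward the ensemble median with 10 prior
  degrees of freedom.  The shrinkage is load-bearing: raw per-gene moment
  estimates at 4–5 replicates are noisy enough that the plug-in χ²₁ LRT
  rejects ~9% of null genes at p < 0.05; with shrinkage the null
  distribution is uniform to KS ≈ 0.02–0.03 while extreme tails (and
  hence BH survival of strong effects among 20,000 genes) are preserved.
  Group means are then fitted by Newton iteration on the NB score at
  fixed dispersion (the score is strictly monotone in the log-mean, so
  the root is unique), and 2ΔlogL is referred to χ²₁.  All-zero genes get
  p = 1 by convention.
* **BH-FDR**: step-up with enforced monotonicity, capped at 1.
* **DEG filter**: |log2FC| > 1 and q < 0.05 by default (the hiPSC-CM
  screen variant 0.5/0.05 is a parameter change).

### Cross-species concordance

Human and mouse DE tables are joined through 1:1 orthologs only
(ambiguous mappings dropped and logged).  Each gene receives a per-species
stage profile — direction at the compensated stage and at moderate
failure, called "up"/"down"/"ns" by the DEG thresholds — and the conserved
set keeps pairs whose profiles are identical across species and not
(ns, ns).  The stringency mode is configurable (`pattern` default, `all`
requiring significance at both stages); the study's exact supplementary
filtering rule is not recoverable from the main text, so the implemented
rule is a documented reconstruction.  The heatmap matrix exports log2FC
over the four contrasts, ordered by profile class then effect magnitude.

## Sequence utilities

Transcript models carry coding lengths per exon only, so exon-skip
consequences are genome-build independent: skipping removes the summed
coding length, in frame iff divisible by 3 (the packaged CRISPLD1-like
fixture encodes the 303-nt exon 6–8 block whose loss deletes 101 amino
acids; the per-exon split is synthetic).  The aligner is plain
Needleman–Wunsch with configurable scoring and a deterministic traceback
(diagonal ≻ up ≻ left); windowed identity counts matching columns whose
query residue lies in a 1-based inclusive window.  Reproducing the
published 80%/60% signature identities requires the exact UniProt
sequences and blastp's local alignment and is out of scope.

## Numerical and design notes

* All randomness flows from a single integer seed per entry point;
  sub-streams are spawned deterministically per cell/gene
  (`numpy.random.SeedSequence`), so fixed seeds give bit-identical
  outputs.
* Full-scale populations are streamed one recording at a time (a whole
  group would be ~60 GB).
* Pipeline order is extract → smooth → baseline → normalize; whether the
  original analysis normalized before or after smoothing is unstated, and
  the choice only rescales the baseline estimate.
* Time is kept in seconds internally; metrics are reported in ms.
* Degenerate inputs are errors, not NaNs: flat-zero traces (no dynamic
  range), pacing faster than the line rate, missing line-rate metadata,
  all-zero count matrices for size factors, zero pooled variance with
  unequal means in the t-test.
* Problem sizes used by the acceptance computations are the study's own
  (181/183/180/180 cells at 512 × 20,000; 20,000 ortholog pairs at 4–5
  samples per stage); the DE fit is vectorized across genes so the
  transcriptomics arm runs in seconds.

## Known limitations

* The measurement chain is validated against the generator's noise
  model; systematic confocal artifacts (motion, dye saturation,
  photobleaching trends) are not corrected for (bleaching can be
  simulated but not compensated).
* Per-cell t-tests under batch effects are anticonservative (see above).
* The DE engine's p-values are not numerically interchangeable with
  DESeq2's (no dispersion trend fitting or outlier handling); planted
  effect recovery and null calibration are the validated contracts.
* The baseline estimator assumes ≥ ~20% of samples are at rest; it would
  bias upward for duty cycles approaching 1.
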