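# Methods

## The encoding model and its assumptions

A transcript's sedimentation depth in a linear sucrose gradient is taken to
be determined by the number of ribosomes bound to it.  Interpreting a change
in average ribosome number as a change in translation rate additionally
assumes that initiation is rate-limiting, elongation speed is uniform, and
ORF length does not change between conditions.  The synthetic generator
realizes exactly these assumptions; phenomena that violate them (stalled
complexes, localized translation with transit repression, gene-specific
elongation rates) are deliberately outside the model, so agreement of
decoded values with generator truth does not demonstrate robustness to such
biology on real data.

The encoded Cy5/Cy3 value of a transcript is the **ratio of pooled sums**
over fractions, not the abundance-weighted mean of per-fraction ratios; the
pooled-sums form is what physical pooling produces, and both the decoder and
the qPCR oracle use it.

## Encoding scheme

Fraction f contributes proportion `a[f]` to the Cy5 pool, strictly
increasing in f, with both endpoints strictly inside (0, 1) so both channels
stay finite.  The default ramp is **linear in the expected log2 ratio**
log2(a/(1−a)) between `a_min = 0.03` and `a_max = 0.97`.  This choice makes
the expected log2 ratio exactly linear in fraction number, which is the
premise of the ratio→fraction step used throughout: expressing a measured
ratio as a fraction number "using the slope and intercept obtained by linear
regression of the expected ratio for each fraction" is exact only on such a
ramp, and it makes the regression inversion and the piecewise-linear
inversion coincide, so the array decode and the explicit qPCR oracle agree
to machine precision in the noiseless limit.  A ramp linear in the
proportion itself is available (`ramp="proportion"`); it is equally monotone
but its expected log2 ratio is S-shaped in fraction number, and regression
inversion then deviates from piecewise inversion by up to ~0.2 fractions at
15 fractions with 0.1–0.9 endpoints.  The wide default endpoints (0.03/0.97)
give a per-fraction ratio slope of ~0.72 log2 units, which sets how strongly
array ratio noise propagates into position noise (σ_position ≈
σ_ratio/slope).

## Ribosome calibration

A260 peaks are found by topographic prominence (default threshold 5% of the
trace range; the search window should start at the 80S region so 40S/60S
subunit peaks are excluded) and assigned consecutive counts k = 1, 2, ….
The calibration model is **ribosome count linear in log elution time**,
k = α + β ln t, β > 0.  Of the two readings of "count vs. log time", this is
the one that yields a usable continuous time→count map and reproduces the
compression of polysome peaks deeper in the gradient; the alternative
(ln k linear in t) is not implemented.  Positions between fraction midpoints
convert to time by linear interpolation (linear extrapolation beyond the
first/last midpoint).  Decoded average ribosome numbers are continuous, may
be below 1 near the top of the gradient, and are never clipped in the decode
output; clamped ratio inversions (outside the scheme's ratio range) are
flagged and retained rather than dropped, preserving monotone ranking.

Because the fitted line crosses zero at some time above the gradient top, a
decoded average ribosome number can be nonpositive for extreme sub-monosomal
positions.  When log2 matrices are built for differential testing, decoded
values are floored at 0.1 ribosomes; with the default simulation conditions
(mean loads 1.8–7.0) the floor is essentially never reached.

## Synthetic study conditions

Defaults mirror the experimental design being emulated: 15 fractions
(60 s each), three biological replicates per condition, a monosome peak near
150 s with six resolvable peaks out to 600 s, four 100-pg doping controls
per fraction, and a nine-gene qPCR validation panel spanning repression to
activation.  Per gradient, peak times carry 1% lognormal jitter, so each
replicate has its own calibration — gradients are not perfectly
superimposable, and the oracle uses each gradient's own fit.

Per gene, the generator draws a regulation class
{null, translation_up/down, abundance_up/down, coupled}, a mean ribosome
load per condition (log-uniform inside 1.8–7.0, constrained so both
conditions stay on the gradient), an mRNA abundance (lognormal, σ_ln = 0.6),
a gradient dispersion (Gaussian spread of 0.8–1.3 fractions in position
space — a continuous-position model chosen over a discrete ribosome-count
mixture to match average-position semantics), and 1–3 array oligos.  Noise
scales: lognormal σ = 0.10 per fraction, Gaussian σ = 0.20 on array log2
ratios, 5% qPCR CV, 5% of features drawn to fail the quality thresholds,
peptide-level σ = 0.20 with a protein-level residual σ = 0.30.

Three default choices were calibrated deliberately, and the reasoning
matters for interpreting the tests:

- **Ramp width and load depth.**  log2 of the ribosome number is highly
  sensitive to position noise at small loads (d log2 k/dp = βΔt/(t k ln 2)
  diverges as k → 0).  The wide ramp and the 1.8–7.0 load window keep
  replicate correlations of log ribosome numbers above 0.95 at the default
  array noise of 0.2 — the agreement regime this assay is expected to
  operate in.
- **Effect-rich cohort.**  Spearman correlation against a truth vector in
  which a fraction p of genes has an exactly zero effect is bounded by
  √(1 − p³) for any nonzero noise, because the tied block's ranks
  randomize.  Parameter-recovery checks at the ≥ 0.9 level therefore require
  p ≲ 0.5, and the default class mix (40% null, 28% translation-only, 10%
  abundance-only, 22% coupled) is chosen accordingly.  Real cohorts are far
  sparser in effects; the recovery thresholds characterize the pipeline
  under these testable conditions, not expected performance on sparse real
  data.
- **Directional balance.**  Mean-centering each array before testing removes
  array-level intensity bias but assumes the cohort's regulation is
  directionally balanced; a net excess of repression shifts every null gene
  coherently across replicates and inflates false calls.  Default up/down
  proportions are therefore equal.  This is a real failure mode of
  centering-based normalization worth remembering when regulation is
  one-sided.

All randomness flows from the single config seed through named child
streams (`simulate.stream(seed, *keys)` built on `SeedSequence`), so any
table can be regenerated in isolation and no global RNG state is used.

## Differential statistics

The moderated statistic is d = (mean_treated − mean_untreated)/(s + s₀) with
s the unpaired pooled standard error and s₀ the median of s by default (the
original CV-minimizing grid search is not implemented; exact numeric parity
with the reference R implementation is a non-goal).  At 3 vs 3 all 20
distinct label assignments are enumerated deterministically — no sampling,
no seed dependence.  For each candidate |d| threshold, FDR = π₀ × median
permutation false-call count ÷ observed call count, with π₀ estimated from
the share of observed d inside the interquartile range of the permuted d;
per-row q-values are the running minimum over thresholds calling the row,
clipped to [0, 100]%.  Tail-area q-values are the primary statistic; a
Gaussian-kernel local-FDR estimate is exposed separately and labeled
approximate.  Statistics are computed on log2 values.

Classification: a gene is *translation-only* when it passes the translation
FDR cutoff and its abundance change lies within one standard deviation of
the mean over **all** detectable genes (not only significant ones).
Recovery of this subset is assessed over analyzable genes — those with data
in all replicates — since the classifier never sees dropped genes.

## pSILAC aggregation

Peptides with identification probability < 0.95 or a failed quantitation
quality flag are removed (upstream spectral search, quantitation, and
curation are out of scope; their outcomes enter as these two fields, and an
optional protein-probability < 0.05 rejection is exposed).  Remaining log
ratios are median-centered within each direction to remove loading bias.
Protein values are geometric means of all assigned peptide ratios, reported
only for proteins with at least two distinct unique peptide sequences.
Reverse-experiment ratios are stored untreated:treated and are negated
before combining; proteins seen in one direction only are retained and
flagged.  Combination is exactly label-flip invariant.

## Numerical choices

- Dye calibration and abundance spike-in normalization are ordinary least
  squares fits of measured on expected, inverted as (measured − intercept)
  / slope; a calibration with nonpositive slope is rejected.
- qPCR normalization divides by the doping-control reaction per fraction
  with relative errors combined in quadrature, then rescales to a unit sum;
  the rescale is treated as exact (errors are scaled by the same factor).
- Peak finding follows the standard topographic-prominence definition and is
  verified against an exhaustive brute-force scan.
- Ties in |d| are counted fully on both the observed and permuted sides of
  the FDR ratio.

## Limitations

- The generator emulates clean two-color arrays: no spatial/print-tip
  artifacts, dye-bleaching, ozone effects, or amplification bias between
  pools; quality metrics are drawn, not computed from images.
- The published per-fraction pooling table is not reproduced; the log-ratio
  ramp is a reconstruction consistent with the stated monotone design.
- Real-data headline results (replicate correlations, significant-gene
  counts, translation/abundance/protein correlations) depend on the real
  microarray and proteomics measurements and are not asserted here; the
  test suite asserts structural and round-trip properties of the method
  itself under the generator's stated conditions.
- Problem sizes in tests and the acceptance script (2000-gene cohorts,
  100-study ensembles, 10 000 random profiles) are the package's chosen
  verification scale.
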