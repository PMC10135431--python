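# Methods

This note documents the models, defaults, and numerical choices behind
`ribolens`, and what the synthetic-data tests do and do not establish about
real data.

## Study design and the synthetic generator

The generator emulates a four-age-group polysome-profiling design: 5, 6, 4,
and 5 subjects at 3, 6, 12, and 20 months, each contributing one total-RNA
and one polysome library (40 samples), processed in batches (default 2,
round-robin over subjects).

**Count law.** Counts are negative binomial with `Var = μ + φμ²`. Gene-wise
dispersions are log-normal around the configured φ (default 0.05, log-sd
0.5) — typical biological variability for inbred-mouse bulk tissue. Gene
means are log-normal (log-sd 1.5) and scaled so each library sits near
8×10⁶ reads, the constant in the abundance-filter formula, with per-sample
log₂-depth jitter sd 0.15. Batch effects are additive gene-wise log₂
offsets, N(0, 0.2) by default. Each subject carries a gene-wise log₂ random
effect (sd 0.2) shared by its two fractions — the matched-sample structure.
Designated outlier samples receive independent N(0, 2) log₂ perturbations,
large enough to depress their average within-fraction correlation.

**Planted regulatory modes.** Each planted gene gets a trajectory shape
(up, down, peak-at-12, V) scaled so the largest per-age offset equals the
configured effect; `translation` genes shift polysome means only,
`buffering` genes total means only, `abundance` genes both equally.
Designs with fewer than four ages restrict shapes to the monotone pair.

**Paired log₂ simulation for mode recovery.** `simulate_mode_matrices`
works directly on the log₂ scale with a two-group design. Its `noise_sd`
(default 0.25) is the *total* per-sample sd, split into a subject-shared
component carrying 90% of the variance (`coupling = 0.9`) and
fraction-specific residual. The coupling is not a free dial: both libraries
of a subject derive from one tissue homogenate, so subject-level biology
dominates and is shared — and without dominant coupling the ANCOVA
translational effect is statistically indistinguishable from an abundance
change (the regression cannot attribute a polysome shift to the total-RNA
covariate it never co-varies with). The value was fixed from this
identifiability argument, not tuned.

**Transcript TPM.** Planted PSI/psi values enter as inclusion-form shares
of a gene's (log-normal) abundance; noise is applied on the logit scale
with a delta-method scaling so its sd on the PSI scale equals `noise_sd`,
clipped to [0, 1]; exact 0/1 stay exact. Columns are normalized to 10⁶.

**What the generator does not emulate:** GC/length biases, count
correlation between neighboring genes, isoform-level NB noise in TPMs,
partial ribosome occupancy gradients, sex or cohort structure. Passing
recovery tests therefore demonstrates the estimators are correct under the
stated noise model, not that real libraries meet that model.

## Preprocessing

- **Filter**: `N = median over all samples of 8·10⁶ / library size`; a gene
  is kept if its plain CPM is ≥ N in ≥ 4 samples of either fraction
  (inclusive boundary). After outlier-driven attrition the pipeline
  recomputes N on the retained samples.
- **TMM** follows the trimmed-mean-of-M-values estimator: genes zero in
  either sample dropped, 30%/5% two-sided trims on M/A by rank,
  inverse-asymptotic-binomial-variance weights, factors rescaled to
  geometric mean 1; the automatic reference is the sample whose
  upper-quartile depth-normalized count is closest to the mean. The
  implementation agrees with the Bioconductor reference implementation to
  ~1e-15 on shared inputs (cross-checked in the test suite). Depth
  invariance is exact for the trimmed M values and asymptotic for the
  weights, so factors move by < ~1% under pure depth rescaling.
- **log₂ CPM** uses a 0.5 pseudocount.
- **Outliers**: within each fraction, a sample is flagged when its mean
  Pearson correlation to the rest falls more than 1.5 IQR below the first
  quartile; quartiles use linear interpolation (type 7); one pass only.
- **Batch adjustment** is a location-scale empirical-Bayes shrinkage, not a
  full ComBat reimplementation: per gene, batch offsets are estimated from
  residuals after removing age-group means, shrunk toward their across-gene
  mean with precision weights (`τ²/(τ² + σ²_g/n_b)`), scale ratios shrunk on
  the log scale against the chi-square reference; offsets are recentered so
  the sample-weighted total shift is zero. Designs where batch and group
  are confounded are refused. Scale adjustment is skipped for batches with
  fewer than 3 samples (the variance ratio is essentially noise there).

## Differential expression

A linear model of log₂ CPM on age group plus batch is fit per gene by least
squares; residual variances are shrunk with a scaled-inverse-chi-square
prior estimated by method of moments on log s² (trigamma inversion), and
contrasts are tested with a moderated t on `d₀ + d` degrees of freedom.
This is a limma-trend-style approximation of a count GLM — at these
replicate counts it is well calibrated (type-I error on NB null
simulations sits inside the 99% binomial CI of 0.05). Degenerate case:
when all gene variances are numerically identical the prior is a point
mass there and no bias correction is applied. Selection is strict:
`q < 0.05` **and** `|log₂FC| > log₂ 1.2`. BH runs per contrast per
fraction; the union over the six contrasts defines the DEG list.

## Regulatory modes

Per gene and contrast, using only subjects with both fractions present:
`polysome = α + β·total + γ·I(group₂)` gives the translational effect γ;
swapping response and covariate gives the buffering effect γᵇ. Slopes are
per-gene per-contrast. Significance reuses the moderated-variance engine
(one shrinkage implementation for the whole package); BH within direction
and contrast.

Calls per (gene, contrast), in priority order translation > buffering >
abundance:

- **translation**: `q(γ) < α`, `|γ| > log₂ 1.2`, and the polysome change is
  itself selected (`q(ΔP) < α`, `|ΔP| > log₂ 1.2`);
- **buffering**: the mirror with γᵇ and ΔT;
- **abundance**: ΔT and ΔP each selected, same sign.

Requiring the marginal change to be *significant* — not merely large — is
deliberate: the translation group is defined as a selected polysome change
unexplained by total mRNA, and a magnitude-only gate on a noisy marginal
estimate flips a non-trivial fraction of buffering genes into translation
calls. With this rule, planted-mode recovery at effect 1.0 and noise 0.25
reaches ~98% sensitivity and ~96% precision with translation↔buffering
confusion well under 5%.

## Alternative splicing

Events come from pairwise comparison of a gene's transcript exon chains
(coordinates 1-based inclusive in GTF, 0-based half-open internally; the
conversion lives in one module and is tested):

- SE: internal exon of one chain absent from the other, flanking
  boundaries shared; RI: one chain's exon spans two adjacent exons of the
  other with matching outer boundaries; MX: mutually exclusive,
  non-overlapping internal exons between shared flanks;
- A5/A3: exons sharing one boundary and differing at the other, with the
  common junction on the appropriate side; the strand decides which
  genomic boundary is the donor;
- AF/AL: distinct, non-overlapping terminal exons joined to a common
  internal exon; strand decides first vs last.

Duplicate events (same gene, type, coordinates) are merged with transcript
sets unioned. Reflecting all coordinates and flipping strands preserves
every event's type (A5↔A3 and AF↔AL both flip, so the composition is the
identity) — a tested invariant.

PSI is the inclusion-form share of both forms' TPM, missing when the
combined abundance is under 1 TPM (configurable floor). ΔPSI between
groups is tested against an empirical null of within-group replicate
|differences|, pooled across events in 10 expression strata (mean log₁₀
combined TPM), with a +1 pseudocount; empty strata fall back to the global
pool. Because replicate-pair differences are more variable than group-mean
differences, the test is conservative by construction — its observed
type-I error is below nominal, which is the intended operating point for
an enumeration-scale screen; power at ΔPSI = 0.4 with 6 replicates and
noise sd 0.02 is essentially 1.

The overlap of two event sets is tested with the upper-tail hypergeometric
probability (one-sided Fisher) computed in log space — on the printed
margins 883/835 with 244 shared among 65,311 possible events this gives
log₁₀ p ≈ −257. Count trends across ordered comparisons use a Pearson
chi-square against uniform expectation.

## Alternative polyadenylation

Terminal fragments are the final two exons in transcription direction
(monoexonic transcripts contribute their single exon) carrying the 3′-end
coordinate. Ends within 25 nt chain into one site by single linkage, with
the boundary distance inclusive; sites are ordered proximal→distal along
transcription with weights m/(n−1). Gene psi is the weight-averaged site
usage (0 = exclusively proximal, 1 = exclusively distal), missing under
1 TPM of terminal signal. Group differences use a two-sided Welch t with
BH; the degenerate zero-variance cases are pinned to p = 1 (equal means)
or p = 0 (unequal), with the variance-zero check tolerant of float
cancellation noise. A Welch test rather than a nested mixed model is
appropriate here because replicates are exchangeable within group.

## Trajectories

Profiles are per-age means of log₂ CPM, z-scored over the four values
(population sd). Similarity between two profiles is the Pearson
correlation after linear interpolation onto a uniform 101-point grid over
real age [3, 20] — the unequal age spacing therefore matters. The grid
correlation is a quadrature of the continuous one; refinement to 10⁴
points moves values by under 0.05 and convergence is monotone.

Clustering is a 1-D circular SOM: k nodes on a ring, Gaussian neighborhood
on ring distance with width decaying exponentially from k/2 to 0.5,
learning rate 0.5→0.01 over 200 epochs, node init by sampling profiles,
best-matching units by the co-expression similarity; fully deterministic
given a seed.

**Cluster count.** A hard-assignment RSS criterion of the form
`n·d·ln(RSS/(n·d)) + k·d·ln(n)` was implemented first and measured: it
monotonically rewards splitting pure noise (each split cuts RSS by a
scale-free factor worth ~0.1·n·d against a penalty of only d·ln n) and is
additionally misspecified for z-scored profiles, which are degenerate —
mean 0 and fixed norm confine them to a sphere. The count is therefore
chosen by the BIC of a full-covariance Gaussian mixture fitted in the
(d−1)-dimensional mean-zero coordinates, where the soft EM likelihood does
not reward noise splitting; the SOM is then trained at the chosen k for
grouping and circular ordering. On three planted shapes this selects k = 3
with adjusted Rand index 1.0; on a single noise cloud it returns the range
minimum with BIC increasing monotonically in k.

## Enrichment

ORA is the upper-tail hypergeometric test against a user-supplied universe
with BH across the collection — the identical code path as the splicing
overlap test. GSEA uses the weighted KS running sum (hit steps ∝ |score|^w,
w = 1 by default), a gene-label permutation null (the appropriate null for
ranked-list input), sign-matched ES normalization for NES, and the
standard positive/negative-pool FDR. Set sizes outside [5, 500] after
universe intersection are skipped. Ranked axes: total-RNA log₂FC, polysome
log₂FC, γ, γᵇ; ties break by gene id for reproducibility.

Annotation databases are supplied as GMT files; no web service is
involved, since database versioning would make term counts irreproducible.

## Problem sizes

Calibration runs use 2,000 genes/events at the study's replicate counts;
mode recovery uses 2,000 genes with 100 planted per mode; trajectory
recovery uses 60 profiles (20 per shape, noise sd 0.1 — the regime where
a consistent information criterion is decisive rather than saturated);
PSI recovery uses 28 planted events across 24 samples. These sizes give
binomial/Monte-Carlo error small relative to every asserted margin.

## Known limitations

- The moderated linear model approximates a count GLM; at very low counts
  the log-CPM variance trend is not modeled (no trend fit on A).
- The batch adjustment removes additive/multiplicative structure only; it
  is not a full parametric ComBat and does not handle batch-specific
  group-effect interactions.
- Event enumeration covers the seven local event types on annotated
  transcripts; it does not discover unannotated junctions and complex
  nestings of multiple events in one transcript pair may yield more than
  one record by design.
- The ΔPSI empirical test is deliberately conservative; its p-values are
  not uniform under the null.
- GSEA FDR uses the pooled-null normalization, which can be coarse for
  very small collections.
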