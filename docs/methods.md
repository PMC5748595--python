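# Methods

## Classifier

The classifier is a two-template nearest-centroid rule over a signature
gene set. Templates are unweighted per-gene means of the log2
expression of the *BRAF*-mutated and wild-type training samples; no
gene standardization is applied before correlation. The signature
score is the Pearson-correlation difference
`cor(x, template_mut) − cor(x, template_wt)`, bounded in [−2, 2],
antisymmetric under template exchange and invariant under positive
affine transforms of the profile. Cosine similarity is available as an
alternative metric (`metric="cosine"`); Pearson is the default because
it is insensitive to per-sample intensity shifts. A sample is called
mutation-like iff its score is strictly greater than the threshold, so
a score exactly at the threshold is wildtype-like.

Degenerate inputs fail loudly: constant expression vectors or
templates (undefined correlation), identical templates, classes with
fewer than two training samples, and non-finite values all raise.

## Performance estimation

LOOCV rebuilds both templates with the held-out sample removed; the
implementation updates class sums in O(genes) per fold, which is
algebraically identical to an explicit rebuild (tested against one).
One global threshold is then chosen on the full LOOCV score vector:
candidates are midpoints of adjacent distinct sorted scores plus one
sentinel below the minimum and one above the maximum; the candidate
maximizing overall accuracy wins, and among exact ties the lowest
threshold is returned, which makes the search deterministic and, at a
tie, prefers the higher-sensitivity solution.

Sensitivity and specificity are computed against sequenced BRAF
status. Because roughly half of the expression subtype is wild-type,
"false positives" include genuinely mutation-like wild-type tumors;
`expected_specificity(n_mut, n_wt) = 1 − n_mut/n_wt` quantifies the
specificity a score-pre-screened cohort should show under the
assumption that enrichment raises the wild-type mutation-like
prevalence to the (enriched) mutant prevalence.

A structural consequence of this label mismatch is worth stating
plainly: on a cohort where mutants and mutation-like wild-types are
equally frequent, the overall-accuracy criterion does not prefer the
subtype-separating threshold over the trivial call-everything-negative
threshold — the expected error counts of the two differ only by the
small discordant-mutant fraction, in the trivial threshold's favor.
On finite cohorts the optimum is therefore a near-coin-flip between
the two, and simulated cohorts drawn at the population parameters
(20% subtype, half mutated) reproduce exactly this instability: some
seeds recover sensitivity near 1, others collapse to a degenerate
high threshold. This is a property of the published procedure, not of
its implementation; the published confusion table itself sits on the
tie (correct calls = 245 = number of wild-type samples). Cohorts
enriched so that sequenced mutants outnumber mutation-like wild-types
do not suffer from it.

## Synthetic cohorts

The generator emulates a colorectal population in which a fraction
`p_subtype` (default 0.20) of tumors carries the mutation-like
expression program; within the subtype a fraction
`p_mutated_given_subtype` (default 0.5) is sequenced-mutant, and every
mutant loses the expression program with probability `p_discordant`
(default 0.02), modeling tumors whose mutant clone is not dominant —
the mechanism that keeps real-world sensitivity below 100%.

Expression is additive Gaussian on the log2 scale, the standard
microarray error model: per-gene baselines drawn with SD
`baseline_sd` (default 1.0 log2 units, giving templates a realistic
shared gene-level structure), a subtype shift of ±`effect_size`
(default 1.0 log2 units — a two-fold change, typical of curated
signature genes) applied with each signature gene's direction, and
within-class noise `noise_sd` (default 0.5 log2 units). Background
genes (default 942, for a 1000-gene matrix) carry baseline and noise
only. All randomness flows through one `numpy` generator seeded from
the spec, so equal seeds give bit-identical cohorts.

The FFPE channel adds two components: independent per-cell noise
(`degradation_sd`, RNA degradation and technical processing) and a
per-sample shift applied to the signature genes with their direction
signs (`sampling_sd`), modeling the fact that a fresh-frozen and an
FFPE block are cut from different regions of the same tumor — a shift
that moves the whole signature score coherently. The defaults
(0.35, 0.20) partition the paired variance using the two anchors the
study design provides: the technical component alone reproduces
control-replicate SD/range ratios of about 3%, and both components
together give a paired fresh-frozen/FFPE score correlation of
r ≈ 0.88 at 170 pairs. `calibrate_ffpe_noise` re-derives such a pair
by grid search for any cohort configuration. Technical control
replicates of a single block share one tumor region, so they are
generated with `sampling_sd = 0`.

What the generator does **not** emulate: probe-level effects, batch
and array-lot structure, intensity-dependent variance, tumor-purity
gradients, and correlated co-expression among signature genes. Tests
passing on these cohorts therefore demonstrate correctness of the
computational procedure under its stated statistical assumptions, not
clinical performance on real tissue.

## Stability QC and borderline region

The attainable score range is estimated from a cohort as the
symmetric interval `[−max|score|, +max|score|]`; the estimate can only
grow with more samples, so results from cohorts smaller than the
302-sample reference are flagged conservative. Control replicate
spread uses the sample (n−1) standard deviation — the standard choice
for small-replicate QC; at 40 replicates the difference from the
population formula is below reporting precision. A control passes
when SD/range ≤ 10%; the report additionally records whether every
replicate call equals the control's known class. The workflow selects
as controls the clearest member of each class (highest-scoring
sequenced mutant, lowest-scoring wild-type), mirroring how a QC lab
picks unambiguous control samples. Percentages are rounded to one
decimal for display; comparisons use unrounded values.

The borderline region is `threshold ± 1.96 × SD` with SD the largest
control SD (conservative choice); its edges count as borderline
(inclusive interval, again the conservative tie).

## Paired concordance

Quality exclusions run before scoring comparisons: tumor-cell
percentage below the cutoff (default 30%) first, then low microarray
signal, so a sample failing both is tallied once under low tumor.
Samples with unknown tumor percentage are kept (nothing to test
against). Borderline filtering applies to the FFPE score only; the
fresh-frozen call uses its own threshold with no borderline. Agreement
is `1 − switched/outside-borderline` and is reported as undefined when
every pair is borderline. Pearson r is computed over all kept
(post-exclusion) pairs, before borderline filtering.

## Problem sizes

The shipped tests and the acceptance script use 302-sample cohorts
(the reference study size) for LOOCV and range estimation, 170 pairs
for concordance calibration, 40-replicate controls over 100 noise
seeds, and smaller cohorts (60–500 samples) for unit-level checks —
sizes chosen to match the study design while keeping simulation-based
checks statistically meaningful.
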