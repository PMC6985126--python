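# Methods

## Quantification model

Protein and phosphosite abundances are relative quantities: each TMT
reporter channel is divided by the plex's common-reference (CR) channel,
a pool that holds an equal share of every sample, which makes ratios
comparable across plexes.  Rollup from PSMs to features takes the
**median of linear-scale channel/CR ratios** per feature and channel and
log2-transforms afterwards.  The order matters only in the tails
(medians commute with monotone transforms only when the same scale is
used throughout); the linear-then-log order is fixed and covered by a
regression test.  Zero or missing intensities never produce ±infinity;
they become missing values.

Per-sample normalization subtracts the column median and divides by the
median absolute deviation scaled by 1.4826, so the scale estimate agrees
with the SD under normality.  After the operation every column has
median 0 and scaled MAD 1, and the operation is idempotent.

RNA counts are upper-quartile normalized: zeros are treated as missing,
genes with zero counts everywhere are dropped, each column is divided by
the 75th percentile of its non-zero values, rescaled by a fixed constant
(1000 — an arbitrary fixed scale), and log2-transformed.  No pseudocount
is added because zeros are already missing.

### QC gates

* PSMs are excluded when they lack a TMT label, have precursor purity
  below 50% (strict: exactly 50% is retained), or a negative delta
  forward–reverse score (zero is retained).
* Plex labeling QC requires partial labeling strictly above 99%, full
  labeling strictly above 94%, and every member channel's
  |median ratio to CR − 1| within 15%.  Denominators are all PSMs of the
  plex (identified species only).
* A core passes the tumor-content gate when the arithmetic mean of its
  slide tumor-content percentages is ≥ 50% (exactly 50 passes; only
  < 50% fails).

## Copy number

Gene-level values are overlap-length-weighted means of the log2 ratios of
intersecting segments (0-based half-open internally; SEG files on disk
are 1-based inclusive, conversions are exact).  The chromosome
instability score weights |log2 r| by segment length; by default weights
are normalized to length *fractions* per chromosome so that scores are
comparable across samples and invariant to segmentation granularity —
raw Σ|r|·L weighting is available behind a flag since the summation
convention is genuinely open.  The genome-wide index sums autosomes 1–22
only.  GISTIC-style integer calls are consumed, not computed; aberration
means |call| ≥ 2 (the stringent threshold).

## Outlier Z-scores

The reference distribution of each feature is estimated (mean, n−1 SD)
from pre-treatment cores of pCR patients (≥ 3 required).  A feature is
*eligible* when its reference variance is ≥ 1.5 **and** the Shapiro–Wilk
test does not reject normality at α = 0.05; i.e. a feature is removed
when either assumption fails, the conservative reading that keeps only
features satisfying both model assumptions.  Both the α (its value is a
package default, not an asserted study constant) and a variance-only
switch are exposed.  Z-scores are computed per query core (multiple
cores per patient are scored individually); scoring a core against a
reference containing it is blocked by a leakage guard that tests can
disable to verify the reference's own calibration (self-Z mean 0, SD 1).

Note the eligibility gate removes ~9% of genuinely normal features by
construction (≈ 5% Shapiro rejections at α = 0.05 plus ≈ 4% variance-gate
losses at the default patient SD of 2), so recovery rates for spiked
outliers are stated *conditional on eligibility*; conditional on passing
the gate, a ≥ 3-SD spike reaches |Z| ≥ 2 essentially always.

For the targeted ERBB2-locus query (`build_amplicon_profiles`) Z-scores
use the reference mean/SD **without** the eligibility gate: the gate is a
transcriptome-wide multiple-testing guard, and applying it to a fixed
four-gene locus would only censor the locus at random.

## Enrichment statistic

For a ranked vector of signed scores (outlier Z, or signed −log10 p with
p floored at 1e-15), the enrichment score of a set is the area variant of
the weighted KS running sum: identifiers are sorted by descending score
(ties broken by identifier), hits increment by |score|^w normalized
within the set, misses decrement by 1/(N − m), and ES is the sum of the
running-sum values divided by N.  Defaults: w = 0.75, min_size = 5,
1000 identifier-label permutations.  NES divides ES by the mean |null ES|
of matching sign; nominal p is the add-one tail fraction among same-signed
null ES; FDR is Benjamini–Hochberg across sets with a 0.25 reporting
threshold.  Useful exact properties: ES is invariant to strictly monotone
score transforms at w = 0, and negating all scores negates every ES.

PTM signatures key sites by the 15-mer flanking window (modified residue
± 7 amino acids; only fully localized sites should be supplied).  A
directed signature's ES is the up-member ES plus the down-member ES
evaluated on the sign-inverted score vector; this makes re-tagging every
member up→down negate the ES exactly.  Gene-centric collapse keeps, per
symbol, the feature score of maximal magnitude, breaking |score| ties by
lexicographic feature id and flagging genes whose tie spans opposite
signs.  Numerical parity with any external ssGSEA/PTM-SEA release is not
claimed; the statistic is fully specified here and verified against an
independent brute-force evaluation.

## Treatment-response statistics

Replicate cores are averaged to one value per patient and timepoint
before testing (a simpler alternative to duplicate-correlation modelling
inside the linear fit; its small-n behaviour is verified by simulation in
the test suite).  Paired on- vs pre-treatment comparisons use the exact
Wilcoxon signed-rank test (zero differences dropped and counted; exact
enumeration for n ≤ 25, tie-free); group comparisons of fold changes use
the exact rank-sum test with a mid-rank normal fallback under ties.

The moderated t fits each feature by least squares on a design with one
coefficient per group cell and plex dummies (batch absorption), on the
feature's complete cases.  The variance prior (d₀, s₀²) is estimated by
matching moments of log residual variances (digamma/trigamma inversion);
posterior variances are s̃² = (d₀s₀² + df·s²)/(d₀ + df), t = c'β̂ /
(s̃·√(c'(X'X)⁻¹c)) with df + d₀ degrees of freedom.  d₀ → 0 recovers the
ordinary t (exposed via `prior_df` for testing); features with zero
residual df inherit the prior.  Rank-deficient designs (e.g. plex
confounded with group) raise with the confounded columns named.

Concordance metrics: per-gene Spearman correlation of mRNA and protein
over shared samples with the cohort median reported, and average-linkage
hierarchical clustering on correlation distance over the top-500
most-variable features, with a report of whether each replicate pair
joins before any non-replicate (metric and linkage are package defaults;
both are configurable).

## ERBB2 status and resistance annotation

Classification rules: *false positive* — no copy gain (ERBB2 CN log2
below 0.3) and ERBB2 protein Z below −2; *pseudo positive* — copy gain
with low ERBB2 protein or low mean protein Z across the flanking genes
STARD3/PGAP3/GRB7; otherwise *true positive*.  The two thresholds are
package defaults (the distinction is made by inspection and group tests
in practice, without printed cut-offs), and the acceptance surface is
recovery of generator ground truth, not reproduction of any patient's
label.  Every comparison is recorded in the call's evidence list.
Amplicon group tests are Welch two-sample t-tests per gene and on each
sample's arithmetic mean over STARD3+ERBB2+GRB7.  The mucin panel flags
a patient when ≥ 2 panel genes reach Z ≥ 2 in any scored core.
Literature tallying is an offline interface over citation records; the
query is read as ("resist" OR "recur") AND "breast cancer",
case-insensitive substring matching, and publications with more than 100
gene associations are excluded (exactly 100 is retained).

## Synthetic cohort generator

The generator emulates the study design: 14 patients (9 pCR / 5 non-pCR
at the defaults), pre-treatment cores for all, on-treatment cores for
7 pCR + 3 non-pCR patients, duplicated pre+on cores in four patients and
one triplicate pre-treatment series — 35 cores, randomized across TMT
11-plexes of 9 member channels plus two CR channels.  The exact per-patient
core layout is not uniquely fixed by the study description; the default
plan is one consistent choice and is fully configurable.

Generative model per gene g and core c (patient p, timepoint t, plex b):

    y_gc = μ_g + u_gp + τ_gt + β_gb + ε_gc

with μ_g ~ N(0, 0.3), patient effects u_gp ~ N(0, 2.0), plex effects
β_gb ~ N(0, 0.3), noise ε ~ N(0, 0.3).  The patient SD of 2.0 makes
reference variances land near 4 on the log2 scale, comfortably above the
1.5 eligibility threshold for most features (≈ 80–85% eligible, matching
the intended behaviour of the filter).  Phosphosites ride on their host
protein's value plus a fixed per-site offset (SD 0.5) and site-level
treatment effects.

**Spiked effects replace the random patient effect** of the targeted
gene/patient with the configured deterministic deviation, rather than
adding to a random draw.  This makes ground truth exact — a recovery test
compares against the recorded spike, not a spike blurred by a hidden
random effect — while pCR reference patients keep their random effects so
the reference variance is undisturbed.  Defaults: amplicon copy-number
gain 1.0 (log2), amplicon expression +2.5 (true positives) / −6.0
(pseudo/false), on-treatment pCR-specific shifts of −1.0 (ERBB2 protein),
−1.5 (ERBB2 phosphosites), −1.5 (mTOR-target phosphosites), and a mucin
panel deviation of +7.0 (3.5 patient-SDs) in one non-pCR patient.

RNA is tied to protein through a Gaussian copula: the per-gene Pearson
coefficient is set to 2·sin(π·ρ_s/6) so the implied Spearman correlation
equals the configured target (default 0.38); counts are then drawn
negative-binomially (size 50) around the latent log2 value with per-gene
sequencing depths spanning ~2⁵–2¹¹, and the bundled RNA matrix is the
upper-quartile-normalized log2 of those counts.  Count noise attenuates
the realized correlation by well under the ±0.05 check tolerance.

PSM tables are generated for a configurable subset of proteins: linear
abundances 2^y per member channel, the CR channel as the mean of member
abundances, per-PSM lognormal scale and noise, and label/purity/delta
attributes drawn from mixtures with configurable violation rates.  After
drawing, member channels are re-balanced so each channel's median ratio
to the CR is 1 — emulating the bench practice of mixing samples to equal
amounts — which is what the mixing QC gate checks.  The PSM layer is
self-consistent per plex but is not constructed to reproduce the bundled
protein matrix exactly (the matrix is the primary truth carrier).

### What the generator does not emulate

Real acquisition features that the generator omits: missing values from
stochastic peptide sampling (the matrices are complete apart from RNA
zeros), isotope-impurity crosstalk between channels, ratio compression
from co-isolation, heavy-tailed and gene-dependent variance structure,
correlated gene modules, and realistic genome architecture (all
chromosomes are 100 Mb with uniform gene placement; only the 17q12
amplicon is structured).  Passing recovery tests therefore demonstrate
the correctness of the pipeline's statistics under the stated model, not
robustness to these real-data pathologies.

## Problem sizes and numerical choices

Default synthetic cohorts carry 2,500 genes and 1,500 phosphosites;
replication loops in the test suite use 20–50 replicate cohorts or
reduced gene counts where a property concerns per-feature behaviour that
is independent of the number of features.  Permutation tests in the unit
suite use 150–8,000 permutations depending on the convergence tolerance
being demonstrated.  Ties in exact tests fall back to mid-rank normal
approximations with a logged notice; degenerate inputs (zero MAD columns,
empty groups, rank-deficient designs, malformed windows or intervals)
raise errors naming the offending sample/column/row rather than
propagating NaNs.

## Known limitations

* The moderated-t replicate handling (pre-averaging) differs from
  duplicate-correlation modelling; with many replicate cores per patient
  the two can diverge.
* NES normalization and FDR conventions follow this package's definition;
  no numerical parity with external enrichment tools is claimed.
* The ERBB2 classifier thresholds are heuristics tuned to the generator's
  effect-size defaults and documented as such.
* Live literature retrieval is out of scope; the citation interface is
  offline by design.
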