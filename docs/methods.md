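# Methods

This package implements the statistical machinery used to dissect
community assembly in small microbiome surveys — of the order of ten
samples, thousands of sparse taxa — where the central question is why
taxonomic composition varies between samples even when functional
composition does not.  The components are: abundance-aware pairwise
dissimilarities and Mantel distance-decay tests; stepwise regression on
distance matrices with permutation significance; two co-occurrence
null-model tests (a checkerboard score on presence/absence, a Morisita
similarity score on abundances); variability and coverage profiles
(CV-vs-mean, core-biome and collector's curves); and a synthetic survey
generator with known ground truth against which everything is
calibrated.

## Data model

A `CommunityTable` is a labeled nonnegative taxa-by-sample matrix in
`counts` or `proportions` mode (each nonzero column of a proportions
table sums to 1 within 1e-9).  Binarizing with a detection threshold of
one read yields a `PresenceAbsenceMatrix`; the threshold is
configurable because no detection floor is canonical.  Taxonomic
collapsing sums rows sharing a lineage prefix; taxa unclassified at the
target rank are pooled by their deepest classified prefix into distinct
`unclassified-<prefix>` rows rather than dropped, so per-sample totals
are conserved exactly — a requirement for comparing statistics across
ranks.  Gene-group profiles are built by the usual gene-centric
arithmetic: per-sample contig coverages are normalized to proportions,
each predicted protein-coding gene inherits its host contig's
proportion, gene proportions are renormalized, group proportions are
the sums over member genes, and the retained groups are renormalized to
1.  Catch-all, non-functional categories can be excluded either before
or after the final renormalization (both orders differ only by a scale
factor, but both are supported because published pipelines are not
explicit about the order).

## Dissimilarities

All three metrics act on per-sample proportion vectors p, q over the
union of taxa:

* Bray-Curtis: `sum |p-q| / sum (p+q)`;
* Hellinger: `sqrt( sum (sqrt p - sqrt q)^2 )`, range [0, sqrt 2], no
  1/sqrt(2) rescaling;
* Jaccard with abundances, in the Ruzicka form
  `1 - sum min(p,q) / sum max(p,q)`, which equals `2*BC/(1+BC)` and
  reduces to the classical Jaccard index on binary data.  "Jaccard"
  on abundance data is ambiguous in the literature; the Ruzicka form
  is the standard quantitative extension in community ecology, and the
  identity with Bray-Curtis is exploited as a cross-check in the test
  suite.

Proportions (not raw counts) are used throughout, consistent with the
relative nature of sequencing data.  Geographic distances are
great-circle (haversine) on a sphere of radius 6371 km; at the few
hundred km scale of interest the sub-0.5% ellipsoidal error is
immaterial.

## Mantel test

The statistic is the Spearman correlation (midranks on ties) over the
n(n-1)/2 unordered pairs of two label-aligned distance matrices.
Significance comes from permuting the rows and columns of the second
matrix simultaneously — permuting sample identities, which preserves
the internal dependence of distance data.  The one-sided "greater"
tail is the default because distance decay predicts positive
correlation.  The p-value uses the add-one convention
`p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)`, so it is never zero and
is exactly valid as a permutation p-value.  Constant lower triangles
make rank correlation undefined and raise an explicit degenerate-input
error rather than returning NaN.

## Stepwise regression on distance matrices

The response is an unfolded lower triangle of a dissimilarity matrix;
candidates are |delta covariate| matrices and geographic distance.
Forward selection only: at each step every remaining candidate is added
to the current model, its coefficient's two-sided significance is
estimated by refitting under `n_perm` simultaneous row/column
permutations of the response matrix (the "permutation of raw data"
scheme for matrix regression), and the candidate with the smallest
p-value enters if p < alpha, ties broken by larger |t|.  There is no
backward phase.  Pairs with a missing value in the tested predictor are
dropped for that candidate only.  Perfectly collinear candidates are
skipped with a warning.  An empty selection is a first-class outcome —
on environmentally unstructured data it is the expected one.

Numerical care: an exact (zero-residual) fit leaves only float noise in
the residuals; residual sums of squares below 1e-16 of the response's
own scale are treated as exactly zero, so a coefficient is then either
infinitely significant (genuinely nonzero) or exactly null, instead of
a ratio of roundoff artefacts.

Cross-validation is leave-one-sample-out: all pairs touching the
held-out sample are predicted by a model refit on the remaining pairs.
Pairs sharing a sample are dependent, so leaving out a *pair* would
leak information; leaving out a *sample* is the honest unit.  Pooled
over folds, `R2_cv = 1 - SS_pred / SS_tot` with SS_tot taken about the
grand mean of the response; it can be negative when the model predicts
worse than the mean.  The intercept is always included.

## Co-occurrence null models

**CC score** (presence/absence).  With N samples, occupancies `N_i`,
co-occurrence counts `N_ij` and `p_i = N_i/N`:

    CC = 1 - [ sum_{i<j} (N_i - N_ij)(N_j - N_ij) ]
           / [ sum_{i<j} (N_i - N p_i p_j)(N_j - N p_i p_j) ]

a normalized, sign-reversed relative of the classical checkerboard
C-score: the numerator counts realized checkerboard units, the
denominator their expectation under independent occupancy, so the scale
is stable as N grows and larger CC means more co-occurrence.  `N_ij`
is symmetric and the sums run over unordered pairs.  An exactly zero
denominator (e.g. every row full) raises a degenerate-input error —
this genuinely happens at coarse taxonomic ranks, where every taxon
occupies every sample.

Its null is the fixed-fixed ("SIM9") model: binary matrices with both
margins fixed, sampled by a Markov chain that proposes a random pair of
rows and columns and flips the 2x2 submatrix when it is a checkerboard.
The proposal is symmetric, so the *lazy* chain (which stays put on
rejected proposals) has a uniform stationary distribution over the
fixed-marginal state space.  Burn-in and thinning are therefore counted
in **trial** swaps, not accepted swaps: spacing emissions by accepted
swaps is the jump chain, which oversamples states with many available
checkerboards, and a chi-square goodness-of-fit test against the
enumerated state space of a 4x4 matrix rejects that variant
decisively.  Defaults are burn-in = 50x and thinning = 5x the number of
1s in the matrix, both overridable; the uniformity test in the suite
guards their adequacy.  A matrix admitting no checkerboard at all is
frozen and reported as a degenerate null.  The inner loop is compiled
with numba.

**MA score** (abundances).  With `p_ij` the relative abundance of
taxon i in sample j:

    MA = sum_i [ (sum_j p_ij)^2 - sum_j p_ij^2 ]
         / [ (N-1) sum_i sum_j p_ij^2 ]

the generalized Morisita similarity across the N samples: 1 iff all
samples have identical composition, 0 when every taxon is confined to
one sample.  (Both inner sums run over all N samples; one printed
source renders the second sum's upper limit with an undefined symbol,
and N is the only reading consistent with the Morisita index.)

Its null is the "IT" model: reads are re-assigned to cells one at a
time with probability proportional to (remaining row quota) x
(remaining column quota) until both marginal totals are met.  Because
the weight factorizes, the row choice at every step is an urn draw
without replacement from the multiset of row tokens, independent of the
column choices; the whole scheme is therefore realized exactly by
pairing a uniformly shuffled row-token sequence with the column-token
sequence and histogramming — O(total reads) per null matrix, marginals
exact by construction.  A literal one-read-at-a-time reference
implementation is kept, and a brute-force enumeration of the sequential
scheme's placement paths on tiny matrices pins the distribution of the
fast route in the tests.  Each null matrix is renormalized to
proportions before scoring MA, as is the observed table.

Both tests report add-one tail probabilities; `p_low < alpha` is the
segregation direction (taxa overlap less than chance), `p_high` the
aggregation direction.  The Bonferroni helper returns `alpha/n` for
families of tests across levels, metrics, or level x metric x
candidate combinations.

## Variability and coverage profiles

CV profiles use the sample standard deviation (n-1 denominator, with a
flag for the population version) divided by the mean of each row's
proportions across samples; zero-mean rows are excluded and counted.
The core-biome curve — the expected number of taxa present in all of n
randomly chosen samples — is computed exactly via the hypergeometric
identity `value(n) = sum_i C(k_i, n) / C(N, n)` (k_i = occupancy); the
Monte-Carlo subsampling variant is retained as an oracle.  The
collector's curve — expected distinct taxa after d reads drawn without
replacement — uses the standard rarefaction identity
`E[S(d)] = sum_i [1 - C(T-c_i, d) / C(T, d)]`, with subset enumeration
as the oracle at tiny depth.  Binomial coefficients are evaluated via
log-gamma for numerical range.

## Synthetic survey generator

The generator emulates the statistical *shape* of a small
sediment-microbiome survey, not its sequences: 10 geolocated samples in
a coastal box a few hundred km across, 2000 taxa in 100 functional
groups of 20 (lognormal group masses, log-sd 1; lognormal within-group
shares, log-sd 2 — heavy tails), read depths lognormal around 5412
reads per sample (log-sd 0.3, mirroring real library-size spread), and
reads drawn multinomially per sample, which produces realistic sparsity
(roughly a quarter of taxa are never detected at these depths).
Taxonomy is a random balanced hierarchy so collapsing is exercised at
every rank, with a configurable unclassified fraction at genus.

Ground-truth switches:

* **Segregation s.**  For s > 0 each group splits into two factions;
  each sample hosts one faction (fair coin) and each member follows the
  hosting pattern with probability s (otherwise independent
  Bernoulli(1/2)).  The hosted members share the group's fixed mass in
  proportion to their base shares.  Within-group co-presence is thereby
  depressed relative to independence while every taxon keeps occupancy
  near N/2 — which is what gives the presence-based CC test its power.
  (A winner-takes-all variant, one random winner per group per sample,
  was evaluated first and rejected: it drives occupancies to ~1 sample,
  and the fixed-fixed null, which conditions on exactly those margins,
  absorbs nearly the entire signal — measured power ~30% versus ~100%
  for the faction design at the same scale.)  Group masses are
  identical in every sample, so gene-group proportions stay nearly
  constant while taxonomic composition turns over: the functional
  redundancy signature, with taxon CVs roughly an order of magnitude
  above gene-group CVs at matched mean proportions.  For s < 0 whole
  groups drop out of samples together (aggregation).  s = 0 is neutral.
* **Distance decay** lambda (per km): each taxon's log-intensity gains
  a Gaussian field over samples with covariance `exp(-lambda * d_jk)`,
  scaled by `decay_sigma`, so community similarity decays with
  distance and Mantel tests have a planted positive signal.
* **Environmental effects**: per chosen covariate, taxon-specific
  normal response coefficients scaled by the effect size multiply
  log-intensities, making |delta covariate| genuinely predictive of
  pairwise dissimilarity for the stepwise regression.

Calibration by construction: at s = 0 with no decay and no effects,
cell intensities factor as (taxon weight) x (sample depth).  Reads are
then exchangeable with both null models — conditional on both margins,
a product-multinomial with row-only weights is exactly the
fixed-margins law the IT scheme samples, and the induced binary matrix
is uniform on its fixed-marginal state space — so the null tests'
p-values are uniform on neutral data.  This was verified empirically
(no false rejections in 60 neutral replicates at the 5% level) and is
what makes the generator usable as a ground truth for type-I error.

What the generator does **not** emulate: phylogenetic structure in
abundances or co-occurrence, PCR/chimera artefacts, compositional
correlations induced by shared extraction batches, spatial structure in
the environmental covariates (they are iid standard normal), and
read-level error.  Passing tests therefore demonstrate correctness and
calibration of the statistics under the stated generating model, not
robustness to those real-data complications.

## Problem sizes and determinism

Every stochastic routine takes an explicit integer seed; the same seed
reproduces datasets and summaries byte-for-byte.  The analysis drivers
default to the full generator scale (2000 taxa, 1000 permutations /
null matrices).  The test suite and the acceptance script use reduced
scales chosen for statistical adequacy — e.g. 200-replicate calibration
runs at 199 nulls, 100-replicate power runs at the generator scale of
the stated power condition (200 taxa in 10 groups), and a 600-taxon
survey for the end-to-end recomputation — sizes at which the binomial
error bands used in the assertions are decisive.

## Known limitations

* The CC denominator is exactly zero whenever all (or nearly all)
  taxa occupy all samples, so the CC/SIM9 test is unavailable at
  coarse taxonomic ranks in deeply-sampled surveys; this is inherent
  to the statistic, and the package reports it as a degenerate input
  rather than guessing.
* The SIM9 chain's mixing time depends on matrix shape; the defaults
  are adequate for the tested regimes (up to thousands of taxa by tens
  of samples) but very large, very dense matrices may need longer
  burn-in, which is why both parameters are exposed.
* The stepwise procedure inherits the usual caveats of forward
  selection: per-step p-values are marginal, and the family-wise
  false-entry rate across many candidates exceeds alpha (about
  1-(1-alpha)^k for k candidates); the Bonferroni helper exists for
  exactly this reason.
* `R2_cv` compares against the grand mean of all pairs; with only ~10
  samples its sampling variance is large, and negative values on weak
  models are routine.
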