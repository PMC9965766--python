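# Methods

`metabonet` implements an integrated statistical and network analysis
for serum metabolomics cohorts with a case / intermediate / control
structure (the canonical use case: colorectal cancer (CRC), polyposis
(PP) and healthy controls (CTR) profiled by targeted LC-MS/MS, with
abundances reported as counts per second). This note records the models,
the parameters that matter, the numerical conventions, and the design
choices made where the design was genuinely open.

## Data model

An `AbundanceMatrix` is a samples × metabolites table of non-negative
intensities with per-sample group labels (and optional subgroup labels,
e.g. colon/rectal within CRC). Missing values are carried as NaN, never
as silent zeros. Before analysis, a metabolite with more than 20%
missing values within any group is rejected; remaining missing entries
are imputed as half the minimum positive observed value of that
metabolite — a common MS convention, chosen here as a documented
default. Group labels in public exports vary in spelling, so the reader
accepts a case-insensitive alias table ("control", "healthy" → CTR).

## Preprocessing

**Outlier removal.** Samples are flagged when their scores on the first
two principal components of the pooled, unit-variance-scaled data fall
outside the 95% Hotelling confidence ellipse: the statistic
d² = (t − t̄)ᵀ S⁻¹ (t − t̄) on the 2-D scores is compared to
2(n−1)/(n−2) · F₀.₉₅(2, n−2). Detection runs once (no iterative
re-fitting) on all groups pooled. Columns whose spread is at floating
rounding level are treated as constant and dropped before scaling. At
`confidence=1.0` nothing is flagged. On spherical Gaussian data the
empirical exclusion rate is the nominal 5% (asserted at n = 10000 in the
test suite).

**Normalization.** The rank-based inverse normal transform (INT) with
Blom's offset k = 3/8 maps each metabolite to
probit((rank − k)/(n − 2k + 1)), with average ranks for ties. The output
is monotone in the ranks, so Spearman correlation matrices — the basis
of every network stage — are exactly invariant under the transform. INT
data feed the classification and network stages.

**Univariate transform.** The t-tests run by default on the square root
of the raw (post-QC) abundances, a variance-stabilizing choice for
count-like MS intensities. Whether univariate testing should use
sqrt-of-raw, INT, or a combination is genuinely ambiguous in this kind
of protocol; the config switch `univariate_input: {sqrt_raw, int,
sqrt_int}` exposes all three (`sqrt_int` is the signed square root of
the INT z-scores, defined for negative values).

## Univariate testing

Per metabolite, a two-sided pooled-variance Student's t-test compares
the two groups (`welch: true` switches to unequal variances). Zero
pooled variance yields t = 0, p = 1 with a warning rather than NaN.
Benjamini-Hochberg adjustment is applied across all metabolites of one
pairwise comparison (three separate families for the three
comparisons); q < 0.05 flags significance. The BH computation is shared
by every stage that corrects across multiple tests.

## Classification

Pairwise Random-Forest classification uses k = 100 resamplings: each
draws 85% of each group (stratified, without replacement) as training
data, fits a forest with 500 trees and mtry = ⌊√p⌋, and scores the
held-out 15%. The held-out evaluation (rather than out-of-bag) follows
from reading "retaining 85% of data per group" as a training-set
construction; `eval` is the obvious place to extend if OOB is wanted.
Sensitivity = TP/(TP+FN) with the first group of the pair as the
positive class; specificity = TN/(TN+FP); AUROC is the rank statistic
on class-probability scores. Accuracy, sensitivity and specificity are
reported as percentages; aggregation over resamplings is the arithmetic
mean with 2.5/97.5-percentile intervals.

Model significance is a label-permutation test with n = 1000
permutations and p = (1 + #{perm ≥ obs})/(1 + n). For tractability each
permutation uses a reduced scheme (default 2 resamplings, 100 trees) —
and the observed statistic is recomputed under that same reduced scheme
so observed and permuted values are exchangeable under the null. One
permutation null is accumulated per metric (accuracy is the headline
statistic). Per-metabolite importance significance compares observed
Gini importances to importances from label-permuted forests, BH-adjusted
across metabolites.

## PCLRC network inference

The Probabilistic Context Likelihood of Relatedness on Correlation
algorithm estimates, per group, the probability that each
metabolite-metabolite association is genuine:

1. draw ⌊0.75 n⌋ samples without replacement;
2. compute the Spearman correlation matrix of the subsample;
3. apply the CLR background filter to the **squared** correlations:
   z_i|j = (M_ij − mean_i)/sd_i over row i excluding the diagonal
   (sd with ddof = 1), combined as z_ij = √(max(0,z_i|j)² + max(0,z_j|i)²);
4. mark the top 30% of nonzero CLR scores as kept;
5. repeat 1000 times; p_ij is the fraction of iterations in which the
   edge was kept.

CLR needs a non-negative relevance measure, hence the squaring: strong
negative associations count as strong associations, and the sign is
restored from the full-data Spearman matrix R when networks are built.
The defaults (1000 iterations, 0.75 fraction, 0.30 retention quantile,
p ≥ 0.95) are the reference defaults of the published PCLRC method; all
are exposed in config. Networks threshold on p_ij ≥ 0.95 **and**
|r_ij| ≥ 0.6, keeping every metabolite as a (possibly isolated) node.

Numerical notes: for tie-free data (checked once per call) column ranks
are permutations of 1..n, so Spearman reduces to a single matrix
product with a closed-form normalization; CLR row statistics are
computed from sums with a relative-tolerance guard against catastrophic
cancellation on near-constant rows. Because every iteration keeps a
fixed fraction of edges, the mean of P over all pairs equals the
retention quantile times the average nonzero-CLR fraction, and the
strongest few null pairs in any finite sample persist across subsamples
— a null dataset therefore always has *some* pairs with p_ij near 1
(about 0.5% of pairs reach 0.95 at n = 80). This is intrinsic to
fixed-quantile retention, which is why network construction also
requires |r| ≥ 0.6.

## Differential connectivity

Connectivity of metabolite i in one group is the probability-weighted
strength C_i = Σ_j p_ij·|r_ij|. The weighted form (rather than counting
edges above the thresholds) avoids cliff artifacts at the cutoffs and
reduces to a weighted degree when P is binary; `statistic:
thresholded_degree` is available. Note the deliberate asymmetry with
network construction: connectivity uses all of (P, R), while the
drawn networks only show edges passing both thresholds — the two answer
different questions.

The two-sided permutation test shuffles group labels among the pooled
samples of the two groups (sizes preserved), recomputes both
connectivity profiles per permutation (PCLRC rerun at a reduced 100
iterations by default; configurable), and sets
p_i = (1 + #{|Δᵖᵉʳᵐ| ≥ |Δᵒᵇˢ|})/(1 + n_perm), BH-adjusted across
metabolites with q ≤ 0.05 flagging significance. Two implementation
choices strengthen reproducibility:

* the pooled ordering and all derived seeds are canonicalized on the
  sorted group pair, so swapping the pair exactly negates Δ and leaves
  every p-value unchanged;
* the two groups of each comparison share one subsample seed stream
  (common random numbers), pairing the Monte-Carlo noise — two
  literally identical groups give exactly Δ = 0 and p = 1.

The p-value resolution floor is 1/(n_perm + 1). This matters for BH:
with n_perm = 100 the smallest achievable p (0.0099) exceeds the BH
step-up threshold for, say, 8 discoveries among 100 metabolites
(0.05·8/100 = 0.004), so at that permutation budget **no** metabolite
can be BH-significant at 0.05 regardless of effect size. Budgets of
n_perm ≥ ~250 give the q ≤ 0.05 rule real power at this scale; smaller
budgets support detection only at the resolution floor (observed |Δ|
beating every permutation). The test suite measures recovery
accordingly, and the acceptance script uses n_perm = 300.

Colon-vs-rectal-style subgroup comparisons are the same operation with
a substituted label vector (`labels=` argument).

## Topology

The ten NetworkAnalyzer-style node metrics are computed on the
unweighted thresholded graph (edge weights shape network construction,
not path lengths): degree, average shortest path length (within the
node's component), betweenness (normalized by (n_c−1)(n_c−2)/2 per
component), closeness (1 / mean distance to reachable nodes),
clustering coefficient, eccentricity (max finite distance),
neighborhood connectivity (mean neighbor degree), radiality
((Δ_c + 1 − aspl)/Δ_c with Δ_c the component diameter), stress (number
of shortest paths through the node), and topological coefficient
(mean over nodes sharing ≥ 1 neighbor of J(v,m)/k_v, J = shared
neighbors + 1 if adjacent; 0 for nodes with fewer than two neighbors).
Isolated-node conventions are pinned: degree 0, clustering 0,
eccentricity 0, closeness 0, radiality 0. All ten are verified against
a brute-force oracle that enumerates every shortest path explicitly.

Networks are compared by PCA on the stacked (network, node) × metric
table, unit-variance scaled, with deterministic loading signs; three to
five networks alone cannot support a 10-loading PCA, which is why nodes
(not whole-network summaries) are the default observations
(`mode="means"` aggregates instead). Per-network centroid distances in
the PC1-2 plane summarize separation.

## Pathway over-representation

The query (typically the significantly differentially connected
metabolites) is matched against a pathway library by canonicalized name
(lowercase, punctuation stripped), optionally through an explicit
synonyms table — no fuzzy matching. With a universe of N library
compounds, a pathway of K members and a matched query of n compounds
overlapping it in k, p = P(X ≥ k) for X ~ Hypergeometric(N, K, n), BH
across pathways. The impact score is the importance mass of the matched
compounds over the pathway's total importance (uniform importances make
it k/K); only pathways with impact > 0.01 are reported. The shipped
15-pathway library is a small synthetic stand-in for a KEGG Homo
sapiens library (real libraries are versioned and licensed, so they are
user-supplied files), meaning enrichment results on real cohorts are
library-version dependent.

## Synthetic cohorts

The generator is a latent-Gaussian copula: per group, metabolite
log-abundances are multivariate normal with an equicorrelated block
structure (shared-factor construction, positive definite for ρ < 1 by
construction), plus per-metabolite baselines (mean 7, SD 1 on the log
scale — intensities around e⁷ ≈ 1100 counts per second) shared across
groups, plus mean shifts δ (in SD units) on selected metabolites;
intensities are the exponential of the latents. Spearman-based stages
see the planted latent correlation exactly (rank invariance); the
planted Pearson ρ appears as Spearman (6/π)·asin(ρ/2). Differential
connectivity is planted by block rewiring and univariate effects by
mean shifts, independently — mirroring cohorts where the intermediate
group shows network differences without abundance differences.

The shipped `crc_cohort_design` has groups CRC/PP/CTR of 65/74/87
samples (a realistic post-QC split) and 100 metabolites: three control
blocks (ρ = 0.7/0.6/0.5), polyposis sharing two and rewiring one, the
cancer group weakening the first block (ρ 0.7 → 0.3), adding a strong
block (ρ = 0.8) and shifting 15 metabolite means by 0.8 SD. What the
generator does **not** emulate: detector saturation, batch effects,
heteroscedastic noise floors, missingness mechanisms, and real
metabolite identities — so passing tests demonstrate statistical
correctness of the machinery, not performance on any particular real
cohort.

## Problem sizes in the test and acceptance runs

Monte-Carlo checks use deliberately moderate sizes chosen once: PCLRC
calibration at n = 80 with 100 iterations over 10 seeds; differential
connectivity recovery on 65/87 samples with one rewired 8-metabolite
block at 100 iterations / 100 permutations over seeds 0–9; null
calibration on 60/60 samples × 50 metabolites over 20 trials; the RF
null band as the mean over 10 independent null datasets at k = 25
resamplings. The acceptance script runs the full pipeline at k = 50
resamplings, 200 PCLRC iterations and 300 diffcon permutations. These
are the package's own reproduction sizes; all full-scale settings
remain the library defaults.

## Known limitations

* PCLRC probabilities are relative to the fixed-quantile retention and
  are not calibrated posterior edge probabilities; compare them across
  groups of similar sample size.
* The permutation FDR for differential connectivity inherits the
  resolution floor discussed above; choose n_perm accordingly.
* The univariate stage assumes approximate normality after the chosen
  transform; no nonparametric alternative is provided.
* Hotelling-ellipse outlier detection assumes an approximately
  elliptical score cloud; it is not a robust-PCA method.
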