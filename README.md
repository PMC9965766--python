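# metabonet

Integrated statistical and network analysis of serum metabolomics
cohorts — built for case / intermediate / control designs such as
colorectal cancer (CRC) vs. polyposis (PP) vs. healthy controls (CTR)
profiled by targeted LC-MS/MS.

Abundance-level statistics (t-tests, Random-Forest classification) ask
*which metabolites change and how well groups can be told apart*. This
package adds the complementary network view: *which metabolite–metabolite
association patterns rewire between conditions*, even when no individual
abundance shifts. The core machinery:

* **PCLRC network inference** — Probabilistic Context Likelihood of
  Relatedness on Correlation. Repeatedly subsample 75% of a group's
  samples, compute the Spearman correlation matrix, background-correct
  the squared correlations with the CLR filter
  z_ij = √(max(0,z_i|j)² + max(0,z_j|i)²), and retain the top 30% of
  CLR scores; the edge probability p_ij is the fraction of 1000
  iterations in which the pair survived. Networks keep edges with
  p_ij ≥ 0.95 and |r_ij| ≥ 0.6.
* **Differential connectivity** — per-metabolite probability-weighted
  strength C_i = Σ_j p_ij·|r_ij|, with Δ_i = C_i(A) − C_i(B) tested
  against a group-label permutation null and BH-FDR control (q ≤ 0.05).
* **Topology comparison** — the ten NetworkAnalyzer-style node metrics
  (degree, average shortest path length, betweenness, closeness,
  clustering, eccentricity, neighborhood connectivity, radiality,
  stress, topological coefficient), compared across networks by PCA.
* **Pathway over-representation** — hypergeometric tests of the
  differentially connected metabolites against a pathway library, with
  an importance-weighted impact score (> 0.01 filter).
* Supporting stages: PCA-ellipse outlier removal, Blom rank-based
  inverse normal transform, pooled-variance t-tests with
  Benjamini-Hochberg correction, and balanced resampled Random-Forest
  classification (k = 100 resamplings retaining 85% per group, with
  permutation significance).
* A **synthetic-cohort generator** with planted correlation blocks and
  mean shifts, giving every stage a known ground truth.

See `docs/methods.md` for models, conventions and design decisions.

## Worked example

Simulate the shipped three-group cohort (65 CRC / 74 PP / 87 CTR
samples, 100 metabolites; polyposis rewires a correlation block without
abundance shifts, cancer rewires more and shifts 15 metabolite means),
then run QC, networks and a differential-connectivity test:

```python
import metabonet as mn
from metabonet.data_io import GroupPair

data = mn.simulate(mn.crc_cohort_design(seed=1))
clean, report = mn.remove_outliers(data, confidence=0.95)
normed = mn.blom_transform_matrix(clean)

res_ctr = mn.pclrc_infer(normed.group_values("CTR"), seed=1)
net_ctr = mn.build_network(res_ctr, p_min=0.95, r_min=0.6)
print(len(report.removed_sample_ids), net_ctr.n_edges)

rows = mn.differential_connectivity(
    normed, GroupPair("PP", "CTR"), {"n_iterations": 200},
    n_perm=300, seed=1,
)
print(sum(r.significant for r in rows))
```

On this design the pipeline reproduces the qualitative signature such
cohorts show (numbers from `scripts/acceptance.py --seed 1`): the
cancer group is well separated by abundances (Random-Forest accuracy
85.3%, AUROC 0.941 vs. controls; permutation p = 0.005 at 199
permutations), while polyposis vs. control is inseparable at the
abundance level (accuracy 50.8%, AUROC 0.513, **zero** BH-significant
t-tests) — yet its association network still differs: 11 metabolites
are significantly differentially connected vs. control. The cancer
network is markedly sparser (28 edges) than the control network (60
edges), its topology-PCA centroid sits far from control (distance 1.08)
and from polyposis (0.28 between PP and CRC), and the planted rewired
metabolites are recovered with sensitivity 0.88 at zero empirical false
discoveries.

A command-line interface mirrors the library (`metabonet simulate`,
`qc`, `univariate`, `classify`, `network`, `diffcon`, `topology`,
`enrich`, and `all` for the full configured pipeline with a JSON
manifest); run `metabonet --help`.

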