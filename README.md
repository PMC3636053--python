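# pspnet

Proteomics signature profiling over protein complexes and pathway-derived
subnets.

Shotgun/iTRAQ proteomics of small clinical cohorts suffers from notoriously
inconsistent protein identification: two patients with the same disease
stage may share only a small fraction of their detected proteins, and in a
cohort of a dozen tumours almost no protein is detected in everyone.
Clustering patients on raw detection lists therefore fails, and single
proteins make poor biomarkers. `pspnet` implements hit-rate signature
profiling, which sidesteps the inconsistency by moving from individual
proteins to biologically coherent *feature sets* — curated protein
complexes (e.g. a CORUM-style GMT) or **pathway-derived subnets (PDSs)**,
the connected components a pathway fragments into when restricted to
proteins detected in at least half the patients of either class.

## The statistics

For a feature set *C* and patient *i* with detected-protein set *D\_i*, the
**hit rate** is

    H_Ci = |C ∩ D_i| / |C|

The vector of hit rates over all features is the patient's signature
profile. On these profiles the package provides:

- **Clustering** — Ward linkage on Euclidean distances, with cluster
  confidence from multiscale bootstrap resampling of the features: for
  scale *r*, ⌈*r·p*⌉ features are resampled with replacement and the
  per-cluster containment frequency BP*r* is recorded; fitting
  Φ⁻¹(1−BP*r*) ≈ *v*√*r* + *c*/√*r* by weighted least squares gives the
  approximately unbiased confidence AU = 100·(1 − Φ(*v* − *c*)), alongside
  the plain bootstrap probability BP at *r* = 1.
- **Feature selection** — for each feature, the pooled two-sample
  t-statistic between the per-class hit-rate lists,

      t = (H̄_A − H̄_B) / (S_pooled · √(1/n + 1/m)),

  with an empirical p-value from group-size-preserving label permutations
  (exhaustively enumerated whenever the balanced-assignment space is small
  enough), Benjamini–Hochberg adjustment across features, and ranking
  scores built from iTRAQ ratios: every reported ratio *r* contributes
  max(*r*, 1/*r*) − 1, summed and divided by the number of distinct member
  proteins reported in the class.
- **False-positive analysis** — repeatedly split a single class into two
  random pseudo-groups and count "significant" features; the count
  distribution is compared with the nominal expectation
  *n\_features* × α.
- **Co-location analysis** — enrichment of significant-complex overlap on
  pathways that contributed a significant PDS, Jaccard overlap of
  co-located pairs, and OLS regression between their ranking scores.
- **Ontology analysis** — annotation propagation, informative-term
  extraction (≥ 30 annotated proteins, no child above 30), hypergeometric
  enrichment with Bonferroni correction, and functional-class-scoring
  association of features with a curated term list (e.g. lipid-related
  terms) against random same-size protein sets.

A synthetic-data module generates cohorts, pathways, complexes, ratios and
ontologies with planted signal under the same inconsistency regime, so the
whole pipeline is testable without any external downloads.

## Worked example

```python
from pspnet import simulate, PSPModel

data = simulate.hcc_like(seed=1)          # 5+7 cohort, 50 complexes, 8 with signal
model = PSPModel.from_profiles(data["profiles"], data["complexes"])
res = model.fit(n_perm=2000, seed=1, alternative="two-sided", tie_policy="mid")
print(res.summary(max_rows=6))
```

```
Proteomics Signature Profile — permutation t-test
==========================================================
patients:   12   (mod: 5, poor: 7)
features:   50   permutations: 2000 (two-sided)
significant at raw p <= 0.05: 13
----------------------------------------------------------
feature_id  t_score   p_perm     q_bh  significant  score_mod  score_poor
   CPX0000    6.374 0.001263 0.009019         True      2.311      0.5425
   CPX0001    6.839 0.001263 0.009019         True      2.598      0.9806
   CPX0002    14.69 0.001263 0.009019         True      2.525      0.7966
   CPX0003    13.68 0.001263 0.009019         True      2.161       1.066
   CPX0005    9.387 0.001263 0.009019         True       2.65       1.121
   CPX0006    13.96 0.001263 0.009019         True      2.452      0.9199
...
```

The planted signal features (detected at probability 0.9 in the `mod`
class versus 0.2 in `poor`, against a 0.3 background) head the ranking:
`p_perm` is the empirical permutation p-value (0.0013 is the smallest value
2 × C(12,5)⁻¹-scale enumeration can produce at these group sizes), `q_bh`
its Benjamini–Hochberg adjustment, and `score_mod`/`score_poor` the
per-class iTRAQ-ratio ranking scores — higher in `mod`, where the signal
proteins are actually reported. Clustering the same model,

```python
tree = model.cluster(n_boot=200, seed=1)
```

recovers the two classes as the top split; the poor-class cluster reports
`AU = 99.4, BP = 98.5`.

The same stages are available as subcommands of the `pspnet` CLI
(`simulate`, `extract-pds`, `profile`, `cluster`, `select`, `fpr`,
`coloc`, `enrich`, `termscore`, `run`), all writing TSV/Newick outputs
whose headers echo the version, seed and parameters.

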