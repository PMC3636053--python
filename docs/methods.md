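# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations behind `pspnet`. It is written for a
reader who wants to know *why* the package behaves as it does, not just
what it computes.

## Signature profiles

Each patient is represented by the vector of hit rates H_Ci = |C ∩ D_i|/|C|
over a feature collection (complexes and/or PDSs). Hit rates are stored as
exact floating-point fractions; there is no binarisation and no
abundance weighting — the downstream t-test operates on the fractions
themselves. Patients whose detection list misses every feature are kept as
all-zero rows (the clustering and testing layers tolerate them), because
dropping patients silently would bias any cohort-level conclusion.

Features with fewer than 4 members are excluded from profiling (with a
warning at matrix construction). The threshold exists because tiny sets
make hit rates jump in steps of 1/2 or 1/3, producing large, uninformative
fluctuations. The same minimum applies to PDS extraction.

## PDS extraction

Candidate proteins are those detected in at least half the patients of
either class, computed per class and unioned. "At least half" of an odd
class size rounds up (3 of 5). Each pathway is then restricted to the
candidates; the induced subgraph fragments into connected components, and
components with ≥ 4 nodes become PDSs. Expression-level filters are
deliberately not applied before induction: on sparse detection data they
fragment pathways into mostly sub-threshold pieces.

Multiple PDSs per pathway get deterministic IDs (`<pathway>.pds<k>`,
ordered by descending size, ties by lexicographically smallest member).
This ordering is a reproducibility convention of this implementation, not
a scientific claim; nothing downstream depends on it. Isolated pathway
nodes form components of size 1 and are always dropped at the default
minimum size.

## Clustering and bootstrap confidence

Patients are clustered by Ward linkage on Euclidean distances
(`scipy.cluster.hierarchy.linkage`, deterministic for a fixed input
order). Cluster confidence follows the multiscale bootstrap scheme:

- scale grid r ∈ {0.5, 0.6, …, 1.4} (ten scales straddling 1), B = 1000
  replicates per scale by default — the conventional defaults for this
  procedure; B ≥ 100 is enforced;
- at scale r, round(r·p) features are drawn with replacement, patients are
  reclustered, and each observed cluster's containment frequency BP_r
  (leaf-set equality, invariant to patient input order) is recorded;
- BP_r is clamped to [1/(B+1), B/(B+1)] before the probit transform so
  quantiles stay finite; z_r = Φ⁻¹(1−BP_r) is fitted against
  v√r + c/√r by weighted least squares with the binomial weights
  B·φ(z_r)²/(BP_r(1−BP_r)), falling back to ordinary least squares when
  the weights degenerate;
- AU = 100·(1−Φ(v−c)), clipped to [0, 100]; BP is reported at r = 1.

Degenerate cases bypass the fit: a cluster contained in every replicate at
every scale is reported at AU = 100 (`saturated`), one never observed at
AU = 0 (`never_observed`), and with fewer than two distinct scales AU is
NaN and only BP is reported (`bp_only`). The bootstrap resamples
*features* — the profile dimension — never patients: confidence is about
the stability of the patient tree under perturbation of the feature set.

## Permutation testing

The per-feature statistic is the pooled-variance two-sample t-score.
Zero pooled variance yields t = 0 when the group means agree and a signed
infinity otherwise; both are handled consistently by the empirical null.

The null is built from group-size-preserving label assignments. When
C(n, m) ≤ n\_perm every balanced assignment (including the identity) is
enumerated and the p-value is exact; otherwise n\_perm uniform assignments
are drawn, with an independent, reproducible stream per feature. The
"weighted randomisation" sometimes described for this protocol is
implemented as uniform balanced permutation — no defensible weighting
scheme being available, uniformity is the assumption-free choice.

Three conventions govern how the observed t is compared with the null,
and their interaction matters:

- **Tail.** The classical description — take the tail matching the sign
  of the observed t and report the fraction of null scores beyond it —
  is available as `alternative="signed"` and is the default of
  `permutation_pvalue` and `PSPModel.fit`. As a *test at level α*,
  however, this rule has size ≈ 2α under a symmetric null: each tail
  rejects with probability α and the two events are disjoint (a property
  test in the suite measures 10% at α = 5% on continuous noise).
  `alternative="two-sided"` doubles the adaptive tail (capped at 1) and
  restores size α.
- **Ties.** Hit-rate columns are discrete, so permutation nulls are
  heavily tied. Counting only strictly-beyond scores makes whole tie
  groups at the extremes reject together (measured two-sided size 7.7% at
  α = 5% on the synthetic preset), while counting ties fully is
  conservative (3.4%). `tie_policy="mid"` gives ties half weight — the
  standard mid-p treatment for discrete permutation nulls — and measures
  4.8% discrete and 4.98% continuous. The strict rule remains the
  default for fidelity to the classical description; analyses whose
  *purpose* is comparison against a nominal level (the false-positive
  protocol, the synthetic parameter-recovery evaluation) default to
  two-sided mid-p.
- **Tie detection.** t-scores are rounded to 9 decimals before
  comparison, so permutations that are mathematically tied compare equal
  regardless of floating-point summation order. At typical t magnitudes
  this is ~10⁵ × the accumulation error and far below any significance
  resolution, so it cannot flip a genuine non-tie.

An optional pseudocount mode computes (b+1)/(B+1) for users who need
strictly positive p-values; it is off by default, so a constant feature
degenerates to p = 0 under the strict rule and is flagged as `constant` in
the output rather than silently treated as significant evidence.

BH adjustment uses the standard step-up procedure
(`statsmodels.multipletests`). The default significance call in the
results table is on raw p ≤ α, with the BH column alongside; the
false-positive protocol applies BH by default, matching how such counts
are conventionally reported.

## Ranking scores

For a significant feature and one class, every (member protein, patient)
pair with a reported ratio r contributes max(r, 1/r) − 1 — so a ratio and
its reciprocal count identically, and r = 1 contributes nothing. The sum
S is divided by the number of *distinct member proteins reported in that
class* (not by feature size): without this, a large feature with one
strongly deregulated member outranks a small feature deregulated
throughout. A feature with no reported member scores 0. "Reported" means
a ratio is present; detection without a ratio does not count toward the
denominator.

## False-positive protocol

One class is split into pseudo-groups of floor(n/2)/ceil(n/2) uniformly at
random (every patient used each round), features are tested, and
significant counts are collected over rounds. When C(n, ⌊n/2⌋) ≤ 20,000,
the t-scores of *all* balanced splits are computed once and every round's
null is the exact split distribution — rounds then differ only in which
split plays "observed", which is both exact and fast. For larger classes
each round draws its own Monte-Carlo inner null (1000 assignments by
default). Rounds that cannot produce two groups of ≥ 2 patients are
skipped with a warning, never silently retried.

Two structural facts about this protocol are worth recording. First,
with an exact permutation p and no correction, the raw p is rank-uniform
over splits for *any* fixed data, so the mean count equals
n\_features × α whether or not the class is homogeneous — hidden
substructure shows up as over-dispersion (rounds aligned with the
substructure reject en masse), and under BH as an inflated mean, not in
the uncorrected mean. Second, the nominal-expectation comparison is only
meaningful for a size-α test, hence the two-sided mid-p defaults here.

## Co-location and regression

A pathway "overlaps" a complex when they share at least one protein — the
most permissive reading, configurable via `min_shared`. Enrichment is the
ratio of overlapping fractions among involved versus non-involved
pathways, with NaN sentinels when a denominator is empty. Jaccard overlap
of co-located (PDS, complex) pairs is summarised by the fraction below
0.2, the conventional bar for "essentially disjoint". The score
regression fits complex score on PDS score by OLS; the direction is
arbitrary (R² and the F-test p are direction-invariant for a simple
regression) so the reverse slope is reported too. Outliers are either
user-specified or flagged at |externally studentised residual| > 3;
automated flagging can only suggest what a scatter plot would show.

## Ontology analysis

Annotations propagate to ancestors through `is_a` and `part_of` only
(`regulates` and other relations are excluded, following the usual
term-enrichment convention); propagation is set-valued, so diamonds count
once, and a cyclic parent graph is an error. Informative terms require a
propagated count ≥ 30 with no child *above* 30 — a child at exactly 30
does not disqualify its parent. Propagated (rather than direct) counts
are the default because the frontier rule is otherwise dominated by
annotation granularity quirks; a `direct_only` flag exists.

Hypergeometric enrichment is upper-tailed with a Bonferroni multiplier
equal to the number of terms actually tested for that feature. The
FCS-style term-list association draws random same-size sets without
replacement from a universe which defaults to all annotated proteins —
the choice of universe materially shifts the p-value and is echoed in
output headers. Hits are counted against the term list closed under
descendants (configurable off). The p-value counts random hit rates
*strictly* greater than observed, so a feature at hit rate 1 always
scores p = 0.

## Synthetic data

The generators emulate the detection-inconsistency regime the method is
designed for. Defaults: a 5 + 7 two-class cohort over ~1500 proteins,
background detection probability 0.3 (two patients then share ~18% of
detections — p/(2−p) — and the chance a protein is detected in all seven
patients of the larger class is ≈ 2·10⁻⁴, i.e. near-zero overlap across a
whole class, as observed in real cohorts of this kind), signal features
detected at 0.9 versus 0.2 by class, log-normal ratios (σ = 0.25) centred
at 1 with a ×1.5 shift on signal proteins — enough to produce ranking
scores in the few-fold range. Pathways are random spanning trees plus
Bernoulli extra edges (connected by construction) over a partially shared
namespace; ontologies carry a planted informative frontier (terms with 31
annotated proteins, so their ancestors are disqualified by a child above
the threshold).

Detection is independent across proteins, which real data violates
(co-detection of abundant complexes, per-sample depth effects); a
per-patient log-normal coverage factor (`coverage_sigma`) reintroduces
patient-level correlation when wanted. Passing tests on these cohorts
therefore demonstrates correctness of the machinery and calibration under
the stated model, not robustness to every correlation structure of real
proteomes.

## Verification sizes

The test suite and `scripts/acceptance.py` use problem sizes chosen to
make Monte-Carlo bands tight while keeping each check in seconds: 523
continuous null features × 1500 bipartition rounds for the
false-positive mean; 100 random graphs against a flood-fill component
oracle; 12 random 6×10 matrices against an O(n³) Lance–Williams oracle;
20 seeded two-block cohorts (30 features, B = 250 per scale) for the
AU ≥ 95 recovery rate; 10,000 draws against exact hypergeometric tails;
and 20 seeds × (50 signal + 450 null) features for parameter recovery,
where signal and null features draw from disjoint proteome blocks so the
null block is genuinely null.

## Known limitations

- Identifier namespaces are taken as given; no ID mapping is performed.
- The PDS notion is purely topological (connected components after
  candidate restriction); score-optimised subnetwork search is out of
  scope.
- AU values inherit the asymptotic approximations of the multiscale
  bootstrap; for very small feature counts the scale grid spans few
  distinct resample sizes and AU becomes coarse.
- The FCS universe and the pathway-overlap definition are both
  choices with visible effect on p-values; they are surfaced as
  parameters and echoed in outputs rather than hidden.
- Mid-p calibration on discrete hit-rate features is approximate (measured
  ≈ 4.8% at α = 5% under the preset); exact size-α testing on coarse
  discrete nulls is not attainable by any tie convention.
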