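# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the tests demonstrate.

## The contamination problem and the filter

A low-biomass specimen yields an amplicon library in which reagent and
environmental DNA ("background") can dominate the genuine community.
Negative field controls — empty sampling instruments exposed to the
sampling environment and processed identically — sample that background.
The filter compares every feature (ASV) between the specimen group and the
control group of the *same sample type* on two axes:

* prevalence: the fraction of samples in the group where the feature's
  count is at least `presence_threshold` (default 1 read);
* mean relative abundance (mra): the feature's count divided by the
  sample's read depth, averaged over **all** samples of the group,
  zero-count samples included (a zero-depth sample contributes 0).

A feature is removed when both
`prev_s ≤ prevalence_ratio · prev_c` (default ratio 2) and
`mra_s ≤ abundance_ratio · mra_c` (default 10) hold. Rationale for the
choices the inequalities leave open:

* **Both sides use relative abundance.** Comparing a specimen-side
  fraction to a control-side raw count would be dimensionally
  inconsistent; the same statistic is evaluated on both groups.
* **Zeros are included in the mean.** Restricting the mean to samples
  containing the feature would leave the statistic undefined for absent
  features and make it discontinuous at single-read detections.
* **AND combination** is the default; an `OR` variant exists for
  sensitivity analysis (`DecontamParams(combine="or")`).
* **Literal ≤ semantics.** A feature with zero counts everywhere in a
  sample type satisfies `0 ≤ 0` on both criteria and is flagged removed;
  this is vacuous (no reads are removed) but keeps the implementation
  identical to the defining inequalities. The useful guarantee is: a
  feature present in at least one specimen and absent from every control
  has `prev_s > 2·prev_c = 0` and is always retained.

Statistics are computed **once** on the input table (single pass, never
re-estimated on the filtered table). Filtering is independent per sample
type; controls of one type never inform another. After feature removal,
specimens with remaining depth strictly below `min_sample_reads`
(default 500) are dropped; the report retains both the pre-dropout and
post-dropout tables together with per-sample read accounting so either
convention can be used downstream.

Two provable properties are enforced by tests: the removal set is
monotone (weakly grows) in both ratios, and matches a brute-force
evaluation of the inequalities on random tables.

## qPCR quantification

The standard curve is an ordinary least-squares fit of Cq on
log₁₀(copies) over a dilution series (≥ 3 distinct points); amplification
efficiency is `10^(−1/slope) − 1` (slope −3.3219 ⇔ efficiency 1.0, a
perfect doubling per cycle). Unknowns are inverted as
`copies = unit_scale · 10^((Cq − intercept)/slope)`; each run is
calibrated by its own standard series with no cross-run pooling.
Technical replicates are combined as the mean of back-calculated copies
by default (mean-of-Cq is available); non-detects are excluded by default
or mapped to zero copies behind an explicit flag.

Specimen/control comparisons use a two-tailed Mann–Whitney U test. U is
computed from midrank sums. For pooled sizes n₁+n₂ ≤ 20 the p-value is
exact: all C(n₁+n₂, n₁) assignments of the pooled values to the groups
are enumerated, and `p = P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|)` — the
distance-from-null-mean rule rather than tail-doubling. For tie-free data
the two coincide (the null distribution of U is symmetric); with ties the
distance rule remains well defined and the enumeration stays exact
conditional on the observed values. Larger samples use the normal
approximation with tie correction and a 0.5 continuity correction. At
n₁ = n₂ = 8 the attainable size nearest the 0.05 level is 0.0499, so the
exact test is essentially nominal there (verified by simulation in the
test suite).

## Community statistics

* **Genus aggregation** sums features sharing the lineage prefix down to
  the requested rank. A feature whose classification stops above the rank
  is pooled under its deepest classified parent as
  `…;<parent>;unclassified <parent>`; fully unclassified features pool
  into a single `unclassified` group. This conserves per-sample depth
  exactly and makes aggregation idempotent across ranks (genus → family
  equals direct family aggregation).
* **Shannon diversity** uses the natural logarithm and is computed on
  proportions without rarefaction.
* **Bray–Curtis** is computed on per-sample proportions by default so
  unequal sequencing depths do not masquerade as composition differences;
  a raw-count mode exists because the convention differs between
  pipelines. Two all-zero samples are defined as distance 0.
* **PCoA** is classical metric scaling: double-center `B = −½ J D² J`,
  eigendecompose, keep positive-eigenvalue axes, scale eigenvectors by
  √λ. Negative eigenvalues (non-Euclidean distances) are discarded
  without Lingoes/Cailliez correction; proportions explained are relative
  to the positive-eigenvalue total. Tested against scikit-bio's
  implementation and against direct distance reconstruction (≤ 1e-8 for
  Euclidean inputs).
* **PERMANOVA** is one-way with unrestricted label permutations:
  `SS_total = Σ_{i<j} d²_ij / n`, `SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g`,
  pseudo-F = `((SS_t − SS_w)/(g−1)) / (SS_w/(n−g))`, `R² = 1 − SS_w/SS_t`.
  Monte Carlo p is `(hits + 1)/(n_perm + 1)` (identity permutation
  included), so the smallest attainable p at 9,999 permutations is 1e-4;
  an exhaustive mode enumerates all distinct label arrangements for small
  n. An all-zero distance matrix returns F = 0, p = 1 rather than
  erroring. Seeds are explicit arguments.
* **Dispersion homogeneity (betadisper-style)** embeds samples in the
  positive-eigenvalue PCoA space, takes each sample's Euclidean distance
  to its group centroid, computes the one-way ANOVA F on those distances,
  and permutes the distances for the p-value. The imaginary-axis
  bookkeeping that some reference implementations apply to negative
  eigenvalues is deliberately omitted — for Bray–Curtis matrices of the
  size handled here the discarded inertia is small, and the simpler
  estimator is easier to reason about. Groups need ≥ 2 members.
* **Paired Spearman correlations** between sample types of the same
  subject use absolute counts over features selected by
  `select_shared_features` (default: summed count over all samples of
  both tables strictly greater than 100 — the alternative per-sample
  reading is available behind a flag, since the phrase "present more than
  100 times in all samples" is genuinely ambiguous). Rho uses midranks;
  p-values use the t approximation, or exact enumeration of all k!
  rank permutations when k ≤ 8 features. Bonferroni m = number of pairs.
  A pair with a constant vector has undefined rho; it is flagged and
  excluded from the arithmetic average. How per-pair p-values should be
  averaged into a single summary is not well defined and is not done.

## Synthetic-data model

Each feature class has an absolute-load model, and counts follow from
loads:

* **Contaminants** (default k = 40) get per-taxon base log-loads
  `b_i ~ Normal(μ_c, 1.0)` drawn once per study, and per-sample loads
  `Lognormal(b_i, 0.6)` with the **same parameters in specimens and field
  controls** — the reagent/environment regime in which prevalence and
  abundance ratios center near 1, which is exactly what the 2×/10×
  thresholds presuppose. μ_c is set so the expected summed contaminant
  load is 980 copies.
* **Signal taxa** (default 25 per sample type, of which 6 are shared
  between the two types' pools to give the paired-correlation analysis a
  substrate) occur only in specimens, each independently with presence
  probability 0.3 and load `Lognormal(μ_s, 1.5)`. μ_s is solved
  analytically so the expected summed signal load matches the calibration
  anchor: specimen qPCR mean − control qPCR mean (3,370 copies for
  meconium, 1,560 for amniotic fluid). An optional leak probability
  (default 0) lets signal taxa appear in controls to probe filter
  specificity.
* **Counts**: a sample's composition is its load vector normalised;
  counts are Dirichlet-multinomial with concentration 100 (moderate
  overdispersion) at a lognormal depth whose mean/SD equal the study
  anchors (≈ 92k/36k and 128k/22k reads for specimens, 127k/21k and
  136k/13k for controls). Depth is independent of load — library
  preparation equalises input, which is why a control can out-sequence a
  specimen.
* **qPCR**: specimens read `scale · (total signal load) + background`,
  controls read background alone; backgrounds are lognormal with
  mean/SD 980/850 (meconium) and 1,610/790 (amniotic fluid), and the
  reading carries multiplicative lognormal noise (log-SD 0.25, unit
  mean so anchors are preserved). The qPCR background draw is decoupled
  from the sequencing-side contaminant loads: in a real workflow
  sequencing contamination largely enters at library preparation, after
  the qPCR aliquot is taken, so the two backgrounds need not agree.

Group sizes default to 23 paired specimens per type with 11 (meconium)
and 8 (amniotic fluid) field controls. All randomness flows from a single
`numpy` Generator seeded by `SimulationConfig.seed`; identical seeds give
byte-identical tables.

**What the generator does not emulate.** Taxonomic realism (lineages are
synthetic labels), compositional correlation between taxa, batch effects,
index-hopping/cross-talk, PCR-cycle bias, chimeras — and, notably, the
severe read attrition some real low-biomass specimens show after
filtering: with the default calibration, genuine DNA is ~77 % of a
specimen's absolute load, so decontaminated specimens keep most of their
reads and the <500-read dropout rarely triggers. Real studies in this
regime can lose a quarter of their specimens; the dropout rule is
exercised by constructed fixtures instead. Passing tests therefore show
that the algorithms are correct on the stated model, not that the model
captures every failure mode of real data.

## Problem sizes and runtime choices

The test suite and acceptance script favour sizes that finish in seconds
to a few minutes on one CPU while keeping every statistical check
honest: 1,000 random tables for the filter-oracle equivalence, 1,000
null draws at n = 8 + 8 for the exact-test size, 500 null simulations at
999 permutations for the PERMANOVA size, 200 replicate studies for the
qPCR calibration, and 9,999 permutations for single PERMANOVA runs
(matching the package default). Monte Carlo assertions use ±3 binomial
standard errors.

## Known limitations

* The dispersion test permutes distances-to-centroid rather than
  least-squares residuals and ignores negative-eigenvalue axes; results
  can differ slightly from R's `betadisper`/`permutest` on strongly
  non-Euclidean matrices.
* The exact Mann–Whitney enumeration is O(C(n₁+n₂, n₁)) and capped at a
  pooled size of 20; beyond that the normal approximation is used even
  when an exact network algorithm would be feasible.
* `aggregate_by_rank` trusts the provided lineages; it does not resolve
  conflicting or re-ranked taxonomies.
* The pipeline assumes one metadata row per sequenced sample and exactly
  two sample classes; longitudinal or multi-batch designs are out of
  scope.
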