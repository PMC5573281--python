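# Methods

## Study design being modelled

Two case strata (restricted-eating, n₁ = 38; binge-eating, n₁ = 55) receive
exome sequencing without matched controls. The control information comes
from a reference exome aggregate: for each gene, a count x₂ of qualifying
(novel, predicted-damaging) variants and the number n₂ of individuals
contributing to that count (n₂ ≈ 60,000, varying per gene with coverage).
The per-gene question is whether the cohort's qualifying-variant rate
exceeds the reference rate.

## Variant filter

A call qualifies iff all of:

* region class ∈ {exonic, UTR, splicing};
* caller FILTER flags ∩ {QD, Q20, badReads, alleleBias} = ∅;
* no membership in the known-variant databases (1000 Genomes, dbSNP, EVS)
  — membership is consumed as input annotation, never queried live;
* CADD phred ≥ 15, **or** CADD missing and the consequence is in the
  unscored-keep set {stopgain, frameshift, nonframeshift_indel}.

The unscored-keep set includes length-preserving MNVs and in-frame indels
(`nonframeshift_indel`) as well as truncating classes: these are
protein-altering calls the scorer does not cover, and excluding them for
lack of a score would silently discard exactly the indel/MNV calls of
interest. The set is configurable (`FilterConfig.unscored_keep_consequences`),
as is the boolean `keep_unscored_truncating` gate.

Counting unit: the burden count is **variant-carrier events** — a kept
variant carried by k individuals contributes k to each annotated gene. For
novel ultra-rare sites each site has a single carrier, so events, variants
and carriers coincide; the unit stays well defined for recurrent sites.
Multi-gene annotations count once per gene and are tallied in the audit log.

## Burden test

Default mode (`chisq`) reproduces the classical one-sided two-sample
proportion test: the 2×2 table (x₁, n₁−x₁ / x₂, n₂−x₂) gives the Yates-
corrected statistic χ² = Σ (|O−E| − min(0.5, |x₁−E₁₁|))²/E, and
p = 1 − Φ(sign(p̂₁−p̂₂)·√χ²). This matches R's `prop.test(...,
alternative="greater")` to ~10 significant digits on frozen regression
cases. Conventions: p = 1 when x₁ = x₂ = 0; p = 0.5 when the proportions
are exactly equal.

Exact mode (`exact`) returns the binomial tail P(X ≥ x₁ | n₁, p̂) at the
pooled rate p̂ = (x₁+x₂)/(n₁+n₂). The pooled rate (rather than x₂/n₂) keeps
the test defined when x₂ = 0 and is slightly conservative otherwise.

**Approximation regime.** The chi-square tail tracks the exact binomial
tail within a factor of 3 only on a fairly narrow ridge: reference sample
≈ 5–10× the cohort, expected cohort count n₁·(x₂/n₂) ≳ 2, reference rate
≤ 10⁻³, and p ∈ [10⁻⁶, 0.5]. Outside it the approximation degrades in both
directions: with a 38-person cohort against 60,000 reference exomes at
rate 5×10⁻⁴, the corrected chi-square p for a cohort singleton can
understate the exact tail by one to thirty orders of magnitude (the
normal tail cannot represent the skew of a count with expectation ≈ 0.02);
conversely, when the reference is not much larger than the cohort the
two-sample statistic is far more conservative than a fixed-rate binomial
oracle, because the oracle ignores reference sampling noise. The factor-3
oracle test in the suite therefore runs on the documented ridge, and the
calibration/power studies use the exact mode. Practically: with cohorts of
tens of individuals against a large reference, the default chi-square mode
reproduces the classical procedure but inflates significance for 1–3
observed variants; the exact switch is the statistically safe choice there.

Multiple testing: Benjamini–Hochberg step-up within each phenotype group
(the two strata are reported as separate gene lists); a pooled mode exists.
Only genes with x₁ > 0 are tested ("genes hit in the cohort"); genes
missing from the reference table get x₂ = 0 with n₂ set to the largest
reference cohort seen, flagged `ref_missing`.

**Selection caveat.** Testing only genes with x₁ > 0 and correcting over
that random subset makes BH's guarantee conditional-invalid in the extreme
ultra-rare regime: when the null expectation of x₁ is ≪ 1, *every* tested
gene is a 1-in-30-or-rarer event and the tested-subset p-values are no
longer super-uniform, so the realized FDR can approach 1 regardless of the
nominal level. This is a property of the procedure being modelled, not an
implementation artifact. The null-calibration study therefore runs at the
generator's default baseline (expected cohort counts ≈ 2, where nearly all
genes with signal are testable and the discrete p-values are conservative);
at that operating point the empirical FDR over 20 seeds is ≈ 0.03 against
the nominal 0.1.

## Synthetic-data generator

All randomness flows from one integer seed through fixed per-table
sub-streams (SeedSequence spawn keys), so every output is byte-reproducible
and tables are independently perturbable.

* **Cohort**: occurrences Poisson per gene × individual; each occurrence is
  an independent novel site with a single carrier. Defaults: 2000 genes,
  baseline rate 0.05 qualifying variants/gene/individual, 2% of genes
  spiked per group at 25× the baseline, half of the spiked genes drawn from
  the training positives (so hit lists are genuinely enriched for them).
  Annotation mixtures: 80% of scored variants with CADD ≥ 15, 30% carrying
  a known-database record, 5% caller-flagged, 5% unscored frameshifts,
  region mix 70/15/10/5 exonic/UTR/splicing/other — chosen to exercise
  every filter branch.
* **Reference**: per-gene count Poisson(n_ref × baseline) at the *baseline*
  rate (the reference is never enriched); contributing individuals uniform
  in [0.8, 1.0]×n_ref to emulate coverage variation.
* **Features**: expression X = λ f′ + 0.5·ε with a sparse unit loading over
  8 of 40 columns and λ ~ N(signal, 1) for positives, N(0, 1) otherwise;
  annotation matrix Bernoulli with a reserved 20-term block where the
  positive-class rate is 0.05 + 0.12·signal. At signal 0 the classes are
  exchangeable by construction; at signal 3 held-out AUC exceeds 0.9 for
  both forms. The citation table gives positives ≥ 3 topical citations and
  reserves the globally highest total-citation counts for the designated
  negatives, so the training-set builder recovers both classes exactly.
* **Network**: preferential-attachment background (3 edges/node, scores
  150–949) plus positive–positive edges with probability 0.3 at scores
  700–999, forming a module detectable at the default confidence threshold.

**Why baseline 0.05.** The generator's default baseline rate was set
analytically, before any end-to-end run, to put expected per-gene cohort
counts near 2 (0.05 × 38 ≈ 1.9): below roughly 0.02 the selection caveat
above makes the tested-subset FDR uncontrollable for *any* test, because a
single observed variant is already individually significant. Realistic
per-gene rates for novel damaging variation are orders of magnitude lower;
the default is a test-power choice, not a biological claim, and the
ultra-rare regime is exercised separately by the spike-recovery scenario.

**Scenario constructors.** `SimulationConfig.null_calibration(seed)` (no
spike, clean annotations, sharp null) and
`SimulationConfig.spike_recovery(seed)` (baseline 50/60000 so expected
reference counts are 50; 60-fold spike). In the spiked scenario recovery is
limited by the chance of observing ≥ 1 cohort variant at all:
mean of P(Poisson(n_g·rate·60) ≥ 1) over the two group sizes ≈ 0.9, which
is why the multiplier sits at 60 — at 25× the same bound is ≈ 0.55 and no
test can recover 80% of spiked genes from cohorts this small. Both
scenarios zero the annotation contamination so the realized qualifying rate
equals the nominal rate; they measure the burden stage, not filter
attrition.

## Evidence scores

Hand-rolled bagging over sklearn `DecisionTreeClassifier`
(`max_features="sqrt"`, otherwise library defaults), 100 trees, bootstrap
samples the size of the training set. Scores are **vote proportions** (not
averaged leaf probabilities); training genes are scored only by trees whose
bootstrap excluded them, and the per-tree bootstrap/OOB bookkeeping can be
returned for audit (`keep_trace=True`). Class imbalance (~100 positives vs
1000 negatives) is left unweighted by default, with a `class_weight`
switch. Missing feature values are median-imputed per column and the
affected columns reported. One shared training set serves both evidence
forms. Combined score = max(expression, GO); a gene with one missing form
carries the other, flagged.

## Enrichment and network

Enrichment uses the exact hypergeometric (Fisher) two-sided p and the
sample odds ratio (a·d)/(b·c); zero cells flag the result degenerate with
an infinite/undefined OR. The default universe is the set of genes with at
least one tested cohort variant — the odds ratio is only interpretable
relative to a stated universe, and this is the smallest defensible one.

The module rule is deliberately conservative: anchors are training
positives that are themselves in the projected (significant) node set;
`include_all_positives=True` adds every positive present in the network as
a potential anchor. Edge threshold 700 is the conventional high-confidence
STRING cutoff and is configurable; identifier mapping is delegated to an
optional alias table.

## Numerical and degenerate-input conventions

* p = 1 at x₁ = x₂ = 0; p = 0.5 at exactly equal proportions; errors on
  negative counts, x > n, or non-positive n.
* BH ties need no special handling (step-up handles them); q-values are
  order-preserving in p.
* Filtering is idempotent; toggling one filter rule changes only decisions
  citing that rule.
* Empty inputs (cohorts, modules, graphs) produce empty outputs, never
  errors; an empty gene universe for enrichment is an error.
* Gene-name ties in training-set construction break lexicographically.

## What the synthetic validation does and does not show

The generator draws independent Poisson counts per gene — no gene-length
variation, no site-frequency spectrum, no linkage or ancestry structure,
no correlated coverage between cohort and reference, and annotation flags
independent of true deleteriousness. Passing calibration/power tests
therefore demonstrates the statistical machinery is correct under its own
assumptions, not that real-cohort hit lists at these settings would have
the same error rates; in particular the real-data regime (per-gene rates
~10⁻⁵–10⁻³) sits squarely in the selection-caveat zone where burden lists
from tested-subset BH should be treated as hypothesis-generating. Problem
sizes in the test suite (300–2000 genes, 10–20 seeds) were chosen so the
full suite completes in well under a minute of simulation per study while
keeping Monte-Carlo error small relative to the asserted margins.
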