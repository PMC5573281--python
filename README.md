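# burdenscope

Rare-variant burden analysis for small, deeply phenotyped cohorts compared
against a large reference exome database, with literature-anchored gene
prioritization and interaction-network module extraction.

The package is aimed at the study design where a modest number of cases
(here: two disordered-eating phenotype strata, restricted-eating *n* = 38
and binge-eating *n* = 55) receive whole-exome sequencing without matched
controls, and the burden of **novel, predicted-damaging** variants in each
gene is compared to per-gene counts from a reference population of tens of
thousands of exomes (ExAC-style: per gene, a qualifying-variant count and
the number of individuals contributing to it). Because no real cohort is
bundled, a first-class synthetic-data generator emulates every input with
known ground truth, so each stage's operating characteristics are testable.

## The analysis

1. **Filter** (`burdenscope.filtering`) — a variant qualifies iff it lies in
   an exonic/UTR/splicing region, carries none of the caller FILTER flags
   {QD, Q20, badReads, alleleBias}, is absent from the known-variant
   databases (1000 Genomes, dbSNP, EVS), and has CADD phred ≥ 15 (unscored
   protein-altering indels/MNVs are retained). Every decision carries its
   failed-rule labels and the audit log reconciles input = kept + dropped.
2. **Burden test** (`burdenscope.burden`) — for each gene with x₁ > 0
   qualifying variants among n₁ cohort individuals versus x₂ among n₂
   reference individuals, a one-sided two-sample proportion test of
   H₁: x₁/n₁ > x₂/n₂. The default statistic is the continuity-corrected
   chi-square, referred to N(0,1) as p = 1 − Φ(sign(p̂₁−p̂₂)·√χ²) — the
   classical `prop.test` form — with an exact binomial-tail mode
   (P(X ≥ x₁ | n₁, p̂_pooled)) for the ultra-rare regime where the normal
   approximation's tail fails. P values are Benjamini–Hochberg adjusted
   within each phenotype group; genes with q < 0.1 are carried forward.
3. **Evidence scores** (`burdenscope.evidence`) — positives are genes with
   ≥ 3 topical literature citations; negatives the 1000 most-cited genes
   with none. Per evidence form (expression matrix, binary GO annotation
   matrix) a bagged ensemble of 100 decision trees yields each gene's score
   as the fraction of trees voting "candidate" (out-of-bag votes for
   training genes); the combined score is max(expression, GO).
4. **Enrichment** (`burdenscope.pipeline.overlap_enrichment`) — 2×2 overlap
   of burden hits with training positives over a stated gene universe:
   sample odds ratio (a·d)/(b·c) and exact hypergeometric (Fisher) p.
5. **Network module** (`burdenscope.network`) — burden-significant genes are
   projected onto a STRING-dialect weighted network (edges ≥ 700 by
   default); the module is the union of connected components, among
   significant genes that are training positives or their neighbors, that
   contain at least one training positive.

## Worked example

The packaged variant table (25 annotated calls in neuropeptide-pathway
genes, one distinct carrier per row) run through the default filter:

```python
import burdenscope as bs

kept = bs.filter_cohort(bs.load_table1_fixture(), bs.FilterConfig())
print(kept.audit["n_kept"], "of", kept.audit["n_input"], "qualify")
print("NTS/NTSR1 restricted carriers:",
      bs.count_pathway_carriers(kept.kept, {"NTS", "NTSR1"}, "restricted"))
print("GCG/GLP1R binge carriers:",
      bs.count_pathway_carriers(kept.kept, {"GCG", "GLP1R"}, "binge"))
```

prints

```
23 of 25 qualify
NTS/NTSR1 restricted carriers: 5
GCG/GLP1R binge carriers: 4
```

The two excluded rows (UCN, POMC) fail the novelty rule — both carry dbSNP
records and non-zero reference-population MAFs. Five of 38 restricted-eating
individuals carry qualifying variants in the neurotensin ligand/receptor
pair, and four of 55 binge-eating individuals in the GLP-1 ligand/receptor
pair; NTS itself carries 4 qualifying variants in the restricted group.

A full synthetic run (simulate → filter → burden → evidence → enrichment →
network), which writes all artifacts plus a reproducibility manifest:

```python
cfg = bs.PipelineConfig(sim=bs.SimulationConfig(
    n_genes=300, n_positive_training=40, n_negative_training=120, seed=7))
manifest = bs.run_all(cfg, "out/run7")
print(manifest.summary)
```

```
{'enrichment_odds_ratio': 6.38, 'enrichment_p_value': 0.0040,
 'spiked_recall_restricted': 1.0, 'spiked_recall_binge': 1.0,
 'fdp_restricted': 0.0, 'fdp_binge': 0.0, 'module_size': 6}
```

Here all spiked risk genes (25-fold rate elevation) were recovered at
q < 0.1 with no false calls, and — because half of the spiked genes are
drawn from the training positives — the hit list is strongly enriched for
them (OR 6.4). The same pipeline is scriptable from a shell via the
`burdenscope` command (`simulate`, `filter`, `burden`, `evidence`,
`network`, `enrich`, `run`).

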