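"""Synthetic cohorts with known ground truth for exercising the pipeline.

The generator emulates the five inputs the analysis consumes: an annotated
cohort variant table for two phenotype groups (restricted-eating n=38,
binge-eating n=55 by default), per-gene reference-population counts, a gene
citation table, expression and functional-annotation feature matrices, and a
weighted interaction network.  A subset of "risk" genes per group receives a
fold-elevated qualifying-variant rate; a subset of "training positive" genes
shares feature-space signal and excess mutual edges.  Every output is a
deterministic function of the config seed (independent sub-streams per
table), and the ground truth is emitted alongside each dataset.

Variant occurrences are Poisson per gene x individual in the ultra-rare
regime: each occurrence is an independent novel site carried by a single
individual, so carrier events and variant counts coincide.  Annotation
mixtures (CADD, database membership, caller flags, region classes) default to
values that exercise every filter branch; the scenario constructors used by
the calibration and power studies zero them out so the realized qualifying
rate equals the nominal rate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .filtering import AnnotatedVariant

_BASES = ("A", "C", "G", "T")
# fixed sub-stream identifiers so each output table has independent randomness
_STREAMS = {"truth": 0, "cohort": 1, "reference": 2, "features": 3, "citations": 4, "network": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    ``baseline_rate`` is the expected number of qualifying (novel,
    predicted-damaging) variants per gene per individual.  The default 0.05
    puts expected per-gene cohort counts near 2, the regime in which the
    per-gene proportion test is informative for cohorts of tens of
    individuals; the ultra-rare regime (expected reference counts 5-50) is
    covered by :meth:`spike_recovery`.  ``rate_multiplier`` is the fold
    elevation applied to each group's risk genes.
    """

    n_genes: int = 2000
    n_restricted: int = 38
    n_binge: int = 55
    n_reference: int = 60000
    baseline_rate: float = 0.05
    risk_gene_fraction: float = 0.02
    rate_multiplier: float = 25.0
    risk_from_positive_fraction: float = 0.5
    n_positive_training: int = 100
    n_negative_training: int = 1000
    n_expression_samples: int = 40
    n_go_terms: int = 200
    n_go_signal_terms: int = 20
    signal_strength: float = 2.0
    edge_density: float = 3.0
    positive_edge_prob: float = 0.3
    cadd_damaging_fraction: float = 0.8
    known_fraction: float = 0.3
    flagged_fraction: float = 0.05
    truncating_unscored_fraction: float = 0.05
    region_weights: tuple[tuple[str, float], ...] = (
        ("exonic", 0.70), ("UTR", 0.15), ("splicing", 0.10), ("other", 0.05)
    )
    gene_aliases: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_restricted": self.n_restricted,
            "n_binge": self.n_binge, "n_reference": self.n_reference,
            "n_positive_training": self.n_positive_training,
            "n_negative_training": self.n_negative_training,
            "n_expression_samples": self.n_expression_samples,
            "n_go_terms": self.n_go_terms,
        }
        for name, val in counts.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if not np.isfinite(self.baseline_rate) or not 0 <= self.baseline_rate < 1:
            raise ValueError("baseline_rate must be finite and in [0, 1)")
        if not np.isfinite(self.rate_multiplier) or self.rate_multiplier < 1:
            raise ValueError("rate_multiplier must be finite and >= 1")
        if not 0 < self.risk_gene_fraction < 1:
            raise ValueError("risk_gene_fraction must be in (0, 1)")
        if self.n_positive_training + self.n_negative_training > self.n_genes:
            raise ValueError("training sets cannot exceed the gene universe")

    # -- named study scenarios -------------------------------------------------

    @classmethod
    def null_calibration(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Sharp null: no spiked genes, clean annotations (every emitted
        variant qualifies), so cohort and reference share one rate exactly."""
        defaults = dict(
            rate_multiplier=1.0,
            cadd_damaging_fraction=1.0,
            known_fraction=0.0,
            flagged_fraction=0.0,
            truncating_unscored_fraction=0.0,
            region_weights=(("exonic", 1.0),),
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def spike_recovery(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Ultra-rare spiked scenario: expected reference count 50 per gene
        (baseline 50/60000) and a 60-fold elevation in risk genes, the point
        at which spiked genes are expected to surface in >=80% of cases given
        cohorts of 38 and 55 (recovery is limited by the chance of observing
        at least one variant: mean of P(Poisson(n_g * rate) >= 1) ~ 0.9)."""
        defaults = dict(
            baseline_rate=50 / 60000,
            rate_multiplier=60.0,
            cadd_damaging_fraction=1.0,
            known_fraction=0.0,
            flagged_fraction=0.0,
            truncating_unscored_fraction=0.0,
            region_weights=(("exonic", 1.0),),
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def gene_universe(self) -> list[str]:
        names = [f"G{i + 1:06d}" for i in range(self.n_genes)]
        for i, alias in enumerate(self.gene_aliases[: self.n_genes]):
            names[i] = alias
        return names

    def sample_ids(self) -> dict[str, list[str]]:
        return {
            "restricted": [f"RES{i + 1:03d}" for i in range(self.n_restricted)],
            "binge": [f"BIN{i + 1:03d}" for i in range(self.n_binge)],
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region_weights"] = [list(x) for x in self.region_weights]
        d["gene_aliases"] = list(self.gene_aliases)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "region_weights" in d:
            d["region_weights"] = tuple((str(k), float(v)) for k, v in d["region_weights"])
        if "gene_aliases" in d:
            d["gene_aliases"] = tuple(d["gene_aliases"])
        return cls(**d)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    risk_genes_restricted: frozenset[str]
    risk_genes_binge: frozenset[str]
    training_positives: frozenset[str]
    seed: int

    def to_dict(self) -> dict:
        return {
            "risk_genes_restricted": sorted(self.risk_genes_restricted),
            "risk_genes_binge": sorted(self.risk_genes_binge),
            "training_positives": sorted(self.training_positives),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            risk_genes_restricted=frozenset(d["risk_genes_restricted"]),
            risk_genes_binge=frozenset(d["risk_genes_binge"]),
            training_positives=frozenset(d["training_positives"]),
            seed=int(d["seed"]),
        )


def make_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw training positives, then per-group risk genes (a configurable
    fraction of which are drawn from the positives, so burden hits are
    enriched for training genes as in a study where the spiked biology
    overlaps the literature)."""
    rng = _rng(config.seed, "truth")
    genes = np.array(config.gene_universe())
    positives = rng.choice(genes, size=config.n_positive_training, replace=False)
    pos_set = set(positives)
    others = np.array(sorted(set(genes) - pos_set))

    n_risk = max(1, round(config.risk_gene_fraction * config.n_genes))
    risk_sets = []
    for _ in ("restricted", "binge"):
        n_from_pos = min(len(positives), round(config.risk_from_positive_fraction * n_risk))
        chosen = set(rng.choice(positives, size=n_from_pos, replace=False))
        chosen |= set(rng.choice(others, size=n_risk - n_from_pos, replace=False))
        risk_sets.append(frozenset(chosen))

    return SyntheticTruth(
        risk_genes_restricted=risk_sets[0],
        risk_genes_binge=risk_sets[1],
        training_positives=frozenset(positives),
        seed=config.seed,
    )


def generate_cohort(
    config: SimulationConfig, truth: SyntheticTruth | None = None
) -> tuple[list[AnnotatedVariant], SyntheticTruth]:
    """Draw the cohort variant table: per gene g and individual i the number
    of qualifying occurrences is Poisson(baseline_rate x multiplier[g, group]),
    each occurrence an independent novel site carried by that individual only.
    Annotations (CADD mixture, database membership, caller flags, region
    class, unscored truncating class) are drawn per variant at the configured
    fractions."""
    if not np.isfinite(config.baseline_rate):
        raise ValueError("baseline_rate must be finite")
    truth = truth or make_truth(config)
    rng = _rng(config.seed, "cohort")
    genes = config.gene_universe()
    samples = config.sample_ids()
    risk_by_group = {
        "restricted": truth.risk_genes_restricted,
        "binge": truth.risk_genes_binge,
    }
    region_names = [r for r, _ in config.region_weights]
    region_p = np.array([w for _, w in config.region_weights], dtype=float)
    region_p = region_p / region_p.sum()

    variants: list[AnnotatedVariant] = []
    for group in ("restricted", "binge"):
        ids = samples[group]
        risk = risk_by_group[group]
        rates = np.array(
            [
                config.baseline_rate * (config.rate_multiplier if g in risk else 1.0)
                for g in genes
            ]
        )
        counts = rng.poisson(np.repeat(rates[:, None], len(ids), axis=1))
        gi, ii = np.nonzero(counts)
        for g_idx, i_idx in zip(gi.tolist(), ii.tolist()):
            for _ in range(int(counts[g_idx, i_idx])):
                chrom = str(1 + g_idx % 22)
                pos = int(rng.integers(1, 2**27))
                ref, alt = rng.choice(_BASES, size=2, replace=False).tolist()
                region = region_names[int(rng.choice(len(region_names), p=region_p))]
                known = frozenset({"dbSNP"}) if rng.random() < config.known_fraction else frozenset()
                flags = (
                    frozenset({str(rng.choice(["QD", "Q20", "badReads", "alleleBias"]))})
                    if rng.random() < config.flagged_fraction
                    else frozenset()
                )
                if rng.random() < config.truncating_unscored_fraction:
                    consequence, cadd = "frameshift", None
                    ref = ref + alt  # represent as a deletion-style allele pair
                    alt = ref[0]
                else:
                    consequence = "missense"
                    if rng.random() < config.cadd_damaging_fraction:
                        cadd = float(np.round(rng.uniform(15.0, 45.0), 3))
                    else:
                        cadd = float(np.round(rng.uniform(0.0, 14.99), 3))
                variants.append(
                    AnnotatedVariant(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        genes=(genes[g_idx],),
                        region_class=region,
                        consequence=consequence,
                        cadd_phred=cadd,
                        known_in=known,
                        caller_filters=flags,
                        carriers=(ids[i_idx],),
                        group=group,
                    )
                )
    return variants, truth


def generate_reference_counts(config: SimulationConfig) -> pd.DataFrame:
    """Per-gene reference counts at the baseline rate (the reference
    population carries no spike): count ~ Poisson(n_reference x
    baseline_rate); the contributing-individual count is uniform in
    [0.8, 1.0] x n_reference to emulate per-gene coverage variation."""
    if config.n_reference <= 0:
        raise ValueError("n_reference must be positive")
    if not np.isfinite(config.baseline_rate):
        raise ValueError("baseline_rate must be finite")
    rng = _rng(config.seed, "reference")
    genes = config.gene_universe()
    counts = rng.poisson(config.n_reference * config.baseline_rate, size=len(genes))
    n_ind = rng.integers(int(0.8 * config.n_reference), config.n_reference + 1, size=len(genes))
    return pd.DataFrame({"gene": genes, "count": counts, "n_individuals": n_ind})


def generate_feature_matrices(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrix, binary annotation matrix and citation table.

    Expression: X = lambda f' + noise with a sparse unit loading f over 8
    columns; the latent factor lambda is N(signal_strength, 1) for training
    positives and N(0, 1) otherwise.  Annotation: a reserved block of terms
    where positives have an elevated Bernoulli rate (0.05 baseline, +0.12 per
    unit signal).  Citations: positives get >=3 topical citations; a reserved
    set of ``n_negative_training`` genes gets 0 topical citations with totals
    above every other gene, so the training-set builder can recover both
    classes exactly."""
    genes = config.gene_universe()
    universe = set(genes)
    for name, gene_set in (
        ("training_positives", truth.training_positives),
        ("risk_genes_restricted", truth.risk_genes_restricted),
        ("risk_genes_binge", truth.risk_genes_binge),
    ):
        if not gene_set <= universe:
            raise ValueError(f"truth {name} outside the gene universe")

    rng = _rng(config.seed, "features")
    n, d = len(genes), config.n_expression_samples
    is_pos = np.array([g in truth.training_positives for g in genes])

    loading = np.zeros(d)
    signal_cols = rng.choice(d, size=min(8, d), replace=False)
    loading[signal_cols] = 1.0 / np.sqrt(len(signal_cols))
    lam = rng.normal(0.0, 1.0, size=n) + config.signal_strength * is_pos
    # residual noise at 0.5 SD: the shared factor dominates the signal
    # columns, as in regional expression profiles with a strong program
    expr = np.outer(lam, loading) + 0.5 * rng.normal(0.0, 1.0, size=(n, d))
    expr_df = pd.DataFrame(
        expr, index=pd.Index(genes, name="gene"), columns=[f"S{j + 1:03d}" for j in range(d)]
    )

    t = config.n_go_terms
    base_p = np.full(t, 0.05)
    p_matrix = np.tile(base_p, (n, 1))
    k = min(config.n_go_signal_terms, t)
    elevated = min(0.95, 0.05 + 0.12 * config.signal_strength)
    p_matrix[np.ix_(is_pos, np.arange(k))] = elevated
    go = (rng.random((n, t)) < p_matrix).astype(np.int8)
    go_df = pd.DataFrame(
        go, index=pd.Index(genes, name="gene"), columns=[f"GO{j + 1:04d}" for j in range(t)]
    )

    rng_c = _rng(config.seed, "citations")
    topical = np.zeros(n, dtype=int)
    total = np.round(rng_c.lognormal(mean=3.0, sigma=1.0, size=n)).astype(int) + 1
    topical[is_pos] = 3 + rng_c.poisson(5.0, size=int(is_pos.sum()))
    neg_pool = np.flatnonzero(~is_pos)
    neg_idx = rng_c.choice(neg_pool, size=config.n_negative_training, replace=False)
    total[neg_idx] = 100000 + rng_c.permutation(len(neg_idx))
    # sprinkle sub-threshold topical citations among remaining genes to
    # exercise the "neither class" branch of the training-set builder
    rest = np.array(sorted(set(range(n)) - set(neg_idx) - set(np.flatnonzero(is_pos))))
    if len(rest):
        topical[rest] = rng_c.choice([0, 1, 2], size=len(rest), p=[0.85, 0.10, 0.05])
    total = np.maximum(total, topical)
    citations = pd.DataFrame({"gene": genes, "topical_citations": topical, "total_citations": total})
    return expr_df, go_df, citations


def generate_network(config: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Weighted undirected edge list (STRING dialect, scores 0-1000).

    Background topology is preferential attachment with ``edge_density``
    edges per incoming node (scores uniform 150-949); training positives
    additionally gain mutual edges with probability ``positive_edge_prob``
    and high confidence (700-999), forming a detectable module.  Edges are
    canonically ordered, deduplicated (max score wins) and self-loop free.
    """
    rng = _rng(config.seed, "network")
    genes = config.gene_universe()
    edges: dict[tuple[str, str], int] = {}

    m = int(config.edge_density)
    if m >= 1 and config.n_genes > m:
        base = nx.barabasi_albert_graph(config.n_genes, m, seed=int(rng.integers(2**31)))
        for u, v in sorted(base.edges()):
            a, b = sorted((genes[u], genes[v]))
            edges[(a, b)] = int(rng.integers(150, 950))

    positives = sorted(truth.training_positives)
    for i, g1 in enumerate(positives):
        for g2 in positives[i + 1:]:
            if rng.random() < config.positive_edge_prob:
                key = tuple(sorted((g1, g2)))
                score = int(rng.integers(700, 1000))
                edges[key] = max(edges.get(key, 0), score)

    rows = [(a, b, s) for (a, b), s in sorted(edges.items())]
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


def generate_all(config: SimulationConfig) -> dict:
    """Generate every synthetic input with a shared truth; keys: variants,
    truth, reference, expression, go, citations, edges."""
    truth = make_truth(config)
    variants, _ = generate_cohort(config, truth)
    expr, go, citations = generate_feature_matrices(config, truth)
    return {
        "variants": variants,
        "truth": truth,
        "reference": generate_reference_counts(config),
        "expression": expr,
        "go": go,
        "citations": citations,
        "edges": generate_network(config, truth),
    }
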