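"""Reduction of annotated cohort variant calls to the novel, predicted-damaging set.

A qualifying variant must lie in a coding-relevant region (exonic, UTR or
splicing), carry none of the caller's low-confidence FILTER flags, be absent
from the configured known-variant databases, and either reach the CADD phred
deleteriousness cutoff or be an unscored protein-altering indel/MNV class that
CADD does not score.  Everything downstream (burden testing, prioritization)
consumes only the variants that survive this reduction.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

REGION_CLASSES = frozenset({"exonic", "UTR", "splicing", "other"})
CONSEQUENCES = frozenset(
    {"missense", "stopgain", "frameshift", "nonframeshift_indel", "synonymous", "other"}
)
GROUPS = ("restricted", "binge")

# ordered rule labels used in FilterDecision.reasons and the audit log
RULE_REGION = "region"
RULE_CALLER_FILTER = "caller_filter"
RULE_KNOWN = "known_variant"
RULE_CADD_BELOW = "cadd_below_threshold"
RULE_CADD_MISSING = "cadd_missing"
RULE_ORDER = (RULE_REGION, RULE_CALLER_FILTER, RULE_KNOWN, RULE_CADD_BELOW, RULE_CADD_MISSING)


@dataclass(frozen=True)
class AnnotatedVariant:
    """One cohort variant call with its annotations and carrier list.

    Coordinates are 1-based inclusive (VCF convention).  ``genes`` may list
    several overlapping symbols; burden counting assigns the variant once per
    gene.  ``carriers`` holds the distinct sample IDs carrying the alternate
    allele; all carriers of a record belong to the phenotype ``group``.
    ``cadd_phred`` is ``None`` for records the scorer does not cover
    (typically multi-nucleotide substitutions and indels).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genes: tuple[str, ...]
    region_class: str | None
    consequence: str = "missense"
    cadd_phred: float | None = None
    known_in: frozenset[str] = frozenset()
    caller_filters: frozenset[str] = frozenset()
    carriers: tuple[str, ...] = ()
    group: str = "restricted"
    rs_id: str | None = None
    exac_maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.genes:
            raise ValueError("variant must be annotated to at least one gene")
        if not self.carriers:
            raise ValueError("variant must have at least one carrier")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        # normalise collection fields so records hash/compare reliably
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "known_in", frozenset(self.known_in))
        object.__setattr__(self, "caller_filters", frozenset(self.caller_filters))
        object.__setattr__(self, "carriers", tuple(self.carriers))


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and label sets for the novelty/damage filter.

    ``cadd_threshold`` 15 is the conventional predicted-damaging cutoff on the
    phred scale.  ``unscored_keep_consequences`` lists the consequence classes
    retained when CADD is missing: truncating classes plus length-preserving
    MNVs/in-frame indels, which the scorer leaves unscored but which are
    protein-altering and cannot be excluded on score.
    """

    cadd_threshold: float = 15.0
    filter_blacklist: frozenset[str] = frozenset({"QD", "Q20", "badReads", "alleleBias"})
    allowed_regions: frozenset[str] = frozenset({"exonic", "UTR", "splicing"})
    known_databases: frozenset[str] = frozenset({"1000G", "dbSNP", "EVS"})
    keep_unscored_truncating: bool = True
    unscored_keep_consequences: frozenset[str] = frozenset(
        {"stopgain", "frameshift", "nonframeshift_indel"}
    )

    def __post_init__(self) -> None:
        if self.cadd_threshold < 0:
            raise ValueError("cadd_threshold must be >= 0")
        object.__setattr__(self, "filter_blacklist", frozenset(self.filter_blacklist))
        object.__setattr__(self, "allowed_regions", frozenset(self.allowed_regions))
        object.__setattr__(self, "known_databases", frozenset(self.known_databases))
        object.__setattr__(
            self, "unscored_keep_consequences", frozenset(self.unscored_keep_consequences)
        )


@dataclass(frozen=True)
class FilterDecision:
    kept: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must be equivalent to an empty reason list")


def classify_variant(v: AnnotatedVariant, cfg: FilterConfig | None = None) -> FilterDecision:
    """Decide whether one variant qualifies, enumerating every failed rule.

    Raises ``ValueError`` when ``region_class`` is missing (incomplete
    annotation) — region membership is the first gate and cannot be skipped.
    """
    cfg = cfg or FilterConfig()
    if v.region_class is None:
        raise ValueError(f"variant {v.chrom}:{v.pos} has no region_class annotation")
    if v.region_class not in REGION_CLASSES:
        raise ValueError(f"unknown region_class {v.region_class!r}")

    reasons: list[str] = []
    if v.region_class not in cfg.allowed_regions:
        reasons.append(RULE_REGION)
    if v.caller_filters & cfg.filter_blacklist:
        reasons.append(RULE_CALLER_FILTER)
    if v.known_in & cfg.known_databases:
        reasons.append(RULE_KNOWN)
    if v.cadd_phred is not None:
        if v.cadd_phred < cfg.cadd_threshold:
            reasons.append(RULE_CADD_BELOW)
    else:
        keep_unscored = (
            cfg.keep_unscored_truncating and v.consequence in cfg.unscored_keep_consequences
        )
        if not keep_unscored:
            reasons.append(RULE_CADD_MISSING)
    return FilterDecision(kept=not reasons, reasons=tuple(reasons))


@dataclass
class FilterResult:
    """Kept variants, per-(gene, group) counts and the filter audit log."""

    kept: list[AnnotatedVariant]
    counts: pd.DataFrame  # columns: gene, group, n_variants, n_carrier_events
    audit: dict


def filter_cohort(
    variants: Iterable[AnnotatedVariant], cfg: FilterConfig | None = None
) -> FilterResult:
    """Apply :func:`classify_variant` to a cohort and tabulate per-gene counts.

    The burden count unit is variant-carrier events: a kept variant carried by
    k individuals contributes k to each gene it is annotated to.  Variants
    annotated to multiple genes are counted once per gene and tallied in the
    audit log.  ``audit`` reconciles: n_input = n_kept + n_dropped, with
    per-rule drop counts (a variant failing several rules increments each).
    """
    cfg = cfg or FilterConfig()
    kept: list[AnnotatedVariant] = []
    rule_counts: collections.Counter[str] = collections.Counter()
    n_input = n_dropped = multi_gene = 0
    tallies: dict[tuple[str, str], list[int]] = {}

    for v in variants:
        n_input += 1
        decision = classify_variant(v, cfg)
        if not decision.kept:
            n_dropped += 1
            rule_counts.update(decision.reasons)
            continue
        kept.append(v)
        if len(v.genes) > 1:
            multi_gene += 1
        for gene in v.genes:
            slot = tallies.setdefault((gene, v.group), [0, 0])
            slot[0] += 1
            slot[1] += len(v.carriers)

    counts = pd.DataFrame(
        [
            {"gene": g, "group": grp, "n_variants": nv, "n_carrier_events": nc}
            for (g, grp), (nv, nc) in sorted(tallies.items())
        ],
        columns=["gene", "group", "n_variants", "n_carrier_events"],
    )
    audit = {
        "n_input": n_input,
        "n_kept": len(kept),
        "n_dropped": n_dropped,
        "dropped_by_rule": {rule: rule_counts.get(rule, 0) for rule in RULE_ORDER},
        "multi_gene_kept": multi_gene,
    }
    return FilterResult(kept=kept, counts=counts, audit=audit)


def count_pathway_carriers(
    kept: Iterable[AnnotatedVariant], gene_set: Iterable[str], group: str
) -> int:
    """Number of distinct individuals in ``group`` carrying >=1 kept variant
    in any gene of ``gene_set``."""
    genes = set(gene_set)
    if not genes:
        raise ValueError("gene_set must be non-empty")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    carriers: set[str] = set()
    for v in kept:
        if v.group == group and genes.intersection(v.genes):
            carriers.update(v.carriers)
    return len(carriers)
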