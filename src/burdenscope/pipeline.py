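"""End-to-end orchestration: simulate -> filter -> burden -> evidence ->
enrichment -> network, under a single seeded configuration, with a manifest
sufficient to reproduce the run.

The enrichment stage quantifies the overlap between burden-significant genes
and the literature-anchored training positives with an exact hypergeometric
(Fisher) test over a stated gene universe — by default every gene with at
least one tested cohort variant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as bio
from .burden import BurdenResult, run_burden
from .evidence import build_training_set, combine_evidence, score_genes
from .filtering import FilterConfig, FilterResult, filter_cohort
from .fixtures import FIXTURE_GROUP_SIZES, load_table1_fixture  # noqa: F401  (re-export)
from .network import annotate_and_export, extract_module, load_edges
from .synthetic import SimulationConfig, generate_all

__all__ = [
    "EnrichmentResult", "PipelineConfig", "RunManifest",
    "overlap_enrichment", "run_all", "run_from_manifest", "load_table1_fixture",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 overlap of burden hits with known positives over a gene universe.

    Cell convention: a = hit & positive, b = hit & non-positive,
    c = non-hit & positive, d = non-hit & non-positive;
    odds_ratio = (a*d)/(b*c), reported as inf (flagged degenerate) when a
    zero cell makes the ratio undefined.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    universe_size: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "table": [list(r) for r in self.table],
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "universe_size": self.universe_size,
            "degenerate": self.degenerate,
        }


def overlap_enrichment(
    hits: Iterable[str], positives: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """Exact two-sided test of hit/positive association on the
    hypergeometric null, with the sample odds ratio."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    hits = set(hits)
    positives = set(positives)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if not positives <= universe:
        raise ValueError("positives must be a subset of the universe")

    a = len(hits & positives)
    b = len(hits - positives)
    c = len(positives - hits)
    d = len(universe) - a - b - c
    degenerate = (b * c == 0) or (a * d == 0)
    if b * c == 0:
        odds_ratio = float("inf") if a * d > 0 else float("nan")
    else:
        odds_ratio = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        table=((a, b), (c, d)),
        odds_ratio=odds_ratio,
        p_value=float(p),
        universe_size=len(universe),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """One document configuring every stage, serializable to YAML."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    fdr_threshold: float = 0.1
    burden_method: str = "chisq"
    pool_groups: bool = False
    n_trees: int = 100
    min_topical_citations: int = 3
    edge_threshold: int = 700
    include_all_positives: bool = False
    make_figure: bool = True

    def to_dict(self) -> dict:
        d = {
            "sim": self.sim.to_dict(),
            "filter": {
                "cadd_threshold": self.filter.cadd_threshold,
                "filter_blacklist": sorted(self.filter.filter_blacklist),
                "allowed_regions": sorted(self.filter.allowed_regions),
                "known_databases": sorted(self.filter.known_databases),
                "keep_unscored_truncating": self.filter.keep_unscored_truncating,
                "unscored_keep_consequences": sorted(self.filter.unscored_keep_consequences),
            },
        }
        for name in (
            "fdr_threshold", "burden_method", "pool_groups", "n_trees",
            "min_topical_citations", "edge_threshold", "include_all_positives",
            "make_figure",
        ):
            d[name] = getattr(self, name)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim = SimulationConfig.from_dict(d.pop("sim", {}))
        fd = d.pop("filter", {})
        for key in ("filter_blacklist", "allowed_regions", "known_databases",
                    "unscored_keep_consequences"):
            if key in fd:
                fd[key] = frozenset(fd[key])
        return cls(sim=sim, filter=FilterConfig(**fd), **d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list[dict]
    digests: dict[str, str]
    outdir: str
    summary: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir: str) -> RunManifest:
    """Execute every stage on a synthetic dataset and write all artifacts.

    Artifacts are plain TSV/JSON/VCF/GraphML (plus one PNG figure).  The
    manifest records the config snapshot, seed, per-stage status and a
    sha256 digest of every written file; a failed stage leaves earlier
    outputs in place and the manifest marks the failure point.
    """
    from . import __version__

    os.makedirs(outdir, exist_ok=True)
    stages: list[dict] = []
    paths: dict[str, str] = {}
    summary: dict = {}

    def artifact(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    def finish(status_error: str | None = None) -> RunManifest:
        digests = {name: _sha256(p) for name, p in sorted(paths.items()) if os.path.exists(p)}
        manifest = RunManifest(
            config=config.to_dict(),
            seed=config.sim.seed,
            version=__version__,
            stages=stages,
            digests=digests,
            outdir=outdir,
            summary=summary,
        )
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        if status_error is not None:
            raise RuntimeError(status_error)
        return manifest

    try:
        # -- simulate -----------------------------------------------------
        data = generate_all(config.sim)
        truth = data["truth"]
        bio.write_variants_tsv(data["variants"], artifact("variants.tsv"))
        samples = config.sim.sample_ids()
        bio.write_variants_vcf(
            data["variants"], artifact("variants.vcf"),
            sample_ids=samples["restricted"] + samples["binge"],
        )
        bio.write_table(data["reference"], artifact("reference.tsv"))
        bio.write_matrix(data["expression"], artifact("expression.tsv"))
        bio.write_matrix(data["go"], artifact("go.tsv"))
        bio.write_table(data["citations"], artifact("citations.tsv"))
        bio.write_table(data["edges"], artifact("edges.tsv"))
        bio.write_truth(truth, artifact("truth.json"))
        stages.append({"stage": "simulate", "status": "ok", "n_variants": len(data["variants"])})

        # -- filter -------------------------------------------------------
        filtered = filter_cohort(data["variants"], config.filter)
        bio.write_variants_tsv(filtered.kept, artifact("kept_variants.tsv"))
        bio.write_table(filtered.counts, artifact("counts.tsv"))
        with open(artifact("filter_audit.json"), "w") as fh:
            json.dump(filtered.audit, fh, indent=2, sort_keys=True)
            fh.write("\n")
        stages.append({"stage": "filter", "status": "ok", **filtered.audit})

        # -- burden -------------------------------------------------------
        group_sizes = {"restricted": config.sim.n_restricted, "binge": config.sim.n_binge}
        burden = run_burden(
            filtered.counts, data["reference"], group_sizes=group_sizes,
            fdr_threshold=config.fdr_threshold, method=config.burden_method,
            pool_groups=config.pool_groups,
        )
        bio.write_table(burden.table, artifact("burden.tsv"))
        for grp in ("restricted", "binge"):
            bio.write_gene_list(burden.significant.get(grp, set()),
                                artifact(f"significant_{grp}.txt"))
        bio.write_gene_list(burden.significant["union"], artifact("significant_union.txt"))
        stages.append({
            "stage": "burden", "status": "ok",
            "n_tested": int(len(burden.table)),
            "n_significant_union": len(burden.significant["union"]),
        })

        # -- evidence -----------------------------------------------------
        training = build_training_set(
            data["citations"], min_topical=config.min_topical_citations,
            n_negatives=config.sim.n_negative_training,
        )
        expr_scores = score_genes(
            data["expression"], training, n_trees=config.n_trees, seed=config.sim.seed,
        )
        go_scores = score_genes(
            data["go"], training, n_trees=config.n_trees, seed=config.sim.seed + 1,
        )
        evidence = combine_evidence(expr_scores, go_scores)
        bio.write_table(evidence, artifact("evidence.tsv"))
        stages.append({"stage": "evidence", "status": "ok",
                       "n_training_positives": len(training.positives)})

        # -- enrichment ---------------------------------------------------
        universe = set(burden.table["gene"])
        hits = burden.significant["union"] & universe
        positives_in_universe = set(training.positives) & universe
        if universe:
            enrichment = overlap_enrichment(hits, positives_in_universe, universe)
            with open(artifact("enrichment.json"), "w") as fh:
                json.dump(enrichment.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            summary["enrichment_odds_ratio"] = enrichment.odds_ratio
            summary["enrichment_p_value"] = enrichment.p_value
        stages.append({"stage": "enrichment", "status": "ok"})

        # -- network ------------------------------------------------------
        graph = load_edges(paths["edges.tsv"], score_threshold=config.edge_threshold)
        module = extract_module(
            graph, burden.significant["union"], training.positives,
            include_all_positives=config.include_all_positives,
        )
        group_of = {}
        for row in burden.table.itertuples(index=False):
            group_of[row.gene] = "both" if group_of.get(row.gene) not in (None, row.group) \
                else row.group
        module_paths = annotate_and_export(
            module, evidence, outdir, groups=group_of,
            basename="module", figure=config.make_figure,
        )
        for key, p in module_paths.items():
            paths[os.path.basename(p)] = p
        stages.append({"stage": "network", "status": "ok", "module_size": len(module)})

        # -- summary vs ground truth -------------------------------------
        spiked = {"restricted": truth.risk_genes_restricted, "binge": truth.risk_genes_binge}
        for grp, spike_set in spiked.items():
            called = burden.significant.get(grp, set())
            recall = len(called & spike_set) / len(spike_set) if spike_set else float("nan")
            false_calls = len(called - spike_set)
            summary[f"spiked_recall_{grp}"] = recall
            summary[f"false_discoveries_{grp}"] = false_calls
            summary[f"fdp_{grp}"] = false_calls / max(len(called), 1)
        summary["module_size"] = len(module)
        with open(artifact("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:  # record the failure point, then re-raise
        stages.append({"stage": "failed", "status": f"error: {exc}"})
        finish(status_error=str(exc))
    return finish()


def run_from_manifest(manifest_path: str, outdir: str) -> RunManifest:
    """Re-execute a recorded run; with the same config and seed the text
    artifacts are reproduced byte-identically."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = PipelineConfig.from_dict(manifest["config"])
    return run_all(config, outdir)
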