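"""Generator contracts: determinism, rate calibration, ground-truth recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from burdenscope import (
    SimulationConfig,
    build_training_set,
    generate_cohort,
    generate_feature_matrices,
    generate_network,
    generate_reference_counts,
    make_truth,
)


def cohort_counts_by_gene(variants):
    counts = {}
    for v in variants:
        for g in v.genes:
            counts[g] = counts.get(g, 0) + len(v.carriers)
    return counts


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes=0),
            dict(baseline_rate=-0.1),
            dict(baseline_rate=float("nan")),
            dict(rate_multiplier=0.5),
            dict(risk_gene_fraction=0.0),
            dict(n_reference=0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestCohort:
    def test_deterministic_under_seed(self, small_config):
        v1, t1 = generate_cohort(small_config)
        v2, t2 = generate_cohort(small_config)
        assert t1 == t2
        assert v1 == v2

    def test_seed_changes_output(self, small_config):
        v1, _ = generate_cohort(small_config)
        import dataclasses
        other = dataclasses.replace(small_config, seed=99)
        v2, _ = generate_cohort(other)
        assert v1 != v2

    def test_zero_rate_emits_nothing(self):
        cfg = SimulationConfig(n_genes=50, baseline_rate=0.0, seed=1,
                               n_positive_training=10, n_negative_training=20)
        variants, _ = generate_cohort(cfg)
        assert variants == []
        ref = generate_reference_counts(cfg)
        assert (ref["count"] == 0).all()

    def test_risk_gene_rate_elevation_matches_poisson_means(self):
        """Mean count in risk genes ~ multiplier x non-risk mean, against
        the analytic Poisson means implied by the generator's own rates."""
        cfg = SimulationConfig(
            n_genes=500, baseline_rate=5e-4, rate_multiplier=25.0,
            risk_gene_fraction=0.02, seed=7,
            n_positive_training=50, n_negative_training=100,
            known_fraction=0.0, flagged_fraction=0.0,
            truncating_unscored_fraction=0.0,
        )
        # aggregate over seeds: per-seed risk-gene counts are small
        risk_tot = nonrisk_tot = n_risk = n_nonrisk = 0
        for seed in range(15):
            c = dataclasses.replace(cfg, seed=seed)
            variants, truth = generate_cohort(c)
            counts = cohort_counts_by_gene(variants)
            restricted_counts = {}
            for v in variants:
                if v.group == "restricted":
                    for g in v.genes:
                        restricted_counts[g] = restricted_counts.get(g, 0) + 1
            risk = truth.risk_genes_restricted
            genes = c.gene_universe()
            for g in genes:
                x = restricted_counts.get(g, 0)
                if g in risk:
                    risk_tot += x
                    n_risk += 1
                else:
                    nonrisk_tot += x
                    n_nonrisk += 1
        lam_nonrisk = cfg.n_restricted * cfg.baseline_rate
        lam_risk = lam_nonrisk * cfg.rate_multiplier
        # 3-sigma bands around the analytic Poisson means
        se_risk = np.sqrt(lam_risk / n_risk)
        se_nonrisk = np.sqrt(lam_nonrisk / n_nonrisk)
        assert risk_tot / n_risk == pytest.approx(lam_risk, abs=3 * se_risk)
        assert nonrisk_tot / n_nonrisk == pytest.approx(lam_nonrisk, abs=3 * se_nonrisk)

    def test_null_config_risk_and_nonrisk_indistinguishable(self):
        """With no spike, rank tests on per-gene counts stay null across seeds."""
        pvals = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_genes=150, baseline_rate=0.05, rate_multiplier=1.0, seed=seed,
                n_positive_training=20, n_negative_training=40,
            )
            variants, truth = generate_cohort(cfg)
            counts = cohort_counts_by_gene(variants)
            risk = truth.risk_genes_restricted | truth.risk_genes_binge
            x_risk = [counts.get(g, 0) for g in cfg.gene_universe() if g in risk]
            x_non = [counts.get(g, 0) for g in cfg.gene_universe() if g not in risk]
            pvals.append(stats.mannwhitneyu(x_risk, x_non).pvalue)
        # at alpha=0.01 over 20 null seeds, >=2 rejections has p < 2e-2
        assert sum(p < 0.01 for p in pvals) <= 1

    def test_annotation_mixtures(self):
        cfg = SimulationConfig(n_genes=400, baseline_rate=0.05, seed=5,
                               n_positive_training=40, n_negative_training=100)
        variants, _ = generate_cohort(cfg)
        n = len(variants)
        assert n > 1500
        known = sum(bool(v.known_in) for v in variants) / n
        flagged = sum(bool(v.caller_filters) for v in variants) / n
        scored = [v for v in variants if v.cadd_phred is not None]
        damaging = sum(v.cadd_phred >= 15 for v in scored) / len(scored)
        assert known == pytest.approx(0.30, abs=0.03)
        assert flagged == pytest.approx(0.05, abs=0.02)
        assert damaging == pytest.approx(0.80, abs=0.03)

    def test_gene_aliases(self):
        cfg = SimulationConfig(n_genes=50, gene_aliases=("NTS", "GCG"), seed=0,
                               n_positive_training=10, n_negative_training=20)
        universe = cfg.gene_universe()
        assert universe[:2] == ["NTS", "GCG"] and universe[2] == "G000003"


class TestReferenceCounts:
    def test_deterministic(self, small_config):
        assert generate_reference_counts(small_config).equals(
            generate_reference_counts(small_config)
        )

    def test_poisson_mean_matches_baseline(self):
        cfg = SimulationConfig(n_genes=2000, baseline_rate=5e-4, seed=2)
        ref = generate_reference_counts(cfg)
        est = ref["count"].mean() / cfg.n_reference
        se = np.sqrt(cfg.baseline_rate / (cfg.n_reference * len(ref)))
        assert est == pytest.approx(cfg.baseline_rate, abs=3 * se)

    def test_contributing_individuals_bounded(self, small_config):
        ref = generate_reference_counts(small_config)
        assert (ref["n_individuals"] <= small_config.n_reference).all()
        assert (ref["n_individuals"] >= 0.8 * small_config.n_reference).all()


class TestFeatureMatrices:
    def test_shapes_and_domains(self, small_config, small_truth):
        expr, go, citations = generate_feature_matrices(small_config, small_truth)
        assert expr.shape == (small_config.n_genes, small_config.n_expression_samples)
        assert go.shape == (small_config.n_genes, small_config.n_go_terms)
        assert set(np.unique(go.to_numpy())) <= {0, 1}
        assert len(citations) == small_config.n_genes

    def test_citation_table_recovers_truth_exactly(self, small_config, small_truth):
        _, _, citations = generate_feature_matrices(small_config, small_truth)
        ts = build_training_set(
            citations, n_negatives=small_config.n_negative_training
        )
        assert ts.positives == small_truth.training_positives
        assert len(ts.negatives) == small_config.n_negative_training
        assert not (ts.negatives & small_truth.training_positives)

    def test_truth_outside_universe_rejected(self, small_config, small_truth):
        import dataclasses
        bad = dataclasses.replace(
            small_truth, training_positives=frozenset({"NOT_A_GENE"})
        )
        with pytest.raises(ValueError, match="outside the gene universe"):
            generate_feature_matrices(small_config, bad)


class TestNetwork:
    def test_canonical_dedup_no_self_loops(self, small_config, small_truth):
        edges = generate_network(small_config, small_truth)
        assert (edges["protein1"] < edges["protein2"]).all()
        pairs = list(zip(edges["protein1"], edges["protein2"]))
        assert len(pairs) == len(set(pairs))
        assert edges["combined_score"].between(0, 1000).all()

    def test_positive_edge_rate_exceeds_background(self, small_config, small_truth):
        edges = generate_network(small_config, small_truth)
        pos = small_truth.training_positives
        n_pos = len(pos)
        n_all = small_config.n_genes
        pos_edges = sum(
            (a in pos) and (b in pos)
            for a, b in zip(edges["protein1"], edges["protein2"])
        )
        pos_rate = pos_edges / (n_pos * (n_pos - 1) / 2)
        bg_rate = len(edges) / (n_all * (n_all - 1) / 2)
        assert pos_rate > 2 * bg_rate

    def test_zero_density_leaves_positive_clique_only(self, small_config, small_truth):
        import dataclasses
        cfg = dataclasses.replace(small_config, edge_density=0.0, positive_edge_prob=1.0)
        edges = generate_network(cfg, small_truth)
        nodes = set(edges["protein1"]) | set(edges["protein2"])
        assert nodes == set(small_truth.training_positives)
        n = len(small_truth.training_positives)
        assert len(edges) == n * (n - 1) // 2
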