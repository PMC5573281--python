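"""Evidence scores: training-set construction, vote proportions, OOB audit."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from burdenscope import (
    SimulationConfig,
    TrainingSet,
    build_training_set,
    combine_evidence,
    generate_feature_matrices,
    make_truth,
    score_genes,
)


def citation_table(rows):
    return pd.DataFrame(rows, columns=["gene", "topical_citations", "total_citations"])


class TestBuildTrainingSet:
    def test_topical_threshold_is_inclusive(self):
        table = citation_table([("A", 3, 10), ("B", 2, 10), ("C", 0, 500), ("D", 0, 400)])
        ts = build_training_set(table, n_negatives=2)
        assert "A" in ts.positives
        # two topical citations: in neither class
        assert "B" not in ts.positives and "B" not in ts.negatives
        assert ts.negatives == {"C", "D"}

    def test_negatives_are_most_cited_zero_topical(self):
        table = citation_table(
            [("P", 5, 1), ("N1", 0, 900), ("N2", 0, 800), ("N3", 0, 700), ("X", 1, 999999)]
        )
        ts = build_training_set(table, n_negatives=2)
        assert ts.negatives == {"N1", "N2"}  # X has a topical citation

    def test_tie_break_lexicographic(self):
        table = citation_table([("P", 3, 1), ("B", 0, 100), ("A", 0, 100), ("C", 0, 100)])
        ts = build_training_set(table, n_negatives=2)
        assert ts.negatives == {"A", "B"}

    def test_too_few_negatives_error_reports_count(self):
        table = citation_table([("P", 3, 1), ("N1", 0, 10)])
        with pytest.raises(ValueError, match="only 1 genes"):
            build_training_set(table, n_negatives=5)

    def test_overlapping_classes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TrainingSet(positives=frozenset("AB"), negatives=frozenset("BC"))


@pytest.fixture(scope="module")
def strong_signal():
    cfg = SimulationConfig(
        n_genes=600, n_positive_training=80, n_negative_training=200,
        signal_strength=3.0, seed=42,
    )
    truth = make_truth(cfg)
    expr, go, citations = generate_feature_matrices(cfg, truth)
    ts = build_training_set(citations, n_negatives=cfg.n_negative_training)
    return cfg, truth, expr, go, ts


class TestScoreGenes:
    def test_scores_in_unit_interval_and_deterministic(self, strong_signal):
        _, _, expr, _, ts = strong_signal
        r1 = score_genes(expr, ts, seed=5)
        r2 = score_genes(expr, ts, seed=5)
        assert r1.scores.between(0, 1).all()
        assert r1.scores.equals(r2.scores)
        r3 = score_genes(expr, ts, seed=6)
        assert not r1.scores.equals(r3.scores)

    def test_missing_training_gene_named(self, strong_signal):
        _, _, expr, _, ts = strong_signal
        with pytest.raises(KeyError, match="absent from feature matrix"):
            score_genes(expr.drop(index=sorted(ts.positives)[0]), ts)

    def test_duplicated_nontraining_rows_score_identically(self, strong_signal):
        _, _, expr, _, ts = strong_signal
        nontrain = [g for g in expr.index if g not in ts.positives | ts.negatives]
        dup = expr.copy()
        dup.loc[nontrain[0]] = dup.loc[nontrain[1]]
        result = score_genes(dup, ts, seed=0)
        assert result.scores[nontrain[0]] == result.scores[nontrain[1]]

    def test_training_genes_scored_out_of_bag(self, strong_signal):
        """Every training gene's score must come only from trees whose
        bootstrap sample excluded it (verified from the ensemble trace)."""
        _, _, expr, _, ts = strong_signal
        small = TrainingSet(
            positives=frozenset(sorted(ts.positives)[:15]),
            negatives=frozenset(sorted(ts.negatives)[:15]),
        )
        result = score_genes(expr, small, n_trees=25, seed=1, keep_trace=True)
        votes = {}
        counts = {}
        for boot, oob in zip(result.trace["bootstrap"], result.trace["oob_votes_by_tree"]):
            for gene, vote in oob.items():
                assert gene not in boot  # OOB means not bootstrapped into this tree
                votes[gene] = votes.get(gene, 0) + vote
                counts[gene] = counts.get(gene, 0) + 1
        for gene in small.positives | small.negatives:
            assert counts.get(gene, 0) == result.oob_counts[gene]
            if counts.get(gene):
                assert result.scores[gene] == pytest.approx(votes.get(gene, 0) / counts[gene])

    def test_separable_features_auc_above_09(self, strong_signal):
        """Held-out AUC > 0.9 under strong signal, for both evidence forms."""
        _, _, expr, go, ts = strong_signal
        for features in (expr, go):
            pos, neg = sorted(ts.positives), sorted(ts.negatives)
            train = TrainingSet(frozenset(pos[: len(pos) // 2]), frozenset(neg[: len(neg) // 2]))
            held = pos[len(pos) // 2:] + neg[len(neg) // 2:]
            labels = [1] * (len(pos) - len(pos) // 2) + [0] * (len(neg) - len(neg) // 2)
            result = score_genes(features, train, seed=2)
            auc = roc_auc_score(labels, result.scores[held])
            assert auc > 0.9

    def test_no_signal_auc_near_half(self):
        """With signal 0 the classes are exchangeable: held-out AUC ~ 0.5."""
        aucs = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_genes=400, n_positive_training=60, n_negative_training=140,
                signal_strength=0.0, seed=seed,
            )
            truth = make_truth(cfg)
            expr, _, citations = generate_feature_matrices(cfg, truth)
            ts = build_training_set(citations, n_negatives=cfg.n_negative_training)
            pos, neg = sorted(ts.positives), sorted(ts.negatives)
            train = TrainingSet(frozenset(pos[:30]), frozenset(neg[:70]))
            held = pos[30:] + neg[70:]
            labels = [1] * len(pos[30:]) + [0] * len(neg[70:])
            result = score_genes(expr, train, seed=seed)
            aucs.append(roc_auc_score(labels, result.scores[held]))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_label_permutation_destroys_separation(self, strong_signal):
        _, _, expr, _, ts = strong_signal
        result = score_genes(expr, ts, seed=3)
        sep = result.scores[sorted(ts.positives)].mean() - result.scores[sorted(ts.negatives)].mean()
        assert sep > 0.5

        rng = np.random.default_rng(0)
        pool = sorted(ts.positives | ts.negatives)
        shuffled = rng.permutation(pool)
        permuted = TrainingSet(
            positives=frozenset(shuffled[: len(ts.positives)]),
            negatives=frozenset(shuffled[len(ts.positives):]),
        )
        presult = score_genes(expr, permuted, seed=3)
        psep = (
            presult.scores[sorted(ts.positives & set(pool))].mean()
            - presult.scores[sorted(ts.negatives & set(pool))].mean()
        )
        assert abs(psep) < 0.1

    def test_median_imputation_flagged(self, strong_signal):
        _, _, expr, _, ts = strong_signal
        holed = expr.copy()
        holed.iloc[0, 0] = np.nan
        result = score_genes(holed, ts, seed=0)
        assert result.imputed_columns == (str(expr.columns[0]),)


class TestCombineEvidence:
    def series(self, mapping):
        return pd.Series(mapping, dtype=float)

    def test_combined_is_elementwise_max(self):
        out = combine_evidence(
            self.series({"A": 0.2, "B": 0.5}), self.series({"A": 0.8, "B": 0.5})
        ).set_index("gene")
        assert out.loc["A", "combined_score"] == 0.8
        assert out.loc["B", "combined_score"] == 0.5

    def test_missing_one_score_flagged_and_carried(self):
        out = combine_evidence(
            self.series({"A": 0.7}), self.series({"A": 0.1, "B": 0.4})
        ).set_index("gene")
        assert out.loc["B", "combined_score"] == 0.4
        assert bool(out.loc["B", "expression_missing"])
        assert not bool(out.loc["A", "expression_missing"])

    def test_training_flags_propagate(self, strong_signal):
        _, _, expr, go, ts = strong_signal
        e = score_genes(expr, ts, seed=0)
        g = score_genes(go, ts, seed=1)
        out = combine_evidence(e, g).set_index("gene")
        some_pos = sorted(ts.positives)[0]
        assert bool(out.loc[some_pos, "is_training"]) and bool(out.loc[some_pos, "oob"])
        assert out["combined_score"].between(0, 1).all()
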