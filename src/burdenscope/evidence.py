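"""Literature-anchored training sets and per-gene evidence scores.

Candidate genes are prioritized by how similar they look to genes already
tied to the phenotype in the literature.  The positive training class is
"genes with >= 3 topical citations"; the negative class is the most highly
cited genes never cited topically.  For each evidence form (an expression
matrix, a binary functional-annotation matrix) a bagged ensemble of 100
decision trees is fitted to discriminate the classes, and the per-gene score
is the fraction of trees voting for the positive class — for training genes,
the out-of-bag (OOB) vote fraction, so no gene is scored by a tree that saw
it.  The two evidence scores are combined by taking the elementwise maximum.

The bagging loop is implemented here (bootstrap per tree over sklearn
decision trees, ``max_features="sqrt"``) rather than via an off-the-shelf
forest, because the scores are defined as vote proportions and the OOB
bookkeeping must be auditable per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier


@dataclass(frozen=True)
class TrainingSet:
    positives: frozenset[str]
    negatives: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.positives or not self.negatives:
            raise ValueError("both training classes must be non-empty")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"training classes overlap: {sorted(overlap)[:5]}")


def build_training_set(
    citations: pd.DataFrame, min_topical: int = 3, n_negatives: int = 1000
) -> TrainingSet:
    """Positives: topical_citations >= min_topical.  Negatives: the
    ``n_negatives`` most-cited genes (by total_citations) among those with
    zero topical citations; ties broken lexicographically by gene symbol."""
    for col in ("gene", "topical_citations", "total_citations"):
        if col not in citations.columns:
            raise ValueError(f"citation table missing column {col!r}")
    if not len(citations):
        raise ValueError("citation table is empty")

    positives = frozenset(citations.loc[citations["topical_citations"] >= min_topical, "gene"])
    eligible = citations.loc[citations["topical_citations"] == 0]
    if len(eligible) < n_negatives:
        raise ValueError(
            f"only {len(eligible)} genes have zero topical citations; "
            f"{n_negatives} negatives requested"
        )
    ranked = eligible.sort_values(
        ["total_citations", "gene"], ascending=[False, True], kind="mergesort"
    )
    negatives = frozenset(ranked["gene"].head(n_negatives))
    provenance = (
        f"positives: topical_citations >= {min_topical}; "
        f"negatives: top {n_negatives} by total_citations with 0 topical citations"
    )
    return TrainingSet(positives=positives, negatives=negatives, provenance=provenance)


@dataclass
class GeneScores:
    """Vote-proportion scores for one evidence form.

    ``scores`` covers every gene in the feature matrix; ``is_training`` marks
    genes whose score came from out-of-bag votes; ``oob_counts`` is the
    number of trees contributing to each training gene's score.  ``trace``
    (optional) holds per-tree bootstrap membership for audit.
    """

    scores: pd.Series
    is_training: pd.Series
    oob_counts: pd.Series
    n_trees: int
    seed: int
    imputed_columns: tuple[str, ...] = ()
    trace: dict | None = None


def score_genes(
    features: pd.DataFrame,
    training_set: TrainingSet,
    n_trees: int = 100,
    seed: int = 0,
    class_weight: str | Mapping | None = None,
    keep_trace: bool = False,
) -> GeneScores:
    """Score every gene in ``features`` as a bagged-ensemble vote proportion.

    Non-training genes are scored by all trees; training genes only by trees
    whose bootstrap sample excluded them (OOB).  Missing feature values are
    median-imputed per column and the affected columns are reported.
    Deterministic for a fixed seed.
    """
    if features.shape[1] < 1:
        raise ValueError("feature matrix needs at least one column")
    index = features.index
    missing = [g for g in (training_set.positives | training_set.negatives) if g not in index]
    if missing:
        raise KeyError(f"training genes absent from feature matrix: {sorted(missing)[:10]}")

    X = features.to_numpy(dtype=float)
    imputed: list[str] = []
    if np.isnan(X).any():
        medians = np.nanmedian(X, axis=0)
        medians = np.where(np.isnan(medians), 0.0, medians)
        for j in np.flatnonzero(np.isnan(X).any(axis=0)):
            imputed.append(str(features.columns[j]))
            col = X[:, j]
            col[np.isnan(col)] = medians[j]

    pos_mask = index.isin(training_set.positives)
    neg_mask = index.isin(training_set.negatives)
    train_mask = pos_mask | neg_mask
    train_idx = np.flatnonzero(train_mask)
    y_train = pos_mask[train_idx].astype(int)
    X_train = X[train_idx]
    n_train = len(train_idx)

    rng = np.random.default_rng(seed)
    votes = np.zeros(len(index))
    oob_votes = np.zeros(n_train)
    oob_counts = np.zeros(n_train, dtype=int)
    trace: dict | None = {"bootstrap": [], "oob_votes_by_tree": []} if keep_trace else None

    nontrain_idx = np.flatnonzero(~train_mask)
    for _ in range(n_trees):
        boot = rng.integers(0, n_train, size=n_train)
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            class_weight=class_weight,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X_train[boot], y_train[boot])
        if len(nontrain_idx):
            votes[nontrain_idx] += tree.predict(X[nontrain_idx])
        oob_mask = np.ones(n_train, dtype=bool)
        oob_mask[boot] = False
        if oob_mask.any():
            preds = tree.predict(X_train[oob_mask])
            oob_votes[oob_mask] += preds
            oob_counts[oob_mask] += 1
            if trace is not None:
                tree_oob = dict(zip(index[train_idx[oob_mask]], preds.tolist()))
                trace["oob_votes_by_tree"].append(tree_oob)
                trace["bootstrap"].append(frozenset(index[train_idx[np.unique(boot)]]))
        elif trace is not None:
            trace["oob_votes_by_tree"].append({})
            trace["bootstrap"].append(frozenset(index[train_idx[np.unique(boot)]]))

    scores = votes / n_trees
    with np.errstate(invalid="ignore"):
        train_scores = np.where(oob_counts > 0, oob_votes / np.maximum(oob_counts, 1), 0.5)
    scores[train_idx] = train_scores

    counts_full = np.zeros(len(index), dtype=int)
    counts_full[train_idx] = oob_counts
    return GeneScores(
        scores=pd.Series(scores, index=index, name="score"),
        is_training=pd.Series(train_mask, index=index, name="is_training"),
        oob_counts=pd.Series(counts_full, index=index, name="oob_counts"),
        n_trees=n_trees,
        seed=seed,
        imputed_columns=tuple(imputed),
        trace=trace,
    )


def combine_evidence(
    expr: GeneScores | pd.Series, go: GeneScores | pd.Series
) -> pd.DataFrame:
    """Combine the two evidence forms: combined_score = max(expression, GO).

    Genes present in only one input carry that score as the combined score
    and are flagged in ``expression_missing`` / ``go_missing``.  Returns one
    row per gene with columns gene, expression_score, go_score,
    combined_score, is_training, oob, expression_missing, go_missing.
    """
    def unpack(obj):
        if isinstance(obj, GeneScores):
            return obj.scores, obj.is_training
        s = pd.Series(obj, dtype=float)
        return s, pd.Series(False, index=s.index)

    e_scores, e_train = unpack(expr)
    g_scores, g_train = unpack(go)
    all_genes = e_scores.index.union(g_scores.index)
    if not len(all_genes):
        warnings.warn("no genes present in either evidence input")

    out = pd.DataFrame(index=pd.Index(all_genes, name="gene"))
    out["expression_score"] = e_scores.reindex(all_genes)
    out["go_score"] = g_scores.reindex(all_genes)
    out["expression_missing"] = out["expression_score"].isna()
    out["go_missing"] = out["go_score"].isna()
    out["combined_score"] = out[["expression_score", "go_score"]].max(axis=1, skipna=True)
    is_training = (
        e_train.reindex(all_genes, fill_value=False) | g_train.reindex(all_genes, fill_value=False)
    )
    out["is_training"] = is_training
    out["oob"] = is_training  # training-gene scores come from out-of-bag votes
    return out.reset_index()
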