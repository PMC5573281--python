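"""Per-gene burden testing of cohort counts against reference-population counts.

Each gene observed in the cohort is compared to a large reference exome
database via a one-sided two-sample proportion test: x_cohort qualifying
variants among n_cohort individuals versus x_ref among n_ref contributing
individuals.  The default statistic reproduces the classical
continuity-corrected chi-square form (the signed square root referred to the
standard normal upper tail), i.e. the behaviour of R's ``prop.test(...,
alternative="greater")``.  An exact binomial-tail mode is provided because the
normal approximation is severely anti-conservative when the expected cohort
count is far below one — the operating regime of a small cohort against a
60,000-exome reference.  P values are corrected per phenotype group with the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_GROUP_SIZES: Mapping[str, int] = {"restricted": 38, "binge": 55}


def two_proportion_test(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    alternative: str = "greater",
    continuity_correction: bool = True,
    method: str = "chisq",
) -> float:
    """One-sided p-value for H1: x1/n1 > x2/n2.

    ``method="chisq"`` (default): Yates-corrected chi-square on the 2x2 table;
    p = 1 - Phi(sign(p1-p2) * sqrt(chi2)).  Matches R prop.test to machine
    precision, including the correction clamp min(0.5, |x1 - E11|).

    ``method="exact"``: binomial tail P(X >= x1 | n1, p_pooled) with
    p_pooled = (x1+x2)/(n1+n2).  Valid (slightly conservative) in the
    ultra-rare regime where the chi-square tail is unreliable.

    Both return 1 by convention when x1 = x2 = 0, and 0.5 when the two
    proportions are exactly equal (no evidence either way).
    """
    if alternative != "greater":
        raise ValueError("only alternative='greater' is supported")
    for name, val in (("x1", x1), ("x2", x2)):
        if val < 0:
            raise ValueError(f"{name} must be >= 0")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be positive")
    if x1 > n1 or x2 > n2:
        raise ValueError("counts cannot exceed the number of individuals")

    if x1 == 0 and x2 == 0:
        return 1.0
    p1, p2 = x1 / n1, x2 / n2
    if p1 == p2:
        return 0.5

    if method == "exact":
        pooled = (x1 + x2) / (n1 + n2)
        return float(stats.binom.sf(x1 - 1, n1, pooled))
    if method != "chisq":
        raise ValueError(f"unknown method {method!r}")

    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if np.any(expected == 0):
        # a degenerate margin (e.g. everyone a carrier in both samples)
        return 0.5
    yates = min(0.5, abs(x1 - expected[0, 0])) if continuity_correction else 0.0
    chi2 = float((((np.abs(obs - expected) - yates) ** 2) / expected).sum())
    z = math.copysign(math.sqrt(chi2), p1 - p2)
    return float(stats.norm.sf(z))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class BurdenResult:
    """Per-(gene, group) test records plus the significant gene sets."""

    table: pd.DataFrame
    significant: dict[str, set[str]]  # per group, plus "union"
    fdr_threshold: float
    method: str


def run_burden(
    count_table: pd.DataFrame,
    reference_table: pd.DataFrame,
    group_sizes: Mapping[str, int] | None = None,
    fdr_threshold: float = 0.1,
    method: str = "chisq",
    pool_groups: bool = False,
) -> BurdenResult:
    """Test every (gene, group) with a non-zero cohort count.

    ``count_table`` needs columns gene/group and either ``x_cohort`` or
    ``n_carrier_events`` (the unit produced by the filter stage).
    ``reference_table`` needs gene/count/n_individuals.  Genes absent from the
    reference get x_ref = 0 with n_ref set to the largest reference cohort
    seen, and are flagged ``ref_missing``.  BH is applied within each
    phenotype group (the groups are reported separately); ``pool_groups``
    corrects across all records at once instead.
    """
    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    counts = count_table.copy()
    if "x_cohort" not in counts.columns:
        if "n_carrier_events" not in counts.columns:
            raise ValueError("count_table needs an x_cohort or n_carrier_events column")
        counts = counts.rename(columns={"n_carrier_events": "x_cohort"})
    for col in ("gene", "group", "x_cohort"):
        if col not in counts.columns:
            raise ValueError(f"count_table missing column {col!r}")
    for col in ("gene", "count", "n_individuals"):
        if col not in reference_table.columns:
            raise ValueError(f"reference_table missing column {col!r}")

    ref = reference_table.set_index("gene")
    default_n_ref = int(ref["n_individuals"].max()) if len(ref) else max(group_sizes.values())

    records = []
    for row in counts.itertuples(index=False):
        if row.x_cohort <= 0:
            continue
        if row.group not in group_sizes:
            raise ValueError(f"no cohort size configured for group {row.group!r}")
        n_cohort = group_sizes[row.group]
        missing = row.gene not in ref.index
        x_ref = 0 if missing else int(ref.loc[row.gene, "count"])
        n_ref = default_n_ref if missing else int(ref.loc[row.gene, "n_individuals"])
        p = two_proportion_test(int(row.x_cohort), n_cohort, x_ref, n_ref, method=method)
        records.append(
            {
                "gene": row.gene,
                "group": row.group,
                "x_cohort": int(row.x_cohort),
                "n_cohort": n_cohort,
                "x_ref": x_ref,
                "n_ref": n_ref,
                "p_value": p,
                "ref_missing": missing,
            }
        )

    table = pd.DataFrame(
        records,
        columns=[
            "gene", "group", "x_cohort", "n_cohort",
            "x_ref", "n_ref", "p_value", "ref_missing",
        ],
    )
    table["q_value"] = np.nan
    if len(table):
        if pool_groups:
            table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        else:
            for grp, idx in table.groupby("group").groups.items():
                table.loc[idx, "q_value"] = bh_adjust(table.loc[idx, "p_value"].to_numpy())
    table = table.sort_values(["group", "q_value", "p_value", "gene"]).reset_index(drop=True)

    significant: dict[str, set[str]] = {grp: set() for grp in group_sizes}
    for row in table.itertuples(index=False):
        if row.q_value < fdr_threshold:
            significant.setdefault(row.group, set()).add(row.gene)
    significant["union"] = set().union(*significant.values()) if significant else set()
    return BurdenResult(
        table=table, significant=significant, fdr_threshold=fdr_threshold, method=method
    )
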