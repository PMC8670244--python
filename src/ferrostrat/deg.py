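"""Group-wise differential expression and ferroptosis-role enrichment of DEGs.

The DE test here is a deliberate, documented stand-in for a count-based
negative-binomial analysis: it works directly on log2(FPKM + 1) with a
Welch t-test (or Wilcoxon rank-sum), because deposited cohorts often ship
FPKM only. The output metadata records the test used so results are never
mistaken for a count-model fit. Fold changes are differences of group mean
log2(FPKM + 1); multiple testing is Benjamini-Hochberg over all tested
genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .mutations import ROLE_PRECEDENCE

__all__ = ["differential_expression", "filter_degs", "ferrdb_enrichment"]


def differential_expression(expr: pd.DataFrame, group_a, group_b,
                            test: str = "welch") -> pd.DataFrame:
    """Per-gene log2 fold change (mean A - mean B of log2(FPKM+1)), raw P
    and BH-adjusted FDR.

    ``group_a`` / ``group_b`` are disjoint sample-id collections with >= 2
    members each. Genes with zero variance in both groups get P = 1 when
    the means agree and P = 0 otherwise. The returned frame's ``attrs``
    record the test, for honest provenance.
    """
    a = [s for s in group_a]
    b = [s for s in group_b]
    if set(a) & set(b):
        raise ValueError("groups overlap")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 samples")
    if test not in ("welch", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    la = np.log2(expr[a].to_numpy(dtype=float) + 1.0)
    lb = np.log2(expr[b].to_numpy(dtype=float) + 1.0)
    lfc = la.mean(axis=1) - lb.mean(axis=1)
    pvals = np.ones(len(expr))
    var_zero = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    testable = ~var_zero
    if testable.any():
        if test == "welch":
            _, p = stats.ttest_ind(la[testable], lb[testable], axis=1, equal_var=False)
        else:
            _, p = stats.mannwhitneyu(la[testable], lb[testable], axis=1,
                                      alternative="two-sided")
        pvals[testable] = p
    # degenerate: both groups constant — identical means are null, distinct are certain
    degenerate = var_zero & ~np.isclose(lfc, 0.0)
    pvals[degenerate] = 0.0
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame({"log2fc": lfc, "p_value": pvals, "fdr": fdr}, index=expr.index)
    out.attrs["test"] = f"{test} on log2(FPKM+1); stand-in, not a count model"
    return out


def filter_degs(table: pd.DataFrame, min_abs_lfc: float = 1.0,
                max_fdr: float = 0.05) -> list[str]:
    """Genes with |log2FC| strictly above ``min_abs_lfc`` and FDR strictly
    below ``max_fdr`` (boundary values excluded)."""
    if min_abs_lfc <= 0 or max_fdr <= 0:
        raise ValueError("thresholds must be positive")
    mask = (table["log2fc"].abs() > min_abs_lfc) & (table["fdr"] < max_fdr)
    return table.index[mask].tolist()


def ferrdb_enrichment(deg_genes, ferrdb: GeneSetCollection,
                      count_in_each: bool = False) -> pd.Series:
    """Counts of DEGs falling in the driver / suppressor / marker role sets.

    By default a gene in several role sets is counted once under precedence
    driver > suppressor > marker; ``count_in_each`` counts it in every set
    it belongs to. The returned Series also carries ``total_degs``.
    """
    degs = {str(g).upper() for g in deg_genes}
    role_sets = {role: ferrdb.genes_with_role(role) for role in ROLE_PRECEDENCE}
    counts = {}
    if count_in_each:
        for role in ROLE_PRECEDENCE:
            counts[role] = len(degs & role_sets[role])
    else:
        remaining = set(degs)
        for role in ROLE_PRECEDENCE:
            hit = remaining & role_sets[role]
            counts[role] = len(hit)
            remaining -= hit
    counts["total_degs"] = len(degs)
    return pd.Series(counts, name="n_genes")
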