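"""Expression-derived immune and drug-sensitivity scores.

All log-based scores operate on log10(FPKM + pseudocount); the default
pseudocount of 1 keeps zero-expression samples finite and the scores
monotone. The rank-based ``mean_rank_z`` method is an explicitly labeled
generic stand-in for ESTIMATE-style microenvironment scoring — it is NOT
the ESTIMATE algorithm and is not claimed to reproduce its values.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GRANZYME_GENES",
    "CYTOLYTIC_GENES",
    "HLA_GENES",
    "SORAFENIB_POSITIVE",
    "SORAFENIB_NEGATIVE",
    "cytolytic_score",
    "signature_score",
    "hla_summary",
    "frg_immune_correlation",
    "sorafenib_sensitivity_score",
    "classify_ctd_genes",
    "score_ic50_concordance",
]

logger = logging.getLogger("ferrostrat")

#: the five human granzyme genes commonly profiled, plus perforin-1
GRANZYME_GENES = ("GZMA", "GZMB", "GZMH", "GZMK", "GZMM")
CYTOLYTIC_GENES = GRANZYME_GENES + ("PRF1",)
HLA_GENES = ("HLA-A", "HLA-B", "HLA-C")

SORAFENIB_POSITIVE = ("FLT3",)
SORAFENIB_NEGATIVE = ("MAPK1", "MAPK3", "GADD45G", "MCL1", "PINK1")


def _require_genes(expr: pd.DataFrame, genes) -> list[str]:
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"gene(s) absent from expression matrix: {missing}")
    return list(genes)


def _log10(expr: pd.DataFrame, genes, pseudocount: float) -> pd.DataFrame:
    x = expr.loc[list(genes)].to_numpy(dtype=float)
    if pseudocount == 0 and (x <= 0).any():
        raise ValueError("zero expression with pseudocount=0; set pseudocount > 0")
    return pd.DataFrame(np.log10(x + pseudocount), index=list(genes), columns=expr.columns)


def cytolytic_score(expr: pd.DataFrame, granzyme_genes=GRANZYME_GENES,
                    prf1: str = "PRF1", pseudocount: float = 1.0) -> pd.Series:
    """Cytolytic activity: mean log10 expression of five granzymes + PRF1."""
    genes = _require_genes(expr, tuple(granzyme_genes) + (prf1,))
    return _log10(expr, genes, pseudocount).mean(axis=0).rename("cytolytic")


def signature_score(expr: pd.DataFrame, genes, method: str = "mean_log",
                    pseudocount: float = 1.0, name: str = "signature") -> pd.Series:
    """Per-sample score of a gene signature.

    ``mean_log``: mean log10(FPKM + pseudocount) over the signature genes
    present. ``mean_rank_z``: mean of per-gene within-cohort rank z-scores
    (generic microenvironment stand-in; a constant gene contributes 0).
    Missing genes are dropped with a warning; an empty intersection is an
    error.
    """
    present = [g for g in genes if g in expr.index]
    absent = [g for g in genes if g not in expr.index]
    if not present:
        raise KeyError(f"no signature gene present in expression matrix: {list(genes)}")
    if absent:
        logger.warning("signature %r: %d gene(s) missing: %s", name, len(absent), absent[:5])
    if method == "mean_log":
        return _log10(expr, present, pseudocount).mean(axis=0).rename(name)
    if method == "mean_rank_z":
        sub = expr.loc[present]
        ranks = sub.rank(axis=1, method="average")
        sd = ranks.std(axis=1, ddof=0)
        centered = ranks.sub(ranks.mean(axis=1), axis=0)
        z = centered.div(sd.replace(0.0, np.inf), axis=0)  # constant gene -> all zeros
        return z.mean(axis=0).rename(name)
    raise ValueError(f"unknown method {method!r}")


def hla_summary(expr: pd.DataFrame, genes=HLA_GENES, pseudocount: float = 1.0) -> pd.Series:
    """Mean log10 expression of the class-I HLA genes (A, B, C)."""
    _require_genes(expr, genes)
    return signature_score(expr, genes, "mean_log", pseudocount, name="hla_mean")


def frg_immune_correlation(expr: pd.DataFrame, fractions: pd.DataFrame,
                           genes=None) -> pd.DataFrame:
    """Pearson r between each gene's expression and each immune cell
    fraction over the shared samples.

    Cell types with zero variance (e.g. a population undetected in every
    sample) are reported as NaN columns rather than silently dropped.
    Requires at least 3 shared samples.
    """
    from .io import IMMUNE_META_COLS

    if genes is not None:
        expr = expr.loc[_require_genes(expr, genes)]
    frac_cols = [c for c in fractions.columns if c not in IMMUNE_META_COLS]
    shared = expr.columns.intersection(fractions.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    X = expr[shared].to_numpy(dtype=float)               # genes x samples
    Y = fractions.loc[shared, frac_cols].to_numpy(dtype=float).T  # cells x samples
    const_x = (X == X[:, [0]]).all(axis=1)
    const_y = (Y == Y[:, [0]]).all(axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Yc.T) / np.outer(sx, sy)
    r[:, const_y | (sy == 0)] = np.nan
    r[const_x | (sx == 0), :] = np.nan
    dropped = [c for c, bad in zip(frac_cols, const_y | (sy == 0)) if bad]
    if dropped:
        logger.info("frg_immune_correlation: zero-variance cell type(s) reported as NaN: %s", dropped)
    return pd.DataFrame(r, index=expr.index, columns=frac_cols)


def sorafenib_sensitivity_score(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.Series:
    """Sorafenib sensitivity: log10(FLT3) minus the summed log10 expression
    of MAPK1, MAPK3, GADD45G, MCL1 and PINK1 (all + pseudocount)."""
    genes = _require_genes(expr, SORAFENIB_POSITIVE + SORAFENIB_NEGATIVE)
    logs = _log10(expr, genes, pseudocount)
    score = logs.loc[SORAFENIB_POSITIVE[0]] - logs.loc[list(SORAFENIB_NEGATIVE)].sum(axis=0)
    return score.rename("sorafenib_sensitivity")


def classify_ctd_genes(expr: pd.DataFrame, risk: pd.Series, genes,
                       alpha: float = 0.05, pseudocount: float = 1.0) -> pd.DataFrame:
    """Classify drug-associated genes as up / down / ns across risk groups.

    Two two-sided Welch t-tests on log10 expression: High vs Low and Middle
    vs Low. 'up' = higher mean in both High and Middle than Low with P <
    ``alpha`` in both comparisons; 'down' = higher in Low in both with P <
    ``alpha`` in both; anything else 'ns'.
    """
    for g in ("High", "Middle", "Low"):
        if (risk == g).sum() < 2:
            raise ValueError(f"risk group {g!r} has fewer than 2 samples")
    present = _require_genes(expr, [g for g in genes if g in expr.index] or list(genes))
    logs = _log10(expr, present, pseudocount)
    cols = {g: logs.columns.intersection(risk.index[risk == g]) for g in ("High", "Middle", "Low")}
    rows = []
    for gene in present:
        v = {g: logs.loc[gene, c].to_numpy() for g, c in cols.items()}
        out = {}
        for comp, a in (("hl", "High"), ("ml", "Middle")):
            if np.var(v[a]) == 0 and np.var(v["Low"]) == 0:
                t, p = (0.0, 1.0) if np.mean(v[a]) == np.mean(v["Low"]) else (np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(v[a], v["Low"], equal_var=False)
            out[f"t_{comp}"], out[f"p_{comp}"] = float(t), float(p)
            out[f"higher_in_{comp}"] = "Low" if np.mean(v[a]) < np.mean(v["Low"]) else a
        sig = out["p_hl"] < alpha and out["p_ml"] < alpha
        if sig and out["higher_in_hl"] == "High" and out["higher_in_ml"] == "Middle":
            cls = "up"
        elif sig and out["higher_in_hl"] == "Low" and out["higher_in_ml"] == "Low":
            cls = "down"
        else:
            cls = "ns"
        rows.append({"gene": gene, "class": cls, **out})
    return pd.DataFrame(rows).set_index("gene")


def score_ic50_concordance(scores: pd.Series, ic50: pd.Series, log_ic50: bool = True):
    """Spearman rank correlation between a sensitivity score and IC50 across
    cell lines; a negative rho means the score is concordant with potency
    (higher score, lower IC50).

    Returns (rho, concordant flag, n). rho is NaN (flag None) when either
    input is constant.
    """
    shared = scores.index.intersection(ic50.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 cell lines with both values, got {len(shared)}")
    x = scores.loc[shared].to_numpy(dtype=float)
    y = ic50.loc[shared].to_numpy(dtype=float)
    if log_ic50:
        y = np.log10(y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), None, len(shared)
    rho, _ = stats.spearmanr(x, y)
    return float(rho), bool(rho < 0), len(shared)
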