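"""FPKM computation, log transforms, and per-gene min-max standardization.

The FPKM convention used throughout is

    FPKM(g, s) = 10^6 * F(g, s) / (N(s) * L(g) / 10^2)

with F the fragment count assigned to gene g in sample s, N the total mapped
reads of sample s, and L the annotated transcript length of g in base pairs.
Note the 10^2 length scaling: the overall constant is 10^8 / (N * L). This is
the convention the rest of the package (scores, clustering) assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "compute_fpkm", "log_transform", "minmax_standardize"]

FPKM_SCALE = 1e8  # 10^6 / (1/10^2)


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x samples) with per-sample library
    sizes and per-gene transcript lengths.

    ``counts`` rows are gene symbols, columns sample ids; ``library_sizes``
    is indexed by sample; ``gene_lengths`` by gene, in base pairs.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("fragment counts must be non-negative")
        missing_n = [s for s in self.counts.columns if s not in self.library_sizes.index]
        if missing_n:
            raise ValueError(f"missing library size for sample(s): {missing_n}")
        missing_l = [g for g in self.counts.index if g not in self.gene_lengths.index]
        if missing_l:
            raise ValueError(f"missing gene length for gene(s): {missing_l}")
        if (self.library_sizes.loc[self.counts.columns] <= 0).any():
            raise ValueError("library sizes must be positive")
        if (self.gene_lengths.loc[self.counts.index] <= 0).any():
            raise ValueError("gene lengths must be positive")


def compute_fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Elementwise FPKM: ``10^8 * F / (N * L)``. Zero counts map to zero."""
    F = counts.counts.to_numpy(dtype=float)
    N = counts.library_sizes.loc[counts.counts.columns].to_numpy(dtype=float)
    L = counts.gene_lengths.loc[counts.counts.index].to_numpy(dtype=float)
    fpkm = FPKM_SCALE * F / (L[:, None] * N[None, :])
    return pd.DataFrame(fpkm, index=counts.counts.index, columns=counts.counts.columns)


def log_transform(expr: pd.DataFrame, base: float = 10.0, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise ``log_base(x + pseudocount)``.

    A zero anywhere with ``pseudocount == 0`` is an error rather than -inf:
    every downstream score assumes finite values.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    x = expr.to_numpy(dtype=float)
    if pseudocount == 0 and (x <= 0).any():
        raise ValueError("zero/negative value with pseudocount=0; set pseudocount > 0")
    return pd.DataFrame(
        np.log(x + pseudocount) / np.log(base), index=expr.index, columns=expr.columns
    )


def minmax_standardize(expr: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene min-max scaling to [0, 1] across samples.

    ``genes`` restricts (and orders) the rows; a gene that is constant across
    the cohort maps to all-zeros instead of NaN so downstream PCA stays
    defined.
    """
    if genes is not None:
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise KeyError(f"gene(s) absent from expression matrix: {missing}")
        expr = expr.loc[genes]
    x = expr.to_numpy(dtype=float)
    lo = x.min(axis=1, keepdims=True)
    span = x.max(axis=1, keepdims=True) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (x - lo) / span
    scaled[np.broadcast_to(span == 0, scaled.shape)] = 0.0
    return pd.DataFrame(scaled, index=expr.index, columns=expr.columns)
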