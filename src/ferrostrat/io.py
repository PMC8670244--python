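"""Readers and writers for the tabular and gene-set formats the pipeline touches.

All tables are plain tab-separated text. Expression matrices are genes x
samples with FPKM values; mutation tables are long-form (sample, gene)
records; survival tables carry follow-up months and a death indicator;
immune-fraction tables are CIBERSORT-style deconvolution output (consumed,
never computed here). Gene sets travel as GMT, with the set's role encoded
in the description field.

Readers validate invariants and raise ``FormatError`` rather than coerce:
a matrix with a negative FPKM, a duplicated sample id, or an NA cell is a
broken input, not something to patch silently. Gene symbols are uppercased
on read; duplicate gene rows are collapsed by mean with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ferrostrat")

__all__ = [
    "FormatError",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_mutations",
    "write_mutations",
    "read_survival",
    "write_survival",
    "read_immune_fractions",
    "write_immune_fractions",
    "filter_immune_samples",
    "read_gene_sets",
    "write_gene_sets",
]

#: roles a gene set may carry in its GMT description field
VALID_ROLES = ("driver", "suppressor", "marker", "drug_positive", "drug_negative", "signature")

IMMUNE_META_COLS = ("P-value", "Correlation", "RMSE")


class FormatError(ValueError):
    """Raised when an input file violates a format invariant."""


@dataclass
class GeneSetCollection:
    """Named gene lists with a role tag per set.

    ``sets`` maps set name -> list of uppercase gene symbols; ``roles`` maps
    set name -> one of :data:`VALID_ROLES`.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = [g.upper() for g in genes]
        for name in self.sets:
            self.roles.setdefault(name, "signature")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def by_role(self, role: str) -> dict[str, list[str]]:
        """All sets carrying ``role``, name -> genes."""
        return {n: g for n, g in self.sets.items() if self.roles[n] == role}

    def genes_with_role(self, role: str) -> set[str]:
        """Union of genes over all sets tagged ``role``."""
        out: set[str] = set()
        for genes in self.by_role(role).values():
            out.update(genes)
        return out


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path, *, duplicate_genes: str = "mean", gene_column: str | int = 0) -> pd.DataFrame:
    """Read a genes x samples FPKM table from tab-separated text.

    The first column (or ``gene_column``) holds gene symbols, the header row
    holds sample identifiers. Symbols are uppercased; duplicate gene rows are
    resolved per ``duplicate_genes`` ("mean" collapses with a warning,
    "error" raises). Deposited supplementary matrices vary in their header
    dialect, hence the knobs rather than guesses.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:] if isinstance(gene_column, int) else [h for h in header if h != gene_column]
    dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dups:
        raise FormatError(f"{path}: duplicate sample id(s): {dups}")
    df = pd.read_csv(path, sep="\t", index_col=gene_column, keep_default_na=False, na_values=[])
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expression matrix needs >= 2 sample columns, got {df.shape[1]}")
    # locate non-numeric cells before coercion so the error can name them
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    df = numeric
    if (df.to_numpy() < 0).any():
        r, c = np.argwhere((df.to_numpy() < 0))[0]
        raise FormatError(f"{path}: negative FPKM at gene {df.index[r]!r}, sample {df.columns[c]!r}")
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        if duplicate_genes == "error":
            raise FormatError(f"{path}: duplicate gene symbol(s): {dup}")
        logger.warning("%s: collapsing %d duplicated gene symbol(s) by mean: %s", path, len(dup), dup[:5])
        df = df.groupby(level=0, sort=False).mean()
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# mutation tables


def read_mutations(path) -> pd.DataFrame:
    """Read a long-form mutation table with columns ``sample`` and ``gene``.

    (sample, gene) pairs are deduplicated after uppercase normalization; an
    optional ``group`` column is carried through untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df["gene"] = df["gene"].str.upper()
    before = len(df)
    df = df.drop_duplicates(subset=["sample", "gene"]).reset_index(drop=True)
    if len(df) != before:
        logger.warning("%s: dropped %d duplicate (sample, gene) record(s)", path, before - len(df))
    return df


def write_mutations(mutations: pd.DataFrame, path) -> None:
    mutations.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# survival tables


def read_survival(path) -> pd.DataFrame:
    """Read survival records: sample id, follow-up ``time`` in months (> 0),
    ``event`` indicator (1 = death)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "sample"].tolist()
        raise FormatError(f"{path}: non-positive follow-up time for sample(s) {bad}")
    if not df["event"].isin([0, 1]).all():
        raise FormatError(f"{path}: event indicator must be 0/1")
    df["event"] = df["event"].astype(int)
    return df.set_index("sample")


def write_survival(survival: pd.DataFrame, path) -> None:
    survival.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# immune fraction tables


def read_immune_fractions(path, *, tol: float = 1e-6) -> pd.DataFrame:
    """Read a CIBERSORT-style output table: one row per sample, 22 cell-type
    fraction columns plus ``P-value``, ``Correlation``, ``RMSE``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    frac_cols = [c for c in df.columns if c not in IMMUNE_META_COLS]
    fracs = df[frac_cols]
    if (fracs.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative immune fraction")
    sums = fracs.sum(axis=1)
    off = sums[(sums - 1.0).abs() > tol]
    if len(off):
        raise FormatError(f"{path}: fractions do not sum to 1 for sample(s) {off.index.tolist()[:5]}")
    return df


def write_immune_fractions(fractions: pd.DataFrame, path) -> None:
    fractions.to_csv(path, sep="\t", index_label="sample")


def filter_immune_samples(fractions: pd.DataFrame, p_max: float = 0.05) -> pd.DataFrame:
    """Keep samples whose deconvolution P-value is below ``p_max``.

    Mirrors the usual quality gate on deconvolution output (strict '<').
    Returns the table unchanged when no P-value column is present and
    ``p_max`` is 1.0.
    """
    if not 0 < p_max <= 1:
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    if "P-value" not in fractions.columns:
        if p_max == 1.0:
            return fractions
        raise FormatError("immune fraction table has no 'P-value' column")
    kept = fractions[fractions["P-value"] < p_max] if p_max < 1.0 else fractions
    dropped = len(fractions) - len(kept)
    if dropped:
        logger.info("filter_immune_samples: dropped %d of %d samples at P >= %g", dropped, len(fractions), p_max)
    if kept.empty:
        logger.warning("filter_immune_samples: no samples pass P < %g", p_max)
    return kept


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene [<tab> gene ...].

    The description field carries the set's role tag (driver, suppressor,
    marker, drug_positive, drug_negative); anything else is treated as a
    generic signature.
    """
    sets: dict[str, list[str]] = {}
    roles: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), needs >= 3")
            name, desc = fields[0], fields[1].strip().lower()
            genes = [g.strip().upper() for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            roles[name] = desc if desc in VALID_ROLES else "signature"
    return GeneSetCollection(sets=sets, roles=roles)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.roles[name], *genes]) + "\n")


def bundled_path(filename: str) -> Path:
    """Path to a gene-set file shipped with the package."""
    return Path(__file__).parent / "data" / filename
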