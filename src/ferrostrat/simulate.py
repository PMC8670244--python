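"""Synthetic Ph-negative B-ALL cohort generator.

Emulates the statistical structure the downstream analysis assumes: ~80
samples in three latent risk groups (High/Middle/Low) with

* group-shifted log10 expression of a 24-gene ferroptosis panel (three
  blocks of eight genes, block *b* upshifted in group *b*),
* Weibull survival with group-specific multiplicative hazards and uniform
  administrative censoring,
* per-sample mutation sets whose size is Poisson per group and whose
  ferroptosis-driver content is binomial per group,
* Dirichlet immune-cell fractions over the 22 LM22 cell types with
  group-specific concentrations ("Dendritic cells resting" is identically
  zero, mirroring a cell type undetected in every sample),
* integer fragment counts, library sizes and gene lengths that reproduce
  the expression matrix exactly through the package's FPKM formula.

Every modality draws from its own RNG stream spawned from the master seed,
so a fixed seed yields a byte-identical cohort and changing one modality's
parameters does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import CountMatrix, compute_fpkm
from . import io as fio

__all__ = [
    "FRG_PANEL",
    "LM22_CELL_TYPES",
    "GROUPS",
    "CohortConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "write_cohort",
]

#: 24-gene ferroptosis-related panel used for clustering and modeling
FRG_PANEL = (
    "ACSL4", "ALOX15", "ATP5G3", "CARS", "CDKN1A", "CISD1", "CS", "DPP4",
    "EMC2", "FANCD2", "FDFT1", "GLS2", "GPX4", "HSPA5", "HSPB1", "LPCAT3",
    "MT1G", "NCOA4", "NFE2L2", "RPL8", "SAT1", "SLC1A5", "SLC7A11", "TFRC",
)

#: LM22 immune cell types (CIBERSORT deconvolution output columns)
LM22_CELL_TYPES = (
    "B cells naive", "B cells memory", "Plasma cells", "T cells CD8",
    "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta", "NK cells resting",
    "NK cells activated", "Monocytes", "Macrophages M0", "Macrophages M1",
    "Macrophages M2", "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated", "Eosinophils", "Neutrophils",
)

GROUPS = ("High", "Middle", "Low")

#: mutation gene pools: ferroptosis drivers (first four are the recurrent
#: B-ALL drivers also present in the bundled role lists) and a background
#: panel of recurrently mutated leukemia genes
DRIVER_MUTATION_POOL = (
    "NRAS", "KRAS", "FLT3", "CDKN2A",
    "EGFR", "IDH1", "PIK3CA", "HRAS", "KEAP1", "ATG5", "ATG7", "PANX1",
)
BACKGROUND_MUTATION_POOL = (
    "TP53", "SETD2", "PTPN11", "PAX5", "IKZF1", "ETV6", "RUNX1", "JAK2",
    "JAK1", "CREBBP", "WHSC1", "KMT2D", "NOTCH1", "FBXW7", "PHF6", "EP300",
    "CTCF", "NT5C2", "XBP1", "MYC", "ABL2", "EPOR", "SH2B3", "TYK2",
    "IL7R", "DNM2", "LEF1", "TBL1XR1", "ERG", "SPI1", "BCL2", "BCL6",
    "CCND3", "ID4", "BTG1", "RB1", "VPREB1", "ZEB2", "GATA3", "ARID1A",
)

# default per-gene, per-group log10 mean shifts planting the immune- and
# drug-score patterns the cohort is analysed for (High, Middle, Low)
_DEFAULT_EXTRA_SHIFTS: dict[str, tuple[float, float, float]] = {
    # Sorafenib sensitivity: FLT3 high in High/Middle, the five negatively
    # signed genes mildly elevated in Low
    "FLT3": (1.0, 0.6, 0.0),
    "MAPK1": (0.0, 0.0, 0.25),
    "MAPK3": (0.0, 0.0, 0.25),
    "GADD45G": (0.0, 0.0, 0.25),
    "MCL1": (0.0, 0.0, 0.25),
    "PINK1": (0.0, 0.0, 0.25),
    # cytotoxic activity and antigen presentation elevated in Low risk
    "GZMA": (0.0, 0.0, 0.4), "GZMB": (0.0, 0.0, 0.4), "GZMH": (0.0, 0.0, 0.4),
    "GZMK": (0.0, 0.0, 0.4), "GZMM": (0.0, 0.0, 0.4), "PRF1": (0.0, 0.0, 0.4),
    "HLA-A": (0.0, 0.0, 0.3), "HLA-B": (0.0, 0.0, 0.3), "HLA-C": (0.0, 0.0, 0.3),
    # inflammatory program mildly elevated in the Low-risk microenvironment
    **{g: (0.0, 0.0, 0.3) for g in ("IL1B", "IL6", "IL8", "TNF", "CCL2", "PTGS2", "NOS2")},
    # checkpoint-blockade response signatures carry no group signal
    **{g: (0.0, 0.0, 0.0) for g in (
        "IFNG", "STAT1", "IDO1", "CXCL10", "CXCL9", "HLA-DRA",
        "CD3D", "CIITA", "CD3E", "CCL5", "CD2", "CXCL13", "IL2RB",
        "NKG7", "HLA-E", "CXCR6", "LAG3", "TAGAP",
    )},
}


def _default_dirichlet_conc() -> np.ndarray:
    """Per-group Dirichlet concentrations over the 22 LM22 cell types.

    Built from one plausible marrow-infiltrate profile, skewed so the Low
    risk group is enriched for neutrophils/monocytes/resting mast cells and
    the High/Middle groups for naive B and plasma cells. 'Dendritic cells
    resting' gets concentration 0 (identically absent).
    """
    base = {
        "B cells naive": 8.0, "B cells memory": 2.0, "Plasma cells": 4.0,
        "T cells CD8": 5.0, "T cells CD4 naive": 3.0,
        "T cells CD4 memory resting": 4.0, "T cells CD4 memory activated": 2.0,
        "T cells follicular helper": 1.5, "T cells regulatory (Tregs)": 1.5,
        "T cells gamma delta": 1.0, "NK cells resting": 2.0,
        "NK cells activated": 1.5, "Monocytes": 5.0, "Macrophages M0": 3.0,
        "Macrophages M1": 1.5, "Macrophages M2": 2.0,
        "Dendritic cells resting": 0.0, "Dendritic cells activated": 1.0,
        "Mast cells resting": 1.5, "Mast cells activated": 0.5,
        "Eosinophils": 1.0, "Neutrophils": 8.0,
    }
    conc = np.array([[base[c] for c in LM22_CELL_TYPES]] * 3, dtype=float)
    idx = {c: i for i, c in enumerate(LM22_CELL_TYPES)}
    # High and Middle: B-lineage expansion, depleted mature myeloid
    for g, fac in ((0, 2.0), (1, 1.6)):
        conc[g, idx["B cells naive"]] *= fac
        conc[g, idx["Plasma cells"]] *= fac
        conc[g, idx["Macrophages M2"]] *= fac
        conc[g, idx["Neutrophils"]] /= fac
        conc[g, idx["Monocytes"]] /= fac
    # Low: myeloid-rich microenvironment
    conc[2, idx["Neutrophils"]] *= 1.8
    conc[2, idx["Monocytes"]] *= 1.5
    conc[2, idx["Mast cells resting"]] *= 1.5
    conc[2, idx["Macrophages M0"]] *= 1.5
    return conc


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    ``frg_shift`` is the per-group mean shift of the planted FRG blocks on
    the log10-FPKM scale; ``hazard_ratios``, ``mutation_rate`` and
    ``fe_driver_enrichment`` are per group in (High, Middle, Low) order.
    """

    n_samples: int = 80
    group_proportions: tuple[float, float, float] = (25 / 80, 39 / 80, 16 / 80)
    frg_names: tuple[str, ...] = FRG_PANEL
    frg_shift: float = 1.0
    n_background_genes: int = 400
    hazard_ratios: tuple[float, float, float] = (4.0, 2.0, 1.0)
    censoring_rate: float = 0.3
    mutation_rate: tuple[float, float, float] = (3.5, 2.0, 1.8)
    fe_driver_enrichment: tuple[float, float, float] = (0.6, 0.4, 0.2)
    dirichlet_conc: np.ndarray = field(default_factory=_default_dirichlet_conc)
    extra_group_shifts: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_EXTRA_SHIFTS)
    )
    seed: int = 0

    # fixed nuisance parameters of the generative model
    frg_base_mean: float = 0.8      # log10 FPKM baseline of panel genes
    background_mean: float = 1.0    # shared log10 FPKM mean of background genes
    sigma: float = 0.3              # per-gene log10 noise SD
    weibull_shape: float = 1.2
    middle_median_os: float = 24.0  # months; anchors the baseline hazard
    n_immune_pvalue_fail: int = 2   # samples planted with a failing deconvolution P

    def __post_init__(self) -> None:
        props = np.asarray(self.group_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError(f"group_proportions must be a simplex, got {self.group_proportions}")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        for p in self.fe_driver_enrichment:
            if not 0 <= p <= 1:
                raise ValueError("fe_driver_enrichment entries must be in [0, 1]")
        if len(self.frg_names) % 3 != 0:
            raise ValueError("frg_names must split into 3 equal blocks")


@dataclass
class SyntheticCohort:
    """A complete simulated cohort. ``truth_labels`` holds the planted risk
    group per sample ('High'/'Middle'/'Low')."""

    expression: pd.DataFrame
    counts: CountMatrix
    survival: pd.DataFrame
    mutations: pd.DataFrame
    immune_fractions: pd.DataFrame
    truth_labels: pd.Series
    config: CohortConfig


def _group_sizes(n: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of n * props to exact integer counts."""
    raw = n * props
    sizes = np.floor(raw).astype(int)
    rem = raw - sizes
    for i in np.argsort(-rem)[: n - sizes.sum()]:
        sizes[i] += 1
    return sizes


def _censoring_horizon(cfg: CohortConfig, sizes: np.ndarray, lam0: float) -> float:
    """Administrative horizon tau such that P(C < T) equals censoring_rate
    under C ~ U(0, tau) and the group-mixture Weibull event model."""
    k = cfg.weibull_shape
    w = sizes / sizes.sum()

    def p_censored(tau: float) -> float:
        t = np.linspace(0.0, tau, 4097)
        s_mix = sum(
            wg * np.exp(-lam0 * hr * t ** k) for wg, hr in zip(w, cfg.hazard_ratios)
        )
        return float(np.trapezoid(s_mix, t) / tau)

    return brentq(lambda tau: p_censored(tau) - cfg.censoring_rate, 1e-3, 1e6, xtol=1e-8)


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw one cohort under ``config`` (defaults are the study conditions)."""
    cfg = config or CohortConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_assign, rng_expr, rng_surv, rng_mut, rng_imm, rng_lib = (
        np.random.default_rng(s) for s in streams
    )

    n = cfg.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]
    sizes = _group_sizes(n, np.asarray(cfg.group_proportions, dtype=float))
    group_idx = rng_assign.permutation(np.repeat(np.arange(3), sizes))
    truth = pd.Series([GROUPS[g] for g in group_idx], index=samples, name="group")

    # --- expression: log10 means per (gene, group), Normal noise, exponentiate
    frgs = list(cfg.frg_names)
    block = len(frgs) // 3
    extra = [g for g in cfg.extra_group_shifts if g not in frgs]
    background = [f"BG{i + 1:04d}" for i in range(cfg.n_background_genes)]
    genes = frgs + extra + background

    mu = np.zeros((len(genes), 3))
    mu[: len(frgs), :] = cfg.frg_base_mean
    for b in range(3):
        mu[b * block : (b + 1) * block, b] += cfg.frg_shift
    for j, g in enumerate(extra, start=len(frgs)):
        mu[j, :] = cfg.background_mean + np.asarray(cfg.extra_group_shifts[g])
    mu[len(frgs) + len(extra) :, :] = cfg.background_mean

    log10_expr = mu[:, group_idx] + rng_expr.normal(0.0, cfg.sigma, size=(len(genes), n))
    target_fpkm = 10.0 ** log10_expr

    # --- counts consistent with expression through the FPKM formula
    lib_sizes = rng_lib.integers(15_000_000, 25_000_000, size=n)
    lengths = rng_lib.integers(500, 5_000, size=len(genes))
    F = np.rint(target_fpkm * lengths[:, None] * lib_sizes[None, :] / 1e8).astype(np.int64)
    counts = CountMatrix(
        counts=pd.DataFrame(F, index=genes, columns=samples),
        library_sizes=pd.Series(lib_sizes, index=samples, name="library_size"),
        gene_lengths=pd.Series(lengths, index=genes, name="length"),
    )
    expression = compute_fpkm(counts)

    # --- survival: Weibull with group hazards, uniform administrative censoring
    k = cfg.weibull_shape
    lam0 = np.log(2.0) / (cfg.hazard_ratios[1] * cfg.middle_median_os ** k)
    hr = np.asarray(cfg.hazard_ratios)[group_idx]
    t_event = (rng_surv.exponential(1.0, size=n) / (lam0 * hr)) ** (1.0 / k)
    if cfg.censoring_rate > 0:
        tau = _censoring_horizon(cfg, sizes, lam0)
        t_cens = rng_surv.uniform(0.0, tau, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    time = np.maximum(np.round(time, 1), 0.1)  # months at one-decimal resolution (ties occur)
    survival = pd.DataFrame({"time": time, "event": event}, index=pd.Index(samples, name="sample"))

    # --- mutations: Poisson burden, binomial driver content, no duplicates
    rates = np.asarray(cfg.mutation_rate)[group_idx]
    probs = np.asarray(cfg.fe_driver_enrichment)[group_idx]
    records: list[tuple[str, str]] = []
    for i, s in enumerate(samples):
        m = int(rng_mut.poisson(rates[i]))
        if m == 0:
            continue
        n_driver = min(int(rng_mut.binomial(m, probs[i])), len(DRIVER_MUTATION_POOL))
        n_other = min(m - n_driver, len(BACKGROUND_MUTATION_POOL))
        hit = list(rng_mut.choice(DRIVER_MUTATION_POOL, size=n_driver, replace=False))
        hit += list(rng_mut.choice(BACKGROUND_MUTATION_POOL, size=n_other, replace=False))
        records.extend((s, g) for g in hit)
    mutations = pd.DataFrame(records, columns=["sample", "gene"])

    # --- immune fractions: Dirichlet per group; zero-concentration types stay 0
    conc = np.asarray(cfg.dirichlet_conc, dtype=float)
    fracs = np.zeros((n, len(LM22_CELL_TYPES)))
    for g in range(3):
        members = np.flatnonzero(group_idx == g)
        pos = np.flatnonzero(conc[g] > 0)
        draws = rng_imm.dirichlet(conc[g, pos], size=len(members))
        fracs[np.ix_(members, pos)] = draws
    immune = pd.DataFrame(fracs, index=pd.Index(samples, name="sample"), columns=list(LM22_CELL_TYPES))
    pvals = np.full(n, 0.01)
    fail = rng_imm.choice(n, size=min(cfg.n_immune_pvalue_fail, n), replace=False)
    pvals[fail] = 0.2
    immune["P-value"] = pvals
    immune["Correlation"] = rng_imm.uniform(0.5, 0.9, size=n)
    immune["RMSE"] = rng_imm.uniform(0.3, 0.7, size=n)

    return SyntheticCohort(
        expression=expression,
        counts=counts,
        survival=survival,
        mutations=mutations,
        immune_fractions=immune,
        truth_labels=truth,
        config=cfg,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write every cohort component as TSV under ``out_dir``; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "counts": out / "counts.tsv",
        "library_sizes": out / "library_sizes.tsv",
        "gene_lengths": out / "gene_lengths.tsv",
        "survival": out / "survival.tsv",
        "mutations": out / "mutations.tsv",
        "immune_fractions": out / "immune_fractions.tsv",
        "truth_labels": out / "truth_labels.tsv",
    }
    fio.write_expression(cohort.expression, paths["expression"])
    cohort.counts.counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    cohort.counts.library_sizes.to_csv(paths["library_sizes"], sep="\t", index_label="sample")
    cohort.counts.gene_lengths.to_csv(paths["gene_lengths"], sep="\t", index_label="gene")
    fio.write_survival(cohort.survival, paths["survival"])
    fio.write_mutations(cohort.mutations, paths["mutations"])
    fio.write_immune_fractions(cohort.immune_fractions, paths["immune_fractions"])
    cohort.truth_labels.to_csv(paths["truth_labels"], sep="\t", index_label="sample")
    return paths
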