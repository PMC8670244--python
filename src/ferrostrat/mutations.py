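"""Per-group co-mutation networks, ferroptosis-role annotation and
driver-burden comparison.

Two genes mutated in the same patient form an 'edge'. Group-level edge
totals are reported both as distinct gene pairs (``unique_pairs``) and as
per-sample pair instances (``instances``, the sum of C(m_i, 2) over
samples); both are normalized by the group's sample count, which is the
arithmetic that turns raw edge totals into comparable per-sample burdens
(e.g. 147 edges over 25 samples -> 5.88).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComutationNetwork",
    "build_comutation_network",
    "normalized_edges",
    "round_half_up",
    "annotate_ferroptosis_roles",
    "fe_driver_burden",
    "group_overlap_classification",
    "mutation_prevalence",
]

ROLE_PRECEDENCE = ("driver", "suppressor", "marker")
ROLE_LABELS = {"driver": "Fe-driver", "suppressor": "Fe-suppressor", "marker": "Fe-marker"}


@dataclass
class ComutationNetwork:
    """Co-mutation network of one sample group."""

    group: str
    nodes: pd.DataFrame          # gene, frequency (#samples in group carrying it)
    edges: pd.DataFrame          # gene_a, gene_b, weight (#samples sharing the pair)
    edge_count: int
    n_samples: int

    @property
    def normalized_edges(self) -> float:
        return normalized_edges(self.edge_count, self.n_samples)

    def to_networkx(self):
        """Optional networkx.Graph view (unique pairs, weighted)."""
        import networkx as nx

        g = nx.Graph(group=self.group)
        for _, row in self.nodes.iterrows():
            g.add_node(row["gene"], frequency=int(row["frequency"]))
        for _, row in self.edges.iterrows():
            g.add_edge(row["gene_a"], row["gene_b"], weight=int(row["weight"]))
        return g


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (1.625 -> 1.63), as printed summaries expect."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(x).quantize(q, rounding=ROUND_HALF_UP))


def normalized_edges(edge_count: int, n_samples: int) -> float:
    """Edge count divided by group sample count (per-sample edge burden)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if edge_count < 0:
        raise ValueError("edge_count must be non-negative")
    return edge_count / n_samples


def _sample_gene_sets(mutations: pd.DataFrame) -> dict[str, set[str]]:
    return {s: set(g) for s, g in mutations.groupby("sample")["gene"]}


def build_comutation_network(mutations: pd.DataFrame, groups: pd.Series,
                             mode: str = "unique_pairs") -> dict[str, ComutationNetwork]:
    """One :class:`ComutationNetwork` per group.

    ``mode='unique_pairs'`` counts distinct unordered gene pairs co-mutated
    in at least one sample of the group; ``mode='instances'`` counts every
    within-sample pair, i.e. the sum over samples of C(m_i, 2). Samples with
    a group label but no mutation records still count toward ``n_samples``.
    """
    if mode not in ("unique_pairs", "instances"):
        raise ValueError(f"unknown mode {mode!r}")
    unlabeled = set(mutations["sample"]) - set(groups.index)
    if unlabeled:
        raise ValueError(f"sample(s) without group label: {sorted(unlabeled)[:5]}")
    per_sample = _sample_gene_sets(mutations)
    out: dict[str, ComutationNetwork] = {}
    for group in pd.unique(groups):
        members = groups.index[groups == group]
        pair_weight: dict[tuple[str, str], int] = {}
        gene_freq: dict[str, int] = {}
        instance_count = 0
        for s in members:
            genes = sorted(per_sample.get(s, ()))
            for g in genes:
                gene_freq[g] = gene_freq.get(g, 0) + 1
            instance_count += len(genes) * (len(genes) - 1) // 2
            for pair in itertools.combinations(genes, 2):
                pair_weight[pair] = pair_weight.get(pair, 0) + 1
        edges = pd.DataFrame(
            [(a, b, w) for (a, b), w in sorted(pair_weight.items())],
            columns=["gene_a", "gene_b", "weight"],
        )
        nodes = pd.DataFrame(sorted(gene_freq.items()), columns=["gene", "frequency"])
        edge_count = len(pair_weight) if mode == "unique_pairs" else instance_count
        out[str(group)] = ComutationNetwork(
            group=str(group), nodes=nodes, edges=edges,
            edge_count=edge_count, n_samples=len(members),
        )
    return out


def annotate_ferroptosis_roles(genes, ferrdb) -> pd.Series:
    """Map each gene to Fe-driver / Fe-suppressor / Fe-marker / Fe-negative.

    Membership is looked up in the driver, suppressor and marker sets of the
    gene-set collection, with precedence driver > suppressor > marker; genes
    absent from all three are Fe-negative.
    """
    role_sets = {role: ferrdb.genes_with_role(role) for role in ROLE_PRECEDENCE}
    out = {}
    for gene in genes:
        g = gene.upper()
        for role in ROLE_PRECEDENCE:
            if g in role_sets[role]:
                out[gene] = ROLE_LABELS[role]
                break
        else:
            out[gene] = "Fe-negative"
    return pd.Series(out, name="fe_role")


def fe_driver_burden(mutations: pd.DataFrame, groups: pd.Series, annotation: pd.Series):
    """Per-sample Fe-driver mutation counts and pairwise group comparisons.

    Returns (per-sample counts Series aligned to ``groups``, DataFrame of
    two-sided Welch t-tests between each pair of groups). Groups with fewer
    than two samples are skipped with a warning row (NaN statistics).
    """
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    driver_genes = set(annotation.index[annotation == "Fe-driver"])
    per_sample = mutations[mutations["gene"].isin(driver_genes)].groupby("sample").size()
    counts = pd.Series(0, index=groups.index, dtype=float, name="fe_driver_count")
    counts.loc[counts.index.intersection(per_sample.index)] = per_sample
    rows = []
    for g1, g2 in itertools.combinations(pd.unique(groups), 2):
        x = counts[groups == g1].to_numpy()
        y = counts[groups == g2].to_numpy()
        if len(x) < 2 or len(y) < 2:
            rows.append({"group_a": g1, "group_b": g2, "mean_a": np.nan, "mean_b": np.nan,
                         "t_statistic": np.nan, "p_value": np.nan, "note": "group too small"})
            continue
        t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append({"group_a": g1, "group_b": g2, "mean_a": float(x.mean()),
                     "mean_b": float(y.mean()), "t_statistic": float(t),
                     "p_value": float(p), "note": ""})
    return counts, pd.DataFrame(rows)


def group_overlap_classification(gene_sets: dict[str, set[str]]) -> pd.Series:
    """Partition the union of three groups' mutated genes into the 7
    exclusive membership categories (H, M, L, H&M, H&L, M&L, H&M&L).

    ``gene_sets`` maps the three group names to their mutated-gene sets;
    category labels join member group names with '&'.
    """
    if len(gene_sets) != 3:
        raise ValueError(f"need exactly 3 groups, got {len(gene_sets)}")
    names = list(gene_sets)
    categories = {}
    for r in (1, 2, 3):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(gene_sets[n] for n in combo))
            outside = set.union(set(), *(gene_sets[n] for n in names if n not in combo))
            categories["&".join(combo)] = len(inside - outside)
    return pd.Series(categories, name="n_genes")


def mutation_prevalence(n_mutated: int, n_total: int) -> float:
    """Percentage of variant-positive patients (e.g. 66 of 80 -> 82.5)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_mutated <= n_total:
        raise ValueError("n_mutated must be in [0, n_total]")
    return 100.0 * n_mutated / n_total
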