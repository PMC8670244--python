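"""PCA + K-means risk clustering and clustering evaluation.

The stratification recipe: min-max standardized expression of the 24-gene
ferroptosis panel is projected to two principal components, K-means (k
chosen by the elbow rule on the inertia curve) partitions the samples, and
the three clusters are named High/Middle/Low risk by their death
proportions. Six evaluation metrics (ARI, AMI, V-measure, Fowlkes-Mallows,
Silhouette, Calinski-Harabasz) are implemented here directly from their
contingency-table / dispersion definitions; scikit-learn provides the
K-means and PCA machinery but is deliberately not used for the metrics, so
the two can cross-check each other.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ClusteringConfig",
    "ClusterAssignment",
    "pca_project",
    "kmeans_fit",
    "elbow_select",
    "adjusted_rand_index",
    "adjusted_mutual_information",
    "v_measure",
    "fowlkes_mallows",
    "silhouette",
    "calinski_harabasz",
    "evaluate_clustering",
    "assign_risk_labels",
    "immune_composition_clusters",
]

RISK_ORDER = ("High", "Middle", "Low")


@dataclass
class ClusteringConfig:
    k: int = 3
    n_components: int = 2
    n_restarts: int = 10
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0
    k_range: tuple[int, ...] = tuple(range(2, 11))
    stability_reps: int = 20

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class ClusterAssignment:
    """Per-sample cluster labels plus centroids, inertia and 2-D coordinates.

    ``risk_labels`` (cluster index -> 'High'/'Middle'/'Low') is attached by
    :func:`assign_risk_labels` when k = 3.
    """

    labels: pd.Series
    centroids: np.ndarray
    inertia: float
    coordinates: pd.DataFrame | None = None
    risk_labels: dict[int, str] | None = None

    def risk_series(self) -> pd.Series:
        if self.risk_labels is None:
            raise ValueError("risk labels not assigned; call assign_risk_labels first")
        return self.labels.map(self.risk_labels).rename("risk")


def pca_project(matrix: pd.DataFrame, n_components: int = 2):
    """Project samples (columns of a genes x samples matrix) onto principal
    components.

    Mean-centered; component signs are fixed so each component's
    largest-magnitude loading is positive. Returns (coordinates DataFrame
    [samples x PCs], explained variance array, loadings array
    [components x genes]).
    """
    X = matrix.to_numpy(dtype=float).T  # samples x features
    if n_components > X.shape[1]:
        raise ValueError(f"n_components={n_components} exceeds feature count {X.shape[1]}")
    if n_components > X.shape[0]:
        raise ValueError(f"n_components={n_components} exceeds sample count {X.shape[0]}")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    components = pca.components_.copy()
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1
            coords[:, i] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=matrix.columns, columns=cols),
        pca.explained_variance_.copy(),
        components,
    )


def kmeans_fit(points: pd.DataFrame, config: ClusteringConfig | None = None, k: int | None = None) -> ClusterAssignment:
    """K-means (k-means++ seeding, Lloyd iterations, best of ``n_restarts``
    by inertia), deterministic under the config seed."""
    cfg = config or ClusteringConfig()
    k = k if k is not None else cfg.k
    X = points.to_numpy(dtype=float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of points {len(X)}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=cfg.n_restarts,
        max_iter=cfg.max_iter, tol=cfg.tol, random_state=cfg.seed,
    ).fit(X)
    coords = points if points.shape[1] == 2 else None
    return ClusterAssignment(
        labels=pd.Series(km.labels_, index=points.index, name="cluster"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        coordinates=coords,
    )


def elbow_select(points: pd.DataFrame, config: ClusteringConfig | None = None,
                 rel_threshold: float = 0.05):
    """Inertia curve over ``k_range`` and the elbow k*.

    k* maximizes the discrete second difference I(k-1) - 2 I(k) + I(k+1) of
    the best-of-restarts inertia curve; the curve is anchored at k=1 (total
    SSE about the grand mean) so an elbow at the low end of ``k_range`` is
    detectable. When the maximal second difference is below
    ``rel_threshold`` times the total inertia drop, no pronounced elbow
    exists and the returned flag says so.
    """
    cfg = config or ClusteringConfig()
    ks = sorted(cfg.k_range)
    if ks[0] < 2 or ks[-1] > len(points) - 1:
        raise ValueError(f"k_range {ks} not within [2, n-1]")
    if len(ks) < 2:
        raise ValueError("k_range too short for an elbow (need >= 2 values)")
    inertia = {k: kmeans_fit(points, cfg, k=k).inertia for k in ks}
    curve = pd.Series(inertia, name="inertia").rename_axis("k")
    X = points.to_numpy(dtype=float)
    ext = dict(inertia)
    if ks[0] == 2:
        ext[1] = float(((X - X.mean(axis=0)) ** 2).sum())
    second = {k: ext[k - 1] - 2 * ext[k] + ext[k + 1] for k in ks[:-1] if (k - 1) in ext}
    if not second:
        raise ValueError("k_range too short for an elbow")
    k_star = max(second, key=second.get)
    total_drop = max(ext.values()) - min(ext.values())
    pronounced = bool(total_drop > 0 and second[k_star] >= rel_threshold * total_drop)
    return curve, k_star, pronounced


# ---------------------------------------------------------------------------
# evaluation metrics, from their contingency / dispersion definitions


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    m = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(m, (ia, ib), 1)
    return m


def _comb2(x):
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def adjusted_rand_index(a, b) -> float:
    """ARI from the pair-counting contingency formula (chance-adjusted)."""
    m = _contingency(np.asarray(a), np.asarray(b))
    n = m.sum()
    sum_ij = _comb2(m).sum()
    sum_a = _comb2(m.sum(axis=1)).sum()
    sum_b = _comb2(m.sum(axis=0)).sum()
    total = _comb2(n)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # degenerate: single cluster or all singletons on both sides
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(m: np.ndarray) -> float:
    n = m.sum()
    a = m.sum(axis=1)
    b = m.sum(axis=0)
    mi = 0.0
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            if m[i, j] > 0:
                mi += (m[i, j] / n) * np.log(n * m[i, j] / (a[i] * b[j]))
    return float(mi)


def _expected_mutual_information(m: np.ndarray) -> float:
    """E[MI] under the permutation (hypergeometric) model with fixed margins."""
    n = int(m.sum())
    a = m.sum(axis=1).astype(int)
    b = m.sum(axis=0).astype(int)
    lgn = gammaln  # log Gamma; log(x!) = gammaln(x+1)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                # hypergeometric P(N_ij = nij) with fixed margins
                logp = (
                    lgn(ai + 1) - lgn(nij + 1) - lgn(ai - nij + 1)
                    + lgn(n - ai + 1) - lgn(bj - nij + 1) - lgn(n - ai - bj + nij + 1)
                    - (lgn(n + 1) - lgn(bj + 1) - lgn(n - bj + 1))
                )
                emi += (nij / n) * np.log(n * nij / (ai * bj)) * np.exp(logp)
    return float(emi)


def adjusted_mutual_information(a, b) -> float:
    """AMI with the arithmetic-mean normalizer: (MI - E[MI]) / (mean(H) - E[MI])."""
    m = _contingency(np.asarray(a), np.asarray(b))
    ha = _entropy(m.sum(axis=1))
    hb = _entropy(m.sum(axis=0))
    if ha == 0.0 and hb == 0.0:  # both partitions trivial
        return 1.0
    mi = _mutual_information(m)
    emi = _expected_mutual_information(m)
    denom = (ha + hb) / 2.0 - emi
    if denom == 0.0:
        return 1.0 if mi == emi else 0.0
    return float((mi - emi) / denom)


def v_measure(a, b) -> float:
    """Harmonic mean of homogeneity and completeness (beta = 1)."""
    m = _contingency(np.asarray(a), np.asarray(b))
    ha = _entropy(m.sum(axis=1))
    hb = _entropy(m.sum(axis=0))
    mi = _mutual_information(m)
    hom = 1.0 if hb == 0 else mi / hb   # H(B|A) = H(B) - MI; homogeneity of b given a
    com = 1.0 if ha == 0 else mi / ha
    if hom + com == 0:
        return 0.0
    return float(2 * hom * com / (hom + com))


def fowlkes_mallows(a, b) -> float:
    """FMI = TP / sqrt((TP+FP)(TP+FN)) over sample pairs."""
    m = _contingency(np.asarray(a), np.asarray(b))
    tp = _comb2(m).sum()
    pa = _comb2(m.sum(axis=1)).sum()
    pb = _comb2(m.sum(axis=0)).sum()
    if pa == 0 or pb == 0:
        return 0.0
    return float(tp / np.sqrt(pa * pb))


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient; NaN for a single-cluster labeling."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return float("nan")
    d = squareform(pdist(np.asarray(points, dtype=float)))
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        ai = d[i, own].sum() / (n_own - 1)
        bi = min(d[i, labels == c].mean() for c in uniq if c != labels[i])
        s[i] = (bi - ai) / max(ai, bi) if max(ai, bi) > 0 else 0.0
    return float(s.mean())


def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """Between/within dispersion ratio scaled by (n-k)/(k-1)."""
    X = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = len(X), len(uniq)
    if k < 2:
        return float("nan")
    overall = X.mean(axis=0)
    ssb = ssw = 0.0
    for c in uniq:
        mem = X[labels == c]
        cen = mem.mean(axis=0)
        ssb += len(mem) * ((cen - overall) ** 2).sum()
        ssw += ((mem - cen) ** 2).sum()
    if ssw == 0:
        return float("inf")
    return float((ssb / ssw) * (n - k) / (k - 1))


def evaluate_clustering(points: pd.DataFrame, labels_by_k: dict[int, pd.Series],
                        reference_mode: str = "stability",
                        reference_labels: pd.Series | None = None,
                        config: ClusteringConfig | None = None) -> pd.DataFrame:
    """Metric report (one row per k): ARI, AMI, V-measure, FMI against a
    reference, plus Silhouette and Calinski-Harabasz from the points.

    ``reference_mode``:

    * ``"stability"`` (default) — external metrics are the mean agreement
      between the full-data labeling and re-clusterings of seeded 80%
      subsamples (B = ``stability_reps``), evaluated on the shared samples.
      No ground truth is assumed; high values mean the partition is
      reproducible under perturbation, not that it is "correct".
    * ``"truth"`` — agreement with ``reference_labels`` (e.g. planted
      synthetic groups).
    * ``"survival_labels"`` — agreement with ``reference_labels`` derived
      from outcomes (e.g. the event indicator).
    """
    cfg = config or ClusteringConfig()
    if reference_mode not in ("stability", "truth", "survival_labels"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if reference_mode in ("truth", "survival_labels") and reference_labels is None:
        raise ValueError(f"reference_mode={reference_mode!r} requires reference_labels")
    X = points.to_numpy(dtype=float)
    rows = []
    rng = np.random.default_rng(cfg.seed)
    for k, labels in sorted(labels_by_k.items()):
        lab = labels.to_numpy()
        if reference_mode == "stability":
            ext = _stability_agreement(points, lab, k, cfg, rng)
        else:
            ref = reference_labels.loc[labels.index].to_numpy()
            ext = {
                "ARI": adjusted_rand_index(ref, lab),
                "AMI": adjusted_mutual_information(ref, lab),
                "V_measure": v_measure(ref, lab),
                "FMI": fowlkes_mallows(ref, lab),
            }
        rows.append({
            "k": k, **ext,
            "Silhouette": silhouette(X, lab),
            "Calinski_Harabasz": calinski_harabasz(X, lab),
        })
    return pd.DataFrame(rows).set_index("k")


def _stability_agreement(points: pd.DataFrame, full_labels: np.ndarray, k: int,
                         cfg: ClusteringConfig, rng: np.random.Generator) -> dict[str, float]:
    n = len(points)
    m = max(k + 1, int(round(0.8 * n)))
    acc: dict[str, list[float]] = {"ARI": [], "AMI": [], "V_measure": [], "FMI": []}
    for b in range(cfg.stability_reps):
        idx = rng.choice(n, size=m, replace=False)
        sub = points.iloc[idx]
        sub_cfg = ClusteringConfig(
            k=k, n_restarts=cfg.n_restarts, max_iter=cfg.max_iter,
            tol=cfg.tol, seed=int(rng.integers(2**31 - 1)),
        )
        re_lab = kmeans_fit(sub, sub_cfg, k=k).labels.to_numpy()
        ref = full_labels[idx]
        acc["ARI"].append(adjusted_rand_index(ref, re_lab))
        acc["AMI"].append(adjusted_mutual_information(ref, re_lab))
        acc["V_measure"].append(v_measure(ref, re_lab))
        acc["FMI"].append(fowlkes_mallows(ref, re_lab))
    return {k_: float(np.mean(v)) for k_, v in acc.items()}


# ---------------------------------------------------------------------------
# risk labeling and immune composition


def assign_risk_labels(assignment: ClusterAssignment, survival: pd.DataFrame) -> ClusterAssignment:
    """Name the k=3 clusters High/Middle/Low by death proportion.

    Clusters are ranked by event proportion descending; ties break by
    ascending median follow-up among the deceased (dying sooner = higher
    risk). Requires survival for at least one sample per cluster.
    """
    clusters = sorted(assignment.labels.unique())
    if len(clusters) != 3:
        raise ValueError(f"risk naming is defined for exactly 3 clusters, got {len(clusters)}")
    stats = []
    for c in clusters:
        members = assignment.labels.index[assignment.labels == c]
        surv = survival.loc[survival.index.intersection(members)]
        if surv.empty:
            raise ValueError(f"no survival records for cluster {c}")
        deaths = surv[surv["event"] == 1]
        med = float(deaths["time"].median()) if len(deaths) else float("inf")
        stats.append((c, surv["event"].mean(), med))
    ranked = sorted(stats, key=lambda t: (-t[1], t[2]))
    assignment.risk_labels = {c: RISK_ORDER[i] for i, (c, _, _) in enumerate(ranked)}
    return assignment


def immune_composition_clusters(fractions: pd.DataFrame, risk: pd.Series,
                                k: int = 5, seed: int = 0):
    """K-means (k=5) on the 22 immune-cell fraction vectors, crossed with
    risk groups.

    Returns (per-sample immune-cluster labels, risk x immune-cluster
    contingency table, per-risk-pair chi-square DataFrame with the test
    statistic, P and -log10 P).
    """
    from .io import IMMUNE_META_COLS

    frac_cols = [c for c in fractions.columns if c not in IMMUNE_META_COLS]
    X = fractions[frac_cols]
    if k > len(X):
        raise ValueError(f"k={k} exceeds sample count {len(X)}")
    cfg = ClusteringConfig(k=max(k, 2), seed=seed)
    labels = kmeans_fit(X, cfg, k=k).labels.rename("immune_cluster")
    risk = risk.loc[labels.index]
    table = pd.crosstab(risk, labels)
    rows = []
    for g1, g2 in itertools.combinations(sorted(risk.unique()), 2):
        sub = table.loc[[g1, g2]]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        if sub.shape[1] < 2:
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = chi2_contingency(sub.to_numpy())
        rows.append({"group_a": g1, "group_b": g2, "chi2": float(stat),
                     "p_value": float(p), "neg_log10_p": float(-np.log10(max(p, 1e-300)))})
    return labels, table, pd.DataFrame(rows)
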