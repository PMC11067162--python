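"""Clonal homogeneity, clone clustering, pseudotime and dosage trends.

Clonal homogeneity of a sample is the mean pairwise Pearson correlation of
its malignant cells' CNV profiles — fewer or more similar clones give higher
values. Pseudotime is a deterministic trajectory stand-in: PCA, a symmetric
k-nearest-neighbour graph with distance-weighted edges, and shortest-path
distance from a root cell set, scaled to [0, 1]. Dosage trends correlate a
gene's per-cell CNV score with pseudotime and characterise the top-decile
cells by origin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.sparse.csgraph import dijkstra
from scipy.stats import mannwhitneyu, pearsonr
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    statistic: float  # rank-sum statistic W of the first sample (midrank ties)
    p: float
    method: str
    degenerate: bool = False


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> RankSumResult:
    """Two-sample Wilcoxon rank-sum test.

    Exact enumeration when n_x + n_y <= 20 and there are no ties, otherwise
    a normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    w = float(pd.Series(combined).rank().to_numpy()[: len(x)].sum())
    if np.all(combined == combined[0]):
        return RankSumResult(statistic=w, p=1.0, method="degenerate", degenerate=True)
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return RankSumResult(statistic=w, p=float(res.pvalue), method=method)


# ---------------------------------------------------------------------------
# clonal homogeneity
# ---------------------------------------------------------------------------

@dataclass
class HomogeneityResult:
    table: pd.DataFrame  # sample, origin, mean_r, n_cells, n_pairs_skipped
    pairwise_p: pd.DataFrame  # origin x origin two-sided rank-sum p
    excluded_samples: list = field(default_factory=list)


def mean_pairwise_correlation(profiles: np.ndarray) -> tuple[float, int]:
    """Mean Pearson correlation over all unordered cell pairs; zero-variance
    profiles are skipped and the number of skipped pairs returned."""
    profiles = np.asarray(profiles, dtype=float)
    var = profiles.var(axis=1)
    ok = var > 0
    n_total_pairs = math.comb(profiles.shape[0], 2)
    kept = profiles[ok]
    if kept.shape[0] < 2:
        return np.nan, n_total_pairs
    C = np.corrcoef(kept)
    iu = np.triu_indices_from(C, k=1)
    n_skipped = n_total_pairs - math.comb(kept.shape[0], 2)
    return float(C[iu].mean()), n_skipped


def clonal_homogeneity(
    cnv_values: np.ndarray,
    sample_ids,
    malignant_mask,
    origins,
) -> HomogeneityResult:
    """Per-sample mean pairwise Pearson correlation of malignant-cell CNV
    profiles, grouped by origin, with two-sided rank-sum tests between
    origin groups. Samples with fewer than 2 malignant cells are excluded."""
    cnv_values = np.asarray(cnv_values, dtype=float)
    sample_ids = np.asarray(sample_ids)
    malignant_mask = np.asarray(malignant_mask, dtype=bool)
    origins = np.asarray(origins)
    rows = []
    excluded = []
    for s in pd.unique(sample_ids):
        mask = (sample_ids == s) & malignant_mask
        if mask.sum() < 2:
            logger.info("sample %s has <2 malignant cells; excluded from homogeneity", s)
            excluded.append(s)
            continue
        mean_r, skipped = mean_pairwise_correlation(cnv_values[mask])
        origin = origins[mask][0]
        rows.append(dict(sample=s, origin=origin, mean_r=mean_r,
                         n_cells=int(mask.sum()), n_pairs_skipped=skipped))
    table = pd.DataFrame(rows, columns=["sample", "origin", "mean_r", "n_cells",
                                        "n_pairs_skipped"])
    groups = {o: g["mean_r"].dropna().to_numpy() for o, g in table.groupby("origin")}
    names = sorted(groups)
    pw = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(groups[a]) and len(groups[b]):
                res = wilcoxon_rank_sum(groups[a], groups[b])
                pw.loc[a, b] = pw.loc[b, a] = res.p
    return HomogeneityResult(table=table, pairwise_p=pw, excluded_samples=excluded)


# ---------------------------------------------------------------------------
# pseudotime
# ---------------------------------------------------------------------------

@dataclass
class Pseudotime:
    values: pd.Series  # per-cell in [0, 1]; NaN = unreachable
    root_cells: pd.Index
    n_components: int
    k_neighbors: int
    n_unreachable: int = 0


def compute_pseudotime(
    X,
    root_cells,
    n_components: int = 10,
    k_neighbors: int = 15,
    cell_ids=None,
) -> Pseudotime:
    """Graph pseudotime from a root cell set.

    PCA to ``n_components``, symmetric k-NN graph with Euclidean edge
    lengths, shortest-path distance from the nearest root, scaled to [0, 1].
    If more than 5% of cells are unreachable, k is doubled (with a warning)
    until they are connected or k reaches the number of cells; remaining
    unreachable cells get NaN.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    ids = pd.Index(cell_ids) if cell_ids is not None else pd.RangeIndex(n)
    roots = pd.Index(root_cells)
    root_idx = ids.get_indexer(roots)
    if len(root_idx) == 0 or (root_idx < 0).any():
        raise ValueError("root cells empty or not present")
    nc = min(n_components, n - 1, X.shape[1])
    Z = PCA(n_components=nc, svd_solver="full").fit_transform(X) if nc >= 1 else X
    k = min(k_neighbors, n - 1)
    while True:
        G = kneighbors_graph(Z, n_neighbors=k, mode="distance", include_self=False)
        G = G.maximum(G.T)  # symmetrize
        dist = dijkstra(G, directed=False, indices=root_idx, min_only=True)
        unreachable = ~np.isfinite(dist)
        if unreachable.mean() <= 0.05 or k >= n - 1:
            break
        k = min(2 * k, n - 1)
        logger.warning("pseudotime graph disconnected; increasing k to %d", k)
    if unreachable.any():
        logger.warning("%d cells unreachable from the root set", int(unreachable.sum()))
    finite = dist[~unreachable]
    scale = finite.max() if len(finite) and finite.max() > 0 else 1.0
    vals = dist / scale
    vals[unreachable] = np.nan
    return Pseudotime(
        values=pd.Series(vals, index=ids, name="pseudotime"),
        root_cells=roots, n_components=nc, k_neighbors=k,
        n_unreachable=int(unreachable.sum()),
    )


# ---------------------------------------------------------------------------
# dosage trends
# ---------------------------------------------------------------------------

@dataclass
class DosageTrendResult:
    gene: str
    r: float
    p: float
    top_decile_cells: pd.Index
    top_decile_composition: pd.Series  # origin -> fraction, sums to 1
    compare_pair: tuple | None
    compare_p: float
    undefined: bool = False


def dosage_trend(
    gene_score: pd.Series,
    pseudotime: pd.Series,
    origins: pd.Series,
    compare_pair: tuple | None = ("Lm", "Pm1"),
    gene: str | None = None,
) -> DosageTrendResult:
    """Correlate a gene's per-cell CNV score with pseudotime.

    Pearson r with two-sided t-distribution p; top decile = the ceil(0.10 n)
    highest-scoring cells (boundary ties included) with its origin
    composition; two-sided rank-sum comparison of scores between the named
    origin pair. Constant scores give an undefined (flagged) result.
    """
    gene = gene or (gene_score.name if hasattr(gene_score, "name") else "gene")
    score = pd.Series(gene_score).astype(float)
    pt = pd.Series(pseudotime).reindex(score.index)
    ori = pd.Series(origins).reindex(score.index)
    ok = score.notna() & pt.notna()
    score, pt, ori = score[ok], pt[ok], ori[ok]
    n = len(score)
    if n < 3 or score.nunique() == 1:
        logger.warning("dosage trend for %s undefined (constant or tiny input)", gene)
        return DosageTrendResult(
            gene=gene, r=np.nan, p=np.nan, top_decile_cells=pd.Index([]),
            top_decile_composition=pd.Series(dtype=float), compare_pair=compare_pair,
            compare_p=np.nan, undefined=True,
        )
    r, p = pearsonr(score, pt)
    k = math.ceil(0.10 * n)
    threshold = np.sort(score.to_numpy())[::-1][k - 1]
    top = score.index[score >= threshold]  # ties at the boundary included
    comp = ori.loc[top].value_counts(normalize=True).sort_index()
    cp = np.nan
    if compare_pair is not None:
        a, b = compare_pair
        xa = score[ori == a].to_numpy()
        xb = score[ori == b].to_numpy()
        if len(xa) and len(xb):
            cp = wilcoxon_rank_sum(xa, xb).p
    return DosageTrendResult(
        gene=gene, r=float(r), p=float(p), top_decile_cells=top,
        top_decile_composition=comp, compare_pair=compare_pair, compare_p=cp,
    )


# ---------------------------------------------------------------------------
# clone clustering
# ---------------------------------------------------------------------------

def hierarchical_cluster_cnv(cnv_values: np.ndarray, n_clusters: int):
    """Agglomerative (Ward, Euclidean) clustering of cells by CNV profile.

    Returns (labels in 1..n_clusters, linkage matrix). Deterministic given
    input order; scipy breaks ties by lowest observation index.
    """
    cnv_values = np.asarray(cnv_values, dtype=float)
    n = cnv_values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds n_cells={n}")
    Z = sch.linkage(cnv_values, method="ward")
    labels = sch.fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, Z
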