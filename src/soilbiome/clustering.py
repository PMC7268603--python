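"""Ward clustering of sites, cut-level selection and post-hoc rank tests.

Sites are clustered by Ward's minimum-variance criterion applied to an
arbitrary dissimilarity matrix (the Ward.D2 convention: the Lance-Williams
update operates on squared dissimilarities).  A single cut level is chosen
by voting across three diagnostics computed for every candidate number of
clusters: mean silhouette width, the correlation between the dissimilarity
matrix and the binary same/different-cluster matrix, and a species-fidelity
profile (how many OTUs are good indicators of some cluster).  Dunn's
rank-based post-hoc test characterises how soil variables differ among the
resulting clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import norm, rankdata
from skbio import DistanceMatrix

__all__ = [
    "ClusterTree",
    "ClusterSolution",
    "ward_cluster",
    "cut_tree",
    "silhouette",
    "matrix_correlation",
    "fidelity_profile",
    "select_cut_level",
    "dunn_test",
]


@dataclass(frozen=True)
class ClusterTree:
    """Agglomeration history in SciPy linkage form plus the leaf IDs."""

    linkage: np.ndarray  # (n-1, 4): left, right, height, size
    leaf_ids: tuple

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass(frozen=True)
class ClusterSolution:
    """A flat partition of sites into ``k`` clusters."""

    k: int
    labels: pd.Series  # site id -> cluster label (1..k, first-appearance order)
    source: str = "community"

    def __post_init__(self):
        found = self.labels.nunique()
        if found != self.k:
            raise ValueError(f"expected {self.k} non-empty clusters, found {found}")

    def members(self, cluster) -> pd.Index:
        return self.labels.index[self.labels == cluster]


def ward_cluster(dist: DistanceMatrix) -> ClusterTree:
    """Agglomerate sites under Ward's minimum-variance criterion (Ward.D2).

    The Lance-Williams update is applied to squared dissimilarities:
    d(AB, C)^2 = [(a+c) d(A,C)^2 + (b+c) d(B,C)^2 - c d(A,B)^2] / (a+b+c).
    Deterministic; ties are broken by the lexicographically lowest pair of
    cluster indices.  Heights are non-decreasing (Ward is reducible, so the
    greedy merge order produces no inversions).
    """
    if isinstance(dist, DistanceMatrix):
        d, ids = np.asarray(dist.data, dtype=float), tuple(dist.ids)
    else:  # raw square array: validate it ourselves
        d = np.asarray(dist, dtype=float)
        ids = tuple(str(i) for i in range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sites to cluster")

    d2 = d.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    sizes = np.ones(n)
    cluster_id = np.arange(n)  # linkage numbering: leaves 0..n-1, merges n..2n-2
    active = np.ones(n, dtype=bool)
    Z = np.empty((n - 1, 4))
    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], d2, np.inf)
        # argmin on the row-major flattened upper triangle -> lowest (i, j)
        iu = np.triu_indices(n, k=1)
        flat = masked[iu]
        best = int(np.argmin(flat))
        i, j = int(iu[0][best]), int(iu[1][best])
        h2 = d2[i, j]
        height = np.sqrt(h2)
        a, b = sizes[i], sizes[j]
        lo, hi = sorted((cluster_id[i], cluster_id[j]))
        Z[step] = (lo, hi, height, a + b)
        # Lance-Williams update into slot i; retire slot j
        others = active.copy()
        others[i] = others[j] = False
        c = sizes[others]
        new = ((a + c) * d2[i, others] + (b + c) * d2[j, others] - c * h2) / (a + b + c)
        d2[i, others] = new
        d2[others, i] = new
        active[j] = False
        sizes[i] = a + b
        cluster_id[i] = n + step
    order = np.argsort(Z[:, 2], kind="stable")
    if not np.array_equal(order, np.arange(n - 1)):  # pragma: no cover - Ward has no inversions
        raise RuntimeError("unexpected height inversion in Ward agglomeration")
    return ClusterTree(linkage=Z, leaf_ids=ids)


def cut_tree(tree: ClusterTree, k: int, source: str = "community") -> ClusterSolution:
    """Cut the dendrogram into ``k`` clusters (drop the k-1 highest merges).

    Cluster labels 1..k are assigned in order of first leaf appearance.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = sch.cut_tree(tree.linkage, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for pos, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[pos] = relabel[lab]
    return ClusterSolution(
        k=k, labels=pd.Series(labels, index=list(tree.leaf_ids)), source=source
    )


def _aligned_codes(dist: DistanceMatrix, solution: ClusterSolution) -> np.ndarray:
    labels = solution.labels.loc[list(dist.ids)]
    return labels.to_numpy()


def silhouette(
    dist: DistanceMatrix, solution: ClusterSolution
) -> tuple[pd.Series, float]:
    """Per-site silhouette widths s(i) = (b - a) / max(a, b) and their mean.

    a(i) is the mean distance to the other members of i's cluster and b(i)
    the smallest mean distance to any other cluster.  Members of singleton
    clusters receive s(i) = 0 by convention.
    """
    if solution.k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    codes = _aligned_codes(dist, solution)
    d = dist.data
    uniq = np.unique(codes)
    widths = np.zeros(len(codes))
    for idx in range(len(codes)):
        own = codes[idx]
        own_mask = codes == own
        if own_mask.sum() == 1:
            widths[idx] = 0.0
            continue
        a = d[idx, own_mask].sum() / (own_mask.sum() - 1)
        b = min(d[idx, codes == g].mean() for g in uniq if g != own)
        denom = max(a, b)
        widths[idx] = 0.0 if denom == 0 else (b - a) / denom
    series = pd.Series(widths, index=list(dist.ids))
    return series, float(series.mean())


def matrix_correlation(dist: DistanceMatrix, solution: ClusterSolution) -> float:
    """Pearson correlation between dissimilarity and cluster separation.

    Over the strict lower triangle, correlates d(i, j) with the binary
    indicator [i and j are in different clusters]; high values mean the
    partition separates dissimilar sites.
    """
    if solution.k < 2:
        raise ValueError("matrix correlation requires at least 2 clusters")
    codes = _aligned_codes(dist, solution)
    iu = np.triu_indices(len(codes), k=1)
    dvec = dist.data[iu]
    bvec = (codes[iu[0]] != codes[iu[1]]).astype(float)
    if np.ptp(bvec) == 0:
        raise ValueError("binary cluster matrix is constant; correlation undefined")
    if np.ptp(dvec) == 0:
        raise ValueError("distance matrix is constant; correlation undefined")
    return float(np.corrcoef(dvec, bvec)[0, 1])


def fidelity_profile(
    table: pd.DataFrame, solution: ClusterSolution, indval_threshold: float = 0.25
) -> tuple[int, float]:
    """Count and summed value of OTUs whose best IndVal reaches a threshold.

    IndVal for an OTU is max over clusters of A*B (specificity times
    fidelity, see :mod:`soilbiome.indicators`).  Used as the
    species-fidelity criterion when comparing candidate cut levels.
    """
    if not 0 <= indval_threshold <= 1:
        raise ValueError("indval_threshold must be in [0, 1]")
    from .indicators import indicator_scores

    scores = indicator_scores(table, solution)
    indval = scores.best["indval_best"]
    passing = indval[indval >= indval_threshold]
    return int(len(passing)), float(passing.sum())


def select_cut_level(
    tree: ClusterTree,
    dist: DistanceMatrix,
    table: pd.DataFrame | None,
    k_range: Iterable[int],
    min_cluster_size: int = 5,
    indval_threshold: float = 0.25,
    source: str = "community",
) -> tuple[int, pd.DataFrame]:
    """Choose a cut level by voting across the per-k diagnostics.

    For every candidate k the mean silhouette width, the matrix
    correlation, and (when an abundance table is supplied) the fidelity
    profile are computed.  Candidates whose smallest cluster is below
    ``min_cluster_size`` are excluded so every cluster keeps enough sites
    for downstream modelling.  The chosen k is best on the most criteria;
    ties go to the smaller k.  The full diagnostics table is returned for
    audit.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = tree.n_leaves
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    rows = []
    for k in ks:
        sol = cut_tree(tree, k, source=source)
        sizes = sol.labels.value_counts()
        _, mean_sil = silhouette(dist, sol)
        mcor = matrix_correlation(dist, sol)
        if table is not None:
            fid_count, fid_sum = fidelity_profile(table, sol, indval_threshold)
        else:
            fid_count, fid_sum = np.nan, np.nan
        rows.append(
            {
                "k": k,
                "mean_silhouette": mean_sil,
                "matrix_correlation": mcor,
                "fidelity_count": fid_count,
                "fidelity_sum": fid_sum,
                "min_cluster_size": int(sizes.min()),
                "cluster_sizes": "/".join(map(str, sizes.sort_index())),
            }
        )
    diag = pd.DataFrame(rows).set_index("k")
    feasible = diag[diag["min_cluster_size"] >= min_cluster_size]
    if feasible.empty:
        raise ValueError(
            f"no candidate k satisfies min_cluster_size={min_cluster_size}; "
            "consider lowering it"
        )
    votes = pd.Series(0, index=feasible.index)
    criteria = [feasible["mean_silhouette"], feasible["matrix_correlation"]]
    if table is not None:
        # lexicographic: count first, summed IndVal breaks count ties
        fid = feasible["fidelity_count"] + feasible["fidelity_sum"] / (
            1.0 + feasible["fidelity_sum"].abs().max()
        )
        criteria.append(fid)
    for crit in criteria:
        votes[crit[crit == crit.max()].index] += 1
    best = votes[votes == votes.max()].index.min()
    diag = diag.assign(feasible=diag.index.isin(feasible.index))
    diag.loc[feasible.index, "votes"] = votes
    return int(best), diag.reset_index()


def dunn_test(
    values, groups, adjustment: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's post-hoc test on Kruskal-Wallis ranks with tie correction.

    All observations are ranked jointly with mid-ranks for ties.  For each
    group pair the statistic is
    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)),
    where T = sum(t^3 - t) over tie groups; two-sided p from the standard
    normal, Bonferroni-adjusted over all pairs by default.
    """
    if adjustment != "bonferroni":
        raise ValueError("only Bonferroni adjustment is supported")
    vals = np.asarray(pd.Series(values), dtype=float)
    grp = np.asarray(pd.Series(groups))
    if len(vals) != len(grp):
        raise ValueError("values and groups must have equal length")
    uniq, codes = np.unique(grp, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("Dunn's test needs at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 observations")
    if np.ptp(vals) == 0:
        raise ValueError("all values identical: ranks are degenerate")
    n_total = len(vals)
    ranks = rankdata(vals)
    _, tie_counts = np.unique(vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks = np.array([ranks[codes == g].mean() for g in range(len(uniq))])
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            se = np.sqrt(var_base * (1.0 / counts[i] + 1.0 / counts[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * norm.sf(abs(z))
            rows.append({"group1": uniq[i], "group2": uniq[j], "z": z, "p_value": p})
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_adjusted"] = np.minimum(1.0, out["p_value"] * m)
    return out
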