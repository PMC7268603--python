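"""Community-matrix preprocessing and dissimilarity statistics.

Operations on site-by-OTU abundance tables held as :class:`pandas.DataFrame`
(rows = samples or sites, columns = OTUs): rarefaction to a common depth,
replicate averaging, Bray-Curtis dissimilarity, and one-way PERMANOVA with
pairwise post-hoc tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PermanovaResult",
    "rarefy",
    "average_replicates",
    "bray_curtis",
    "permanova",
    "pairwise_permanova",
    "adjust_pvalues",
]


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: ``"bonferroni"`` or ``"bh"`` (step-up)."""
    if method not in {"bonferroni", "bh"}:
        raise ValueError(f"unknown adjustment {method!r}")
    stats_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
    return multipletests(np.asarray(pvalues, dtype=float), method=stats_method)[1]


def _check_table(table: pd.DataFrame) -> None:
    if table.index.has_duplicates:
        raise ValueError("duplicate row IDs in OTU table")
    if table.columns.has_duplicates:
        raise ValueError("duplicate OTU IDs in OTU table")
    if table.isna().any().any():
        raise ValueError("OTU table contains missing entries")
    if (table.values < 0).any():
        raise ValueError("OTU table contains negative values")


def rarefy(table: pd.DataFrame, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample each row without replacement to exactly ``depth`` reads.

    Rows whose total is below ``depth`` are dropped with a logged warning;
    this mirrors standard practice of retaining only samples that reach the
    rarefaction depth.  Counts must be integers.

    Parameters
    ----------
    table:
        Sample-by-OTU integer count table.
    depth:
        Target number of reads per sample (>= 1).
    seed:
        Seed for the subsampling random stream; one draw per retained row.

    Returns
    -------
    pandas.DataFrame
        Integer table whose rows each sum to ``depth``.
    """
    _check_table(table)
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    values = table.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError("rarefy requires integer counts")
    values = np.round(values).astype(np.int64)
    totals = values.sum(axis=1)
    keep = totals >= depth
    dropped = table.index[~keep]
    if len(dropped):
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped),
            depth,
            ", ".join(map(str, dropped[:10])),
        )
    if not keep.any():
        raise ValueError(f"all rows have fewer than {depth} reads; nothing to rarefy")
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), values.shape[1]), dtype=np.int64)
    for i, row in enumerate(values[keep]):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=table.index[keep], columns=table.columns)


def average_replicates(
    table: pd.DataFrame, sample_to_site: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Average replicate rows into one representative row per site.

    Every row ID of ``table`` must appear in ``sample_to_site``.  Output
    sites appear in order of first occurrence among the input rows.
    """
    _check_table(table)
    mapping = pd.Series(sample_to_site)
    missing = table.index.difference(mapping.index)
    if len(missing):
        raise KeyError(
            f"sample ID(s) not in replicate mapping: {', '.join(map(str, missing[:10]))}"
        )
    sites = mapping.loc[table.index]
    averaged = table.groupby(sites.to_numpy(), sort=False).mean()
    averaged.index.name = "site_id"
    return averaged


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all row pairs.

    d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk), in [0, 1].
    """
    _check_table(table)
    if len(table) < 2:
        raise ValueError("need at least 2 rows to compute dissimilarities")
    row_sums = table.sum(axis=1)
    empty = row_sums[row_sums == 0]
    if len(empty):
        raise ValueError(
            f"row(s) with all-zero abundance: {', '.join(map(str, empty.index[:10]))}"
        )
    condensed = pdist(table.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in table.index])


@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA summary (distance-based pseudo-F test)."""

    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    group_labels: tuple
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ss_total: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["between", "within", "total"],
                "df": [self.df_between, self.df_within, self.df_between + self.df_within],
                "SS": [self.ss_between, self.ss_within, self.ss_total],
                "pseudo_F": [self.pseudo_F, np.nan, np.nan],
                "R2": [self.R2, np.nan, np.nan],
                "p": [self.p_value, np.nan, np.nan],
            }
        )


def _align_groups(dist: DistanceMatrix, groups) -> np.ndarray:
    """Return group labels ordered like ``dist.ids``."""
    if isinstance(groups, pd.Series):
        return groups.loc[list(dist.ids)].to_numpy()
    if isinstance(groups, Mapping):
        return np.asarray([groups[i] for i in dist.ids])
    arr = np.asarray(groups)
    if len(arr) != len(dist.ids):
        raise ValueError("groups length does not match distance matrix")
    return arr


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        ss += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Uses the distance-based sum-of-squares partition
    SS_total = (1/N) sum_{i<j} d_ij^2,
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2,
    pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)),
    with significance by free permutation of the group labels and the
    (1 + count) / (1 + n_permutations) convention, so p is never zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = _align_groups(dist, groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(codes)
    small = uniq[counts < 2]
    if len(small):
        raise ValueError(f"group(s) with fewer than 2 sites: {', '.join(map(str, small))}")
    d = dist.data
    offdiag = d[np.triu_indices_from(d, k=1)]
    if np.ptp(offdiag) == 0:
        raise ValueError("constant distance matrix: pseudo-F is undefined")
    d2 = d**2
    n = len(labels)
    a = len(uniq)
    ss_total = d2[np.triu_indices_from(d2, k=1)].sum() / n
    ss_within = _ss_within(d2, codes, a)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        raise ValueError("within-group sum of squares is zero: pseudo-F is undefined")
    df_b, df_w = a - 1, n - a
    f_obs = (ss_between / df_b) / (ss_within / df_w)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        ssw = _ss_within(d2, perm, a)
        ssb = ss_total - ssw
        if ssw <= 0 or (ssb / df_b) / (ssw / df_w) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=f_obs,
        R2=ss_between / ss_total,
        p_value=p,
        n_permutations=n_permutations,
        group_labels=tuple(uniq),
        df_between=df_b,
        df_within=df_w,
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_total,
    )


def pairwise_permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    adjustment: str = "bonferroni",
    seed: int | None = None,
) -> pd.DataFrame:
    """PERMANOVA on every pair of groups with multiple-testing adjustment.

    ``adjustment`` is ``"bonferroni"`` (default) or ``"bh"``
    (Benjamini-Hochberg step-up).  Returns one row per group pair with raw
    and adjusted p-values.
    """
    if adjustment not in {"bonferroni", "bh"}:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    labels = _align_groups(dist, groups)
    uniq = np.unique(labels)
    ids = np.asarray(dist.ids)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            mask = np.isin(labels, [uniq[i], uniq[j]])
            sub = dist.filter(ids[mask])
            res = permanova(
                sub,
                labels[mask],
                n_permutations=n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append(
                {
                    "group1": uniq[i],
                    "group2": uniq[j],
                    "pseudo_F": res.pseudo_F,
                    "R2": res.R2,
                    "p_value": res.p_value,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p_value"].to_numpy(), adjustment)
    return out
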