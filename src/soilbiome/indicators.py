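"""Specificity-fidelity indicator statistics for OTU screening.

For each OTU k and cluster g two components are computed:

* specificity A(k, g): the group-size-corrected share of the OTU's
  abundance concentrated in g — mean abundance in g divided by the sum of
  the per-cluster mean abundances (so A sums to 1 over clusters);
* fidelity B(k, g): the fraction of sites in g where the OTU occurs.

Their product A*B is the indicator value (IndVal).  OTUs with a cluster in
which both components exceed chosen thresholds are retained as model
features, drastically shrinking the predictor set while keeping the taxa
that discriminate between community (or chemistry) clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterSolution

__all__ = ["IndicatorScores", "indicator_scores", "select_indicator_otus"]


@dataclass(frozen=True)
class IndicatorScores:
    """Per (OTU, cluster) specificity/fidelity and per-OTU best summary."""

    A: pd.DataFrame  # otu x cluster specificity, rows sum to 1 (0 if absent)
    B: pd.DataFrame  # otu x cluster presence fidelity in [0, 1]
    best: pd.DataFrame  # per otu: best_cluster, A_best, B_best, indval_best
    absent_otus: tuple  # OTUs with zero abundance everywhere (flagged)

    def to_frame(self) -> pd.DataFrame:
        long = (
            self.A.stack()
            .rename("A")
            .to_frame()
            .join(self.B.stack().rename("B"))
            .reset_index()
        )
        long.columns = ["otu_id", "cluster", "A", "B"]
        return long


def indicator_scores(table: pd.DataFrame, solution: ClusterSolution) -> IndicatorScores:
    """Compute specificity A and fidelity B for every (OTU, cluster) pair.

    ``table`` rows are sites aligned with ``solution.labels``; abundance may
    be averaged (non-integer).  OTUs absent from every site get A = 0 for
    all clusters and are flagged in ``absent_otus``.
    """
    if solution.k < 2:
        raise ValueError("indicator scores need at least 2 clusters")
    labels = solution.labels.loc[table.index]
    clusters = sorted(labels.unique())
    if len(clusters) != solution.k:
        raise ValueError("solution has empty clusters on this table")
    means = table.groupby(labels.to_numpy()).mean().T  # otu x cluster
    means = means[clusters]
    presence = (table > 0).groupby(labels.to_numpy()).mean().T[clusters]
    totals = means.sum(axis=1)
    absent = totals == 0
    A = means.divide(totals.where(~absent, 1.0), axis=0)
    A[absent] = 0.0
    indval = A * presence
    best_cluster = indval.idxmax(axis=1)
    best = pd.DataFrame(
        {
            "best_cluster": best_cluster,
            "A_best": A.to_numpy()[np.arange(len(A)), indval.to_numpy().argmax(axis=1)],
            "B_best": presence.to_numpy()[
                np.arange(len(A)), indval.to_numpy().argmax(axis=1)
            ],
            "indval_best": indval.max(axis=1),
        },
        index=A.index,
    )
    return IndicatorScores(
        A=A,
        B=presence,
        best=best,
        absent_otus=tuple(A.index[absent]),
    )


def select_indicator_otus(
    scores: IndicatorScores, a_min: float, b_min: float
) -> list:
    """Select OTUs with some cluster where A > a_min and B > b_min (strict).

    Flagged all-absent OTUs are never selected.  The result is ordered by
    descending best IndVal (max over clusters of A*B), ties broken by OTU
    ID, so the strongest indicators come first.
    """
    for name, t in (("a_min", a_min), ("b_min", b_min)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    passing = ((scores.A > a_min) & (scores.B > b_min)).any(axis=1)
    passing[list(scores.absent_otus)] = False
    chosen = scores.best.loc[passing, "indval_best"]
    order = sorted(chosen.index, key=lambda o: (-chosen[o], str(o)))
    return list(order)
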