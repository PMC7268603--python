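"""Random-forest prediction of land use, chemistry clusters and soil variables.

Sites are split 80/20 with stratified random sampling (so every land use or
cluster keeps its share in the training set), random forests with the
field's customary defaults (500 trees, sqrt(p) candidate features per split
for classification, p/3 for regression) are fitted on indicator-OTU
features, and predictions are evaluated with confusion matrices or with an
ordinary least-squares regression of predicted on actual values (slope and
adjusted R^2 close to 1 indicate a good model).  Variable importance is
measured by explicit permutation of one feature at a time on evaluation
data, expressed as the percentage increase in error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "ClassificationResult",
    "RegressionEval",
    "ImportanceTable",
    "stratified_split",
    "fit_classifier",
    "fit_regressor",
    "evaluate_classification",
    "evaluate_regression",
    "permutation_importance",
    "aggregate_importance_by_phylum",
    "top_otu_overlap",
    "repeated_splits",
]


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple
    test_ids: tuple
    stratum: pd.Series
    fraction: float
    seed: int | None


def stratified_split(
    metadata: pd.DataFrame | pd.Series,
    stratum_key: str | None = None,
    fraction: float = 0.8,
    seed: int | None = None,
) -> SplitSpec:
    """Sample a train fraction within every stratum, without replacement.

    ``metadata`` is a site-indexed DataFrame (with ``stratum_key`` naming
    the stratification column) or a site -> stratum Series.  The per-stratum
    train count is round(fraction * n) with ties rounded up, so the split
    is deterministic under a seed and within one site of the exact
    fraction.
    """
    if isinstance(metadata, pd.Series):
        strata = metadata
    else:
        if stratum_key is None:
            raise ValueError("stratum_key is required for DataFrame metadata")
        strata = metadata[stratum_key]
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    singletons = strata.value_counts()
    bad = singletons[singletons < 2]
    if len(bad):
        raise ValueError(
            f"stratum(s) with a single site: {', '.join(map(str, bad.index))}"
        )
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for stratum in sorted(strata.unique(), key=str):
        ids = list(strata.index[strata == stratum])
        n_train = int(np.floor(fraction * len(ids) + 0.5))  # nearest, ties up
        n_train = min(max(n_train, 1), len(ids) - 1)  # keep both sides non-empty
        picked = rng.choice(len(ids), size=n_train, replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        mask[picked] = True
        train.extend(np.asarray(ids)[mask])
        test.extend(np.asarray(ids)[~mask])
    return SplitSpec(
        train_ids=tuple(train),
        test_ids=tuple(test),
        stratum=strata,
        fraction=fraction,
        seed=seed,
    )


def _check_disjoint(train_index, test_index) -> None:
    overlap = set(train_index) & set(test_index)
    if overlap:
        raise ValueError(f"train/test leakage: {sorted(overlap)[:10]}")


def fit_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    hyperparams: Mapping | None = None,
) -> RandomForestClassifier:
    """Random-forest classifier: 500 trees, sqrt(p) features per split."""
    labels = labels.loc[features.index]
    if labels.nunique() < 2:
        raise ValueError("classification needs at least 2 classes in the training data")
    params = dict(
        n_estimators=500,
        max_features="sqrt",
        oob_score=True,
        random_state=0,
        n_jobs=1,
    )
    params.update(hyperparams or {})
    model = RandomForestClassifier(**params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny forests emit OOB coverage warnings
        model.fit(features.to_numpy(), labels.to_numpy())
    model.feature_ids_ = tuple(features.columns)
    model.train_ids_ = tuple(features.index)
    return model


def fit_regressor(
    features: pd.DataFrame,
    target: pd.Series,
    hyperparams: Mapping | None = None,
) -> RandomForestRegressor:
    """Random-forest regressor: 500 trees, p/3 features per split."""
    target = target.loc[features.index].astype(float)
    if target.std(ddof=0) == 0:
        raise ValueError("regression target has zero variance")
    params = dict(
        n_estimators=500,
        max_features=1.0 / 3.0,
        oob_score=True,
        random_state=0,
        n_jobs=1,
    )
    params.update(hyperparams or {})
    model = RandomForestRegressor(**params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(features.to_numpy(), target.to_numpy())
    model.feature_ids_ = tuple(features.columns)
    model.train_ids_ = tuple(features.index)
    return model


@dataclass(frozen=True)
class ClassificationResult:
    confusion: pd.DataFrame  # true x predicted counts
    accuracy: float
    per_class_recall: pd.Series
    predictions: pd.Series


def evaluate_classification(
    model: RandomForestClassifier,
    test_features: pd.DataFrame,
    test_labels: pd.Series,
) -> ClassificationResult:
    """Confusion matrix and accuracy on held-out sites."""
    _check_disjoint(model.train_ids_, test_features.index)
    test_labels = test_labels.loc[test_features.index]
    unseen = set(test_labels.unique()) - set(model.classes_)
    if unseen:
        logger.warning("test label(s) unseen in training: %s", sorted(unseen))
    pred = pd.Series(model.predict(test_features.to_numpy()), index=test_features.index)
    classes = sorted(set(model.classes_) | set(test_labels.unique()), key=str)
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(test_labels, pred):
        confusion.loc[t, p] += 1
    accuracy = float(np.trace(confusion.to_numpy()) / confusion.to_numpy().sum())
    row_sums = confusion.sum(axis=1)
    recall = (pd.Series(np.diag(confusion), index=classes) / row_sums.replace(0, np.nan))
    return ClassificationResult(
        confusion=confusion,
        accuracy=accuracy,
        per_class_recall=recall,
        predictions=pred,
    )


@dataclass(frozen=True)
class RegressionEval:
    predictions: pd.Series
    slope: float
    intercept: float
    r2: float
    adj_R2: float
    n: int


def evaluate_regression(
    model: RandomForestRegressor,
    test_features: pd.DataFrame,
    test_target: pd.Series,
) -> RegressionEval:
    """OLS of predicted (response) on actual (explanatory) values.

    Returns the slope, intercept and adjusted R^2
    (1 - (1 - R^2)(n - 1)/(n - 2)); both slope and adjusted R^2 near 1
    indicate accurate, unbiased prediction.
    """
    _check_disjoint(model.train_ids_, test_features.index)
    test_target = test_target.loc[test_features.index].astype(float)
    if len(test_target) < 3:
        raise ValueError("need at least 3 test sites for regression evaluation")
    if test_target.std(ddof=0) == 0:
        raise ValueError("actual values have zero variance")
    pred = pd.Series(model.predict(test_features.to_numpy()), index=test_features.index)
    if np.ptp(pred.to_numpy()) == 0:
        slope, intercept, r = 0.0, float(pred.iloc[0]), 0.0
    else:
        res = stats.linregress(test_target.to_numpy(), pred.to_numpy())
        slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    n = len(test_target)
    r2 = r**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionEval(
        predictions=pred, slope=slope, intercept=intercept, r2=r2, adj_R2=adj, n=n
    )


@dataclass(frozen=True)
class ImportanceTable:
    table: pd.DataFrame  # otu_id, importance (% increase in error), rank
    top_k: tuple
    metric: str  # "mse" or "error_rate"


def permutation_importance(
    model,
    data: pd.DataFrame,
    target_or_labels: pd.Series,
    n_repeats: int = 10,
    seed: int | None = None,
    top_k: int = 15,
) -> ImportanceTable:
    """Percent increase in error when one feature's values are permuted.

    For every feature, importance = mean over repeats of
    (error after permuting that column - baseline error) / baseline error
    * 100, with mean squared error for regressors and misclassification
    rate for classifiers, computed on the supplied evaluation data.  If the
    baseline error is zero the absolute increase (x100) is reported.  Ranks
    break ties by OTU ID; ``top_k`` lists the leading features.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = target_or_labels.loc[data.index]
    X = data.to_numpy()
    is_classifier = hasattr(model, "classes_")

    def err(Xm: np.ndarray) -> float:
        pred = model.predict(Xm)
        if is_classifier:
            return float(np.mean(pred != y.to_numpy()))
        return float(np.mean((pred - y.to_numpy(dtype=float)) ** 2))

    baseline = err(X)
    rng = np.random.default_rng(seed)
    importances = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(err(Xp) - baseline)
        mean_delta = float(np.mean(deltas))
        importances[j] = 100.0 * (mean_delta / baseline if baseline > 0 else mean_delta)
    table = pd.DataFrame(
        {"otu_id": list(data.columns), "importance": importances}
    )
    table = table.sort_values(
        ["importance", "otu_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceTable(
        table=table,
        top_k=tuple(table["otu_id"].head(top_k)),
        metric="error_rate" if is_classifier else "mse",
    )


def aggregate_importance_by_phylum(
    importance: ImportanceTable, taxonomy: pd.DataFrame | pd.Series
) -> dict:
    """Count the top-k OTUs per phylum; missing taxonomy -> "unclassified"."""
    if isinstance(taxonomy, pd.DataFrame):
        phyla = taxonomy["phylum"]
    else:
        phyla = taxonomy
    counts: dict = {}
    for otu in importance.top_k:
        phylum = phyla.get(otu, "unclassified")
        if pd.isna(phylum) or phylum == "":
            phylum = "unclassified"
        counts[phylum] = counts.get(phylum, 0) + 1
    return counts


def top_otu_overlap(tables: Mapping[str, ImportanceTable]) -> dict:
    """Histogram of how many models share each top OTU.

    Returns {n_models: number of OTUs that are in the top list of exactly
    n_models}.
    """
    tally: dict = {}
    for imp in tables.values():
        for otu in imp.top_k:
            tally[otu] = tally.get(otu, 0) + 1
    hist: dict = {}
    for count in tally.values():
        hist[count] = hist.get(count, 0) + 1
    return dict(sorted(hist.items()))


def repeated_splits(
    pipeline_stage: Callable[[int], Mapping[str, float]],
    n_repeats: int,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rerun split -> fit -> evaluate with seeds base_seed + i.

    ``pipeline_stage(seed)`` returns a flat mapping of metric name ->
    value.  A failed repeat is recorded (with the error message) and
    skipped rather than aborting the whole experiment.  Returns the
    per-repeat metrics and a summary (mean, sd, quartiles) per metric.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    rows = []
    failures = []
    for i in range(n_repeats):
        seed = base_seed + i
        try:
            metrics = dict(pipeline_stage(seed))
        except Exception as exc:  # noqa: BLE001 - robustness across repeats
            logger.warning("repeat %d (seed %d) failed: %s", i, seed, exc)
            failures.append({"seed": seed, "error": str(exc)})
            continue
        metrics["seed"] = seed
        rows.append(metrics)
    if not rows:
        raise RuntimeError(f"all {n_repeats} repeats failed; first: {failures[0]}")
    per_repeat = pd.DataFrame(rows).set_index("seed")
    summary = per_repeat.agg(["mean", "std", "min", "median", "max"]).T
    summary.columns = ["mean", "sd", "min", "median", "max"]
    return per_repeat, summary
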