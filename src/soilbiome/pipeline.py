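"""End-to-end orchestration: file I/O, stage composition, experiments.

The full chain mirrors the monitoring-survey design: rarefy replicate samples to a
common depth, average them into one community per site, compute Bray-Curtis
dissimilarities and PERMANOVA, Ward-cluster the communities and pick a cut
level, screen indicator OTUs, Ward-cluster the (standardized) soil
chemistry and characterise the clusters with Dunn's test, summarise the
chemistry with probabilistic PCA, then fit stratified random forests that
predict land use, chemistry cluster and each soil variable from the
indicator-OTU features, and finally convert regression predictions into
soil-quality categories.

The mid-level experiment functions (``predict_land_use``,
``predict_chemistry_clusters``, ``predict_soil_variables``,
``score_predicted_quality``) are the reusable building blocks behind both
the command-line ``run`` subcommand and the reproduction script.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from . import __version__, clustering, community, indicators, models, soilchem
from .soilchem import QualityThresholds

logger = logging.getLogger(__name__)

__all__ = [
    "example_thresholds_path",
    "read_tables",
    "prepare_site_table",
    "predict_land_use",
    "predict_chemistry_clusters",
    "predict_soil_variables",
    "score_predicted_quality",
    "run_pipeline",
]

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


def example_thresholds_path() -> Path:
    """Path of the shipped (synthetic, non-normative) thresholds config."""
    return Path(resources.files("soilbiome") / "data" / "example_thresholds.yaml")


# ---------------------------------------------------------------------------
# file I/O


def read_tables(
    otu_path,
    metadata_path,
    chemistry_path=None,
    taxonomy_path=None,
) -> dict:
    """Load and cross-validate the standard input tables.

    OTU table: TSV, first column sample IDs, remaining columns OTU counts.
    Metadata: CSV with sample_id, site_id, land_use[, region].  Chemistry:
    CSV with site_id plus variable columns, empty cell = missing.
    Taxonomy: TSV with otu_id plus up to 7 rank columns; absent ranks are
    filled with "unclassified".
    """
    otu = pd.read_csv(otu_path, sep="\t", index_col=0)
    bad = otu.columns[~otu.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ValueError(f"{otu_path}: non-numeric OTU column(s): {list(bad[:10])}")
    metadata = pd.read_csv(metadata_path, index_col=0)
    for col in ("site_id", "land_use"):
        if col not in metadata.columns:
            raise ValueError(f"{metadata_path}: missing required column {col!r}")
    unmapped = otu.index.difference(metadata.index)
    if len(unmapped):
        raise ValueError(
            f"sample(s) in OTU table but not in metadata: "
            f"{', '.join(map(str, unmapped[:10]))}"
        )
    out = {"otu": otu, "metadata": metadata.loc[otu.index]}
    if chemistry_path is not None:
        chem = pd.read_csv(chemistry_path, index_col=0)
        sites = set(metadata["site_id"])
        missing_sites = sites - set(chem.index)
        if missing_sites:
            logger.warning(
                "site(s) without chemistry: %s",
                ", ".join(sorted(map(str, missing_sites))[:10]),
            )
        n_missing = int(chem.isna().sum().sum())
        if n_missing:
            logger.info("chemistry: %d missing cell(s) loaded as NaN", n_missing)
        out["chemistry"] = chem
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        tax.columns = [c.lower() for c in tax.columns]
        for rank in TAXONOMY_RANKS:
            if rank not in tax.columns:
                tax[rank] = "unclassified"
        tax = tax[list(TAXONOMY_RANKS)].fillna("unclassified").replace("", "unclassified")
        out["taxonomy"] = tax
    return out


# ---------------------------------------------------------------------------
# stage composition


def prepare_site_table(
    otu: pd.DataFrame,
    metadata: pd.DataFrame,
    depth: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rarefy replicate samples and average them into one row per site."""
    rarefied = community.rarefy(otu, depth=depth, seed=seed)
    mapping = metadata.loc[rarefied.index, "site_id"]
    return community.average_replicates(rarefied, mapping)


def chemistry_distance(chem: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance on per-variable standardized chemistry.

    The 7 variables have incommensurate units, so each is centred and
    scaled to unit variance before computing distances.  Rows with missing
    entries are excluded (Ward needs complete pairwise distances).
    """
    complete = chem.dropna()
    z = (complete - complete.mean()) / complete.std(ddof=1)
    d = squareform(pdist(z.to_numpy()))
    return DistanceMatrix(d, ids=[str(i) for i in complete.index])


def _indicator_features(
    site_table: pd.DataFrame,
    solution: clustering.ClusterSolution,
    a_min: float,
    b_min: float,
) -> pd.DataFrame:
    scores = indicators.indicator_scores(site_table, solution)
    selected = indicators.select_indicator_otus(scores, a_min=a_min, b_min=b_min)
    if not selected:
        raise ValueError(
            f"no OTU passes the indicator thresholds A > {a_min}, B > {b_min}"
        )
    return site_table[selected]


@dataclass(frozen=True)
class LandUsePrediction:
    features: pd.DataFrame
    split: models.SplitSpec
    result: models.ClassificationResult
    n_indicator_otus: int
    community_k: int


def predict_land_use(
    site_table: pd.DataFrame,
    land_use: pd.Series,
    k: int = 5,
    a_min: float = 0.4,
    b_min: float = 0.4,
    fraction: float = 0.8,
    seed: int | None = None,
    rf_params=None,
) -> LandUsePrediction:
    """Community clustering -> indicator screen -> stratified RF -> accuracy.

    Sites are Ward-clustered on Bray-Curtis dissimilarity, the dendrogram
    cut at ``k``, indicator OTUs selected against those clusters, and a
    random-forest classifier of land use trained on a stratified 80/20
    split and evaluated on the held-out sites.
    """
    dist = community.bray_curtis(site_table)
    tree = clustering.ward_cluster(dist)
    solution = clustering.cut_tree(tree, k)
    features = _indicator_features(site_table, solution, a_min, b_min)
    split = models.stratified_split(land_use, fraction=fraction, seed=seed)
    train, test = list(split.train_ids), list(split.test_ids)
    fitted = models.fit_classifier(
        features.loc[train], land_use,
        hyperparams={"random_state": seed, **(rf_params or {})},
    )
    result = models.evaluate_classification(fitted, features.loc[test], land_use)
    return LandUsePrediction(
        features=features,
        split=split,
        result=result,
        n_indicator_otus=features.shape[1],
        community_k=k,
    )


@dataclass(frozen=True)
class ChemistryClusterPrediction:
    solution: clustering.ClusterSolution
    chosen_k: int
    diagnostics: pd.DataFrame
    dunn: pd.DataFrame
    result: models.ClassificationResult
    n_indicator_otus: int


def predict_chemistry_clusters(
    site_table: pd.DataFrame,
    chemistry: pd.DataFrame,
    k_range=range(2, 9),
    min_cluster_size: int = 5,
    a_min: float = 0.4,
    b_min: float = 0.4,
    fraction: float = 0.8,
    seed: int | None = None,
    rf_params=None,
) -> ChemistryClusterPrediction:
    """Cluster sites on chemistry, then predict the cluster from community.

    Chemistry is standardized and Ward-clustered; the cut level is chosen
    by the multi-criteria vote.  Dunn's test describes how each variable
    differs among clusters.  A random forest trained on indicator-OTU
    features (selected against the chemistry clusters) predicts cluster
    membership of held-out sites.
    """
    chem_dist = chemistry_distance(chemistry.loc[site_table.index])
    chem_sites = list(chem_dist.ids)
    table = site_table.loc[chem_sites]
    tree = clustering.ward_cluster(chem_dist)
    chosen_k, diag = clustering.select_cut_level(
        tree,
        chem_dist,
        table,
        k_range=k_range,
        min_cluster_size=min_cluster_size,
        source="chemistry",
    )
    solution = clustering.cut_tree(tree, chosen_k, source="chemistry")
    dunn_rows = []
    for var in chemistry.columns:
        vals = chemistry.loc[chem_sites, var]
        ok = vals.notna()
        try:
            d = clustering.dunn_test(vals[ok], solution.labels[ok])
        except ValueError:
            continue
        d.insert(0, "variable", var)
        dunn_rows.append(d)
    dunn = pd.concat(dunn_rows, ignore_index=True) if dunn_rows else pd.DataFrame()
    features = _indicator_features(table, solution, a_min, b_min)
    split = models.stratified_split(solution.labels, fraction=fraction, seed=seed)
    train, test = list(split.train_ids), list(split.test_ids)
    fitted = models.fit_classifier(
        features.loc[train], solution.labels,
        hyperparams={"random_state": seed, **(rf_params or {})},
    )
    result = models.evaluate_classification(fitted, features.loc[test], solution.labels)
    return ChemistryClusterPrediction(
        solution=solution,
        chosen_k=chosen_k,
        diagnostics=diag,
        dunn=dunn,
        result=result,
        n_indicator_otus=features.shape[1],
    )


@dataclass(frozen=True)
class SoilVariablePredictions:
    evaluations: dict  # variable -> RegressionEval
    summary: pd.DataFrame  # variable, adj_R2, slope, n_test
    predicted: pd.DataFrame  # held-out site x variable predictions
    actual: pd.DataFrame  # held-out site x variable actual values
    split: models.SplitSpec


def predict_soil_variables(
    site_table: pd.DataFrame,
    chemistry: pd.DataFrame,
    land_use: pd.Series,
    variables=None,
    k: int = 5,
    a_min: float = 0.4,
    b_min: float = 0.4,
    fraction: float = 0.8,
    seed: int | None = None,
    rf_params=None,
) -> SoilVariablePredictions:
    """Random-forest regressions of each soil variable on indicator OTUs.

    One stratified (by land use) 80/20 split is shared by all variables;
    each fitted forest is evaluated by regressing predicted on actual
    held-out values (slope, adjusted R^2).
    """
    variables = list(variables) if variables is not None else list(chemistry.columns)
    dist = community.bray_curtis(site_table)
    tree = clustering.ward_cluster(dist)
    solution = clustering.cut_tree(tree, k)
    features = _indicator_features(site_table, solution, a_min, b_min)
    split = models.stratified_split(land_use.loc[site_table.index], fraction=fraction, seed=seed)
    train, test = list(split.train_ids), list(split.test_ids)
    evaluations: dict = {}
    pred_cols: dict = {}
    actual_cols: dict = {}
    for var in variables:
        target = chemistry.loc[site_table.index, var]
        train_ok = [s for s in train if pd.notna(target.get(s))]
        test_ok = [s for s in test if pd.notna(target.get(s))]
        if len(train_ok) < 2 or len(test_ok) < 3:
            logger.warning(
                "skipping %s: only %d train / %d test sites with measurements",
                var, len(train_ok), len(test_ok),
            )
            continue
        fitted = models.fit_regressor(
            features.loc[train_ok], target,
            hyperparams={"random_state": seed, **(rf_params or {})},
        )
        ev = models.evaluate_regression(fitted, features.loc[test_ok], target)
        evaluations[var] = ev
        pred_cols[var] = ev.predictions
        actual_cols[var] = target.loc[test_ok]
    evaluated = list(evaluations)
    summary = pd.DataFrame(
        {
            "variable": evaluated,
            "adj_R2": [evaluations[v].adj_R2 for v in evaluated],
            "slope": [evaluations[v].slope for v in evaluated],
            "n_test": [evaluations[v].n for v in evaluated],
        }
    )
    return SoilVariablePredictions(
        evaluations=evaluations,
        summary=summary,
        predicted=pd.DataFrame(pred_cols),
        actual=pd.DataFrame(actual_cols),
        split=split,
    )


def score_predicted_quality(
    predictions: SoilVariablePredictions,
    thresholds: QualityThresholds,
    contexts=None,
) -> soilchem.QualityAssessment:
    """Convert held-out predictions and actuals to quality-category outcomes."""
    return soilchem.score_table(
        predictions.actual, predictions.predicted, thresholds, contexts=contexts
    )


# ---------------------------------------------------------------------------
# full pipeline


def _scope_sites(metadata: pd.DataFrame, scope: str) -> pd.Series:
    """Site -> land use for the requested dataset scope."""
    site_lu = metadata.drop_duplicates("site_id").set_index("site_id")["land_use"]
    if scope == "all":
        return site_lu
    if scope == "AM":  # all managed sites
        return site_lu[site_lu != "indigenous"]
    if scope == "NPG":  # non-pastoral-grassland managed sites
        return site_lu[~site_lu.isin(["indigenous", "pastoral"])]
    raise ValueError(f"unknown scope {scope!r}; expected all, AM or NPG")


def run_pipeline(config: dict, outdir) -> Path:
    """Execute every stage for one scope and write all artifacts.

    ``config`` keys (with defaults): paths (otu, metadata, chemistry,
    taxonomy, thresholds), depth (2000), scope ("all"), k_range ([2..8]),
    min_cluster_size (5), a_min/b_min (0.4), fraction (0.8),
    n_components (2), seed (0).  Returns the run directory, which receives
    one CSV per stage plus a JSON manifest recording the config hash and
    package version.
    """
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    depth = int(cfg.get("depth", 2000))
    scope = cfg.get("scope", "all")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    stage("read_tables")
    tables = read_tables(
        cfg["otu"],
        cfg["metadata"],
        chemistry_path=cfg.get("chemistry"),
        taxonomy_path=cfg.get("taxonomy"),
    )
    metadata = tables["metadata"]
    site_lu = _scope_sites(metadata, scope)

    stage("rarefy+average")
    samples_in_scope = metadata.index[metadata["site_id"].isin(site_lu.index)]
    site_table = prepare_site_table(
        tables["otu"].loc[samples_in_scope], metadata, depth=depth, seed=seed
    )
    site_lu = site_lu.loc[site_table.index]
    site_table.to_csv(outdir / "site_otu_table.csv")

    stage("bray_curtis+permanova")
    dist = community.bray_curtis(site_table)
    perm = community.permanova(dist, site_lu, n_permutations=999, seed=seed)
    perm.to_frame().to_csv(outdir / "permanova.csv", index=False)
    if site_lu.nunique() > 2:
        community.pairwise_permanova(dist, site_lu, n_permutations=999, seed=seed).to_csv(
            outdir / "permanova_pairwise.csv", index=False
        )

    stage("community_clustering")
    tree = clustering.ward_cluster(dist)
    k_range = cfg.get("k_range", range(2, 9))
    k, diag = clustering.select_cut_level(
        tree, dist, site_table, k_range=k_range,
        min_cluster_size=int(cfg.get("min_cluster_size", 5)),
    )
    diag.to_csv(outdir / "community_cut_diagnostics.csv", index=False)
    solution = clustering.cut_tree(tree, k)
    solution.labels.rename("cluster").rename_axis("site_id").to_csv(
        outdir / "community_clusters.csv"
    )

    stage("indicator_selection")
    a_min = float(cfg.get("a_min", 0.4))
    b_min = float(cfg.get("b_min", 0.4))
    scores = indicators.indicator_scores(site_table, solution)
    scores.to_frame().to_csv(outdir / "indicator_scores.csv", index=False)
    selected = indicators.select_indicator_otus(scores, a_min=a_min, b_min=b_min)
    (outdir / "selected_otus.txt").write_text("\n".join(map(str, selected)) + "\n")
    features = site_table[selected]

    stage("land_use_model")
    fraction = float(cfg.get("fraction", 0.8))
    rf_params = cfg.get("rf_params") or {}
    split = models.stratified_split(site_lu, fraction=fraction, seed=seed)
    train, test = list(split.train_ids), list(split.test_ids)
    results_summary = {
        "scope": scope,
        "n_sites": len(site_table),
        "community_k": k,
        "n_indicator_otus": len(selected),
        "permanova_R2": perm.R2,
        "permanova_p": perm.p_value,
    }
    if site_lu.nunique() >= 2 and min(site_lu.value_counts()) >= 2:
        clf = models.fit_classifier(
            features.loc[train], site_lu,
            hyperparams={"random_state": seed, **rf_params},
        )
        cls_res = models.evaluate_classification(clf, features.loc[test], site_lu)
        cls_res.confusion.to_csv(outdir / "landuse_confusion.csv")
        results_summary["landuse_accuracy"] = cls_res.accuracy

    chem = tables.get("chemistry")
    assessment = None
    if chem is not None:
        chem = chem.loc[chem.index.intersection(site_table.index), :]

        stage("chemistry_clustering")
        chem_pred = predict_chemistry_clusters(
            site_table,
            chem,
            k_range=k_range,
            min_cluster_size=int(cfg.get("min_cluster_size", 5)),
            a_min=a_min,
            b_min=b_min,
            fraction=fraction,
            seed=seed,
            rf_params=rf_params,
        )
        chem_pred.diagnostics.to_csv(outdir / "chemistry_cut_diagnostics.csv", index=False)
        chem_pred.solution.labels.rename("cluster").rename_axis("site_id").to_csv(
            outdir / "chemistry_clusters.csv"
        )
        chem_pred.dunn.to_csv(outdir / "chemistry_dunn.csv", index=False)
        chem_pred.result.confusion.to_csv(outdir / "chemcluster_confusion.csv")
        results_summary["chemistry_k"] = chem_pred.chosen_k
        results_summary["chemcluster_accuracy"] = chem_pred.result.accuracy

        stage("ppca")
        pca = soilchem.ppca_em(
            chem, n_components=int(cfg.get("n_components", 2)), seed=seed
        )
        pca.scores.rename_axis("site_id").to_csv(outdir / "ppca_scores.csv")
        pca.loadings.rename_axis("variable").to_csv(outdir / "ppca_loadings.csv")

        stage("soil_variable_models")
        soil_pred = predict_soil_variables(
            site_table, chem, site_lu,
            k=k, a_min=a_min, b_min=b_min, fraction=fraction, seed=seed,
            rf_params=rf_params,
        )
        soil_pred.summary.to_csv(outdir / "regression_summary.csv", index=False)
        soil_pred.predicted.rename_axis("site_id").to_csv(outdir / "predicted_values.csv")

        stage("quality_scoring")
        thresholds_path = cfg.get("thresholds") or example_thresholds_path()
        thresholds = soilchem.load_quality_thresholds(thresholds_path)
        contexts = site_lu if cfg.get("context_by_land_use", True) else None
        assessment = score_predicted_quality(soil_pred, thresholds, contexts=contexts)
        assessment.records.to_csv(outdir / "quality_records.csv", index=False)
        assessment.proportions.to_csv(outdir / "quality_proportions.csv")
        results_summary["quality_correct_pooled"] = float(
            assessment.pooled_proportions()["correct"]
        )

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": {key: str(v) for key, v in cfg.items()},
        "config_hash": hashlib.sha256(
            json.dumps({key: str(v) for key, v in cfg.items()}, sort_keys=True).encode()
        ).hexdigest(),
        "results": results_summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline complete: %s", outdir)
    return outdir
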