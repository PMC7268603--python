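"""Reference synthetic scenarios exercising the pipeline at desk scale.

These bundle scenario construction with the corresponding pipeline run so
the same conditions can be repeated under different seeds:

* a strong-signal land-use scenario (300 sites in survey-like land-use
  proportions, 500 OTUs of which 60 respond, sequencing depth 2000,
  5 replicate cores) for land-use classification and per-variable
  regressions, optionally with the pH coupling doubled;
* a two-land-use scenario whose chemistry means form four well-separated
  clusters (a +- grid over two multivariate contrast patterns at 2.5
  within-cluster SDs per variable, so neighbouring centres differ by 5 SDs
  on every variable of one block) for chemistry-cluster recovery and
  prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pipeline, soilchem
from .synthetic import (
    CHEM_VARIABLES,
    DEFAULT_CHEM_MEANS,
    DEFAULT_CHEM_SDS,
    ScenarioConfig,
    SyntheticDataset,
    generate_chemistry,
    generate_counts,
    generate_land_use,
    generate_scenario,
    scenario_coefficients,
)

__all__ = [
    "strong_signal_config",
    "strong_signal_dataset",
    "landuse_trial",
    "soil_variable_trial",
    "clustered_chemistry_trial",
]


def strong_signal_config(
    seed: int,
    n_sites: int = 300,
    effect_size_chem: float = 2.0,
    effect_size_landuse: float = 2.0,
) -> ScenarioConfig:
    """300 sites in proportions (0.10, 0.12, 0.23, 0.55), strong coupling."""
    return ScenarioConfig(
        n_sites=n_sites,
        land_use_proportions=(0.10, 0.12, 0.23, 0.55),
        n_replicates=5,
        n_otus=500,
        n_responsive_otus=60,
        depth_mean=2000,
        effect_size_chem=effect_size_chem,
        effect_size_landuse=effect_size_landuse,
        seed=seed,
    )


def strong_signal_dataset(seed: int, ph_boost: bool = False, **kwargs) -> SyntheticDataset:
    """Generate the strong-signal scenario, optionally doubling pH coupling."""
    config = strong_signal_config(seed, **kwargs)
    if not ph_boost:
        return generate_scenario(config)
    coef = scenario_coefficients(config)
    beta = coef["beta"].copy()
    beta["pH"] *= 2.0
    return generate_scenario(config, beta=beta.to_numpy())


def landuse_trial(seed: int, **kwargs) -> dict:
    """Full land-use prediction chain on the strong-signal scenario.

    Rarefy(2000) -> average replicates -> Ward cut at k=5 -> indicator
    screen (A, B > 0.4) -> stratified 80/20 random forest -> held-out
    accuracy.
    """
    dataset = strong_signal_dataset(seed, **kwargs)
    site_table = pipeline.prepare_site_table(
        dataset.otu_counts, dataset.metadata, depth=2000, seed=seed
    )
    land_use = dataset.site_metadata["land_use"].loc[site_table.index]
    res = pipeline.predict_land_use(site_table, land_use, k=5, seed=seed)
    return {
        "accuracy": res.result.accuracy,
        "n_test": len(res.split.test_ids),
        "n_indicator_otus": res.n_indicator_otus,
    }


def soil_variable_trial(
    seed: int, ph_boost: bool = False, thresholds=None, **kwargs
) -> dict:
    """Per-variable regressions plus quality scoring on held-out sites."""
    dataset = strong_signal_dataset(seed, ph_boost=ph_boost, **kwargs)
    site_table = pipeline.prepare_site_table(
        dataset.otu_counts, dataset.metadata, depth=2000, seed=seed
    )
    land_use = dataset.site_metadata["land_use"].loc[site_table.index]
    chem = dataset.latent_chemistry.loc[site_table.index]
    preds = pipeline.predict_soil_variables(
        site_table, chem, land_use, k=5, seed=seed
    )
    if thresholds is None:
        thresholds = soilchem.load_quality_thresholds(pipeline.example_thresholds_path())
    assessment = pipeline.score_predicted_quality(preds, thresholds, contexts=land_use)
    correct_by_var = assessment.proportions["correct"]
    return {
        "summary": preds.summary,
        "best_adj_R2": float(preds.summary["adj_R2"].max()),
        "assessment": assessment,
        "correct_pooled": float(assessment.pooled_proportions()["correct"]),
        "correct_pH": float(correct_by_var.get("pH", np.nan)),
    }


def _four_cluster_means(scale_sds: float = 2.5) -> dict:
    """Four chemistry centres on a +-grid over two multivariate contrasts.

    Soil conditions covary in blocks, so the centres are separated along
    two patterns rather than single variables: a fertility/pH axis (pH and
    Olsen P up, macroporosity down / bulk density up, as on limed and
    trafficked soils) and an organic-matter axis (carbon, total N and AMN
    together).  Neighbouring centres differ by 2 * scale_sds within-cluster
    SDs on every variable of one pattern.
    """
    base = np.asarray(DEFAULT_CHEM_MEANS["pastoral"], dtype=float)
    sds = np.asarray(DEFAULT_CHEM_SDS)
    idx = {v: i for i, v in enumerate(CHEM_VARIABLES)}
    pattern_ph = np.zeros(len(CHEM_VARIABLES))
    pattern_ph[idx["pH"]] = 1.0
    pattern_ph[idx["olsen_p_mg_kg"]] = 1.0
    pattern_ph[idx["bulk_density_t_m3"]] = 0.8
    pattern_ph[idx["macroporosity_pct"]] = -0.8
    pattern_om = np.zeros(len(CHEM_VARIABLES))
    for v in ("carbon_pct", "total_n_pct", "amn_mg_kg"):
        pattern_om[idx[v]] = 1.0
    centres = {}
    for name, (s1, s2) in {
        "grp1": (-1, -1),
        "grp2": (-1, +1),
        "grp3": (+1, -1),
        "grp4": (+1, +1),
    }.items():
        centre = base + scale_sds * sds * (s1 * pattern_ph + s2 * pattern_om)
        centres[name] = tuple(centre)
    return centres


def clustered_chemistry_trial(seed: int, n_sites: int = 200) -> dict:
    """Chemistry-cluster recovery and prediction on a planted-cluster scenario.

    Chemistry means form 4 well-separated clusters (5 within-cluster SDs
    between neighbouring centres on one variable block, see
    ``_four_cluster_means``) independent of a two-land-use layout;
    composition is strongly coupled to chemistry (effect_size_chem = 2).
    The chemistry dendrogram is cut by the multi-criteria vote and a
    random forest on indicator-OTU features predicts the cluster of
    held-out sites.
    """
    chem_config = ScenarioConfig(
        n_sites=n_sites,
        land_use_proportions=(0.25, 0.25, 0.25, 0.25),
        chem_means=_four_cluster_means(),
        n_replicates=5,
        n_otus=500,
        n_responsive_otus=60,
        depth_mean=2000,
        effect_size_chem=2.0,
        effect_size_landuse=1.0,
        seed=seed,
    )
    groups = generate_land_use(chem_config)  # planted chemistry groups
    _, latent = generate_chemistry(chem_config, groups)
    counts_config = ScenarioConfig(
        n_sites=n_sites,
        land_use_proportions=(0.5, 0.5),
        chem_means={
            "exotic": DEFAULT_CHEM_MEANS["exotic"],
            "horticulture": DEFAULT_CHEM_MEANS["horticulture"],
        },
        n_replicates=5,
        n_otus=500,
        n_responsive_otus=60,
        depth_mean=2000,
        effect_size_chem=2.0,
        effect_size_landuse=1.0,
        seed=seed + 7919,
    )
    land_use = generate_land_use(counts_config)
    counts, _ = generate_counts(counts_config, latent, land_use)
    metadata = pd.DataFrame(
        {
            "sample_id": counts.index,
            "site_id": [s.rsplit("_r", 1)[0] for s in counts.index],
        }
    ).set_index("sample_id")
    site_table = pipeline.prepare_site_table(counts, metadata, depth=2000, seed=seed)
    res = pipeline.predict_chemistry_clusters(
        site_table,
        latent.loc[site_table.index],
        k_range=range(2, 9),
        min_cluster_size=5,
        seed=seed,
    )
    labels = res.solution.labels
    planted = groups.loc[labels.index]
    return {
        "accuracy": res.result.accuracy,
        "chosen_k": res.chosen_k,
        "planted_groups": planted,
        "cluster_labels": labels,
        "n_test": len(res.result.predictions),
    }
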