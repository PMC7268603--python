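"""Synthetic soil-microbiome scenario generator with known ground truth.

Emulates the structure the analysis chain assumes: sites drawn from four
land-use classes (indigenous forest, exotic forest, horticulture, pastoral
grassland), five replicate soil cores per site, seven soil
physico-chemical variables with land-use-dependent means and a negative
macroporosity / bulk-density correlation, and OTU count tables whose
composition responds to the latent chemistry (especially pH) and to land
use through a softmax log-linear model.  Replicate counts are
Dirichlet-multinomial so within-site overdispersion is controllable, and
sequencing depth is Poisson around a configurable mean.

Every draw is governed by a single scenario seed; identical configurations
produce bit-identical datasets.  The coefficient matrices actually used
are returned as ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LAND_USES",
    "CHEM_VARIABLES",
    "DEFAULT_CHEM_MEANS",
    "DEFAULT_CHEM_SDS",
    "ScenarioConfig",
    "SyntheticDataset",
    "ConfigError",
    "generate_land_use",
    "scenario_coefficients",
    "generate_chemistry",
    "generate_counts",
    "generate_scenario",
    "write_dataset",
]

LAND_USES = ("indigenous", "exotic", "horticulture", "pastoral")

CHEM_VARIABLES = (
    "pH",
    "carbon_pct",
    "total_n_pct",
    "amn_mg_kg",
    "olsen_p_mg_kg",
    "macroporosity_pct",
    "bulk_density_t_m3",
)

# Plausible per-land-use means for temperate managed topsoils (pH units, %, %,
# mg/kg, mg/kg, % v/v, t/m^3): natural forest soils are carbon- and
# nitrogen-rich with low Olsen P and open structure; horticultural soils
# are limed (higher pH), fertilized (high Olsen P) and more compacted;
# pastoral soils sit in between with elevated nutrient status.
DEFAULT_CHEM_MEANS: Mapping[str, tuple] = {
    "indigenous": (5.75, 8.0, 0.50, 125.0, 8.0, 19.0, 0.95),
    "exotic": (5.15, 6.0, 0.35, 100.0, 15.0, 17.0, 1.05),
    "horticulture": (6.40, 3.0, 0.20, 60.0, 70.0, 14.0, 1.20),
    "pastoral": (5.85, 6.0, 0.45, 115.0, 35.0, 12.0, 1.10),
}

DEFAULT_CHEM_SDS = (0.30, 1.5, 0.08, 25.0, 12.0, 3.5, 0.12)

# default land-use mix: a national-survey-like layout of 606 sites
# split 61/72/139/334 across the four classes
DEFAULT_LAND_USE_PROPORTIONS = (61 / 606, 72 / 606, 139 / 606, 334 / 606)


class ConfigError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic study scenario.

    ``chem_means`` maps each land use to the 7 variable means (ordered as
    ``CHEM_VARIABLES``); a land use present in ``land_use_proportions`` with
    positive weight must have a mean vector.  ``chem_corr`` is the
    macroporosity / bulk-density correlation (compaction closes large
    pores, so it should be negative).  ``effect_size_chem`` scales the
    log-abundance response of responsive OTUs to standardized chemistry and
    ``effect_size_landuse`` the land-use-specific offsets.
    ``overdispersion`` is the total Dirichlet concentration governing
    replicate-to-replicate compositional noise (smaller = noisier).
    """

    n_sites: int = 60
    land_use_proportions: tuple = DEFAULT_LAND_USE_PROPORTIONS
    n_replicates: int = 5
    n_otus: int = 500
    depth_mean: int = 2000
    chem_means: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_CHEM_MEANS)
    )
    chem_sds: tuple = DEFAULT_CHEM_SDS
    chem_corr: float = -0.6  # macroporosity vs bulk density
    n_responsive_otus: int = 60
    effect_size_chem: float = 1.0
    effect_size_landuse: float = 1.0
    baseline_sd: float = 1.5  # spread of per-OTU baseline log-abundance
    overdispersion: float = 200.0
    missing_chem_rate: float = 0.0
    seed: int = 0

    def land_uses(self) -> tuple:
        return tuple(self.chem_means)

    def validate(self) -> None:
        if self.n_sites < 1 or self.n_replicates < 1 or self.n_otus < 1:
            raise ConfigError("n_sites, n_replicates and n_otus must be positive")
        props = np.asarray(self.land_use_proportions, dtype=float)
        if len(props) != len(self.chem_means):
            raise ConfigError(
                "land_use_proportions must have one weight per land use in chem_means"
            )
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError("land_use_proportions must be non-negative and sum to 1")
        for lu, means in self.chem_means.items():
            if len(means) != len(CHEM_VARIABLES):
                raise ConfigError(
                    f"chem_means[{lu!r}] must have {len(CHEM_VARIABLES)} entries"
                )
        if len(self.chem_sds) != len(CHEM_VARIABLES):
            raise ConfigError(f"chem_sds must have {len(CHEM_VARIABLES)} entries")
        if (np.asarray(self.chem_sds) <= 0).any():
            raise ConfigError("chem_sds must be strictly positive")
        if not -1.0 <= self.chem_corr <= 0.0:
            raise ConfigError("chem_corr (macroporosity-bulk density) must be in [-1, 0]")
        if not 0 <= self.n_responsive_otus <= self.n_otus:
            raise ConfigError("n_responsive_otus must be in [0, n_otus]")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        if self.overdispersion <= 0 or self.baseline_sd <= 0:
            raise ConfigError("overdispersion and baseline_sd must be strictly positive")
        if not 0 <= self.missing_chem_rate < 1:
            raise ConfigError("missing_chem_rate must be in [0, 1)")
        for e in (self.effect_size_chem, self.effect_size_landuse):
            if e < 0:
                raise ConfigError("effect sizes must be non-negative")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated scenario: counts, chemistry, metadata and ground truth."""

    otu_counts: pd.DataFrame  # replicate-level, (n_sites * n_replicates) x n_otus
    chemistry: pd.DataFrame  # observed site x variable, NaN = missing
    latent_chemistry: pd.DataFrame  # noise-free (unmasked) values
    metadata: pd.DataFrame  # sample_id index: site_id, land_use, region
    truth: dict  # beta, gamma, baseline, expected_proportions

    @property
    def site_metadata(self) -> pd.DataFrame:
        return self.metadata.drop_duplicates("site_id").set_index("site_id")[
            ["land_use", "region"]
        ]


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per generation stage
    return np.random.default_rng([int(config.seed), stream])


def generate_land_use(config: ScenarioConfig) -> pd.Series:
    """Draw per-site land-use labels from the configured proportions."""
    config.validate()
    rng = _rng(config, 0)
    sites = [f"S{i + 1:04d}" for i in range(config.n_sites)]
    labels = rng.choice(
        list(config.land_uses()),
        size=config.n_sites,
        p=np.asarray(config.land_use_proportions, dtype=float),
    )
    return pd.Series(labels, index=sites, name="land_use")


def generate_chemistry(
    config: ScenarioConfig, land_use_labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw site chemistry from the land-use-specific multivariate normal.

    Returns ``(observed, latent)``: the latent table holds the noise-free
    (unmasked) values; the observed table equals it with entries masked
    completely at random at ``missing_chem_rate``.  Values are kept on
    natural scales: pH clipped to [3, 10], percentage variables to
    [0, 100], concentrations and bulk density floored just above zero.
    """
    config.validate()
    unknown = set(land_use_labels.unique()) - set(config.land_uses())
    if unknown:
        raise ConfigError(f"labels outside the configured land uses: {sorted(unknown)}")
    sds = np.asarray(config.chem_sds, dtype=float)
    p = len(CHEM_VARIABLES)
    corr = np.eye(p)
    i_mp = CHEM_VARIABLES.index("macroporosity_pct")
    i_bd = CHEM_VARIABLES.index("bulk_density_t_m3")
    corr[i_mp, i_bd] = corr[i_bd, i_mp] = config.chem_corr
    cov = np.outer(sds, sds) * corr
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - single off-diagonal is PD
        raise ConfigError(
            f"chem_sds/chem_corr imply a non-positive-definite covariance "
            f"(chem_corr={config.chem_corr})"
        ) from exc
    rng = _rng(config, 1)
    n = len(land_use_labels)
    z = rng.standard_normal((n, p))
    means = np.vstack(
        [np.asarray(config.chem_means[lu], dtype=float) for lu in land_use_labels]
    )
    values = means + z @ chol.T
    # clip to physically meaningful ranges
    values[:, CHEM_VARIABLES.index("pH")] = np.clip(
        values[:, CHEM_VARIABLES.index("pH")], 3.0, 10.0
    )
    for var in ("carbon_pct", "total_n_pct", "macroporosity_pct"):
        j = CHEM_VARIABLES.index(var)
        values[:, j] = np.clip(values[:, j], 0.0, 100.0)
    for var in ("amn_mg_kg", "olsen_p_mg_kg", "bulk_density_t_m3"):
        j = CHEM_VARIABLES.index(var)
        values[:, j] = np.clip(values[:, j], 0.01, None)
    latent = pd.DataFrame(values, index=land_use_labels.index, columns=CHEM_VARIABLES)
    observed = latent.copy()
    if config.missing_chem_rate > 0:
        mask = rng.random(latent.shape) < config.missing_chem_rate
        observed = observed.mask(mask)
    return observed, latent


def _draw_coefficients(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Baseline, responsive-OTU set, chemistry and land-use coefficients."""
    baseline = rng.normal(scale=config.baseline_sd, size=config.n_otus)
    responsive = np.sort(
        rng.choice(config.n_otus, size=config.n_responsive_otus, replace=False)
    )
    p = len(CHEM_VARIABLES)
    n_lu = len(config.land_uses())
    beta = np.zeros((config.n_otus, p))
    gamma = np.zeros((config.n_otus, n_lu))
    if config.n_responsive_otus:
        active = rng.random((config.n_responsive_otus, p)) < 0.5
        for row in range(config.n_responsive_otus):  # every responsive OTU responds
            if not active[row].any():
                active[row, rng.integers(p)] = True
        signs = np.where(rng.random((config.n_responsive_otus, p)) < 0.5, -1.0, 1.0)
        beta[responsive] = config.effect_size_chem * signs * active
        lu_active = rng.random((config.n_responsive_otus, n_lu)) < 0.5
        lu_signs = np.where(
            rng.random((config.n_responsive_otus, n_lu)) < 0.5, -1.0, 1.0
        )
        gamma[responsive] = config.effect_size_landuse * lu_signs * lu_active
    return baseline, responsive, beta, gamma


def scenario_coefficients(config: ScenarioConfig) -> dict:
    """The coefficient matrices ``generate_counts`` would draw for ``config``.

    Useful for constructing modified scenarios (e.g. strengthening one
    variable's coupling) without generating counts twice: edit the returned
    ``beta`` / ``gamma`` and pass them back to :func:`generate_counts` or
    :func:`generate_scenario`.
    """
    config.validate()
    baseline, responsive, beta, gamma = _draw_coefficients(config, _rng(config, 2))
    otu_ids = [f"OTU_{k + 1:05d}" for k in range(config.n_otus)]
    return {
        "baseline": baseline,
        "responsive_otus": [otu_ids[k] for k in responsive],
        "beta": pd.DataFrame(beta, index=otu_ids, columns=list(CHEM_VARIABLES)),
        "gamma": pd.DataFrame(gamma, index=otu_ids, columns=list(config.land_uses())),
    }


def generate_counts(
    config: ScenarioConfig,
    latent_chemistry: pd.DataFrame,
    land_use_labels: pd.Series,
    beta: np.ndarray | None = None,
    gamma: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw replicate-level OTU counts responding to chemistry and land use.

    Per site the expected relative abundances are
    softmax(baseline_k + sum_v beta_kv z_v + gamma_k[land use]) with z the
    column-standardized latent chemistry.  Each replicate draws its total
    reads from Poisson(depth_mean) and its composition from a Dirichlet
    with concentration ``overdispersion * expected_abundance``, then counts
    from the resulting multinomial.  Pass ``beta`` / ``gamma`` to override
    the randomly drawn coefficient matrices (e.g. to strengthen one
    variable's coupling); they are recorded in the returned truth dict.
    """
    config.validate()
    if latent_chemistry.isna().any().any():
        raise ConfigError("latent chemistry must not contain missing values")
    rng = _rng(config, 2)
    baseline, responsive, beta_drawn, gamma_drawn = _draw_coefficients(config, rng)
    if beta is None:
        beta = beta_drawn
    else:
        beta = np.asarray(beta, dtype=float)
    if gamma is None:
        gamma = gamma_drawn
    else:
        gamma = np.asarray(gamma, dtype=float)
    chem = latent_chemistry.loc[land_use_labels.index]
    z = (chem - chem.mean(axis=0)) / chem.std(axis=0, ddof=0).replace(0.0, 1.0)
    lu_index = {lu: i for i, lu in enumerate(config.land_uses())}
    lu_codes = np.asarray([lu_index[lu] for lu in land_use_labels])
    logits = baseline[None, :] + z.to_numpy() @ beta.T + gamma[:, lu_codes].T
    logits -= logits.max(axis=1, keepdims=True)
    props = np.exp(logits)
    props /= props.sum(axis=1, keepdims=True)

    otu_ids = [f"OTU_{k + 1:05d}" for k in range(config.n_otus)]
    n_rows = len(land_use_labels) * config.n_replicates
    counts = np.zeros((n_rows, config.n_otus), dtype=np.int64)
    sample_ids = []
    row = 0
    for s, site in enumerate(land_use_labels.index):
        alpha = config.overdispersion * props[s]
        for r in range(config.n_replicates):
            total = int(rng.poisson(config.depth_mean))
            p_rep = rng.dirichlet(alpha)
            counts[row] = rng.multinomial(total, p_rep)
            sample_ids.append(f"{site}_r{r + 1}")
            row += 1
    table = pd.DataFrame(counts, index=sample_ids, columns=otu_ids)
    truth = {
        "otu_ids": otu_ids,
        "responsive_otus": [otu_ids[k] for k in responsive],
        "baseline": baseline,
        "beta": pd.DataFrame(beta, index=otu_ids, columns=list(CHEM_VARIABLES)),
        "gamma": pd.DataFrame(gamma, index=otu_ids, columns=list(config.land_uses())),
        "expected_proportions": pd.DataFrame(
            props, index=land_use_labels.index, columns=otu_ids
        ),
    }
    return table, truth


def generate_scenario(
    config: ScenarioConfig,
    beta: np.ndarray | None = None,
    gamma: np.ndarray | None = None,
) -> SyntheticDataset:
    """Generate a complete scenario: labels, chemistry, counts, metadata."""
    config.validate()
    labels = generate_land_use(config)
    observed, latent = generate_chemistry(config, labels)
    counts, truth = generate_counts(config, latent, labels, beta=beta, gamma=gamma)
    rng = _rng(config, 3)
    regions = pd.Series(
        rng.choice([f"R{r + 1:02d}" for r in range(10)], size=config.n_sites),
        index=labels.index,
    )
    meta_rows = []
    for sample_id in counts.index:
        site = sample_id.rsplit("_r", 1)[0]
        meta_rows.append(
            {
                "sample_id": sample_id,
                "site_id": site,
                "land_use": labels.loc[site],
                "region": regions.loc[site],
            }
        )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return SyntheticDataset(
        otu_counts=counts,
        chemistry=observed,
        latent_chemistry=latent,
        metadata=metadata,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write the dataset in the pipeline's on-disk formats.

    OTU counts as TSV (first column ``sample_id``), metadata and chemistry
    as CSV (empty cell = missing), ground truth as JSON.  Returns the paths
    written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": outdir / "otu_table.tsv",
        "metadata": outdir / "metadata.csv",
        "chemistry": outdir / "chemistry.csv",
        "truth": outdir / "truth.json",
    }
    dataset.otu_counts.rename_axis("sample_id").to_csv(paths["otu_table"], sep="\t")
    dataset.metadata.to_csv(paths["metadata"])
    dataset.chemistry.rename_axis("site_id").to_csv(paths["chemistry"])
    truth = dataset.truth
    serializable = {
        "responsive_otus": truth["responsive_otus"],
        "baseline": np.asarray(truth["baseline"]).tolist(),
        "beta": truth["beta"].to_dict(orient="index"),
        "gamma": truth["gamma"].to_dict(orient="index"),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(serializable, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
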