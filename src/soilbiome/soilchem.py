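"""Soil-chemistry ordination and guideline-based quality categories.

Two independent pieces live here:

* probabilistic PCA (PPCA) fitted by expectation-maximization, which
  tolerates missing measurements by marginalizing them in the E-step.  The
  model is x = W z + mu + eps with isotropic noise eps ~ N(0, sigma^2 I);
  on complete data its maximum-likelihood subspace coincides with classical
  PCA, which gives a sharp correctness contract.  Site scores on the
  leading axes summarise the whole chemistry profile and can themselves be
  predicted from community data.

* conversion of soil measurements into five ordered quality categories
  (very low, low, normal, high, very high) using per-variable, per-context
  breakpoints loaded from a config file, and the bookkeeping to compare a
  predicted category against the true one (correct / better / worse /
  opposite relative to the variable's optimal category).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PcaResult",
    "ppca_em",
    "CATEGORIES",
    "QualityThresholds",
    "load_quality_thresholds",
    "assign_category",
    "compare_categories",
    "QualityAssessment",
    "score_table",
]

CATEGORIES = ("very low", "low", "normal", "high", "very high")
OUTCOMES = ("correct", "better", "worse", "opposite")


# ---------------------------------------------------------------------------
# probabilistic PCA


@dataclass(frozen=True)
class PcaResult:
    n_components: int
    loadings: pd.DataFrame  # variable x component (scaled by singular values)
    scores: pd.DataFrame  # site x component (posterior mean of z, rotated)
    noise_variance: float
    mean: pd.Series  # fitted mean on the standardized scale
    standardize_mean: pd.Series  # per-variable centering used
    standardize_sd: pd.Series  # per-variable scaling used
    iterations_run: int
    converged: bool
    loglik_trace: np.ndarray

    def reconstruction(self) -> pd.DataFrame:
        """Model reconstruction of every entry on the natural scale.

        W z + mu mapped back through the standardization; observed cells
        are smoothed, missing cells are the model's imputation.
        """
        fitted_std = (
            self.scores.to_numpy() @ self.loadings.to_numpy().T + self.mean.to_numpy()
        )
        natural = fitted_std * self.standardize_sd.to_numpy() + self.standardize_mean.to_numpy()
        return pd.DataFrame(natural, index=self.scores.index, columns=self.loadings.index)


def _observed_loglik(
    X: np.ndarray, mask: np.ndarray, W: np.ndarray, mu: np.ndarray, s2: float
) -> float:
    ll = 0.0
    for i in range(X.shape[0]):
        o = mask[i]
        if not o.any():
            continue
        x = X[i, o] - mu[o]
        Wo = W[o]
        C = Wo @ Wo.T + s2 * np.eye(int(o.sum()))
        sign, logdet = np.linalg.slogdet(C)
        ll += -0.5 * (o.sum() * np.log(2 * np.pi) + logdet + x @ np.linalg.solve(C, x))
    return float(ll)


def ppca_em(
    chem: pd.DataFrame,
    n_components: int = 2,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int | None = None,
) -> PcaResult:
    """Fit probabilistic PCA by EM, marginalizing missing entries.

    Variables are first standardized using their observed entries.  Each EM
    sweep computes the exact posterior of the latent scores given the
    observed coordinates of every site, then updates the mean, loadings and
    noise variance in turn (conditional maximizations, so the observed-data
    log-likelihood never decreases).  Convergence is declared when the
    relative log-likelihood change drops below ``tol``.

    Returns loadings rotated to the orthogonal, variance-ordered form (so
    on complete data they span the classical PCA subspace) and site scores
    as posterior means in that rotated basis.
    """
    if n_components >= chem.shape[1]:
        raise ValueError("n_components must be smaller than the number of variables")
    obs_counts = chem.notna().sum(axis=0)
    bad = obs_counts[obs_counts < 2]
    if len(bad):
        raise ValueError(
            "variable(s) observed in fewer than 2 sites: "
            + ", ".join(map(str, bad.index))
        )
    mu_std = chem.mean(axis=0)
    sd_std = chem.std(axis=0, ddof=1)
    if (sd_std == 0).any():
        zero = sd_std.index[sd_std == 0]
        raise ValueError(f"constant variable(s): {', '.join(map(str, zero))}")
    Xdf = (chem - mu_std) / sd_std
    X = Xdf.to_numpy(dtype=float)
    mask = ~np.isnan(X)
    Xf = np.where(mask, X, 0.0)
    n, p = X.shape
    q = n_components

    rng = np.random.default_rng(seed)
    W = rng.normal(scale=0.1, size=(p, q))
    mu = np.zeros(p)
    s2 = 1.0

    trace = []
    ll_old = -np.inf
    converged = False
    iters = 0
    M = np.zeros((n, q))  # posterior means
    Cs = np.zeros((n, q, q))  # posterior covariances
    for iters in range(1, max_iter + 1):
        # E-step: exact posterior of z_i given the observed coordinates
        for i in range(n):
            o = mask[i]
            Wo = W[o]
            Mi = Wo.T @ Wo + s2 * np.eye(q)
            Mi_inv = np.linalg.inv(Mi)
            M[i] = Mi_inv @ Wo.T @ (Xf[i, o] - mu[o])
            Cs[i] = s2 * Mi_inv
        # CM-step 1: mean, given current loadings
        fitted = M @ W.T
        resid = np.where(mask, Xf - fitted, 0.0)
        mu = resid.sum(axis=0) / mask.sum(axis=0)
        # CM-step 2: loadings, row by row over the sites observing each variable
        Ezz = Cs + np.einsum("ik,il->ikl", M, M)
        for j in range(p):
            rows = mask[:, j]
            S1 = (Xf[rows, j] - mu[j]) @ M[rows]
            S2 = Ezz[rows].sum(axis=0)
            W[j] = np.linalg.solve(S2, S1)
        # CM-step 3: noise variance
        total = 0.0
        for j in range(p):
            rows = mask[:, j]
            r = Xf[rows, j] - mu[j] - M[rows] @ W[j]
            total += float(r @ r) + float(W[j] @ Cs[rows].sum(axis=0) @ W[j])
        # floor keeps the likelihood finite when the data are exactly low-rank
        s2 = max(total / mask.sum(), 1e-9)
        ll = _observed_loglik(Xf, mask, W, mu, s2)
        trace.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll
    if not converged:
        logger.warning("ppca_em did not converge in %d iterations", max_iter)

    # final E-step in the converged parameters, then rotate to the
    # orthogonal variance-ordered basis
    for i in range(n):
        o = mask[i]
        Wo = W[o]
        Mi = Wo.T @ Wo + s2 * np.eye(q)
        M[i] = np.linalg.solve(Mi, Wo.T @ (Xf[i, o] - mu[o]))
    U, S, Vt = np.linalg.svd(W, full_matrices=False)
    loadings = U * S
    scores = M @ Vt.T
    for c in range(q):  # deterministic sign: dominant loading positive
        jmax = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[jmax, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{c + 1}" for c in range(q)]
    return PcaResult(
        n_components=q,
        loadings=pd.DataFrame(loadings, index=chem.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=chem.index, columns=comp_names),
        noise_variance=float(s2),
        mean=pd.Series(mu, index=chem.columns),
        standardize_mean=mu_std,
        standardize_sd=sd_std,
        iterations_run=iters,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# quality categories


@dataclass(frozen=True)
class QualityThresholds:
    """Per-variable, per-context category breakpoints and optimal category.

    Four strictly increasing breakpoints per (variable, context) delimit
    the five ordered categories.  A ``"default"`` context is used when a
    requested context has no entry for the variable.
    """

    breakpoints: Mapping[str, Mapping[str, tuple]]  # variable -> context -> 4 floats
    optimal: Mapping[str, Mapping[str, str]]  # variable -> context -> category

    @property
    def variables(self) -> tuple:
        return tuple(self.breakpoints)

    def lookup(self, variable: str, context: str = "default") -> tuple[tuple, str]:
        if variable not in self.breakpoints:
            raise KeyError(f"no quality thresholds for variable {variable!r}")
        ctxs = self.breakpoints[variable]
        if context not in ctxs:
            if "default" not in ctxs:
                raise KeyError(
                    f"variable {variable!r} has neither context {context!r} nor a default"
                )
            logger.debug(
                "thresholds: falling back to default context for %s (%s)",
                variable,
                context,
            )
            context = "default"
        return tuple(ctxs[context]), self.optimal[variable][context]


def load_quality_thresholds(path) -> QualityThresholds:
    """Load a YAML thresholds config and validate its structure.

    Expected layout::

        variables:
          pH:
            optimal: normal          # optional, default "normal"
            contexts:
              default: {breakpoints: [5.0, 5.5, 6.2, 6.6]}
              pastoral: {breakpoints: [5.2, 5.6, 6.3, 6.6]}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "variables" not in raw:
        raise ValueError(f"{path}: thresholds file must have a top-level 'variables' map")
    breakpoints: dict = {}
    optimal: dict = {}
    for var, spec in raw["variables"].items():
        var_optimal = spec.get("optimal", "normal")
        contexts = spec.get("contexts", {})
        if not contexts:
            raise ValueError(f"{path}: variable {var!r} has no contexts")
        breakpoints[var] = {}
        optimal[var] = {}
        for ctx, ctx_spec in contexts.items():
            bps = ctx_spec.get("breakpoints")
            if bps is None or len(bps) != 4:
                raise ValueError(
                    f"{path}: {var}/{ctx} needs exactly 4 breakpoints, got {bps!r}"
                )
            bps = tuple(float(b) for b in bps)
            if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
                raise ValueError(
                    f"{path}: {var}/{ctx} breakpoints must be strictly increasing: {bps}"
                )
            opt = ctx_spec.get("optimal", var_optimal)
            if opt not in CATEGORIES:
                raise ValueError(f"{path}: {var}/{ctx} unknown optimal category {opt!r}")
            breakpoints[var][ctx] = bps
            optimal[var][ctx] = opt
    return QualityThresholds(breakpoints=breakpoints, optimal=optimal)


def assign_category(
    value: float, variable: str, context: str, thresholds: QualityThresholds
) -> str:
    """Map a measured or predicted value to its quality category.

    Intervals are lower-closed / upper-open, so a value exactly on a
    breakpoint belongs to the higher category.
    """
    bps, _ = thresholds.lookup(variable, context)
    idx = int(np.searchsorted(np.asarray(bps), value, side="right"))
    return CATEGORIES[idx]


def compare_categories(
    true_cat: str,
    pred_cat: str,
    variable: str,
    thresholds: QualityThresholds,
    context: str = "default",
) -> str:
    """Classify a predicted category against the true one.

    Both categories are expressed as signed deviations from the variable's
    optimal category.  Identical categories are ``correct``; equal-magnitude
    deviations on opposite sides are ``opposite``; a strictly smaller
    absolute deviation is ``better``; anything else is ``worse``.
    """
    for cat in (true_cat, pred_cat):
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
    _, opt = thresholds.lookup(variable, context)
    opt_idx = CATEGORIES.index(opt)
    dev_true = CATEGORIES.index(true_cat) - opt_idx
    dev_pred = CATEGORIES.index(pred_cat) - opt_idx
    if dev_true == dev_pred:
        return "correct"
    if dev_true != 0 and dev_pred == -dev_true:
        return "opposite"
    if abs(dev_pred) < abs(dev_true):
        return "better"
    return "worse"


@dataclass(frozen=True)
class QualityAssessment:
    """Per (site, variable) category comparison plus per-variable summary."""

    records: pd.DataFrame  # site, variable, true/pred value+category, outcome
    proportions: pd.DataFrame  # variable x outcome, rows sum to 1

    def pooled_proportions(self) -> pd.Series:
        """Outcome proportions pooled over all (site, variable) records."""
        return self.records["outcome"].value_counts(normalize=True).reindex(
            OUTCOMES, fill_value=0.0
        )


def score_table(
    true_values: pd.DataFrame,
    predicted_values: pd.DataFrame,
    thresholds: QualityThresholds,
    contexts=None,
) -> QualityAssessment:
    """Categorize true and predicted values and tally comparison outcomes.

    ``contexts`` may be None (use the default context everywhere), a single
    context name, or a per-site mapping (e.g. each site's land use).
    Entries where either value is missing are skipped.
    """
    common_sites = true_values.index.intersection(predicted_values.index)
    common_vars = [v for v in true_values.columns if v in predicted_values.columns]
    if contexts is None:
        ctx_series = pd.Series("default", index=common_sites)
    elif isinstance(contexts, str):
        ctx_series = pd.Series(contexts, index=common_sites)
    else:
        ctx_series = pd.Series(contexts).loc[common_sites]
    rows = []
    for var in common_vars:
        for site in common_sites:
            t = true_values.loc[site, var]
            p = predicted_values.loc[site, var]
            if pd.isna(t) or pd.isna(p):
                continue
            ctx = ctx_series.loc[site]
            tc = assign_category(t, var, ctx, thresholds)
            pc = assign_category(p, var, ctx, thresholds)
            rows.append(
                {
                    "site_id": site,
                    "variable": var,
                    "true_value": t,
                    "predicted_value": p,
                    "true_category": tc,
                    "predicted_category": pc,
                    "outcome": compare_categories(tc, pc, var, thresholds, ctx),
                }
            )
    records = pd.DataFrame(rows)
    if records.empty:
        raise ValueError("no comparable (site, variable) entries to score")
    proportions = (
        records.groupby("variable")["outcome"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(OUTCOMES), fill_value=0.0)
    )
    return QualityAssessment(records=records, proportions=proportions)
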