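"""Variant-specific priors by EM regression of posteriors on covariates.

The shared empirical prior gives every variant the same prior mean.  This
module re-calibrates the prior per variant from its covariates (in-silico
scores, clinical classification, structural density) by a fixed-point EM
scheme:

1. responses start at the empirical posterior means;
2. logit(response) is regressed on the covariates by weighted least squares;
3. fitted means are converted to variant-specific beta priors (carrying the
   empirical concentration nu) and responses are recomputed as the
   conjugate posterior under the new priors;

steps 2-3 repeat until the largest change in any fitted mean falls below a
tolerance.  Evidence weights keep sparsely observed variants from dragging
the regression; the concentration is conserved, so only the prior *mean* is
covariate-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .empirical_bayes import BetaParams, empirical_posterior
from .variant_data import CovariateSet, VariantTable, encode_clinvar

__all__ = [
    "EMModel",
    "VariantPrior",
    "DEFAULT_COVARIATES",
    "covariate_matrix",
    "regress_step",
    "em_fit",
    "predict_prior",
]

DEFAULT_COVARIATES = ("cpvt_density", "revel", "alphamissense", "clinvar")

EPS = 1e-4


@dataclass(frozen=True)
class VariantPrior:
    """Variant-specific beta prior produced by the EM calibration."""

    key: tuple[int, str, str]
    alpha_em: float
    beta_em: float
    from_covariates: bool = True

    def __post_init__(self) -> None:
        if not (self.alpha_em > 0 and self.beta_em > 0):
            raise ValueError("prior parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha_em / (self.alpha_em + self.beta_em)

    @property
    def nu(self) -> float:
        return self.alpha_em + self.beta_em


@dataclass
class EMModel:
    """Fitted EM regression: coefficients on the logit scale plus metadata.

    Covariates are standardized to zero weighted mean / unit weighted
    variance before fitting; missing values are mean-imputed with a paired
    missingness-indicator column.  ``coefficients`` maps design-column names
    (including ``intercept`` and ``<name>__missing`` indicators) to weights.
    """

    covariate_names: tuple[str, ...]
    coefficients: dict[str, float]
    impute_means: dict[str, float]
    standardize_mean: dict[str, float]
    standardize_scale: dict[str, float]
    nu: float
    n_iterations: int = 0
    converged: bool = False
    trajectory: list[float] = field(default_factory=list)
    dropped: tuple[str, ...] = ()


def _raw_covariate(cov: CovariateSet, name: str) -> Optional[float]:
    if name == "clinvar":
        return encode_clinvar(cov.clinvar_code)
    return getattr(cov, name)


def covariate_matrix(variants: VariantTable,
                     covariates: Sequence[str] = DEFAULT_COVARIATES
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Raw covariate matrix (n x p) with NaN for missing, plus missing mask."""
    rows = []
    for rec in variants:
        rows.append([
            v if (v := _raw_covariate(rec.covariates, name)) is not None
            else np.nan
            for name in covariates])
    X = np.asarray(rows, dtype=float).reshape(len(rows), len(covariates))
    return X, np.isnan(X)


def _build_design(X_raw: np.ndarray, miss: np.ndarray, w: np.ndarray,
                  names: Sequence[str]):
    """Impute, standardize and assemble the design; returns metadata too."""
    wn = w / w.sum()
    impute, center, scale = {}, {}, {}
    cols, col_names, dropped = [], [], []
    for j, name in enumerate(names):
        x = X_raw[:, j].copy()
        m = miss[:, j]
        if m.all():
            dropped.append(name)
            impute[name] = 0.0
            center[name] = 0.0
            scale[name] = 1.0
            continue
        wj = wn[~m] / wn[~m].sum()
        mu_obs = float(np.sum(wj * x[~m]))
        impute[name] = mu_obs
        x[m] = mu_obs
        mu = float(np.sum(wn * x))
        sd = float(np.sqrt(np.sum(wn * (x - mu) ** 2)))
        if sd <= 1e-12:
            dropped.append(name)
            center[name] = mu
            scale[name] = 1.0
            continue
        center[name] = mu
        scale[name] = sd
        cols.append((x - mu) / sd)
        col_names.append(name)
        if m.any():
            cols.append(m.astype(float))
            col_names.append(f"{name}__missing")
    design = np.column_stack([np.ones(len(X_raw))] + cols) \
        if cols else np.ones((len(X_raw), 1))
    col_names = ["intercept"] + col_names
    return design, col_names, impute, center, scale, tuple(dropped)


def _wls(design: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w / w.sum())
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    return beta


def regress_step(variants: VariantTable, responses: Sequence[float],
                 weights: Sequence[float],
                 covariates: Sequence[str] = DEFAULT_COVARIATES
                 ) -> dict[str, float]:
    """One weighted least-squares fit of logit(response) on the covariates.

    Returns the coefficient map (standardized-covariate scale).  Constant or
    fully missing covariates are dropped with a warning.
    """
    y = logit(np.clip(np.asarray(responses, dtype=float), EPS, 1 - EPS))
    w = np.asarray(weights, dtype=float)
    X_raw, miss = covariate_matrix(variants, covariates)
    design, names, *_, dropped = _build_design(X_raw, miss, w, covariates)
    if dropped:
        warnings.warn(f"dropped degenerate covariates: {dropped}")
    beta = _wls(design, y, w)
    return dict(zip(names, beta.tolist()))


def em_fit(variants: VariantTable, empirical_prior: BetaParams,
           covariates: Sequence[str] = DEFAULT_COVARIATES,
           tol: float = 1e-6, max_iter: int = 100
           ) -> tuple[EMModel, dict[tuple[int, str, str], VariantPrior]]:
    """Fit variant-specific priors by the fixed-point EM scheme.

    Returns the fitted model and a map from variant key to its prior.
    ``nu`` (the concentration) is carried unchanged from the empirical
    prior, so alpha_em + beta_em = nu for every variant.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    recs = list(variants)
    if not recs:
        raise ValueError("empty variant table")
    keys = [r.key for r in recs]
    a = np.array([r.counts.affected for r in recs], dtype=float)
    t = np.array([r.counts.total for r in recs], dtype=float)
    w = np.array([r.weight if r.weight is not None else 1.0 for r in recs])
    if w.sum() <= 0:
        raise ValueError("all evidence weights are zero")
    nu = empirical_prior.nu

    X_raw, miss = covariate_matrix(variants, covariates)
    design, col_names, impute, center, scale, dropped = _build_design(
        X_raw, miss, w, covariates)
    if dropped:
        warnings.warn(f"dropped degenerate covariates: {dropped}")

    responses = np.array([
        empirical_posterior(r.counts, empirical_prior) for r in recs])
    p_prev = responses.copy()
    trajectory: list[float] = []
    converged = False
    beta = np.zeros(design.shape[1])
    p_hat = p_prev
    for it in range(1, max_iter + 1):
        y = logit(np.clip(responses, EPS, 1 - EPS))
        beta = _wls(design, y, w)
        fitted = design @ beta
        if not np.all(np.isfinite(fitted)):
            bad = np.flatnonzero(~np.isfinite(fitted))[:10]
            raise FloatingPointError(
                f"non-finite fitted values at rows {bad.tolist()} "
                f"(keys {[keys[i] for i in bad]})")
        p_hat = np.clip(expit(fitted), EPS, 1 - EPS)
        responses = (a + p_hat * nu) / (t + nu)
        delta = float(np.max(np.abs(p_hat - p_prev)))
        trajectory.append(delta)
        p_prev = p_hat
        if delta < tol:
            converged = True
            break

    model = EMModel(
        covariate_names=tuple(covariates),
        coefficients=dict(zip(col_names, beta.tolist())),
        impute_means=impute,
        standardize_mean=center,
        standardize_scale=scale,
        nu=float(nu),
        n_iterations=len(trajectory),
        converged=converged,
        trajectory=trajectory,
        dropped=dropped,
    )
    priors = {
        key: VariantPrior(key, float(p * nu), float((1 - p) * nu))
        for key, p in zip(keys, p_hat)
    }
    return model, priors


def predict_prior(model: EMModel, covariates: CovariateSet,
                  key: tuple[int, str, str] = (0, "?", "?"),
                  empirical_prior: Optional[BetaParams] = None
                  ) -> VariantPrior:
    """Variant prior for an (possibly unseen) covariate vector.

    If every covariate is missing, falls back to the empirical prior mean
    (flagged via ``from_covariates=False``); ``empirical_prior`` must then
    be supplied.
    """
    raw = {name: _raw_covariate(covariates, name)
           for name in model.covariate_names}
    if all(v is None for v in raw.values()):
        if empirical_prior is None:
            raise ValueError(
                "all covariates missing and no empirical prior to fall back on")
        p = empirical_prior.mean
        return VariantPrior(key, p * model.nu, (1 - p) * model.nu,
                            from_covariates=False)
    z = model.coefficients.get("intercept", 0.0)
    for name in model.covariate_names:
        if name not in model.standardize_scale or \
                f"{name}" not in model.coefficients:
            continue
        v = raw[name]
        missing = v is None
        if missing:
            v = model.impute_means[name]
        x = (v - model.standardize_mean[name]) / model.standardize_scale[name]
        z += model.coefficients[name] * x
        mcol = f"{name}__missing"
        if missing and mcol in model.coefficients:
            z += model.coefficients[mcol]
    p = float(np.clip(expit(z), EPS, 1 - EPS))
    return VariantPrior(key, p * model.nu, (1 - p) * model.nu)
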