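"""Shared beta prior across variants and per-variant conjugate posteriors.

The ensemble of variants is modelled as a beta-binomial: each variant's true
penetrance is a draw from a shared Beta(alpha, beta) prior, and its affected
count is binomial given that penetrance.  The prior mean is pinned to the
evidence-weighted average of observed penetrance; the concentration
nu = alpha + beta is estimated from the ensemble (weighted marginal
likelihood by default).  Conjugacy then gives closed-form per-variant
posteriors and equal-tailed credible intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from .variant_data import HeterozygoteCounts, VariantTable

__all__ = [
    "BetaParams",
    "weighted_prior_mean",
    "fit_empirical_prior",
    "empirical_posterior",
    "credible_interval",
]

NU_BOUNDS = (0.1, 1e4)


@dataclass(frozen=True)
class BetaParams:
    """A beta distribution acting as a penetrance prior."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def nu(self) -> float:
        """Concentration (prior pseudo-count mass)."""
        return self.alpha + self.beta


def _arrays(variants: VariantTable):
    recs = [r for r in variants if r.counts.total > 0]
    if not recs:
        raise ValueError("no variants with observed heterozygotes")
    a = np.array([r.counts.affected for r in recs], dtype=float)
    t = np.array([r.counts.total for r in recs], dtype=float)
    w = np.array([r.weight if r.weight is not None else 1.0 for r in recs])
    return a, t, w


def weighted_prior_mean(variants: VariantTable) -> float:
    """Evidence-weighted average of observed penetrance across variants.

    Weights are normalized to sum to one inside the average.
    """
    a, t, w = _arrays(variants)
    if w.sum() <= 0:
        raise ValueError("all evidence weights are zero")
    return float(np.sum((a / t) * w) / w.sum())


def _weighted_bb_nll(log_nu: float, a, b, w, mean: float) -> float:
    """Negative weighted beta-binomial marginal log-likelihood at fixed mean."""
    nu = np.exp(log_nu)
    pa, pb = mean * nu, (1.0 - mean) * nu
    ll = betaln(a + pa, b + pb) - betaln(pa, pb)
    return float(-np.sum(w * ll) / np.sum(w))


def _loo_means(a, t, w):
    """Leave-one-out weighted prior means (each variant's own row removed)."""
    p = a / t
    s, ws = np.sum(p * w), np.sum(w)
    denom = ws - w
    with np.errstate(invalid="ignore", divide="ignore"):
        m = (s - p * w) / denom
    m[denom <= 0] = s / ws
    return np.clip(m, 1e-12, 1 - 1e-12)


def _mse_objective(log_nu: float, a, t, w, means) -> float:
    nu = np.exp(log_nu)
    post = (a + means * nu) / (t + nu)
    return float(np.sum(w * (post - a / t) ** 2) / np.sum(w))


def fit_empirical_prior(variants: VariantTable,
                        method: str = "mle") -> BetaParams:
    """Estimate the shared empirical beta prior from the variant ensemble.

    The prior mean is the evidence-weighted average of observed penetrance.
    The concentration nu is estimated by the chosen criterion, optimized over
    log nu in [0.1, 1e4]:

    ``mle``
        maximize the weighted beta-binomial marginal likelihood at fixed
        mean (default; identifies nu from the ensemble's overdispersion).
    ``mse_loo`` / ``mse_insample``
        minimize the weighted squared error between each variant's conjugate
        posterior (prior mean computed with/without its own row) and its
        observed penetrance.  This error is monotone in nu, so these
        criteria pin nu at the lower bound; they are retained for
        transparency and comparison, not recommended.

    If the smooth optimizer fails, a log-spaced grid search over the same
    range is used with a warning.
    """
    a, t, w = _arrays(variants)
    if len(a) < 2:
        raise ValueError("need at least two variants with heterozygotes")
    if w.sum() <= 0:
        raise ValueError("all evidence weights are zero")
    mean = float(np.sum((a / t) * w) / w.sum())
    mean = min(max(mean, 1e-9), 1 - 1e-9)
    b = t - a

    if method == "mle":
        def obj(log_nu):
            return _weighted_bb_nll(log_nu, a, b, w, mean)
    elif method == "mse_loo":
        means = _loo_means(a, t, w)

        def obj(log_nu):
            return _mse_objective(log_nu, a, t, w, means)
    elif method == "mse_insample":
        def obj(log_nu):
            return _mse_objective(log_nu, a, t, w, np.full_like(a, mean))
    else:
        raise ValueError(f"unknown method {method!r}")

    lo, hi = np.log(NU_BOUNDS[0]), np.log(NU_BOUNDS[1])
    res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    if res.success and np.isfinite(res.fun):
        log_nu = float(res.x)
    else:  # pragma: no cover - defensive fallback
        warnings.warn("scalar optimizer failed; falling back to grid search")
        grid = np.linspace(lo, hi, 400)
        vals = [obj(g) for g in grid]
        log_nu = float(grid[int(np.argmin(vals))])
    nu = float(np.exp(log_nu))
    return BetaParams(mean * nu, (1.0 - mean) * nu)


def empirical_posterior(counts: HeterozygoteCounts, prior: BetaParams) -> float:
    """Posterior mean penetrance under the shared prior (conjugate update)."""
    return (counts.affected + prior.alpha) / (counts.total + prior.nu)


def credible_interval(shape: BetaParams, level: float = 0.95
                      ) -> tuple[float, float]:
    """Equal-tailed beta quantile interval for a posterior shape."""
    if not (0.0 < level < 1.0):
        raise ValueError("credible level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo = float(beta_dist.ppf(tail, shape.alpha, shape.beta))
    hi = float(beta_dist.ppf(1.0 - tail, shape.alpha, shape.beta))
    return lo, hi
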