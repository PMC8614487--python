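"""Derived genetic parameters and their uncertainty.

Heritability, genetic/phenotypic correlations and the genetic
coefficient of variation are simple functions of the fitted (co)variance
components; their standard errors are obtained by repeated sampling of
the parameter vector from its asymptotic normal distribution (10,000
draws by default), and significance of correlations by likelihood-ratio
tests of nested reduced models against chi-squared thresholds (3.84 at
1 df, 5.99 at 2 df, alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .aireml import REMLFit, VarianceComponents

__all__ = [
    "heritability",
    "correlation",
    "cv_genetic",
    "SamplingSE",
    "se_by_sampling",
    "LRTResult",
    "lrt_correlations",
]


def heritability(vc: VarianceComponents, trait: int = 0) -> float:
    """h^2 = sigma2_g / (sigma2_g + sigma2_e) for one trait."""
    s2g = float(vc.G[trait, trait])
    s2e = float(vc.R[trait, trait])
    s2p = s2g + s2e
    if s2p <= 0:
        raise ValueError("phenotypic variance must be positive")
    return s2g / s2p


def correlation(vc: VarianceComponents, kind: str = "genetic",
                pair: tuple = (0, 1)) -> float:
    """Genetic or phenotypic correlation between two traits.

    ``genetic``: cov_g / sqrt(var_gX var_gY); ``phenotypic``: the same on
    P = G + R.
    """
    i, j = pair
    if kind == "genetic":
        M = vc.G
    elif kind == "phenotypic":
        M = vc.P
    else:
        raise ValueError("kind must be 'genetic' or 'phenotypic'")
    vx, vy = float(M[i, i]), float(M[j, j])
    if vx <= 0 or vy <= 0:
        raise ValueError("correlation undefined for a zero-variance trait")
    return float(M[i, j] / np.sqrt(vx * vy))


def cv_genetic(sigma2_g: float, mean: float) -> float:
    """Genetic coefficient of variation, percent: sqrt(sigma2_g)/mean * 100."""
    if mean <= 0:
        raise ValueError("trait mean must be positive")
    if sigma2_g < 0:
        raise ValueError("genetic variance must be non-negative")
    return float(np.sqrt(sigma2_g) / mean * 100.0)


@dataclass
class SamplingSE:
    """Sampling-based standard error plus draw bookkeeping."""

    se: float
    n_samples: int
    n_redrawn: int

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.se


def se_by_sampling(
    fit: REMLFit,
    fn: Callable[[np.ndarray, np.ndarray], float],
    n_samples: int = 10_000,
    seed: int | np.random.Generator | None = None,
    max_invalid_fraction: float = 0.5,
) -> SamplingSE:
    """SE of a parameter function by sampling from N(theta, theta_cov).

    ``fn(G, R)`` is evaluated on each draw; draws producing a
    non-positive-definite G or R (e.g. negative variances) are redrawn
    and counted.  Deterministic given the seed.  Raises if more than
    ``max_invalid_fraction`` of draws are invalid - the estimate is then
    too close to the boundary for this SE method.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    theta = fit.theta
    cov = fit.theta_cov
    # guard tiny negative eigenvalues of the asymptotic covariance
    w, Q = np.linalg.eigh(0.5 * (cov + cov.T))
    L = Q * np.sqrt(np.clip(w, 0.0, None))
    pmap = fit.pmap
    values = np.empty(n_samples)
    filled = 0
    n_redrawn = 0
    max_total = int(np.ceil(n_samples / (1.0 - max_invalid_fraction))) + 1
    total = 0
    while filled < n_samples:
        batch = min(n_samples - filled + 1024, 4 * n_samples)
        draws = theta[None, :] + rng.standard_normal((batch, theta.size)) @ L.T
        for row in draws:
            if filled == n_samples:
                break
            total += 1
            G, R = pmap.unpack(row)
            if _valid_draw(G, R):
                values[filled] = fn(G, R)
                filled += 1
            else:
                n_redrawn += 1
            if total > max_total:
                raise ValueError(
                    "more than half of the sampled parameter vectors were "
                    "invalid; the estimate is too close to a boundary for "
                    "sampling-based SEs"
                )
    return SamplingSE(
        se=float(np.std(values, ddof=1)) if n_samples > 1 else 0.0,
        n_samples=n_samples,
        n_redrawn=n_redrawn,
    )


def _valid_draw(G: np.ndarray, R: np.ndarray) -> bool:
    for M in (G, R):
        if np.any(np.diag(M) <= 0):
            return False
        if M.shape[0] > 1 and np.linalg.eigvalsh(M).min() <= 0:
            return False
    return True


@dataclass
class LRTResult:
    """Likelihood-ratio test of a reduced against a full model."""

    minus2logLambda: float
    df: int
    threshold: float
    significant: bool
    p_value: float


def lrt_correlations(full: REMLFit, reduced: REMLFit, df: int) -> LRTResult:
    """-2 (logL_reduced - logL_full) against the chi-squared 95th percentile.

    ``df = 1`` corresponds to zeroing the genetic covariance only (test
    of the genetic correlation), ``df = 2`` to zeroing both genetic and
    residual covariances (test of the phenotypic correlation).
    """
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    n_full = full.pmap.k
    n_red = reduced.pmap.k
    if n_full - n_red != df:
        raise ValueError(
            f"models are not nested with df={df}: full has {n_full} free "
            f"parameters, reduced has {n_red}"
        )
    full_set = set(full.pmap.entries)
    if not set(reduced.pmap.entries) <= full_set:
        raise ValueError("reduced model parameters are not a subset of the full model")
    stat = -2.0 * (reduced.loglik - full.loglik)
    threshold = float(stats.chi2.ppf(0.95, df))
    return LRTResult(
        minus2logLambda=float(stat),
        df=df,
        threshold=threshold,
        significant=bool(stat > threshold),
        p_value=float(stats.chi2.sf(max(stat, 0.0), df)),
    )
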