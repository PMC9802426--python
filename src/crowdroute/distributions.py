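"""Random-variate machinery for the two stochastic ingredients of the model.

Two sources of individual variability drive the route-choice process:

* additive Gaussian noise ``eps`` on each pedestrian's walking speed,
  superimposed on the linear density--speed law (zero mean, standard
  deviation ``sigma_eps`` in m/s);
* the crowd-shared perceived path-length ratio ``lambda_p``, modeled as an
  exponentially modified Gaussian (EMG) -- the sum of an independent normal
  ``X ~ N(mu, sigma)`` and exponential ``Y ~ Exp(beta)`` variate.  The EMG
  captures the right-skewed, heavy-tailed empirical distribution of the
  squared speed ratio between the two paths.

The module provides density, sampling, moments, a numerical mode, and
maximum-likelihood fitting for the EMG, plus sampling for the velocity
noise.  Every sampling routine takes an explicit seed (or an existing
:class:`numpy.random.Generator`) so Monte Carlo runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "EmgParameters",
    "NoiseParameters",
    "LAMBDA_P_DATA_FIT",
    "LAMBDA_P_TUNED",
    "emg_pdf",
    "emg_cdf",
    "emg_sample",
    "emg_mean",
    "emg_mode",
    "emg_fit",
    "noise_sample",
]


@dataclass(frozen=True)
class EmgParameters:
    """Parameters of the exponentially modified Gaussian for ``lambda_p``.

    ``mu`` and ``sigma`` are location and scale of the Gaussian component,
    ``beta`` the scale of the exponential component; all dimensionless.
    The mean is ``mu + beta`` exactly.
    """

    mu: float
    sigma: float
    beta: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.mu, self.sigma, self.beta]).all():
            raise ValueError("EMG parameters must be finite")
        if self.sigma <= 0 or self.beta <= 0:
            raise ValueError("sigma and beta must be positive")

    @property
    def mean(self) -> float:
        return self.mu + self.beta


@dataclass(frozen=True)
class NoiseParameters:
    """Standard deviation of the additive velocity noise (m/s, >= 0)."""

    sigma_eps: float = 0.15

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_eps) or self.sigma_eps < 0:
            raise ValueError("sigma_eps must be finite and >= 0")


#: EMG fitted to the empirical perceived-ratio distribution of the field study.
LAMBDA_P_DATA_FIT = EmgParameters(mu=0.77, sigma=0.30, beta=0.68)

#: EMG tuned so that the routing model reproduces the observed occupancy and
#: herding statistics; used as the simulation default.
LAMBDA_P_TUNED = EmgParameters(mu=1.15, sigma=0.20, beta=0.33)


def _frozen(params: EmgParameters):
    # scipy's exponnorm uses K = beta / sigma as its shape parameter; its
    # density loses precision for K below ~1e-4, where the distribution is
    # Gaussian to within O(K) anyway.
    k = params.beta / params.sigma
    if k < 1e-4:
        return stats.norm(loc=params.mu, scale=params.sigma)
    return stats.exponnorm(K=k, loc=params.mu, scale=params.sigma)


def emg_pdf(params: EmgParameters, x) -> np.ndarray | float:
    """Probability density of ``X + Y`` at ``x``."""
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("x must be finite")
    out = _frozen(params).pdf(arr)
    return float(out) if np.isscalar(x) else out


def emg_cdf(params: EmgParameters, x) -> np.ndarray | float:
    """Cumulative distribution of ``X + Y`` at ``x``."""
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("x must be finite")
    out = _frozen(params).cdf(arr)
    return float(out) if np.isscalar(x) else out


def emg_sample(params: EmgParameters, n: int, seed,
               positive_only: bool = True) -> np.ndarray:
    """Draw ``n`` EMG variates.

    With ``positive_only`` (the default) any draw <= 0 is rejected and
    resampled: a perceived length ratio must be positive.  At realistic
    parameter values the rejection probability is negligible, so this does
    not measurably distort the distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = rng.normal(params.mu, params.sigma, size=n) + \
        rng.exponential(params.beta, size=n)
    if positive_only:
        for _ in range(100):
            bad = out <= 0
            if not bad.any():
                break
            k = int(bad.sum())
            out[bad] = rng.normal(params.mu, params.sigma, size=k) + \
                rng.exponential(params.beta, size=k)
        else:  # pragma: no cover - pathological parameters only
            raise RuntimeError("positivity rejection did not terminate")
    return out


def emg_mean(params: EmgParameters) -> float:
    """Expected value ``mu + beta`` (exact)."""
    return params.mu + params.beta


def emg_mode(params: EmgParameters, xatol: float = 1e-9) -> float:
    """Mode of the EMG, located numerically.

    The density is unimodal with the mode in ``(mu, mu + beta)``; we run a
    bounded scalar maximization on ``[mu - 3 sigma, mu + 3 (sigma + beta)]``.
    For ``beta`` vanishing relative to ``sigma`` the Gaussian limit ``mu``
    is returned directly (the scipy density is numerically fragile there).
    """
    if params.beta <= 1e-8 * params.sigma:
        return params.mu
    lo = params.mu - 3.0 * params.sigma
    hi = params.mu + 3.0 * (params.sigma + params.beta)
    res = optimize.minimize_scalar(
        lambda x: -emg_pdf(params, float(x)),
        bounds=(lo, hi), method="bounded", options={"xatol": xatol})
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"mode search did not converge: {res.message}")
    return float(res.x)


def emg_fit(samples) -> EmgParameters:
    """Maximum-likelihood EMG fit with moment-based initialization.

    The exponential scale is initialized from the sample skewness
    (``beta0 = s * (g1 / 2)**(1/3)``), the Gaussian part from the residual
    first two moments; scipy's ``exponnorm.fit`` then refines by MLE.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 50:
        raise ValueError("need a 1-d array of at least 50 samples")
    if not np.isfinite(x).all():
        raise ValueError("samples must be finite")
    s = x.std(ddof=1)
    if s <= 1e-9 * max(1.0, abs(x.mean())):
        raise ValueError("samples are degenerate (zero variance)")
    g1 = stats.skew(x)
    beta0 = s * np.cbrt(max(g1, 1e-3) / 2.0)
    beta0 = min(max(beta0, 1e-3 * s), 0.99 * 3 * s)
    sigma0 = np.sqrt(max(s**2 - beta0**2, (0.05 * s) ** 2))
    mu0 = x.mean() - beta0
    try:
        k, loc, scale = stats.exponnorm.fit(x, beta0 / sigma0,
                                            loc=mu0, scale=sigma0)
    except stats.FitError as exc:
        raise ValueError(f"EMG maximum-likelihood fit failed: {exc}") \
            from exc
    return EmgParameters(mu=float(loc), sigma=float(scale),
                         beta=float(max(k * scale, 1e-12)))


def noise_sample(params: NoiseParameters, n: int, seed) -> np.ndarray:
    """Draw ``n`` zero-mean Gaussian velocity perturbations (m/s)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if params.sigma_eps == 0:
        return np.zeros(n)
    return rng.normal(0.0, params.sigma_eps, size=n)
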