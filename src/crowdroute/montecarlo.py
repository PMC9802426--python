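"""Monte Carlo ensembles of optimal route-choice configurations.

Three model variants are simulated over a range of global pedestrian counts:

* ``deterministic`` -- no velocity noise, fixed perceived ratio; the optimal
  configuration is unique and the statistics are a point mass.
* ``velocity_noise`` -- per-pedestrian Gaussian speed perturbations, fixed
  perceived ratio.
* ``full`` -- speed perturbations plus a perceived ratio drawn per
  realization from the EMG.

For each realization the discomfort minimizer is solved exactly and the
occupancy of path B recorded; aggregating over realizations and counts gives
the conditional occupancy law P(N_B | N), mean occupancies, and the herding
probability P(N_B = 0 | N).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .distributions import EmgParameters, emg_mean, emg_sample
from .routing import FundamentalDiagram, Geometry, minimize_split_batch

__all__ = [
    "ModelVariant",
    "EnsembleResult",
    "EnsembleStatistics",
    "run_ensemble",
    "sweep_counts",
    "estimate_activation_threshold",
]


class ModelVariant(str, Enum):
    DETERMINISTIC = "deterministic"
    VELOCITY_NOISE = "velocity_noise"
    FULL = "full"


_VARIANT_INDEX = {v: i for i, v in enumerate(ModelVariant)}


def _as_variant(variant) -> ModelVariant:
    if isinstance(variant, ModelVariant):
        return variant
    try:
        return ModelVariant(variant)
    except ValueError:
        raise ValueError(f"invalid model variant {variant!r}") from None


def _stream(base_seed: int, variant: ModelVariant, n: int
            ) -> np.random.Generator:
    """One independent, reproducible stream per (variant, N)."""
    ss = np.random.SeedSequence(entropy=base_seed,
                                spawn_key=(_VARIANT_INDEX[variant], n))
    return np.random.default_rng(ss)


@dataclass
class EnsembleResult:
    """Empirical distribution of the path-B occupancy at one global count."""

    n: int
    n_b_samples: np.ndarray

    @property
    def m(self) -> int:
        return self.n_b_samples.size

    @property
    def pmf(self) -> np.ndarray:
        """P(N_B = k) for k = 0..n."""
        return np.bincount(self.n_b_samples, minlength=self.n + 1) / self.m

    @property
    def mean_n_b(self) -> float:
        return float(self.n_b_samples.mean())


def run_ensemble(variant, geom: Geometry, fd: FundamentalDiagram,
                 emg: EmgParameters, n: int, m: int, seed,
                 fixed_lambda_p: float | None = None) -> EnsembleResult:
    """Simulate ``m`` independent realizations at global count ``n``.

    ``fixed_lambda_p`` overrides the constant ratio used by the two
    non-``full`` variants; the default is the EMG mean (the model's expected
    perception).
    """
    variant = _as_variant(variant)
    if m < 1:
        raise ValueError("m must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    const_lam = emg_mean(emg) if fixed_lambda_p is None else fixed_lambda_p

    if variant is ModelVariant.DETERMINISTIC:
        # no randomness: solve once and replicate
        n_b, _, _ = minimize_split_batch(
            fd, np.array([const_lam]), np.zeros((1, n)), l_a=geom.l_a)
        return EnsembleResult(n, np.full(m, n_b[0], dtype=int))

    sigma = fd.noise.sigma_eps
    eps = rng.normal(0.0, sigma, size=(m, n)) if sigma > 0 else \
        np.zeros((m, n))
    if variant is ModelVariant.FULL:
        lam = emg_sample(emg, m, rng)
    else:
        lam = np.full(m, const_lam)
    n_b, _, _ = minimize_split_batch(fd, lam, eps, l_a=geom.l_a)
    return EnsembleResult(n, n_b)


@dataclass
class EnsembleStatistics:
    """Conditional occupancy statistics aggregated over a sweep of counts.

    ``p_nb[n]`` is the vector ``P(N_B = k | N = n)`` for ``k = 0..n``;
    ``mean_n_a + mean_n_b == n_values`` by construction.
    """

    variant: ModelVariant
    n_values: np.ndarray
    mean_n_b: np.ndarray
    p_nb: dict[int, np.ndarray]
    n_realizations: int

    @property
    def mean_n_a(self) -> np.ndarray:
        return self.n_values - self.mean_n_b

    @property
    def p_empty_b(self) -> np.ndarray:
        return np.array([self.p_nb[n][0] for n in self.n_values])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: variant, N, k, probability."""
        rows = []
        for n in self.n_values:
            for k, p in enumerate(self.p_nb[int(n)]):
                rows.append((self.variant.value, int(n), k, p))
        return pd.DataFrame(rows, columns=["variant", "N", "k", "probability"])

    def summary_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "n_values": [int(n) for n in self.n_values],
            "mean_n_a": [float(v) for v in self.mean_n_a],
            "mean_n_b": [float(v) for v in self.mean_n_b],
            "p_empty_b": [float(v) for v in self.p_empty_b],
            "n_realizations": self.n_realizations,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary_dict(), **kwargs)


def sweep_counts(variant, geom: Geometry, fd: FundamentalDiagram,
                 emg: EmgParameters, n_range, m: int, seed: int,
                 fixed_lambda_p: float | None = None) -> EnsembleStatistics:
    """Run :func:`run_ensemble` for every count in ``n_range``.

    Each (variant, N) pair gets an independent child stream spawned from the
    base seed, so sweeps are bit-reproducible and insensitive to the order
    or subset of counts requested.
    """
    variant = _as_variant(variant)
    n_values = np.asarray(sorted(int(n) for n in n_range))
    if n_values.size == 0:
        raise ValueError("n_range must be nonempty")
    mean_n_b = np.empty(n_values.size)
    p_nb: dict[int, np.ndarray] = {}
    for i, n in enumerate(n_values):
        res = run_ensemble(variant, geom, fd, emg, int(n), m,
                           _stream(seed, variant, int(n)),
                           fixed_lambda_p=fixed_lambda_p)
        mean_n_b[i] = res.mean_n_b
        p_nb[int(n)] = res.pmf
    return EnsembleStatistics(variant, n_values, mean_n_b, p_nb, m)


def estimate_activation_threshold(stats: EnsembleStatistics) -> int:
    """Smallest global count at which the mean path-B occupancy reaches 1.

    This is the model-side analog of the empirical activation threshold N*.
    Raises if the sweep never crosses 1 (or is not a contiguous range).
    """
    n = stats.n_values
    if n.size > 1 and not np.all(np.diff(n) == 1):
        raise ValueError("sweep must cover a contiguous range of counts")
    crossing = np.flatnonzero(stats.mean_n_b >= 1.0)
    if crossing.size == 0:
        raise ValueError("mean N_B never reaches 1 in the swept range")
    return int(n[crossing[0]])
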