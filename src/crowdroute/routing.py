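"""Variational route-choice model for a two-path (A/B) bifurcation.

A crowd of ``N`` pedestrians splits between a straight path A and a longer
detour B.  Walking speed on a path follows a linear fundamental diagram in
the path's own occupancy, ``v = v0 - kappa * N_J``, perturbed per pedestrian
by additive Gaussian noise.  Each pedestrian perceives a travel time: the
geometric time ``L_J / v`` on A, rescaled by the shared perceived-length
ratio ``lambda_p`` on B (the geometric ratio ``lambda_g`` cancels once
perception is expressed relative to path A, so only ``lambda_p * L_A``
enters).  The crowd adopts the assignment minimizing the total perceived
travel time -- the discomfort functional -- over all ``2**N`` configurations.

Besides an exhaustive enumeration (usable as an oracle for small ``N``) the
module implements an exact polynomial-time solver exploiting that, at a
fixed split ``(N_A, N_B)``, speeds on each path are fixed and the optimal
membership is obtained by moving to B the pedestrians with the smallest
cost difference.  The noiseless, fixed-ratio limit admits a closed-form
continuum split derived from the equal-optical-length condition
``L_A / v_A = L_B / (sqrt(ratio) * v_B)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import NoiseParameters

__all__ = [
    "V_MIN",
    "FundamentalDiagram",
    "Geometry",
    "PedestrianEnsemble",
    "Configuration",
    "local_mean_velocity",
    "individual_velocity",
    "perceived_time",
    "total_discomfort",
    "minimize_bruteforce",
    "minimize_exact",
    "minimize_split_batch",
    "deterministic_split",
    "optical_length_residual",
    "speed_ratio_squared",
    "activation_threshold_deterministic",
]

#: Floor on any walking speed (m/s).  Keeps travel times finite and positive
#: for extreme noise draws; never reached at realistic parameters.
V_MIN = 0.1


@dataclass(frozen=True)
class FundamentalDiagram:
    """Linear density--speed law ``<v(N_J)> = v0 - kappa * N_J``.

    ``v0`` is the free-stream speed (m/s) in the zero-density limit,
    ``kappa`` the decay per additional pedestrian on the path, and
    ``noise`` the additive per-pedestrian Gaussian perturbation.
    """

    v0: float
    kappa: float
    noise: NoiseParameters = field(default_factory=NoiseParameters)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.v0) and self.v0 > 0):
            raise ValueError("v0 must be positive")
        if not (np.isfinite(self.kappa) and self.kappa >= 0):
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class Geometry:
    """Bifurcation geometry: length ratio, reference length, reference area.

    ``lambda_g = L_B / L_A`` is the geometric path-length ratio (> 1 for a
    genuine detour), ``l_a`` the reference length of path A (the model is
    invariant under its rescaling, so 1 m is the convention), and ``a_ref``
    the reference area (m^2) converting counts to densities.
    """

    lambda_g: float = 1.35
    l_a: float = 1.0
    a_ref: float = 15.0

    def __post_init__(self) -> None:
        if self.lambda_g <= 0 or self.l_a <= 0 or self.a_ref <= 0:
            raise ValueError("lambda_g, l_a and a_ref must be positive")

    def density(self, n: float) -> float:
        """Crowd density rho = N / A_ref (ped/m^2)."""
        return n / self.a_ref


@dataclass(frozen=True)
class PedestrianEnsemble:
    """One stochastic realization: per-pedestrian speed perturbations and
    the single perceived-length ratio shared by the whole crowd."""

    eps: np.ndarray
    lambda_p: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "eps", np.asarray(self.eps, dtype=float))
        if self.eps.ndim != 1:
            raise ValueError("eps must be a 1-d vector")
        if not (np.isfinite(self.lambda_p) and self.lambda_p > 0):
            raise ValueError("lambda_p must be positive")

    @property
    def n(self) -> int:
        return self.eps.size


@dataclass(frozen=True)
class Configuration:
    """An assignment of every pedestrian to path 'A' or 'B'."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(lab not in ("A", "B") for lab in self.labels):
            raise ValueError("labels must be 'A' or 'B'")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_a(self) -> int:
        return sum(lab == "A" for lab in self.labels)

    @property
    def n_b(self) -> int:
        return self.n - self.n_a


def local_mean_velocity(fd: FundamentalDiagram, n_j: float) -> float:
    """Mean walking speed on a path occupied by ``n_j`` pedestrians."""
    if n_j < 0:
        raise ValueError("n_j must be >= 0")
    return max(fd.v0 - fd.kappa * n_j, V_MIN)


def individual_velocity(fd: FundamentalDiagram, n_j: float,
                        eps_i: float) -> float:
    """Speed of one pedestrian: the diagram value plus its perturbation,
    floored at ``V_MIN``.  The pedestrian counts itself in ``n_j``."""
    if n_j < 1:
        raise ValueError("n_j must be >= 1 (the pedestrian counts itself)")
    return max(fd.v0 - fd.kappa * n_j + eps_i, V_MIN)


def perceived_time(geom: Geometry, fd: FundamentalDiagram, path: str,
                   n_j: int, eps_i: float, lambda_p: float) -> float:
    """Perceived travel time of one pedestrian on ``path``.

    Path A: the geometric time ``L_A / v``.  Path B: ``lambda_p * L_A / v``
    -- the perception map replaces the geometric ratio by the perceived one,
    so ``lambda_g`` drops out.
    """
    if lambda_p <= 0:
        raise ValueError("lambda_p must be positive")
    v = individual_velocity(fd, n_j, eps_i)
    if path == "A":
        return geom.l_a / v
    if path == "B":
        return lambda_p * geom.l_a / v
    raise ValueError(f"invalid path label {path!r}")


def total_discomfort(geom: Geometry, fd: FundamentalDiagram,
                     ens: PedestrianEnsemble, c: Configuration) -> float:
    """Crowd discomfort: the sum of all perceived travel times under ``c``,
    each pedestrian slowed by the total occupancy of its assigned path."""
    if ens.n != c.n:
        raise ValueError("ensemble and configuration sizes differ")
    if ens.n == 0:
        return 0.0
    n_a, n_b = c.n_a, c.n_b
    total = 0.0
    for lab, e in zip(c.labels, ens.eps):
        n_j = n_a if lab == "A" else n_b
        total += perceived_time(geom, fd, lab, n_j, e, ens.lambda_p)
    return total


def _labels_from_mask(on_b: np.ndarray) -> tuple[str, ...]:
    return tuple("B" if b else "A" for b in on_b)


def minimize_bruteforce(geom: Geometry, fd: FundamentalDiagram,
                        ens: PedestrianEnsemble,
                        max_n: int = 20) -> tuple[Configuration, float]:
    """Exhaustive minimization over all ``2**N`` configurations.

    Ties are broken in favor of larger ``N_A``, then the lexicographically
    smallest label vector.  Guarded to ``N <= max_n``; intended as the
    ground-truth oracle for :func:`minimize_exact`.
    """
    n = ens.n
    if n > max_n:
        raise ValueError(f"N={n} exceeds the brute-force guard ({max_n})")
    if n == 0:
        return Configuration(()), 0.0
    eps = ens.eps
    lam = ens.lambda_p
    best_key = None
    best = None
    chunk = 1 << 14
    for start in range(0, 1 << n, chunk):
        codes = np.arange(start, min(start + chunk, 1 << n), dtype=np.int64)
        on_b = ((codes[:, None] >> np.arange(n)) & 1).astype(bool)
        n_b = on_b.sum(axis=1)
        n_a = n - n_b
        v_a = np.maximum(fd.v0 - fd.kappa * n_a[:, None] + eps, V_MIN)
        v_b = np.maximum(fd.v0 - fd.kappa * n_b[:, None] + eps, V_MIN)
        cost = np.where(on_b, lam * geom.l_a / v_b, geom.l_a / v_a).sum(axis=1)
        lo = cost.min()
        for i in np.flatnonzero(cost == lo):
            key = (cost[i], int(n_b[i]), _labels_from_mask(on_b[i]))
            if best_key is None or key < best_key:
                best_key, best = key, (Configuration(key[2]), float(cost[i]))
    return best


def _order_ties_high_index_first(delta: np.ndarray) -> np.ndarray:
    """Argsort by (delta ascending, index descending).

    Sending tied pedestrians with the highest indices to B yields the
    lexicographically smallest label vector, matching the brute-force
    tie-break."""
    n = delta.size
    rev = np.argsort(delta[::-1], kind="stable")
    return (n - 1) - rev


def minimize_exact(geom: Geometry, fd: FundamentalDiagram,
                   ens: PedestrianEnsemble) -> tuple[Configuration, float]:
    """Exact polynomial-time minimizer of the discomfort functional.

    At a fixed split ``N_A = s`` every speed is fixed, so the cost separates:
    the all-on-A baseline plus, for each pedestrian sent to B, its individual
    cost difference ``lambda_p L_A / v_B - L_A / v_A``.  The optimal members
    of B at that split are the ``N - s`` smallest differences; scanning all
    splits gives the global optimum in ``O(N^2 log N)``.
    """
    n = ens.n
    if n == 0:
        return Configuration(()), 0.0
    eps = ens.eps
    lam = ens.lambda_p
    best_total = np.inf
    best_sel: np.ndarray | None = None
    for s in range(n, -1, -1):  # descending: ties resolve to larger N_A
        v_a = np.maximum(fd.v0 - fd.kappa * s + eps, V_MIN)
        v_b = np.maximum(fd.v0 - fd.kappa * (n - s) + eps, V_MIN)
        cost_a = geom.l_a / v_a
        delta = lam * geom.l_a / v_b - cost_a
        order = _order_ties_high_index_first(delta)
        sel = order[: n - s]
        total = cost_a.sum() + delta[sel].sum()
        if total < best_total:
            best_total = total
            best_sel = sel
    on_b = np.zeros(n, dtype=bool)
    on_b[best_sel] = True
    return Configuration(_labels_from_mask(on_b)), float(best_total)


def minimize_split_batch(fd: FundamentalDiagram, lam: np.ndarray,
                         eps: np.ndarray, l_a: float = 1.0
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`minimize_exact` over ``m`` independent realizations.

    Parameters
    ----------
    lam : (m,) array of perceived ratios, one per realization.
    eps : (m, n) array of per-pedestrian speed perturbations.

    Returns
    -------
    n_b : (m,) int array, optimal occupancy of path B.
    on_b : (m, n) bool array, optimal membership of path B.
    cost : (m,) float array, minimal discomfort.
    """
    lam = np.asarray(lam, dtype=float)
    eps = np.asarray(eps, dtype=float)
    m, n = eps.shape
    if n == 0:
        return (np.zeros(m, dtype=int), np.zeros((m, 0), dtype=bool),
                np.zeros(m))
    totals = np.empty((m, n + 1))
    for s in range(n + 1):
        v_a = np.maximum(fd.v0 - fd.kappa * s + eps, V_MIN)
        v_b = np.maximum(fd.v0 - fd.kappa * (n - s) + eps, V_MIN)
        cost_a = l_a / v_a
        delta = lam[:, None] * l_a / v_b - cost_a
        k = n - s
        base = cost_a.sum(axis=1)
        if k == 0:
            totals[:, s] = base
        elif k == n:
            totals[:, s] = base + delta.sum(axis=1)
        else:
            part = np.partition(delta, k - 1, axis=1)
            totals[:, s] = base + part[:, :k].sum(axis=1)
    # argmin with ties resolved to the larger N_A
    s_best = n - np.argmin(totals[:, ::-1], axis=1)
    cost = totals[np.arange(m), s_best]
    on_b = np.zeros((m, n), dtype=bool)
    for s in np.unique(s_best):
        k = n - int(s)
        if k == 0:
            continue
        rows = np.flatnonzero(s_best == s)
        v_a = np.maximum(fd.v0 - fd.kappa * s + eps[rows], V_MIN)
        v_b = np.maximum(fd.v0 - fd.kappa * (n - s) + eps[rows], V_MIN)
        delta = lam[rows, None] * l_a / v_b - l_a / v_a
        rev = np.argsort(delta[:, ::-1], axis=1, kind="stable")
        order = (n - 1) - rev
        sel = order[:, :k]
        on_b[rows[:, None], sel] = True
    return (n - s_best).astype(int), on_b, cost


def deterministic_split(geom: Geometry, fd: FundamentalDiagram, n: float,
                        ratio: float | None = None) -> float:
    """Continuum occupancy of path A in the noiseless fixed-ratio limit.

    ``N_A(N) = min{N, [kappa N + v0 (sqrt(r) - 1)] / [kappa (sqrt(r) + 1)]}``
    clamped to ``[0, N]``, where ``r`` defaults to the geometric ratio but
    may be the (fixed) perceived ratio of the deterministic model variant.
    """
    if fd.kappa <= 0:
        raise ValueError("the continuum split is undefined for kappa = 0")
    r = geom.lambda_g if ratio is None else ratio
    if r <= 0:
        raise ValueError("ratio must be positive")
    sq = np.sqrt(r)
    interior = (fd.kappa * n + fd.v0 * (sq - 1.0)) / (fd.kappa * (sq + 1.0))
    return float(min(n, max(interior, 0.0)))


def speed_ratio_squared(fd: FundamentalDiagram, n_a: float,
                        n: float) -> float:
    """The identity ratio ``(v_B / v_A)**2`` at a continuum split -- equals
    the effective length ratio when the split satisfies the equal
    optical-length condition."""
    v_a = fd.v0 - fd.kappa * n_a
    v_b = fd.v0 - fd.kappa * (n - n_a)
    if v_a <= 0 or v_b <= 0:
        raise ValueError("mean velocities must be positive")
    return (v_b / v_a) ** 2


def optical_length_residual(geom: Geometry, fd: FundamentalDiagram,
                            n_a: float, n: float,
                            ratio: float | None = None) -> float:
    """Residual of the equal optical-length condition at a continuum split.

    Returns ``L_A / v_A - L_B / (sqrt(r) v_B)`` with ``L_B = r L_A``; zero
    exactly at the interior-branch continuum optimum.  Positive when path A
    is overcrowded relative to the optimum.
    """
    r = geom.lambda_g if ratio is None else ratio
    if r <= 0:
        raise ValueError("ratio must be positive")
    v_a = fd.v0 - fd.kappa * n_a
    v_b = fd.v0 - fd.kappa * (n - n_a)
    if v_a <= 0 or v_b <= 0:
        raise ValueError("mean velocities must be positive")
    return geom.l_a / v_a - np.sqrt(r) * geom.l_a / v_b


def activation_threshold_deterministic(geom: Geometry, fd: FundamentalDiagram,
                                       ratio: float | None = None) -> float:
    """Continuum count above which the noiseless model populates path B.

    The interior branch of the continuum split drops below ``N`` at
    ``N = v0 (sqrt(r) - 1) / (kappa sqrt(r))``; below it everyone stays on
    path A.  Returns 0 for ``r <= 1`` (the detour is never longer, so B is
    active immediately).
    """
    r = geom.lambda_g if ratio is None else ratio
    if r <= 1.0:
        return 0.0
    if fd.kappa <= 0:
        raise ValueError("threshold undefined for kappa = 0")
    sq = np.sqrt(r)
    return float(fd.v0 * (sq - 1.0) / (fd.kappa * sq))
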