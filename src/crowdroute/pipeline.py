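"""Measurement-campaign analysis of frame-record datasets.

Given a table of per-frame pedestrian observations (path label + speed),
computes the statistics a field study of the bifurcation reports:

* conditional occupancy curves <N_A(N)>, <N_B(N)> and P(N_B | N), with the
  empirical activation threshold N*;
* the local fundamental diagram fit (OLS of speed on own-path count, pooled
  over both paths, assuming one shared diagram);
* global diagrams <v_J(N)> and the reconstruction check that their slopes
  equal -kappa times the occupancy slopes;
* the per-frame perceived ratio series lambda_p = (v_B / v_A)^2 and its EMG
  fit;
* throughput against the balanced-split upper and all-on-one-path lower
  analytic bounds;
* the herding probability P(N_B = 0 | N) with Wilson intervals.

All conditioning is on integer counts, no smoothing; an optional coarse
10-bin summary mirrors the binning used for error bars in flow plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .distributions import EmgParameters, emg_fit
from .routing import FundamentalDiagram

__all__ = [
    "OccupancyStatistics",
    "DiagramFit",
    "GlobalDiagram",
    "LambdaPSeries",
    "LambdaPFit",
    "FlowTable",
    "frame_table",
    "occupancy_statistics",
    "fit_local_diagram",
    "global_diagram",
    "lambda_p_series",
    "fit_lambda_p",
    "flow_analysis",
    "flow_gap_max",
    "herding_probability",
]


def frame_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-frame summary: N, N_A, N_B, mean speeds per path, total flux."""
    if len(records) == 0:
        raise ValueError("dataset is empty")
    df = records.assign(is_b=records["path"].eq("B"))
    g = df.groupby("frame_id", sort=True)
    out = pd.DataFrame({
        "N": g.size(),
        "n_b": g["is_b"].sum().astype(int),
        "total_speed": g["speed"].sum(),
    })
    out["n_a"] = out["N"] - out["n_b"]
    va = df[~df["is_b"]].groupby("frame_id")["speed"].mean()
    vb = df[df["is_b"]].groupby("frame_id")["speed"].mean()
    out["v_a_hat"] = va.reindex(out.index)
    out["v_b_hat"] = vb.reindex(out.index)
    return out


@dataclass
class OccupancyStatistics:
    """Occupancy curves conditioned on the global count."""

    table: pd.DataFrame              # index N: mean_n_a, mean_n_b, n_frames
    p_nb: dict[int, np.ndarray]      # N -> P(N_B = k | N), k = 0..N

    def activation_threshold(self) -> int:
        """Empirical N*: smallest N with mean N_B >= 1."""
        ok = self.table.index[self.table["mean_n_b"] >= 1.0]
        if len(ok) == 0:
            raise ValueError("mean N_B never reaches 1 in this dataset")
        return int(ok[0])


def occupancy_statistics(records: pd.DataFrame) -> OccupancyStatistics:
    ft = frame_table(records)
    g = ft.groupby("N")
    table = pd.DataFrame({
        "mean_n_b": g["n_b"].mean(),
        "n_frames": g.size(),
    })
    table["mean_n_a"] = table.index.to_numpy() - table["mean_n_b"]
    p_nb = {
        int(n): np.bincount(sub["n_b"], minlength=int(n) + 1) / len(sub)
        for n, sub in ft.groupby("N")
    }
    return OccupancyStatistics(table[["mean_n_a", "mean_n_b", "n_frames"]],
                               p_nb)


@dataclass
class DiagramFit:
    """OLS fit of the linear fundamental diagram ``v = v0 - kappa N_J``."""

    v0_hat: float
    kappa_hat: float
    r_squared: float
    resid_sd: float
    n_points: int
    v0_ci: tuple[float, float]
    kappa_ci: tuple[float, float]

    def as_diagram(self) -> FundamentalDiagram:
        return FundamentalDiagram(self.v0_hat, max(self.kappa_hat, 0.0))


def fit_local_diagram(records: pd.DataFrame,
                      path: str | None = None) -> DiagramFit:
    """Fit speed against own-path occupancy.

    Pooled over both paths by default (one shared diagram); pass
    ``path='A'`` or ``'B'`` for the per-path verification fits.  The
    residual standard deviation estimates the combined behavioral plus
    measurement speed noise.
    """
    df = records if path is None else records[records["path"] == path]
    if len(df) == 0:
        raise ValueError("no records to fit")
    n_own = df.groupby(["frame_id", "path"])["speed"].transform("size")
    if n_own.nunique() < 2:
        raise ValueError("need at least 2 distinct occupancy levels")
    design = sm.add_constant(n_own.to_numpy(dtype=float))
    fit = sm.OLS(df["speed"].to_numpy(), design).fit()
    ci = np.asarray(fit.conf_int(alpha=0.05))
    return DiagramFit(
        v0_hat=float(fit.params[0]),
        kappa_hat=float(-fit.params[1]),
        r_squared=float(fit.rsquared),
        resid_sd=float(np.sqrt(fit.mse_resid)),
        n_points=int(fit.nobs),
        v0_ci=(float(ci[0, 0]), float(ci[0, 1])),
        kappa_ci=(float(-ci[1, 1]), float(-ci[1, 0])),
    )


@dataclass
class GlobalDiagram:
    """Mean per-path speed conditioned on the *global* count, plus the
    finite-difference reconstruction check against the local diagram."""

    table: pd.DataFrame  # index N: v_a, v_b, mean_n_a, mean_n_b, n_frames

    def b_not_slower_fraction(self) -> float:
        """Fraction of counts at which path B is at least as fast as A."""
        t = self.table.dropna(subset=["v_a", "v_b"])
        if len(t) == 0:
            return float("nan")
        return float((t["v_b"] >= t["v_a"]).mean())

    def reconstruction(self, fit: DiagramFit) -> pd.DataFrame:
        """Central-difference slopes of the global diagrams against
        ``-kappa_hat`` times the occupancy slopes, per path."""
        t = self.table
        n = t.index.to_numpy(dtype=float)
        rows = []
        for path, vcol, ncol in [("A", "v_a", "mean_n_a"),
                                 ("B", "v_b", "mean_n_b")]:
            v = t[vcol].to_numpy()
            occ = t[ncol].to_numpy()
            for i in range(1, len(n) - 1):
                if np.isnan(v[i - 1]) or np.isnan(v[i + 1]):
                    continue
                dn = n[i + 1] - n[i - 1]
                lhs = (v[i + 1] - v[i - 1]) / dn
                rhs = -fit.kappa_hat * (occ[i + 1] - occ[i - 1]) / dn
                rows.append((path, int(n[i]), lhs, rhs,
                             abs(lhs - rhs) / max(abs(rhs), 1e-12)))
        return pd.DataFrame(
            rows, columns=["path", "N", "slope", "reconstructed",
                           "rel_residual"])


def global_diagram(records: pd.DataFrame) -> GlobalDiagram:
    ft = frame_table(records)
    g = ft.groupby("N")
    table = pd.DataFrame({
        "v_a": g["v_a_hat"].mean(),
        "v_b": g["v_b_hat"].mean(),
        "mean_n_a": g["n_a"].mean(),
        "mean_n_b": g["n_b"].mean(),
        "n_frames": g.size(),
    })
    return GlobalDiagram(table)


@dataclass
class LambdaPSeries:
    """Per-frame perceived-ratio observations ``(v_B_hat / v_A_hat)^2``,
    restricted to frames with both paths occupied."""

    values: np.ndarray
    global_counts: np.ndarray
    n_frames_used: int
    n_frames_skipped: int


def lambda_p_series(records: pd.DataFrame) -> LambdaPSeries:
    ft = frame_table(records)
    ok = (ft["n_a"] > 0) & (ft["n_b"] > 0)
    sub = ft[ok]
    values = (sub["v_b_hat"] / sub["v_a_hat"]).to_numpy() ** 2
    return LambdaPSeries(values=values,
                         global_counts=sub["N"].to_numpy(),
                         n_frames_used=int(ok.sum()),
                         n_frames_skipped=int((~ok).sum()))


@dataclass
class LambdaPFit:
    params: EmgParameters
    empirical_mode: float
    n_values: int


def fit_lambda_p(series: LambdaPSeries | np.ndarray) -> LambdaPFit:
    """EMG fit of the perceived-ratio series plus a histogram-based
    empirical mode (Freedman-Diaconis bins)."""
    values = series.values if isinstance(series, LambdaPSeries) else \
        np.asarray(series, dtype=float)
    if values.size < 100:
        raise ValueError("need at least 100 lambda_p values")
    params = emg_fit(values)
    counts, edges = np.histogram(values, bins="fd")
    i = int(np.argmax(counts))
    mode = 0.5 * (edges[i] + edges[i + 1])
    return LambdaPFit(params=params, empirical_mode=float(mode),
                      n_values=int(values.size))


@dataclass
class FlowTable:
    """Observed throughput per count against the two analytic bounds.

    Bounds assume equal cross-sections on the two paths (approximately true
    in the reference setup) and the fitted linear diagram:
    ideal = v(N/2) * N (balanced split), unbalanced = v(N) * N (all on one
    path).
    """

    table: pd.DataFrame  # index N: phi_obs, phi_ideal, phi_unbalanced, ...
    equal_sections_assumed: bool = True

    def coarse_summary(self, n_bins: int = 10) -> pd.DataFrame:
        """Equal-width coarse binning of the observed flow (min/mean/max per
        bin), mirroring error-bar style summaries."""
        t = self.table.reset_index()
        bins = pd.cut(t["N"], bins=n_bins)
        g = t.groupby(bins, observed=True)["phi_obs"]
        return pd.DataFrame({"phi_min": g.min(), "phi_mean": g.mean(),
                             "phi_max": g.max()})


def flow_analysis(records: pd.DataFrame, fit: DiagramFit) -> FlowTable:
    if fit.kappa_hat <= 0:
        raise ValueError("flow bounds require a positive fitted kappa")
    ft = frame_table(records)
    g = ft.groupby("N")
    n = g.size().index.to_numpy(dtype=float)
    phi_obs = g["total_speed"].mean().to_numpy()
    phi_ideal = (fit.v0_hat - fit.kappa_hat * n / 2.0) * n
    phi_unbalanced = (fit.v0_hat - fit.kappa_hat * n) * n
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_gap = np.where(phi_ideal > 0,
                           (phi_ideal - phi_unbalanced) / phi_ideal, 0.0)
    table = pd.DataFrame({
        "phi_obs": phi_obs,
        "phi_ideal": phi_ideal,
        "phi_unbalanced": phi_unbalanced,
        "rel_gap": rel_gap,
        "n_frames": g.size().to_numpy(),
    }, index=pd.Index(n.astype(int), name="N"))
    return FlowTable(table)


def flow_gap_max(fd: FundamentalDiagram | DiagramFit,
                 n_max: int = 19) -> float:
    """Closed-form maximum relative gap between the ideal and unbalanced
    throughput bounds over integer counts ``1..n_max``:
    ``(kappa N / 2) / (v0 - kappa N / 2)``, increasing in N."""
    v0 = fd.v0 if isinstance(fd, FundamentalDiagram) else fd.v0_hat
    kappa = fd.kappa if isinstance(fd, FundamentalDiagram) else fd.kappa_hat
    n = np.arange(1, n_max + 1, dtype=float)
    half = kappa * n / 2.0
    gaps = half / (v0 - half)
    return float(gaps.max())


def herding_probability(records: pd.DataFrame) -> pd.DataFrame:
    """P(N_B = 0 | N) per count, with 95% Wilson intervals."""
    ft = frame_table(records)
    g = ft.groupby("N")["n_b"]
    empty = g.apply(lambda s: int((s == 0).sum()))
    total = g.size()
    lo, hi = proportion_confint(empty.to_numpy(), total.to_numpy(),
                                alpha=0.05, method="wilson")
    return pd.DataFrame({
        "p_empty_b": empty / total,
        "ci_low": lo,
        "ci_high": hi,
        "n_frames": total,
    })
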