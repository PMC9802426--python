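"""Synthetic crowd-snapshot generator emulating a tracking dataset.

Produces independent frames of pedestrians at the bifurcation: a per-frame
global count drawn from a configurable law, path labels from the full
stochastic routing model, and recorded speeds following the noisy linear
fundamental diagram plus independent measurement noise.  Frames are i.i.d.
by construction, emulating the decorrelated subsampling applied to real
tracking data.

The CSV dialect is fixed: comma-separated, UTF-8, header
``frame_id,ped_id,path,speed,x,y``; ``path`` in {A, B}; ``x``/``y`` empty
when absent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .distributions import EmgParameters, LAMBDA_P_TUNED, emg_sample
from .routing import (FundamentalDiagram, Geometry, V_MIN,
                      minimize_split_batch)

__all__ = [
    "COLUMNS",
    "SPEED_FLOOR",
    "FrameRecord",
    "CountLaw",
    "DatasetManifest",
    "SchemaError",
    "generate_frames",
    "generate_positions",
    "write_frames",
    "read_frames",
]

COLUMNS = ["frame_id", "ped_id", "path", "speed", "x", "y"]

#: Floor on recorded speeds (m/s): measurement noise may not push a record
#: to zero or below.
SPEED_FLOOR = 0.01

#: Half-width (m) of the corridor band around the straight path A within
#: which A-positions are jittered.
A_CORRIDOR_HALF_WIDTH = 0.5


@dataclass(frozen=True)
class FrameRecord:
    """One pedestrian observed in one frame: the atom of the pipeline."""

    frame_id: int
    ped_id: int
    path: str
    speed: float
    x: float | None = None
    y: float | None = None


class SchemaError(ValueError):
    """A dataset file violates the frame-record CSV dialect."""


@dataclass(frozen=True)
class CountLaw:
    """Law of the per-frame global pedestrian count.

    ``uniform``: integers on ``[low, high]`` inclusive (the default spans
    both sides of the empirical activation threshold).  ``fixed``: point
    mass at ``value``.
    """

    kind: str = "uniform"
    low: int = 1
    high: int = 25
    value: int = 0

    def __post_init__(self) -> None:
        if self.kind == "uniform":
            if not (0 <= self.low <= self.high):
                raise ValueError("need 0 <= low <= high")
        elif self.kind == "fixed":
            if self.value < 0:
                raise ValueError("fixed count must be >= 0")
        else:
            raise ValueError(f"unknown count law {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.integers(self.low, self.high + 1, size=size)
        return np.full(size, self.value, dtype=int)


@dataclass(frozen=True)
class DatasetManifest:
    """Everything needed to regenerate a dataset bit-for-bit."""

    n_frames: int
    seed: int
    count_law: CountLaw = field(default_factory=CountLaw)
    fd: FundamentalDiagram = field(
        default_factory=lambda: FundamentalDiagram(1.012, 0.017))
    emg: EmgParameters = LAMBDA_P_TUNED
    geom: Geometry = field(default_factory=Geometry)
    measurement_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")


def generate_frames(manifest: DatasetManifest) -> pd.DataFrame:
    """Generate the full dataset as a frame-record table.

    Per frame: draw the global count, solve the full routing model (shared
    EMG perceived ratio, per-pedestrian velocity noise), and record each
    pedestrian's speed at the realized occupancy of its path.

    The recorded speed carries a fresh, independent draw of the velocity
    noise (same law as the decision noise) plus measurement noise.  Decision
    noise and the kinematic fluctuation captured in a single frame are
    treated as independent realizations: reusing the decision draw would
    correlate recorded speeds with the routing outcome (the optimizer
    selects who defects partly on their noise), which biases any
    fundamental-diagram fit in a way a measured snapshot does not.
    """
    rng = np.random.default_rng(np.random.SeedSequence(manifest.seed))
    fd, geom = manifest.fd, manifest.geom
    counts = manifest.count_law.sample(rng, manifest.n_frames)
    chunks: list[pd.DataFrame] = []
    for n in np.unique(counts):
        n = int(n)
        if n == 0:
            continue
        frames = np.flatnonzero(counts == n)
        m = frames.size
        sigma = fd.noise.sigma_eps
        eps = rng.normal(0.0, sigma, size=(m, n)) if sigma > 0 else \
            np.zeros((m, n))
        lam = emg_sample(manifest.emg, m, rng)
        n_b, on_b, _ = minimize_split_batch(fd, lam, eps, l_a=geom.l_a)
        n_own = np.where(on_b, n_b[:, None], n - n_b[:, None])
        eps_rec = rng.normal(0.0, sigma, size=(m, n)) if sigma > 0 else \
            np.zeros((m, n))
        speed = np.maximum(fd.v0 - fd.kappa * n_own + eps_rec, V_MIN)
        if manifest.measurement_noise_sd > 0:
            speed = speed + rng.normal(0.0, manifest.measurement_noise_sd,
                                       size=speed.shape)
        speed = np.maximum(speed, SPEED_FLOOR)
        chunks.append(pd.DataFrame({
            "frame_id": np.repeat(frames, n),
            "ped_id": np.tile(np.arange(n), m),
            "path": np.where(on_b, "B", "A").ravel(),
            "speed": speed.ravel(),
            "x": np.nan,
            "y": np.nan,
        }))
    if not chunks:
        return pd.DataFrame(columns=COLUMNS).astype(
            {"frame_id": int, "ped_id": int, "path": str,
             "speed": float, "x": float, "y": float})
    df = pd.concat(chunks, ignore_index=True)
    df = df.sort_values(["frame_id", "ped_id"], kind="stable",
                        ignore_index=True)
    return df[COLUMNS]


def _arc_half_angle(lambda_g: float) -> float:
    """Half-angle of a circular arc whose arc/chord length ratio is
    ``lambda_g`` (solves theta / sin(theta) = lambda_g)."""
    if lambda_g <= 1.0:
        return 0.0
    return float(optimize.brentq(
        lambda t: t / np.sin(t) - lambda_g, 1e-9, np.pi - 1e-9, xtol=1e-12))


def generate_positions(records: pd.DataFrame, geom: Geometry,
                       seed: int = 0) -> pd.DataFrame:
    """Fill cosmetic x/y positions on two template paths.

    Path A is the straight chord from (0, 0) to (L_A, 0) with a small
    transverse jitter inside the corridor band; path B a circular arc over
    the same chord whose arc length is ``lambda_g * L_A``.  Positions are
    placed at a random fraction of the path.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    t = rng.uniform(0.0, 1.0, size=len(out))
    on_a = (out["path"] == "A").to_numpy()
    x = np.empty(len(out))
    y = np.empty(len(out))
    length = geom.l_a
    x[on_a] = t[on_a] * length
    y[on_a] = rng.uniform(-A_CORRIDOR_HALF_WIDTH / 2,
                          A_CORRIDOR_HALF_WIDTH / 2, size=int(on_a.sum()))
    theta = _arc_half_angle(geom.lambda_g)
    on_b = ~on_a
    if theta == 0.0:  # degenerate: equal-length template, straight line
        x[on_b] = t[on_b] * length
        y[on_b] = 0.0
    else:
        radius = length / (2.0 * np.sin(theta))
        phi = -theta + 2.0 * theta * t[on_b]
        x[on_b] = length / 2.0 + radius * np.sin(phi)
        y[on_b] = radius * np.cos(phi) - radius * np.cos(theta)
    out["x"] = x
    out["y"] = y
    return out


def template_arc_length_ratio(geom: Geometry, n_points: int = 200001) -> float:
    """Numerical arc-length ratio of the two position templates (oracle for
    the construction; equals ``lambda_g`` up to quadrature error)."""
    theta = _arc_half_angle(geom.lambda_g)
    if theta == 0.0:
        return 1.0
    radius = geom.l_a / (2.0 * np.sin(theta))
    phi = np.linspace(-theta, theta, n_points)
    x = geom.l_a / 2.0 + radius * np.sin(phi)
    y = radius * np.cos(phi)
    arc = np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2).sum()
    return float(arc / geom.l_a)


def write_frames(records: pd.DataFrame, path, *,
                 header_comment: str | None = None) -> None:
    """Write a frame-record table in the fixed CSV dialect (lossless)."""
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        records[COLUMNS].to_csv(fh, index=False, na_rep="")


def read_frames(path) -> pd.DataFrame:
    """Read and validate a frame-record CSV.

    Raises :class:`SchemaError` with a line number for malformed rows;
    leading ``#`` comment lines (provenance headers) are skipped.
    """
    if isinstance(path, (str, os.PathLike)) and not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#",
                         dtype={"frame_id": "Int64", "ped_id": "Int64",
                                "path": "string", "speed": float,
                                "x": float, "y": float})
    except ValueError as exc:
        raise SchemaError(f"malformed dataset file: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df[COLUMNS]
    for col, cond in [
        ("frame_id", df["frame_id"].notna()),
        ("ped_id", df["ped_id"].notna()),
        ("path", df["path"].isin(["A", "B"])),
        ("speed", df["speed"].notna() & (df["speed"] > 0)),
    ]:
        bad = np.flatnonzero(~cond.to_numpy())
        if bad.size:
            raise SchemaError(
                f"invalid {col!r} at data line {int(bad[0]) + 2}")
    dup = df.duplicated(["frame_id", "ped_id"])
    if dup.any():
        raise SchemaError(
            f"duplicate (frame_id, ped_id) at data line "
            f"{int(np.flatnonzero(dup)[0]) + 2}")
    return df.astype({"frame_id": int, "ped_id": int, "path": str})


def frames_to_records(df: pd.DataFrame) -> list[FrameRecord]:
    """Materialize a table as typed records (convenience for small data)."""
    out = []
    for row in df.itertuples(index=False):
        x = None if pd.isna(row.x) else float(row.x)
        y = None if pd.isna(row.y) else float(row.y)
        out.append(FrameRecord(int(row.frame_id), int(row.ped_id),
                               str(row.path), float(row.speed), x, y))
    return out

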