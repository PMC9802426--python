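"""Run configuration: TOML-backed parameters with provenance hashing.

The shipped defaults carry the reference parameter set of the field study
the model was built for: fundamental diagram v0 = 1.012 m/s, kappa = 0.017
m/s per pedestrian, velocity noise sd 0.15 m/s; the tuned EMG for the
perceived ratio (1.15, 0.20, 0.33) used by simulations, alongside the
data-fit EMG (0.77, 0.30, 0.68) for comparison; reference area 15.0 m^2.
Configurations round-trip losslessly through TOML and hash to a short
provenance token embedded in every output file.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import tomllib
from dataclasses import dataclass, field

from .distributions import EmgParameters, NoiseParameters
from .routing import FundamentalDiagram, Geometry
from .synthetic import CountLaw, DatasetManifest

__all__ = ["PerceptionConfig", "SweepConfig", "DatasetConfig", "RunConfig",
           "default_config"]


@dataclass(frozen=True)
class PerceptionConfig:
    """EMG of the perceived ratio used by simulations, the data-fit EMG kept
    for comparison blocks, and an optional fixed-ratio override for the
    deterministic / velocity-only variants (default: the EMG mean)."""

    emg: EmgParameters = EmgParameters(1.15, 0.20, 0.33)
    data_fit: EmgParameters = EmgParameters(0.77, 0.30, 0.68)
    deterministic_ratio: float | None = None


@dataclass(frozen=True)
class SweepConfig:
    n_min: int = 1
    n_max: int = 30
    m: int = 10000

    def __post_init__(self) -> None:
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError("need 1 <= n_min <= n_max")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def n_range(self) -> range:
        return range(self.n_min, self.n_max + 1)


@dataclass(frozen=True)
class DatasetConfig:
    n_frames: int = 50000
    count_low: int = 1
    count_high: int = 25
    measurement_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        if not (0 <= self.count_low <= self.count_high):
            raise ValueError("need 0 <= count_low <= count_high")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")

    @property
    def count_law(self) -> CountLaw:
        return CountLaw("uniform", self.count_low, self.count_high)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    geometry: Geometry = field(default_factory=Geometry)
    diagram: FundamentalDiagram = field(
        default_factory=lambda: FundamentalDiagram(1.012, 0.017))
    perception: PerceptionConfig = field(default_factory=PerceptionConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)

    # ---- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "geometry": {"lambda_g": self.geometry.lambda_g,
                         "l_a": self.geometry.l_a,
                         "a_ref": self.geometry.a_ref},
            "diagram": {"v0": self.diagram.v0,
                        "kappa": self.diagram.kappa,
                        "sigma_eps": self.diagram.noise.sigma_eps},
            "perception": {
                "mu": self.perception.emg.mu,
                "sigma": self.perception.emg.sigma,
                "beta": self.perception.emg.beta,
                "data_fit_mu": self.perception.data_fit.mu,
                "data_fit_sigma": self.perception.data_fit.sigma,
                "data_fit_beta": self.perception.data_fit.beta,
                **({"deterministic_ratio":
                    self.perception.deterministic_ratio}
                   if self.perception.deterministic_ratio is not None
                   else {}),
            },
            "sweep": {"n_min": self.sweep.n_min, "n_max": self.sweep.n_max,
                      "m": self.sweep.m},
            "dataset": {"n_frames": self.dataset.n_frames,
                        "count_low": self.dataset.count_low,
                        "count_high": self.dataset.count_high,
                        "measurement_noise_sd":
                            self.dataset.measurement_noise_sd},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        geo = d.get("geometry", {})
        dia = d.get("diagram", {})
        per = d.get("perception", {})
        swp = d.get("sweep", {})
        dat = d.get("dataset", {})
        base = cls()
        return cls(
            seed=int(d.get("seed", base.seed)),
            geometry=Geometry(
                lambda_g=geo.get("lambda_g", base.geometry.lambda_g),
                l_a=geo.get("l_a", base.geometry.l_a),
                a_ref=geo.get("a_ref", base.geometry.a_ref)),
            diagram=FundamentalDiagram(
                v0=dia.get("v0", base.diagram.v0),
                kappa=dia.get("kappa", base.diagram.kappa),
                noise=NoiseParameters(
                    dia.get("sigma_eps", base.diagram.noise.sigma_eps))),
            perception=PerceptionConfig(
                emg=EmgParameters(
                    per.get("mu", base.perception.emg.mu),
                    per.get("sigma", base.perception.emg.sigma),
                    per.get("beta", base.perception.emg.beta)),
                data_fit=EmgParameters(
                    per.get("data_fit_mu", base.perception.data_fit.mu),
                    per.get("data_fit_sigma",
                            base.perception.data_fit.sigma),
                    per.get("data_fit_beta", base.perception.data_fit.beta)),
                deterministic_ratio=per.get("deterministic_ratio")),
            sweep=SweepConfig(n_min=swp.get("n_min", base.sweep.n_min),
                              n_max=swp.get("n_max", base.sweep.n_max),
                              m=swp.get("m", base.sweep.m)),
            dataset=DatasetConfig(
                n_frames=dat.get("n_frames", base.dataset.n_frames),
                count_low=dat.get("count_low", base.dataset.count_low),
                count_high=dat.get("count_high", base.dataset.count_high),
                measurement_noise_sd=dat.get(
                    "measurement_noise_sd",
                    base.dataset.measurement_noise_sd)),
        )

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    @classmethod
    def from_toml_str(cls, text: str) -> "RunConfig":
        return cls.from_dict(tomllib.loads(text))

    def to_toml_str(self) -> str:
        def fmt(v) -> str:
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, (int, float)):
                return repr(v)
            return f'"{v}"'

        d = self.to_dict()
        lines = [f"seed = {fmt(d.pop('seed'))}", ""]
        for section, body in d.items():
            lines.append(f"[{section}]")
            lines.extend(f"{k} = {fmt(v)}" for k, v in body.items())
            lines.append("")
        return "\n".join(lines)

    def config_hash(self) -> str:
        """Short SHA-256 token over the canonical TOML rendering."""
        return hashlib.sha256(
            self.to_toml_str().encode("utf-8")).hexdigest()[:12]

    # ---- derived objects -------------------------------------------------
    def manifest(self, seed: int | None = None) -> DatasetManifest:
        return DatasetManifest(
            n_frames=self.dataset.n_frames,
            seed=self.seed if seed is None else seed,
            count_law=self.dataset.count_law,
            fd=self.diagram,
            emg=self.perception.emg,
            geom=self.geometry,
            measurement_noise_sd=self.dataset.measurement_noise_sd)


def default_config() -> RunConfig:
    """The shipped defaults (identical to ``defaults.toml``)."""
    text = importlib.resources.files("crowdroute").joinpath(
        "defaults.toml").read_text(encoding="utf-8")
    return RunConfig.from_toml_str(text)
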