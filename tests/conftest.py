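import numpy as np
import pandas as pd
import pytest

from crowdroute import (FundamentalDiagram, Geometry, NoiseParameters,
                        LAMBDA_P_TUNED)
from crowdroute.synthetic import CountLaw, DatasetManifest, generate_frames


@pytest.fixture(scope="session")
def fd_ref() -> FundamentalDiagram:
    """Reference fundamental diagram of the field study."""
    return FundamentalDiagram(1.012, 0.017, NoiseParameters(0.15))


@pytest.fixture(scope="session")
def geom() -> Geometry:
    return Geometry()


@pytest.fixture(scope="session")
def synthetic_dataset(fd_ref, geom) -> pd.DataFrame:
    """A modest synthetic dataset shared by pipeline unit tests."""
    manifest = DatasetManifest(
        n_frames=20000, seed=202, count_law=CountLaw("uniform", 1, 25),
        fd=fd_ref, emg=LAMBDA_P_TUNED, geom=geom)
    return generate_frames(manifest)


def all_a_dataset(n_frames: int = 50, n_per_frame: int = 4,
                  v0: float = 1.012, kappa: float = 0.017) -> pd.DataFrame:
    """Noiseless dataset with every pedestrian on path A."""
    rows = []
    rng = np.random.default_rng(5)
    for f in range(n_frames):
        n = int(rng.integers(1, n_per_frame + 1))
        for p in range(n):
            rows.append((f, p, "A", v0 - kappa * n, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["frame_id", "ped_id", "path", "speed", "x", "y"])
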