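import numpy as np
import pytest

from ebavbmc.fixtures import SyntheticClusterSpec, build_cluster, example_parameters
from ebavbmc.moves import GasGeometryModel, ReservoirModel
from ebavbmc.potential import PotentialParameters


@pytest.fixture(scope="session")
def water_params() -> PotentialParameters:
    """The packaged example Vashishta-form water set."""
    return example_parameters()


@pytest.fixture(scope="session")
def toy_params() -> PotentialParameters:
    """Steric-only pair + simple three-body, for closed-form checks."""
    return PotentialParameters(
        H={"OO": 1.0, "OH": 1.0, "HH": 1.0},
        eta={"OO": 9.0, "OH": 9.0, "HH": 9.0},
        Z={"O": 0.0, "H": 0.0},
        D={"OO": 0.0, "OH": 0.0, "HH": 0.0},
        W={"OO": 0.0, "OH": 0.0, "HH": 0.0},
        r1s=4.43, r4s=2.5, rc=5.0,
        B=1.0, xi=1.0, r0=2.0, cos_theta0=-0.25,
    )


@pytest.fixture(scope="session")
def gas_model() -> GasGeometryModel:
    """Frozen gas-phase geometry Gaussians for the example potential at 298.15 K."""
    return GasGeometryModel(mu_r=0.977, sigma_r=0.045, mu_theta=105.6, sigma_theta=6.0)


@pytest.fixture(scope="session")
def reservoir() -> ReservoirModel:
    return ReservoirModel(rho_v=6e-7, T=298.15)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def random_cluster(n_molecules: int, rng: np.random.Generator, jitter: float = 0.0):
    """A random single-cluster water configuration, optionally jittered.

    Jitter perturbs every atom independently, which creates stretched
    and transiently dissociated molecules -- useful for exercising the
    bond-agnostic code paths.
    """
    config, topology = build_cluster(SyntheticClusterSpec(n_molecules), rng)
    if jitter:
        config.positions = config.positions + rng.normal(scale=jitter, size=config.positions.shape)
    return config, topology
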