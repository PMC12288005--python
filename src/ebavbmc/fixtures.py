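"""Synthetic inputs: cluster builders, gas-geometry calibration, WHAM test data.

Everything here is generated programmatically and seed-reproducible;
nothing is downloaded.  The shipped example force-field parameter set
(``data/water_example.params``) is a physically plausible
Vashishta-form water parameterization tuned so that an isolated
monomer relaxes to roughly the experimental gas geometry and a dimer
is bound; it is an illustrative set for exercising the pipeline, not
an optimized literature parameterization.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from . import cluster as cluster_mod
from .io import read_params
from .moves import GasGeometryModel, _random_rotation
from .potential import AtomicConfiguration, PotentialParameters, monomer_energy
from .topology import assign_hydrogens
from .units import KB_EV

__all__ = [
    "example_parameters",
    "SyntheticClusterSpec",
    "single_molecule",
    "build_cluster",
    "calibrate_gas_geometry",
    "minimum_energy_monomer",
    "synth_umbrella_data",
    "double_well_profile",
]


def example_parameters() -> PotentialParameters:
    """The packaged example Vashishta-form water parameter set."""
    ref = importlib.resources.files("ebavbmc").joinpath("data/water_example.params")
    with importlib.resources.as_file(ref) as path:
        return read_params(path)


def _monomer_local(oh1: float, oh2: float, angle_deg: float) -> np.ndarray:
    th = math.radians(angle_deg)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 0.0, oh1],
            [oh2 * math.sin(th), 0.0, oh2 * math.cos(th)],
        ]
    )


def single_molecule(
    geometry_model: Optional[GasGeometryModel] = None,
    oh: float = 0.96,
    angle_deg: float = 104.5,
) -> AtomicConfiguration:
    """One intact water monomer at the origin (mean geometry, no noise)."""
    if geometry_model is not None:
        oh, angle_deg = geometry_model.mu_r, geometry_model.mu_theta
    pos = _monomer_local(oh, oh, angle_deg)
    return AtomicConfiguration(np.array(["O", "H", "H"]), pos)


@dataclass
class SyntheticClusterSpec:
    """Recipe for a random single-cluster configuration of intact waters."""

    n_molecules: int
    min_oo: float = 2.6
    r_cl: float = cluster_mod.DEFAULT_R_CL
    oh: float = 0.96
    angle_deg: float = 104.5
    max_attempts: int = 2000

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        if not 0 < self.min_oo <= self.r_cl:
            raise ValueError("need 0 < min_oo <= r_cl for a buildable cluster")
        if self.min_oo <= 2 * self.oh:
            raise ValueError("min_oo must exceed twice the O-H length for unambiguous topology")


def build_cluster(spec: SyntheticClusterSpec, rng: np.random.Generator) -> tuple:
    """Random water cluster satisfying the Stillinger criterion by construction.

    Oxygens are placed by rejection sampling (each new oxygen within
    r_cl of an existing one, none closer than min_oo); two hydrogens
    per oxygen at the spec geometry with a random orientation.
    Returns (config, topology); the assigned topology provably matches
    the construction because min_oo > 2 * oh.
    """
    o_pos = [np.zeros(3)]
    attempts = 0
    while len(o_pos) < spec.n_molecules:
        attempts += 1
        if attempts > spec.max_attempts * spec.n_molecules:
            raise RuntimeError(f"could not pack {spec.n_molecules} oxygens; relax the spec")
        anchor = o_pos[int(rng.integers(len(o_pos)))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        cand = anchor + rng.uniform(spec.min_oo, spec.r_cl) * direction
        if all(np.linalg.norm(cand - p) >= spec.min_oo for p in o_pos):
            o_pos.append(cand)

    species, positions = [], []
    for o in o_pos:
        local = _monomer_local(spec.oh, spec.oh, spec.angle_deg)
        rot = _random_rotation(rng)
        mol = o + local @ rot.T
        species += ["O", "H", "H"]
        positions += [mol[0], mol[1], mol[2]]
    config = AtomicConfiguration(np.array(species), np.array(positions))
    topology = assign_hydrogens(config)
    state = cluster_mod.build_adjacency(config, topology, spec.r_cl)
    assert state.connected, "construction guarantees a single Stillinger cluster"
    return config, topology


def minimum_energy_monomer(params: PotentialParameters, guess=(0.96, 0.96, 104.5)) -> tuple:
    """Relaxed isolated-monomer geometry (r1, r2, angle_deg, energy)."""

    def objective(x):
        r1, r2, ang = x
        if r1 <= 0.3 or r2 <= 0.3 or not 30 < ang < 170:
            return 1e6
        return monomer_energy(_monomer_local(r1, r2, ang), params)

    res = minimize(objective, np.array(guess), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
    r1, r2, ang = res.x
    return float(r1), float(r2), float(ang), float(res.fun)


def calibrate_gas_geometry(
    params: PotentialParameters,
    T: float,
    samples: int = 20000,
    rng: Optional[np.random.Generator] = None,
    step_size: float = 0.04,
    burn_in: int = 2000,
    thin: int = 5,
) -> GasGeometryModel:
    """Fit the gas-phase monomer geometry Gaussians by Metropolis sampling.

    A single isolated molecule is sampled at temperature T under the
    loaded potential (random single-atom displacements, Metropolis
    acceptance); Gaussians are fitted to the marginals of the two O-H
    bond lengths and the H-O-H angle.  This stands in for a gas-phase
    molecular-dynamics fit and is the source of the swap moves'
    monomer generation distribution.
    """
    rng = np.random.default_rng() if rng is None else rng
    r1, r2, ang, _ = minimum_energy_monomer(params)
    pos = _monomer_local(r1, r2, ang)
    energy = monomer_energy(pos, params)
    beta = 1.0 / (KB_EV * T)

    rs, angles = [], []
    for i in range(burn_in + samples * thin):
        atom = int(rng.integers(3))
        trial = pos.copy()
        trial[atom] += rng.uniform(-step_size, step_size, size=3)
        e_new = monomer_energy(trial, params)
        if rng.random() < math.exp(min(0.0, -beta * (e_new - energy))):
            pos, energy = trial, e_new
        if i >= burn_in and (i - burn_in) % thin == 0:
            v1, v2 = pos[1] - pos[0], pos[2] - pos[0]
            d1, d2 = np.linalg.norm(v1), np.linalg.norm(v2)
            rs += [d1, d2]
            cos = float(np.dot(v1, v2) / (d1 * d2))
            angles.append(math.degrees(math.acos(max(-1.0, min(1.0, cos)))))
    rs, angles = np.asarray(rs), np.asarray(angles)
    model = GasGeometryModel(
        mu_r=float(rs.mean()),
        sigma_r=float(rs.std(ddof=1)),
        mu_theta=float(angles.mean()),
        sigma_theta=float(angles.std(ddof=1)),
    )
    if model.sigma_r < 1e-6 or model.sigma_theta < 1e-4:
        import warnings

        warnings.warn("degenerate gas-geometry sampling (near-zero spread)", RuntimeWarning)
    return model


def double_well_profile(n_max: int = 30, barrier: float = 6.0, n_star: int = 12) -> np.ndarray:
    """A smooth test dG(n) in k_B T with a barrier at n_star, dG(1) = 0.

    Shaped like a nucleation profile: rises to ``barrier`` at n_star
    and decreases beyond, giving a second (growing-cluster) basin.
    """
    n = np.arange(1, n_max + 1, dtype=float)
    dg = barrier * (1.0 - ((n - n_star) / (n_star - 1.0)) ** 2)
    return dg - dg[0]


def synth_umbrella_data(
    delta_g_kt: np.ndarray,
    biases_kt,
    samples_per_window: int,
    rng: np.random.Generator,
    as_counts: bool = False,
):
    """Exact biased samples of a known dG(n) for WHAM validation.

    Window w draws i.i.d. sizes from p_w(n) proportional to
    exp(-(dG(n) + eta_w(n))) (everything in k_B T).  Returns either
    integer sample arrays or multinomial count histograms.
    """
    delta_g_kt = np.asarray(delta_g_kt, dtype=float)
    out = []
    for eta in biases_kt:
        eta = np.asarray(eta, dtype=float)
        if len(eta) != len(delta_g_kt):
            raise ValueError("bias length must match profile length")
        logp = -(delta_g_kt + eta)
        p = np.exp(logp - logp.max())
        p /= p.sum()
        if as_counts:
            out.append(rng.multinomial(samples_per_window, p).astype(float))
        else:
            out.append(rng.choice(len(p), size=samples_per_window, p=p) + 1)
    return out
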