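"""Trial moves: single-atom translation and the energy-biased AVBMC swap pair.

The swap moves exchange whole water molecules between the physical
cluster and a fictitious ideal-gas reservoir of number density rho_v.
Insertion grows a monomer by configurational bias (K Rosenbluth
trials, one selected with probability proportional to its Boltzmann
factor) inside the bonded sphere of an energy-biased target molecule;
deletion removes an energy-biased neighbor of an energy-biased target,
subject to the dissociation constraint (both assigned hydrogens must
be the oxygen's two nearest, within 2 A).

Because the model is all-atom, the intramolecular energy U_intra of
the exchanged monomer is subtracted from the energy change on
insertion and added on deletion: the reservoir monomer's internal
Boltzmann weight is represented by the gas-geometry generation
distribution, so only the interaction part of dU may appear in the
acceptance exponent.

Acceptance ratios carry the inverse selection probability 1/(K P_sel)
for the forward Rosenbluth choice and K P_sel for the reverse one --
the unique pairing under which insertion and deletion transition
densities satisfy detailed balance with respect to the grand-canonical
cluster measure (verified numerically in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.special import logsumexp

from . import cluster as cluster_mod
from .potential import (
    AtomicConfiguration,
    PotentialParameters,
    all_molecule_interaction_energies,
    delta_delete,
    delta_insert,
    delta_translate,
    monomer_energy,
    InvalidGeometryError,
)
from .topology import BondTopology, assign_hydrogens, is_deletable
from .units import KB_EV

__all__ = [
    "GasGeometryModel",
    "ReservoirModel",
    "MoveOutcome",
    "boltzmann_select",
    "rosenbluth_probabilities",
    "trial_selection_probability",
    "grow_monomer",
    "select_insertion_target",
    "select_deletion_target",
    "select_deletion_neighbor",
    "translate_atom",
    "insertion_log_acceptance",
    "deletion_log_acceptance",
    "cbmc_insert",
    "avbmc_delete",
]


@dataclass(frozen=True)
class GasGeometryModel:
    """Gaussian monomer geometry of the reservoir gas phase.

    Bond lengths (A) and the H-O-H angle (degrees) are drawn from
    Gaussians fitted to the gas-phase distribution of the loaded
    potential at the run temperature; out-of-range draws (r <= 0,
    theta outside (0, 180)) are rejected and redrawn.
    """

    mu_r: float
    sigma_r: float
    mu_theta: float
    sigma_theta: float

    def __post_init__(self):
        if self.sigma_r < 0 or self.sigma_theta < 0:
            raise ValueError("geometry spreads must be non-negative")

    def sample_bond_length(self, rng: np.random.Generator) -> float:
        while True:
            r = rng.normal(self.mu_r, self.sigma_r)
            if r > 0:
                return float(r)

    def sample_angle_rad(self, rng: np.random.Generator) -> float:
        while True:
            th = rng.normal(self.mu_theta, self.sigma_theta)
            if 0.0 < th < 180.0:
                return float(math.radians(th))


@dataclass(frozen=True)
class ReservoirModel:
    """Ideal-gas reservoir thermodynamically coupled to the cluster.

    beta*mu = ln(rho_v * Lambda^3) with Lambda^3 fixed at 1 A^3 (the
    thermal wavelength is absorbed into the reservoir definition; only
    the consistent +mu/-mu pairing between the two swap rules matters).
    """

    rho_v: float  # number density, 1/A^3
    T: float      # K

    def __post_init__(self):
        if self.rho_v <= 0 or self.T <= 0:
            raise ValueError("reservoir density and temperature must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (KB_EV * self.T)

    @property
    def mu(self) -> float:
        """Chemical potential in eV."""
        return KB_EV * self.T * math.log(self.rho_v)


@dataclass
class MoveOutcome:
    move: str
    accepted: bool
    reason: Optional[str] = None
    d_u: float = 0.0
    u_intra: float = 0.0
    p_insert: float = 1.0
    p_remove: float = 1.0
    p_trial: float = 1.0
    bias_delta: float = 0.0
    log_acceptance: float = 0.0
    n_new: int = 0
    new_config: Optional[AtomicConfiguration] = None
    new_topology: Optional[BondTopology] = None


def boltzmann_select(log_weights: np.ndarray, rng: np.random.Generator) -> tuple:
    """Sample an index with probability softmax(log_weights); return (idx, prob).

    The exponent is max-shifted, so arbitrarily large energies are safe.
    """
    lw = np.asarray(log_weights, dtype=float)
    p = np.exp(lw - logsumexp(lw))
    p = p / p.sum()
    idx = int(rng.choice(len(p), p=p))
    return idx, float(p[idx])


def select_insertion_target(molecule_energies: np.ndarray, alpha: float, rng: np.random.Generator) -> tuple:
    """Energy-biased insertion target: P_i = e^(alpha U_i) / sum_j e^(alpha U_j).

    alpha > 0 favors weakly bound (surface) molecules.
    """
    return boltzmann_select(alpha * np.asarray(molecule_energies, dtype=float), rng)


def select_deletion_target(molecule_energies: np.ndarray, beta: float, rng: np.random.Generator) -> tuple:
    """Energy-biased deletion target: P_i = e^(beta U_i) / sum_j e^(beta U_j)."""
    return boltzmann_select(beta * np.asarray(molecule_energies, dtype=float), rng)


def select_deletion_neighbor(
    neighbor_energies: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    deterministic: bool = False,
) -> tuple:
    """Energy-biased choice among the target's bonded-region neighbors.

    Stochastic Boltzmann sampling by default; with ``deterministic``
    the highest-energy neighbor is always taken, still reported with
    its normalized Boltzmann probability.
    """
    lw = beta * np.asarray(neighbor_energies, dtype=float)
    if deterministic:
        p = np.exp(lw - logsumexp(lw))
        idx = int(np.argmax(lw))
        return idx, float(p[idx])
    return boltzmann_select(lw, rng)


def rosenbluth_probabilities(trial_energies: np.ndarray, beta: float) -> np.ndarray:
    """Normalized selection probabilities P_k = e^(-beta U_k) / W over trials."""
    lw = -beta * np.asarray(trial_energies, dtype=float)
    return np.exp(lw - logsumexp(lw))


def trial_selection_probability(trial_energies: np.ndarray, chosen: int, beta: float) -> float:
    """P_trial of one trial: its Rosenbluth probability scaled by the trial count K."""
    p = rosenbluth_probabilities(trial_energies, beta)
    return float(p[chosen] / len(p))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def grow_monomer(
    geometry_model: GasGeometryModel,
    center: np.ndarray,
    r_cl: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow one water monomer at a uniformly random point in the bonded sphere.

    Returns a (3, 3) array of O, H1, H2 positions: bond lengths r1, r2
    and the H-O-H angle are drawn from the gas geometry model, the
    molecule is given a uniformly random orientation, and its oxygen is
    placed uniformly in the sphere of radius r_cl about ``center``.
    """
    r1 = geometry_model.sample_bond_length(rng)
    r2 = geometry_model.sample_bond_length(rng)
    theta = geometry_model.sample_angle_rad(rng)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 0.0, r1],
            [r2 * math.sin(theta), 0.0, r2 * math.cos(theta)],
        ]
    )
    rot = _random_rotation(rng)
    # uniform point in the sphere: direction uniform, radius ~ r^2 density
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = r_cl * rng.random() ** (1.0 / 3.0)
    origin = np.asarray(center, dtype=float) + radius * direction
    return origin + local @ rot.T


def _bias_delta(bias_table, n_old: int, n_new: int) -> float:
    """eta(n_new) - eta(n_old) from a 1-based bias table (None means zero bias)."""
    if bias_table is None:
        return 0.0
    eta = np.asarray(bias_table, dtype=float)
    return float(eta[n_new - 1] - eta[n_old - 1])


def translate_atom(
    config: AtomicConfiguration,
    topology: BondTopology,
    params: PotentialParameters,
    max_disp: float,
    rng: np.random.Generator,
    beta: float,
    r_cl: float = cluster_mod.DEFAULT_R_CL,
) -> MoveOutcome:
    """Metropolis single-atom translation.

    A molecule is chosen uniformly, then one of its three atoms; each
    coordinate is displaced uniformly in [-max_disp, +max_disp].  Moves
    that fragment the Stillinger cluster are rejected before the energy
    evaluation; otherwise acceptance is min(1, e^(-beta dU)).  Accepted
    moves refresh the bond topology (a hydrogen may change owner).
    """
    n = config.n_molecules
    mol = int(rng.integers(n))
    atoms = topology.molecule_atoms(mol)
    atom = int(atoms[rng.integers(len(atoms))])
    disp = rng.uniform(-max_disp, max_disp, size=3)
    new_pos = config.positions[atom] + disp

    if config.species[atom] == "O" and n > 1:
        trial = config.copy()
        trial.positions[atom] = new_pos
        state = cluster_mod.build_adjacency(trial, topology, r_cl)
        if not state.connected:
            return MoveOutcome("translate", False, reason="fragmented", n_new=n)

    try:
        d_u = delta_translate(config, params, atom, new_pos)
    except InvalidGeometryError:
        return MoveOutcome("translate", False, reason="overlap", n_new=n)

    log_acc = min(0.0, -beta * d_u)
    if math.log(rng.random() + 1e-300) < log_acc:
        new_config = config.copy()
        new_config.positions[atom] = new_pos
        new_topology = assign_hydrogens(new_config)
        return MoveOutcome(
            "translate", True, d_u=d_u, log_acceptance=log_acc, n_new=n,
            new_config=new_config, new_topology=new_topology,
        )
    return MoveOutcome("translate", False, reason="metropolis", d_u=d_u, log_acceptance=log_acc, n_new=n)


def _trial_interaction_energy(
    config: AtomicConfiguration,
    params: PotentialParameters,
    monomer: np.ndarray,
):
    """(U_interaction, dU_full, U_intra, combined config) for one trial monomer.

    Returns U_interaction = inf on atomic overlap.
    """
    try:
        d_u, combined = delta_insert(config, params, np.array(["O", "H", "H"]), monomer)
    except InvalidGeometryError:
        return math.inf, math.inf, math.inf, None
    u_intra = monomer_energy(monomer, params)
    return d_u - u_intra, d_u, u_intra, combined


@dataclass
class _SwapEvaluation:
    """Acceptance evaluation of one concrete swap proposal."""

    log_acceptance: float   # raw (unclamped) log of the acceptance ratio
    d_u: float
    u_intra: float
    log_p_insert: float
    log_p_remove: float
    new_config: Optional[AtomicConfiguration]
    new_topology: Optional[BondTopology]


def insertion_log_acceptance(
    config: AtomicConfiguration,
    topology: BondTopology,
    params: PotentialParameters,
    reservoir: ReservoirModel,
    target: int,
    monomer: np.ndarray,
    p_target_i: float,
    p_sel: float,
    K: int,
    r_cl: float,
    bias_table=None,
) -> _SwapEvaluation:
    """Log acceptance ratio of inserting a concrete monomer at a given target.

    ln[(P_remove / P_insert) / (K P_sel)] - beta (dU - U_intra - mu +
    d_eta), with the reverse-deletion probabilities P_remove evaluated
    in the post-insertion state.  Exposed separately from
    ``cbmc_insert`` so the transition density of a pinned proposal can
    be estimated (the detailed-balance oracle).
    """
    beta = reservoir.beta
    n = config.n_molecules
    u_int, d_u, u_intra, combined = _trial_interaction_energy(config, params, monomer)
    if not math.isfinite(u_int):
        raise InvalidGeometryError("pinned monomer overlaps the cluster")
    new_topology = assign_hydrogens(combined)
    u_mol_new = all_molecule_interaction_energies(combined, new_topology, params)
    inserted = n
    log_p_target_d = float(beta * u_mol_new[target] - logsumexp(beta * u_mol_new))
    neighbors, v_in = cluster_mod.bonded_region_members(combined, new_topology, target, r_cl)
    pos_in_nei = int(np.flatnonzero(neighbors == inserted)[0])
    lw_nei = beta * u_mol_new[neighbors]
    log_p_select_d = float(lw_nei[pos_in_nei] - logsumexp(lw_nei))

    bias_delta = _bias_delta(bias_table, n, n + 1)
    log_p_insert = math.log(p_target_i) - math.log(v_in)
    log_p_remove = log_p_target_d + log_p_select_d
    log_acc = (
        log_p_remove
        - log_p_insert
        - math.log(K * p_sel)
        - beta * (d_u - u_intra - reservoir.mu + bias_delta)
    )
    return _SwapEvaluation(log_acc, d_u, u_intra, log_p_insert, log_p_remove, combined, new_topology)


def deletion_log_acceptance(
    config: AtomicConfiguration,
    topology: BondTopology,
    params: PotentialParameters,
    reservoir: ReservoirModel,
    geometry_model: GasGeometryModel,
    target: int,
    victim: int,
    p_target_d: float,
    p_select_d: float,
    K: int,
    alpha: float,
    rng: np.random.Generator,
    r_cl: float,
    bias_table=None,
) -> _SwapEvaluation:
    """Log acceptance ratio of deleting a concrete victim molecule.

    ln[(P_insert / P_remove) K P_sel] - beta (dU + U_intra + mu +
    d_eta): the reverse-insertion Rosenbluth weight combines the
    actual molecule with K-1 freshly grown ghost trials, and P_insert
    is evaluated in the post-deletion state.
    """
    beta = reservoir.beta
    n = config.n_molecules
    atoms = topology.molecule_atoms(victim)
    d_u, new_config = delta_delete(config, params, atoms.tolist())
    new_topology = assign_hydrogens(new_config)
    u_intra = monomer_energy(config.positions[atoms], params)
    u_actual = -d_u - u_intra  # interaction energy of the removed monomer

    target_new = target if target < victim else target - 1
    center = new_config.positions[new_topology.oxygen_indices[target_new]]
    ghost_u = [
        _trial_interaction_energy(new_config, params, grow_monomer(geometry_model, center, r_cl, rng))[0]
        for _ in range(K - 1)
    ]
    all_u = np.array([u_actual] + ghost_u)
    log_w = np.where(np.isfinite(all_u), -beta * all_u, -np.inf)
    log_p_sel_actual = float(-beta * u_actual - logsumexp(log_w))

    u_mol_new = all_molecule_interaction_energies(new_config, new_topology, params)
    log_p_target_i = float(alpha * u_mol_new[target_new] - logsumexp(alpha * u_mol_new))
    v_in = cluster_mod.bonded_region_volume(r_cl)
    log_p_insert = log_p_target_i - math.log(v_in)
    log_p_remove = math.log(p_target_d) + math.log(p_select_d)

    bias_delta = _bias_delta(bias_table, n, n - 1)
    log_acc = (
        log_p_insert
        - log_p_remove
        + math.log(K) + log_p_sel_actual
        - beta * (d_u + u_intra + reservoir.mu + bias_delta)
    )
    return _SwapEvaluation(log_acc, d_u, u_intra, log_p_insert, log_p_remove, new_config, new_topology)


def cbmc_insert(
    config: AtomicConfiguration,
    topology: BondTopology,
    params: PotentialParameters,
    reservoir: ReservoirModel,
    geometry_model: GasGeometryModel,
    K: int,
    alpha: float,
    rng: np.random.Generator,
    r_cl: float = cluster_mod.DEFAULT_R_CL,
    bias_table=None,
    n_max: Optional[int] = None,
    n_bounds: Optional[tuple] = None,
) -> MoveOutcome:
    """Configurational-bias insertion of one water monomer.

    Target selection is energy-biased (exponent alpha, conventionally
    0.1 beta); K trial monomers are grown in the target's bonded
    sphere and one is picked by its Rosenbluth factor.  The acceptance
    ratio is (P_remove / P_insert) / (K P_sel) * e^(-beta (dU - U_intra
    - mu + d_eta)), with P_remove evaluated in the post-insertion
    state, as reversibility requires.
    """
    beta = reservoir.beta
    n = config.n_molecules
    hi = min(x for x in (n_max, n_bounds[1] if n_bounds else None) if x is not None) if (n_max or n_bounds) else None
    if hi is not None and n + 1 > hi:
        return MoveOutcome("insert", False, reason="cap", n_new=n)

    u_mol = all_molecule_interaction_energies(config, topology, params)
    target, p_target_i = select_insertion_target(u_mol, alpha, rng)
    center = config.positions[topology.oxygen_indices[target]]
    v_in = cluster_mod.bonded_region_volume(r_cl)

    trials = [grow_monomer(geometry_model, center, r_cl, rng) for _ in range(K)]
    results = [_trial_interaction_energy(config, params, t) for t in trials]
    u_int = np.array([r[0] for r in results])
    if not np.any(np.isfinite(u_int)):
        return MoveOutcome("insert", False, reason="overlap", n_new=n)

    log_w = np.where(np.isfinite(u_int), -beta * u_int, -np.inf)
    m, p_sel = boltzmann_select(log_w, rng)

    ev = insertion_log_acceptance(
        config, topology, params, reservoir, target, trials[m],
        p_target_i, p_sel, K, r_cl, bias_table,
    )
    outcome = MoveOutcome(
        "insert",
        False,
        d_u=ev.d_u,
        u_intra=ev.u_intra,
        p_insert=math.exp(ev.log_p_insert),
        p_remove=math.exp(ev.log_p_remove),
        p_trial=p_sel / K,
        bias_delta=_bias_delta(bias_table, n, n + 1),
        log_acceptance=min(0.0, ev.log_acceptance),
        n_new=n,
    )
    if math.log(rng.random() + 1e-300) < ev.log_acceptance:
        outcome.accepted = True
        outcome.n_new = n + 1
        outcome.new_config = ev.new_config
        outcome.new_topology = ev.new_topology
    else:
        outcome.reason = "metropolis"
    return outcome


def avbmc_delete(
    config: AtomicConfiguration,
    topology: BondTopology,
    params: PotentialParameters,
    reservoir: ReservoirModel,
    geometry_model: GasGeometryModel,
    K: int,
    alpha: float,
    rng: np.random.Generator,
    r_cl: float = cluster_mod.DEFAULT_R_CL,
    bias_table=None,
    n_bounds: Optional[tuple] = None,
    deterministic_neighbor: bool = False,
    bond_length_cutoff: float = 2.0,
) -> MoveOutcome:
    """Energy-biased deletion of one water monomer.

    Target and neighbor are chosen with Boltzmann weights e^(beta U);
    the move is rejected without any trial-energy evaluation when the
    neighbor is dissociated (an assigned hydrogen beyond the 2 A bond
    length, or a foreign hydrogen closer to its oxygen) or when removal
    would fragment the cluster.  The reverse-insertion Rosenbluth
    weight combines the actual molecule with K-1 freshly grown ghost
    trials; the acceptance ratio is (P_insert / P_remove) * (K P_sel)
    * e^(-beta (dU + U_intra + mu + d_eta)) with P_insert evaluated in
    the post-deletion state.
    """
    beta = reservoir.beta
    n = config.n_molecules
    lo = max(1, n_bounds[0] if n_bounds else 1)
    if n - 1 < lo:
        return MoveOutcome("delete", False, reason="floor", n_new=n)

    u_mol = all_molecule_interaction_energies(config, topology, params)
    target, p_target_d = select_deletion_target(u_mol, beta, rng)
    neighbors, v_in = cluster_mod.bonded_region_members(config, topology, target, r_cl)
    if len(neighbors) == 0:
        return MoveOutcome("delete", False, reason="no_neighbor", n_new=n)
    nb_pos, p_select_d = select_deletion_neighbor(
        u_mol[neighbors], beta, rng, deterministic=deterministic_neighbor
    )
    victim = int(neighbors[nb_pos])

    if not is_deletable(config, topology, victim, bond_length_cutoff):
        return MoveOutcome("delete", False, reason="dissociated", n_new=n)

    keep = np.ones(n, dtype=bool)
    keep[victim] = False
    o_pos = config.positions[topology.oxygen_indices[keep]]
    if n - 1 > 1:
        adj = squareform(pdist(o_pos)) <= r_cl
        np.fill_diagonal(adj, False)
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            return MoveOutcome("delete", False, reason="fragmented", n_new=n)

    ev = deletion_log_acceptance(
        config, topology, params, reservoir, geometry_model, target, victim,
        p_target_d, p_select_d, K, alpha, rng, r_cl, bias_table,
    )
    outcome = MoveOutcome(
        "delete",
        False,
        d_u=ev.d_u,
        u_intra=ev.u_intra,
        p_insert=math.exp(ev.log_p_insert),
        p_remove=math.exp(ev.log_p_remove),
        bias_delta=_bias_delta(bias_table, n, n - 1),
        log_acceptance=min(0.0, ev.log_acceptance),
        n_new=n,
    )
    if math.log(rng.random() + 1e-300) < ev.log_acceptance:
        outcome.accepted = True
        outcome.n_new = n - 1
        outcome.new_config = ev.new_config
        outcome.new_topology = ev.new_topology
    else:
        outcome.reason = "metropolis"
    return outcome
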