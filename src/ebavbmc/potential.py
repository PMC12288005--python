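"""Vashishta-form reactive water potential.

Two-body terms (steric repulsion, screened Coulomb, screened
charge-dipole attraction, van der Waals attraction) are shifted and
truncated at the cutoff ``r_c`` so that both the energy and its first
derivative are continuous there.  The three-body term is a
bond-stretch x bond-bend product acting on every H-O-H triple whose
two O-H distances are below ``r_0`` -- selected purely geometrically,
independent of the assigned bond topology, which is what allows the
model to dissociate.

The geometry is open (no box, no periodic images): the simulated
object is a single physical cluster.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .units import COULOMB_EV_A

__all__ = [
    "PotentialParameters",
    "AtomicConfiguration",
    "EnergyBreakdown",
    "InvalidGeometryError",
    "shifted_pair_energy",
    "three_body_energy",
    "total_energy",
    "delta_translate",
    "delta_insert",
    "delta_delete",
    "intramolecular_energy",
    "molecule_interaction_energy",
    "all_molecule_interaction_energies",
    "molecule_partition_total",
]

_PAIR_KEYS = ("OO", "OH", "HH")
# species code: O -> 0, H -> 1; pair index = code_i + code_j
_SPECIES_CODE = {"O": 0, "H": 1}

_MIN_SEPARATION = 1e-6  # Angstrom; closer approaches are treated as overlaps


class InvalidGeometryError(ValueError):
    """Raised when atoms overlap or an energy evaluates to a non-finite value."""


@dataclass(frozen=True)
class PotentialParameters:
    """All symbols of the Vashishta water form.

    Pair quantities are dicts keyed by ``"OO"``, ``"OH"``, ``"HH"``;
    ``Z`` is keyed by species.  Units: ``H_ij`` in eV*A^eta, ``D_ij``
    in eV*A^4, ``W_ij`` in eV*A^6, ``Z_i`` in elementary charges,
    lengths in Angstrom, ``B`` in eV.
    """

    H: dict
    eta: dict
    Z: dict
    D: dict
    W: dict
    r1s: float
    r4s: float
    rc: float
    B: float
    xi: float
    r0: float
    cos_theta0: float

    # derived per-pair arrays, filled in __post_init__
    _pair_tables: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.rc <= 0 or self.r0 <= 0:
            raise ValueError("cutoffs rc and r0 must be positive")
        if self.r0 > self.rc:
            raise ValueError("three-body range r0 must not exceed rc")
        if self.r1s <= 0 or self.r4s <= 0:
            raise ValueError("screening lengths must be positive")
        for key in _PAIR_KEYS:
            if self.eta[key] <= 0:
                raise ValueError(f"steric exponent eta[{key}] must be positive")
        H = np.array([self.H[k] for k in _PAIR_KEYS])
        eta = np.array([self.eta[k] for k in _PAIR_KEYS])
        D = np.array([self.D[k] for k in _PAIR_KEYS])
        W = np.array([self.W[k] for k in _PAIR_KEYS])
        zz = np.array(
            [
                self.Z["O"] * self.Z["O"],
                self.Z["O"] * self.Z["H"],
                self.Z["H"] * self.Z["H"],
            ]
        ) * COULOMB_EV_A
        rc = self.rc
        t_shift = _u2_raw(np.full(3, rc), np.arange(3), H, eta, zz, D, W, self.r1s, self.r4s)
        dudr_rc = _du2_raw(np.full(3, rc), np.arange(3), H, eta, zz, D, W, self.r1s, self.r4s)
        object.__setattr__(self, "_pair_tables", (H, eta, zz, D, W, t_shift, dudr_rc))


def _u2_raw(r, pair_idx, H, eta, zz, D, W, r1s, r4s):
    """Unshifted two-body energy for distances r and pair indices pair_idx."""
    r = np.asarray(r, dtype=float)
    i = np.asarray(pair_idx)
    return (
        H[i] / r ** eta[i]
        + zz[i] / r * np.exp(-r / r1s)
        - D[i] / r**4 * np.exp(-r / r4s)
        - W[i] / r**6
    )


def _du2_raw(r, pair_idx, H, eta, zz, D, W, r1s, r4s):
    """d/dr of the unshifted two-body energy."""
    r = np.asarray(r, dtype=float)
    i = np.asarray(pair_idx)
    return (
        -eta[i] * H[i] / r ** (eta[i] + 1)
        + zz[i] * np.exp(-r / r1s) * (-1.0 / r**2 - 1.0 / (r1s * r))
        - D[i] * np.exp(-r / r4s) * (-4.0 / r**5 - 1.0 / (r4s * r**4))
        + 6.0 * W[i] / r**7
    )


def _pair_energy_array(r, pair_idx, params: PotentialParameters):
    """Shifted/truncated two-body energies for arrays of distances."""
    H, eta, zz, D, W, t, du = params._pair_tables
    r = np.asarray(r, dtype=float)
    i = np.asarray(pair_idx)
    if np.any(r < _MIN_SEPARATION):
        raise InvalidGeometryError("overlapping atoms (pair distance ~ 0)")
    out = np.zeros_like(r)
    inside = r < params.rc
    if np.any(inside):
        ri, ii = r[inside], i[inside]
        u = _u2_raw(ri, ii, H, eta, zz, D, W, params.r1s, params.r4s)
        out[inside] = u - t[ii] - (ri - params.rc) * du[ii]
    if not np.all(np.isfinite(out)):
        raise InvalidGeometryError("non-finite two-body energy")
    return out


def shifted_pair_energy(species_i: str, species_j: str, r: float, params: PotentialParameters) -> float:
    """Shifted, truncated two-body energy for one pair at distance ``r`` (A).

    Zero for ``r >= r_c``; energy and first derivative vanish at the
    cutoff by construction of the linear shift.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    idx = _SPECIES_CODE[species_i] + _SPECIES_CODE[species_j]
    return float(_pair_energy_array(np.array([r]), np.array([idx]), params)[0])


def three_body_energy(r_ij: float, r_ik: float, cos_theta: float, params: PotentialParameters) -> float:
    """Stretch x bend three-body energy of one H-O-H triple (O central).

    ``B * exp(xi/(r_ij - r0) + xi/(r_ik - r0)) * (cos - cos0)^2`` when both
    O-H distances are below ``r_0``, else exactly zero.
    """
    if r_ij <= 0 or r_ik <= 0:
        raise ValueError("O-H distances must be positive")
    if not -1.0 <= cos_theta <= 1.0:
        raise ValueError("cos(theta) outside [-1, 1]")
    if r_ij >= params.r0 or r_ik >= params.r0:
        return 0.0
    f = math.exp(params.xi / (r_ij - params.r0) + params.xi / (r_ik - params.r0))
    return params.B * f * (cos_theta - params.cos_theta0) ** 2


@dataclass
class AtomicConfiguration:
    """Positions (A) and species of every atom of the cluster phase.

    ``species`` is an array over {"O", "H"} with count(H) = 2*count(O).
    """

    species: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.species = np.asarray(self.species, dtype="<U1")
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.species) != len(self.positions):
            raise ValueError("species/positions length mismatch")
        n_o = int(np.sum(self.species == "O"))
        n_h = int(np.sum(self.species == "H"))
        if n_o + n_h != len(self.species):
            raise ValueError("species must be 'O' or 'H'")
        if n_h != 2 * n_o:
            raise ValueError(f"need count(H) = 2*count(O), got {n_h} H / {n_o} O")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def n_molecules(self) -> int:
        return int(np.sum(self.species == "O"))

    @property
    def codes(self) -> np.ndarray:
        return (self.species == "H").astype(np.int64)

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(self.species.copy(), self.positions.copy())


@dataclass
class EnergyBreakdown:
    total: float
    two_body: float
    three_body: float
    per_atom: np.ndarray


def _enumerate_triples(config: AtomicConfiguration, params: PotentialParameters):
    """Yield (o, h1, h2, r1, r2, cos) for every geometric H-O-H triple."""
    codes = config.codes
    o_idx = np.flatnonzero(codes == 0)
    h_idx = np.flatnonzero(codes == 1)
    if len(o_idx) == 0 or len(h_idx) < 2:
        return
    d_oh = cdist(config.positions[o_idx], config.positions[h_idx])
    for a, o in enumerate(o_idx):
        close = np.flatnonzero(d_oh[a] < params.r0)
        for b, c in itertools.combinations(close, 2):
            h1, h2 = h_idx[b], h_idx[c]
            r1, r2 = d_oh[a, b], d_oh[a, c]
            v1 = config.positions[h1] - config.positions[o]
            v2 = config.positions[h2] - config.positions[o]
            cos = float(np.dot(v1, v2) / (r1 * r2))
            cos = max(-1.0, min(1.0, cos))
            yield o, h1, h2, r1, r2, cos


def total_energy(config: AtomicConfiguration, params: PotentialParameters) -> EnergyBreakdown:
    """Sum all unique two-body pairs within r_c and all geometric H-O-H triples.

    ``per_atom`` is a bookkeeping partition (half of each pair term to
    each endpoint, each triple to its central oxygen) that sums to the
    total exactly.
    """
    n = config.n_atoms
    per_atom = np.zeros(n)
    if n == 0:
        return EnergyBreakdown(0.0, 0.0, 0.0, per_atom)
    two = 0.0
    if n >= 2:
        d = pdist(config.positions)
        codes = config.codes
        ii, jj = np.triu_indices(n, k=1)
        pair_idx = codes[ii] + codes[jj]
        e = _pair_energy_array(d, pair_idx, params)
        two = float(np.sum(e))
        np.add.at(per_atom, ii, 0.5 * e)
        np.add.at(per_atom, jj, 0.5 * e)
    three = 0.0
    for o, h1, h2, r1, r2, cos in _enumerate_triples(config, params):
        u3 = three_body_energy(r1, r2, cos, params)
        three += u3
        per_atom[o] += u3
    return EnergyBreakdown(two + three, two, three, per_atom)


def _terms_involving(config: AtomicConfiguration, atom_set, params: PotentialParameters) -> float:
    """Energy of every pair/triple term touching at least one atom in ``atom_set``.

    Each term is counted once.  Used for incremental move energies.
    """
    sel = np.zeros(config.n_atoms, dtype=bool)
    sel[list(atom_set)] = True
    idx_sel = np.flatnonzero(sel)
    if len(idx_sel) == 0:
        return 0.0
    codes = config.codes
    pos = config.positions
    total = 0.0
    # cross pairs: selected vs unselected
    idx_rest = np.flatnonzero(~sel)
    if len(idx_rest):
        d = cdist(pos[idx_sel], pos[idx_rest])
        pi = codes[idx_sel][:, None] + codes[idx_rest][None, :]
        total += float(np.sum(_pair_energy_array(d.ravel(), pi.ravel(), params)))
    # internal pairs of the selected set
    if len(idx_sel) >= 2:
        d = pdist(pos[idx_sel])
        ii, jj = np.triu_indices(len(idx_sel), k=1)
        pi = codes[idx_sel][ii] + codes[idx_sel][jj]
        total += float(np.sum(_pair_energy_array(d, pi, params)))
    # triples touching the set
    for o, h1, h2, r1, r2, cos in _enumerate_triples(config, params):
        if sel[o] or sel[h1] or sel[h2]:
            total += three_body_energy(r1, r2, cos, params)
    return total


def delta_translate(config: AtomicConfiguration, params: PotentialParameters, atom: int, new_position: np.ndarray) -> float:
    """Energy change of displacing one atom, from affected terms only."""
    old = _terms_involving(config, [atom], params)
    saved = config.positions[atom].copy()
    config.positions[atom] = new_position
    try:
        new = _terms_involving(config, [atom], params)
    finally:
        config.positions[atom] = saved
    return new - old


def delta_insert(config: AtomicConfiguration, params: PotentialParameters, species: np.ndarray, positions: np.ndarray) -> tuple:
    """Energy change of appending the given atoms; returns (dU, new_config)."""
    new_config = AtomicConfiguration(
        np.concatenate([config.species, np.asarray(species, dtype="<U1")]),
        np.vstack([config.positions, np.asarray(positions, dtype=float).reshape(-1, 3)]),
    )
    new_atoms = range(config.n_atoms, new_config.n_atoms)
    return _terms_involving(new_config, list(new_atoms), params), new_config


def delta_delete(config: AtomicConfiguration, params: PotentialParameters, atoms) -> tuple:
    """Energy change of removing the given atoms; returns (dU, new_config)."""
    atoms = sorted(atoms)
    d_u = -_terms_involving(config, atoms, params)
    keep = np.ones(config.n_atoms, dtype=bool)
    keep[atoms] = False
    new_config = AtomicConfiguration(config.species[keep], config.positions[keep])
    return d_u, new_config


def _molecule_atoms(topology, molecule_id: int):
    o = topology.oxygen_indices[molecule_id]
    hs = topology.hydrogens_of(molecule_id)
    if len(hs) != 2:
        raise ValueError(f"molecule {molecule_id} does not have exactly 2 assigned H")
    return o, hs[0], hs[1]


def intramolecular_energy(config: AtomicConfiguration, topology, molecule_id: int, params: PotentialParameters) -> float:
    """U_intra of one molecule: its three pair terms plus its own H-O-H triple."""
    o, h1, h2 = _molecule_atoms(topology, molecule_id)
    return monomer_energy(config.positions[[o, h1, h2]], params)


def monomer_energy(positions_ohh: np.ndarray, params: PotentialParameters) -> float:
    """Internal energy of an isolated water monomer given O, H, H positions."""
    p = np.asarray(positions_ohh, dtype=float).reshape(3, 3)
    r_oh1 = float(np.linalg.norm(p[1] - p[0]))
    r_oh2 = float(np.linalg.norm(p[2] - p[0]))
    r_hh = float(np.linalg.norm(p[2] - p[1]))
    e = (
        shifted_pair_energy("O", "H", r_oh1, params)
        + shifted_pair_energy("O", "H", r_oh2, params)
        + shifted_pair_energy("H", "H", r_hh, params)
    )
    if r_oh1 < params.r0 and r_oh2 < params.r0:
        cos = float(np.dot(p[1] - p[0], p[2] - p[0]) / (r_oh1 * r_oh2))
        cos = max(-1.0, min(1.0, cos))
        e += three_body_energy(r_oh1, r_oh2, cos, params)
    return e


def molecule_interaction_energy(config: AtomicConfiguration, topology, molecule_id: int, params: PotentialParameters) -> float:
    """Interaction of one molecule with all others.

    All two-body terms between this molecule's atoms and foreign atoms,
    plus every three-body term that spans more than one molecule and
    touches this molecule (counted in full here; the conservation
    identity divides spanning triples equally instead).
    """
    o, h1, h2 = _molecule_atoms(topology, molecule_id)
    mol_atoms = {o, h1, h2}
    sel = np.zeros(config.n_atoms, dtype=bool)
    sel[[o, h1, h2]] = True
    codes = config.codes
    pos = config.positions
    idx_sel = np.array([o, h1, h2])
    idx_rest = np.flatnonzero(~sel)
    total = 0.0
    if len(idx_rest):
        d = cdist(pos[idx_sel], pos[idx_rest])
        pi = codes[idx_sel][:, None] + codes[idx_rest][None, :]
        total += float(np.sum(_pair_energy_array(d.ravel(), pi.ravel(), params)))
    owner = topology.atom_owner
    for ot, h1t, h2t, r1, r2, cos in _enumerate_triples(config, params):
        mols = {owner[ot], owner[h1t], owner[h2t]}
        if len(mols) >= 2 and (ot in mol_atoms or h1t in mol_atoms or h2t in mol_atoms):
            total += three_body_energy(r1, r2, cos, params)
    return total


def all_molecule_interaction_energies(config: AtomicConfiguration, topology, params: PotentialParameters) -> np.ndarray:
    """Vector of molecule_interaction_energy over all molecules."""
    n_mol = config.n_molecules
    out = np.zeros(n_mol)
    codes = config.codes
    pos = config.positions
    owner = topology.atom_owner
    # pair part: sum over cross-molecule pairs, added to both molecules
    n = config.n_atoms
    if n >= 2:
        ii, jj = np.triu_indices(n, k=1)
        cross = owner[ii] != owner[jj]
        ii, jj = ii[cross], jj[cross]
        if len(ii):
            d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
            e = _pair_energy_array(d, codes[ii] + codes[jj], params)
            np.add.at(out, owner[ii], e)
            np.add.at(out, owner[jj], e)
    # spanning triples, full value to each touched molecule
    for o, h1, h2, r1, r2, cos in _enumerate_triples(config, params):
        mols = {owner[o], owner[h1], owner[h2]}
        if len(mols) >= 2:
            u3 = three_body_energy(r1, r2, cos, params)
            for m in mols:
                out[m] += u3
    return out


def molecule_partition_total(config: AtomicConfiguration, topology, params: PotentialParameters) -> float:
    """Total energy reassembled from the per-molecule partition.

    Sum over molecules of U_intra, plus every cross-molecule pair term
    once, plus every spanning triple once (equivalently: divided
    equally among the molecules it touches).  Equals total_energy.
    """
    total = 0.0
    for m in range(config.n_molecules):
        total += intramolecular_energy(config, topology, m, params)
    codes = config.codes
    pos = config.positions
    owner = topology.atom_owner
    n = config.n_atoms
    if n >= 2:
        ii, jj = np.triu_indices(n, k=1)
        cross = owner[ii] != owner[jj]
        ii, jj = ii[cross], jj[cross]
        if len(ii):
            d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
            total += float(np.sum(_pair_energy_array(d, codes[ii] + codes[jj], params)))
    for o, h1, h2, r1, r2, cos in _enumerate_triples(config, params):
        if len({owner[o], owner[h1], owner[h2]}) >= 2:
            total += three_body_energy(r1, r2, cos, params)
    return total
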