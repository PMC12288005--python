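"""Bond topology bookkeeping for the dissociative water model.

The force field itself is bond-agnostic; molecule identity is pure
bookkeeping: every hydrogen is assigned to exactly one oxygen and
every oxygen carries exactly two hydrogens.  The assignment is the
deterministic fixed point of iterative nearest-oxygen reassignment:
each hydrogen prefers closer oxygens, and an oxygen attracting more
than two hydrogens keeps its two nearest while the rest move on to
their next-nearest oxygen.  This is a capacity-2 deferred-acceptance
matching, so the result depends only on the positions (ties broken by
lower atom index), not on input order.

After every accepted Monte Carlo move the assignment is recomputed;
proton transfer (Grotthuss-style hops) shows up as a hydrogen changing
owner between two oxygens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .potential import AtomicConfiguration

__all__ = ["BondTopology", "TopologyError", "assign_hydrogens", "update_after_move", "is_deletable"]


class TopologyError(RuntimeError):
    """Assignment failed to converge (should not happen for valid input)."""


@dataclass
class BondTopology:
    """Mapping hydrogen -> oxygen plus derived molecule ids.

    Molecule ``m`` is the ``m``-th oxygen in atom order; ``h_owner[k]``
    is the molecule id of the ``k``-th hydrogen; ``atom_owner`` maps
    every atom index to its molecule id.
    """

    oxygen_indices: np.ndarray
    hydrogen_indices: np.ndarray
    h_owner: np.ndarray

    @property
    def n_molecules(self) -> int:
        return len(self.oxygen_indices)

    @property
    def atom_owner(self) -> np.ndarray:
        n = len(self.oxygen_indices) + len(self.hydrogen_indices)
        owner = np.empty(n, dtype=np.int64)
        owner[self.oxygen_indices] = np.arange(self.n_molecules)
        owner[self.hydrogen_indices] = self.h_owner
        return owner

    def hydrogens_of(self, molecule_id: int) -> np.ndarray:
        """Atom indices of the hydrogens assigned to a molecule, ascending."""
        return self.hydrogen_indices[np.flatnonzero(self.h_owner == molecule_id)]

    def molecule_atoms(self, molecule_id: int) -> np.ndarray:
        hs = self.hydrogens_of(molecule_id)
        return np.concatenate([[self.oxygen_indices[molecule_id]], hs])

    def validate(self) -> None:
        counts = np.bincount(self.h_owner, minlength=self.n_molecules)
        if not np.all(counts == 2):
            raise TopologyError(f"oxygen capacity violated: counts {counts}")

    def as_pairs(self) -> set:
        """The assignment as a set of (hydrogen atom index, oxygen atom index)."""
        return {
            (int(h), int(self.oxygen_indices[m]))
            for h, m in zip(self.hydrogen_indices, self.h_owner)
        }


def assign_hydrogens(config: AtomicConfiguration) -> BondTopology:
    """Deterministic capacity-2 assignment of hydrogens to oxygens.

    Hydrogen-proposing deferred acceptance on distance-ordered
    preferences: unassigned hydrogens propose to their best remaining
    oxygen; an oversubscribed oxygen rejects all but its two nearest
    proposers.  The fixed point is the hydrogen-optimal stable matching
    and is invariant under relabeling of same-species atoms.
    """
    o_idx = np.flatnonzero(config.species == "O")
    h_idx = np.flatnonzero(config.species == "H")
    n_o, n_h = len(o_idx), len(h_idx)
    if n_h != 2 * n_o:
        raise ValueError("assignment requires count(H) = 2*count(O)")
    if n_o == 0:
        return BondTopology(o_idx, h_idx, np.empty(0, dtype=np.int64))

    d = cdist(config.positions[h_idx], config.positions[o_idx])
    # preference order per hydrogen: by distance, ties by lower oxygen atom index
    pref = np.lexsort((np.broadcast_to(o_idx, d.shape), d), axis=1)

    next_choice = np.zeros(n_h, dtype=np.int64)  # next preference rank to propose to
    owner = np.full(n_h, -1, dtype=np.int64)     # current molecule id per hydrogen
    free = list(range(n_h))
    holders: list[list[int]] = [[] for _ in range(n_o)]

    max_proposals = 10 * n_h * max(n_o, 1)
    proposals = 0
    while free:
        h = free.pop()
        if next_choice[h] >= n_o:
            raise TopologyError("hydrogen exhausted all oxygens; infeasible geometry")
        m = int(pref[h, next_choice[h]])
        next_choice[h] += 1
        proposals += 1
        if proposals > max_proposals:
            raise TopologyError(
                f"assignment did not converge after {proposals} proposals "
                f"({n_o} O / {n_h} H)"
            )
        holders[m].append(h)
        if len(holders[m]) > 2:
            # reject the farthest proposer (ties: higher hydrogen atom index)
            worst = max(holders[m], key=lambda k: (d[k, m], h_idx[k]))
            holders[m].remove(worst)
            owner[worst] = -1
            free.append(worst)
        owner[h] = m

    topo = BondTopology(o_idx, h_idx, owner)
    topo.validate()
    return topo


def update_after_move(config: AtomicConfiguration, topology: BondTopology, moved_atoms=None) -> BondTopology:
    """Topology valid for the post-move configuration.

    Contract: identical to ``assign_hydrogens`` on the new positions.
    A full recompute is cheap at cluster sizes of interest, so no
    incremental shortcut is taken.
    """
    return assign_hydrogens(config)


def is_deletable(
    config: AtomicConfiguration,
    topology: BondTopology,
    molecule_id: int,
    bond_length_cutoff: float = 2.0,
) -> bool:
    """Whether a molecule is an unambiguous structural unit of water.

    True iff the two hydrogens nearest (system-wide) to the molecule's
    oxygen are exactly its two assigned hydrogens and both lie within
    ``bond_length_cutoff`` (default 2 A) of that oxygen.  Deleting a
    dissociated molecule would remove atoms that no longer form a
    water unit, so such deletions are rejected.
    """
    o = topology.oxygen_indices[molecule_id]
    h_pos = config.positions[topology.hydrogen_indices]
    dists = np.linalg.norm(h_pos - config.positions[o], axis=1)
    order = np.lexsort((topology.hydrogen_indices, dists))
    nearest_two = set(topology.hydrogen_indices[order[:2]].tolist())
    assigned = set(topology.hydrogens_of(molecule_id).tolist())
    if nearest_two != assigned:
        return False
    return bool(np.all(dists[order[:2]] <= bond_length_cutoff))
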