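"""Stillinger cluster criterion over molecules.

Two molecules are neighbors when their oxygens are within ``r_cl``
(default 4 A); a cluster is a connected component of that graph.  The
sampler keeps the configuration a single cluster at all times, which
is what makes the cluster size ``n`` a well-defined reaction
coordinate and the grand-canonical cluster ensemble volume-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .potential import AtomicConfiguration
from .topology import BondTopology

__all__ = [
    "DEFAULT_R_CL",
    "ClusterState",
    "build_adjacency",
    "is_single_cluster",
    "bonded_region_members",
    "bonded_region_volume",
]

DEFAULT_R_CL = 4.0


@dataclass
class ClusterState:
    r_cl: float
    adjacency: np.ndarray  # boolean (n_mol, n_mol), symmetric, zero diagonal
    n: int
    connected: bool


def bonded_region_volume(r_cl: float) -> float:
    """V_in = 4 pi r_cl^3 / 3 (A^3), the swap insertion volume."""
    return 4.0 / 3.0 * np.pi * r_cl**3


def build_adjacency(config: AtomicConfiguration, topology: BondTopology, r_cl: float = DEFAULT_R_CL) -> ClusterState:
    """Molecule adjacency under the oxygen-oxygen Stillinger criterion."""
    o_pos = config.positions[topology.oxygen_indices]
    n_mol = len(o_pos)
    if n_mol <= 1:
        adj = np.zeros((n_mol, n_mol), dtype=bool)
        return ClusterState(r_cl, adj, n_mol, True)
    d = squareform(pdist(o_pos))
    adj = (d <= r_cl) & ~np.eye(n_mol, dtype=bool)
    n_comp, _ = connected_components(adj, directed=False)
    return ClusterState(r_cl, adj, n_mol, n_comp == 1)


def is_single_cluster(state: ClusterState) -> bool:
    """True iff the molecule graph has exactly one connected component."""
    return state.connected


def bonded_region_members(
    config: AtomicConfiguration,
    topology: BondTopology,
    target_molecule: int,
    r_cl: float = DEFAULT_R_CL,
) -> tuple:
    """Molecules whose oxygen lies within r_cl of the target's oxygen.

    Excludes the target itself.  Returns (member molecule ids, V_in).
    """
    o_pos = config.positions[topology.oxygen_indices]
    d = np.linalg.norm(o_pos - o_pos[target_molecule], axis=1)
    members = np.flatnonzero((d <= r_cl) & (np.arange(len(o_pos)) != target_molecule))
    return members, bonded_region_volume(r_cl)
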