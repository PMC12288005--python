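"""Simulation driver: move scheduling, umbrella bias, windows, walkers.

A walker runs ``steps`` Monte Carlo steps of ``moves_per_step`` trial
moves each, mixing AVBMC swaps and single-atom translations at a
configurable ratio (1 swap : 10 translations by default, insertions
and deletions attempted with equal frequency).  The cluster size n is
recorded every sampling stride and accumulated into the umbrella
histogram; the bias eta(n) is refined between bursts so that sampling
over n becomes approximately uniform, and multiple independent
walkers (or overlapping windows in n) are merged later by WHAM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import cluster as cluster_mod
from .moves import (
    GasGeometryModel,
    MoveOutcome,
    ReservoirModel,
    avbmc_delete,
    cbmc_insert,
    translate_atom,
)
from .potential import AtomicConfiguration, PotentialParameters
from .topology import BondTopology, assign_hydrogens
from .units import KB_EV

__all__ = ["UmbrellaState", "RunProtocol", "WalkerResult", "run_walker", "refine_bias", "window_schedule"]


@dataclass
class UmbrellaState:
    """Bias table eta(n) (eV) and visit histogram h(n) over n in [1, n_max]."""

    n_max: int
    eta: np.ndarray = None
    histogram: np.ndarray = None
    iteration: int = 0

    def __post_init__(self):
        if self.eta is None:
            self.eta = np.zeros(self.n_max)
        else:
            self.eta = np.asarray(self.eta, dtype=float).copy()
        if self.histogram is None:
            self.histogram = np.zeros(self.n_max)
        else:
            self.histogram = np.asarray(self.histogram, dtype=float).copy()
        if len(self.eta) != self.n_max or len(self.histogram) != self.n_max:
            raise ValueError("bias/histogram length must equal n_max")
        if not np.all(np.isfinite(self.eta)):
            raise ValueError("bias table must be finite")

    def record(self, n: int) -> None:
        self.histogram[n - 1] += 1


def refine_bias(umbrella: UmbrellaState, T: float) -> UmbrellaState:
    """One self-adaptive refinement: push the bias toward flat sampling.

    Visited bins get eta'(n) = eta(n) + k_B T ln(h(n)/hbar) with hbar
    the mean count over visited bins, so over-visited sizes become
    penalized; unvisited bins inherit the update of the nearest visited
    bin.  The histogram is reset and eta' re-anchored to eta'(1) = 0.
    """
    h = umbrella.histogram
    visited = np.flatnonzero(h > 0)
    if len(visited) == 0:
        raise ValueError("cannot refine bias from an empty histogram")
    kT = KB_EV * T
    update = np.zeros(umbrella.n_max)
    hbar = h[visited].mean()
    update[visited] = kT * np.log(h[visited] / hbar)
    unvisited = np.flatnonzero(h == 0)
    if len(unvisited):
        nearest = visited[np.argmin(np.abs(unvisited[:, None] - visited[None, :]), axis=1)]
        update[unvisited] = update[nearest]
    eta = umbrella.eta + update
    eta -= eta[0]
    return UmbrellaState(umbrella.n_max, eta=eta, iteration=umbrella.iteration + 1)


def window_schedule(n_max: int, windows: int, overlap: int) -> list:
    """Contiguous overlapping windows covering [1, n_max].

    Returns a list of (n_lo, n_hi, initial_bias) with adjacent windows
    sharing ``overlap`` bins; a walker restricted to a window rejects
    moves that would leave it.
    """
    if windows < 1:
        raise ValueError("need at least one window")
    if windows == 1:
        return [(1, n_max, np.zeros(n_max))]
    width = int(np.ceil((n_max + (windows - 1) * overlap) / windows))
    if overlap >= width:
        raise ValueError(f"overlap {overlap} must be smaller than window width {width}")
    out = []
    for i in range(windows):
        lo = 1 + i * (width - overlap)
        hi = min(lo + width - 1, n_max)
        if i == windows - 1:
            hi = n_max
        out.append((lo, hi, np.zeros(n_max)))
    if out[-1][0] > n_max:
        raise ValueError("window schedule does not cover the range; reduce windows")
    return out


@dataclass
class RunProtocol:
    """Run-length and move-mix settings of one walker."""

    steps: int
    moves_per_step: int = 100
    n_max: int = 30
    avbmc_every: int = 11      # 1 swap per 10 translations -> 1 in 11 trial moves
    K: int = 50
    alpha: Optional[float] = None  # defaults to 0.1 * beta
    max_disp: float = 0.05
    r_cl: float = cluster_mod.DEFAULT_R_CL
    stride: int = 1
    window: Optional[tuple] = None  # (n_lo, n_hi); defaults to (1, n_max)

    def __post_init__(self):
        for name in ("steps", "moves_per_step", "n_max", "avbmc_every", "K", "stride"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.max_disp <= 0:
            raise ValueError("max_disp must be positive")


@dataclass
class WalkerResult:
    sizes: np.ndarray              # n at each recorded stride
    steps: np.ndarray              # step index of each record
    stats: dict                    # per-move-type attempt/accept/reject counts
    config: AtomicConfiguration
    topology: BondTopology
    umbrella: UmbrellaState

    def acceptance_fraction(self, move: str) -> float:
        s = self.stats[move]
        return s["accepted"] / s["attempts"] if s["attempts"] else float("nan")


def _new_stats() -> dict:
    return {
        m: {"attempts": 0, "accepted": 0, "rejected": 0, "reasons": {}}
        for m in ("translate", "insert", "delete")
    }


def _tally(stats: dict, outcome: MoveOutcome) -> None:
    s = stats[outcome.move]
    s["attempts"] += 1
    if outcome.accepted:
        s["accepted"] += 1
    else:
        s["rejected"] += 1
        s["reasons"][outcome.reason] = s["reasons"].get(outcome.reason, 0) + 1


def run_walker(
    protocol: RunProtocol,
    reservoir: ReservoirModel,
    params: PotentialParameters,
    geometry_model: GasGeometryModel,
    rng: np.random.Generator,
    umbrella: Optional[UmbrellaState] = None,
    initial_config: Optional[AtomicConfiguration] = None,
    refine_every: Optional[int] = None,
) -> WalkerResult:
    """Run one walker; returns its size trajectory and acceptance stats.

    Starts from a single gas-geometry monomer unless an initial
    cluster is supplied.  When ``refine_every`` is set the umbrella
    bias is refined every that many steps (refinement phase); leave it
    None for production with a frozen bias.
    """
    from .fixtures import single_molecule

    if umbrella is None:
        umbrella = UmbrellaState(protocol.n_max)
    if len(umbrella.eta) != protocol.n_max:
        raise ValueError("umbrella table length must equal protocol.n_max")
    window = protocol.window or (1, protocol.n_max)
    if not (1 <= window[0] <= window[1] <= protocol.n_max):
        raise ValueError(f"invalid window {window}")

    if initial_config is None:
        config = single_molecule(geometry_model)
    else:
        config = initial_config.copy()
    topology = assign_hydrogens(config)
    if not (window[0] <= config.n_molecules <= window[1]):
        raise ValueError("initial cluster size outside the sampling window")

    beta = reservoir.beta
    alpha = protocol.alpha if protocol.alpha is not None else 0.1 * beta
    stats = _new_stats()
    sizes, steps_rec = [], []

    for step in range(protocol.steps):
        for _ in range(protocol.moves_per_step):
            if rng.integers(protocol.avbmc_every) == 0:
                if rng.random() < 0.5:
                    outcome = cbmc_insert(
                        config, topology, params, reservoir, geometry_model,
                        protocol.K, alpha, rng, r_cl=protocol.r_cl,
                        bias_table=umbrella.eta, n_max=protocol.n_max,
                        n_bounds=window,
                    )
                else:
                    outcome = avbmc_delete(
                        config, topology, params, reservoir, geometry_model,
                        protocol.K, alpha, rng, r_cl=protocol.r_cl,
                        bias_table=umbrella.eta, n_bounds=window,
                    )
            else:
                outcome = translate_atom(
                    config, topology, params, protocol.max_disp, rng, beta,
                    r_cl=protocol.r_cl,
                )
            _tally(stats, outcome)
            if outcome.accepted:
                config = outcome.new_config
                topology = outcome.new_topology
        if (step + 1) % protocol.stride == 0:
            n = config.n_molecules
            umbrella.record(n)
            sizes.append(n)
            steps_rec.append(step + 1)
        if refine_every and (step + 1) % refine_every == 0 and umbrella.histogram.sum() > 0:
            umbrella = refine_bias(umbrella, reservoir.T)

    return WalkerResult(
        np.asarray(sizes, dtype=np.int64),
        np.asarray(steps_rec, dtype=np.int64),
        stats,
        config,
        topology,
        umbrella,
    )
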