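"""WHAM reconstruction of the nucleation free-energy profile.

Biased cluster-size samples from one or more umbrella windows are
combined by the discrete weighted-histogram self-consistency
equations into the unbiased probability P(n), from which

    dG(n) = -k_B T ln P(n),   anchored dG(1) = 0,

the addition free energy d(dG)(n) = dG(n+1) - dG(n), and the critical
size n* (the barrier top) follow.  Trajectories are chunked into
fixed-length segments, each entering WHAM as its own histogram; the
per-bin statistical uncertainty is the scatter of single-segment
reweighted estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .units import KB_EV

__all__ = [
    "FreeEnergyProfile",
    "WhamError",
    "wham_combine",
    "addition_free_energy",
    "critical_size",
]


class WhamError(RuntimeError):
    pass


@dataclass
class FreeEnergyProfile:
    """dG(n) in units of k_B T over n = 1..n_max, anchored dG(1) = 0."""

    n: np.ndarray
    delta_g: np.ndarray
    uncertainty: np.ndarray
    converged: bool
    iterations: int
    window_free_energies: np.ndarray = field(default=None)

    @property
    def n_max(self) -> int:
        return int(self.n[-1])


def _segment_histograms(samples, biases_kt, n_max, segment_size):
    """Chunk each trajectory into segments; one histogram + bias per segment."""
    hists, etas = [], []
    for traj, eta in zip(samples, biases_kt):
        traj = np.asarray(traj, dtype=np.int64)
        if np.any((traj < 1) | (traj > n_max)):
            raise ValueError("sample outside [1, n_max]")
        for start in range(0, len(traj), segment_size):
            seg = traj[start : start + segment_size]
            if len(seg) == 0:
                continue
            hists.append(np.bincount(seg, minlength=n_max + 1)[1:].astype(float))
            etas.append(np.asarray(eta, dtype=float))
    return np.array(hists), np.array(etas)


def wham_combine(
    samples: Sequence[np.ndarray],
    biases: Sequence[np.ndarray],
    n_max: int,
    T: float,
    tol: float = 1e-7,
    max_iter: int = 30_000,
    segment_size: int = 100_000,
    bias_in_kt: bool = False,
) -> FreeEnergyProfile:
    """Combine biased cluster-size trajectories into an unbiased dG(n).

    ``samples[w]`` is the integer size trajectory of window/walker w,
    ``biases[w]`` its bias table eta(n) (eV by default, k_B T units
    with ``bias_in_kt``).  Iterates the discrete WHAM equations until
    the largest change in any window free-energy constant is below
    ``tol`` (in k_B T) or ``max_iter`` is reached; a non-converged
    result is returned flagged, not silently.
    """
    if len(samples) != len(biases):
        raise ValueError("need one bias table per sample trajectory")
    kT = KB_EV * T
    biases_kt = [
        np.asarray(b, dtype=float) / (1.0 if bias_in_kt else kT) for b in biases
    ]
    for b in biases_kt:
        if len(b) != n_max or not np.all(np.isfinite(b)):
            raise ValueError("each bias table must be finite with length n_max")
    hists, etas = _segment_histograms(samples, biases_kt, n_max, segment_size)
    total = hists.sum(axis=0)
    unvisited = np.flatnonzero(total == 0) + 1
    if len(unvisited):
        raise WhamError(f"bins never visited by any window: n = {unvisited.tolist()}")

    counts = hists.sum(axis=1)  # N_s per segment
    log_h = np.log(np.where(total > 0, total, 1.0))
    f = np.zeros(len(hists))  # -ln of segment normalizations, in kT
    converged = False
    iterations = 0
    log_counts = np.log(counts)
    for iterations in range(1, max_iter + 1):
        # log denominator per bin: ln sum_s N_s exp(f_s - eta_s(n))
        log_den = logsumexp(log_counts[:, None] + f[:, None] - etas, axis=0)
        log_p = log_h - log_den
        f_new = -logsumexp(log_p[None, :] - etas, axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge to {tol} within {max_iter} iterations "
            f"(last change {delta:.3e} kT)",
            RuntimeWarning,
        )

    log_den = logsumexp(log_counts[:, None] + f[:, None] - etas, axis=0)
    log_p = log_h - log_den
    delta_g = -(log_p - log_p[0])

    # single-segment reweighted estimates for the per-bin scatter
    seg_dg = np.full((len(hists), n_max), np.nan)
    for s in range(len(hists)):
        with np.errstate(divide="ignore"):
            lp = np.where(hists[s] > 0, np.log(np.where(hists[s] > 0, hists[s], 1.0)) + etas[s], np.nan)
        if hists[s][0] > 0:
            seg_dg[s] = -(lp - lp[0])
    n_cover = np.sum(~np.isnan(seg_dg), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scatter = np.nanstd(seg_dg, axis=0)
    uncertainty = np.where(n_cover > 1, scatter / np.sqrt(np.maximum(n_cover, 1)), 0.0)

    return FreeEnergyProfile(
        n=np.arange(1, n_max + 1),
        delta_g=delta_g,
        uncertainty=uncertainty,
        converged=converged,
        iterations=iterations,
        window_free_energies=f,
    )


def addition_free_energy(profile: FreeEnergyProfile) -> np.ndarray:
    """Forward difference d(dG)(n) = dG(n+1) - dG(n), length n_max - 1."""
    if len(profile.delta_g) < 2:
        raise ValueError("profile must cover at least two sizes")
    return np.diff(profile.delta_g)


def critical_size(profile: FreeEnergyProfile) -> int:
    """n* = argmax of dG(n), ties broken toward smaller n.

    Warns when the maximum sits at the n_max boundary: the barrier is
    then not contained in the sampled range.
    """
    n_star = int(profile.n[int(np.argmax(profile.delta_g))])
    if n_star == profile.n_max:
        warnings.warn(
            "free-energy maximum at the n_max boundary; barrier not contained",
            RuntimeWarning,
        )
    return n_star
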