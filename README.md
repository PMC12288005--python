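# ebavbmc

Energy-biased aggregation-volume-bias Monte Carlo (EB-AVBMC) for
vapor–liquid nucleation of a **dissociative, all-atom water model** in
the Vashishta potential form, with self-adaptive umbrella sampling,
WHAM free-energy reconstruction, and classical-nucleation-theory (CNT)
analysis of the resulting profiles.

## Who this is for

Molecular simulators studying water (or other associating-fluid)
nucleation who want cluster free energies ΔG(n) from a *reactive*
force field — one in which O–H bonds can stretch, break and re-form —
rather than a rigid water model. Standard grand-canonical cluster
Monte Carlo breaks down for such models in two places: monomer
exchanges must account for the monomer's internal (intramolecular)
energy, and deletion must not tear apart a transiently dissociated
molecule. This package implements both corrections.

## The method

A single physical cluster (Stillinger criterion: molecules are
neighbors when their oxygens are within r_cl = 4 Å) exchanges water
monomers with an ideal-gas reservoir of number density ρ_v. Insertions
are configurational-bias moves: K = 50 trial monomers grown from
gas-phase geometry Gaussians inside the bonded sphere of an
energy-biased target molecule (P ∝ e^(αU_i), α = 0.1β), one selected
by its Rosenbluth factor P_sel = e^(−βU_k)/W. Deletions pick an
energy-biased target and neighbor (P ∝ e^(βU)), constrained so that
only intact molecules — both assigned hydrogens within a 2 Å bond
length and closest to their oxygen — can leave. The acceptance rules

    insert:  min[1, (P_remove/P_insert) · (1/(K·P_sel)) · e^(−β(ΔU − U_intra − μ + Δη))]
    delete:  min[1, (P_insert/P_remove) · (K·P_sel) · e^(−β(ΔU + U_intra + μ + Δη))]

subtract/add the monomer's intramolecular energy U_intra so that only
interaction energy governs the exchange, and satisfy detailed balance
exactly (verified numerically in the test suite). Hydrogen→oxygen
assignment is recomputed after every accepted move by a deterministic
capacity-2 nearest-oxygen matching, so Grotthuss-style proton hops are
just bookkeeping updates.

Cluster size n is the reaction coordinate: an iteratively refined
umbrella bias η(n) flattens the nucleation barrier, WHAM combines the
biased histograms into ΔG(n), and the addition free energy
δΔG(n) = ΔG(n+1) − ΔG(n) is fitted to CNT,

    δΔG(n) = Δμ + γ(36π/ρ_l²)^(1/3) ((n+1)^(2/3) − n^(2/3)),

whose slope yields the surface tension γ and whose intercept
b = Δμ = −k_BT·ln(ρ_v/ρ_eq) yields the saturated gas density.

## Worked example

The synthetic pipeline end to end — build a CNT-shaped profile
(slope 8.26 k_BT, intercept −2.00 k_BT), sample it through two umbrella
windows, reconstruct with WHAM and fit:

```python
import numpy as np
from ebavbmc import cnt_fit, critical_size, reference_slope, wham_combine
from ebavbmc.cnt import cnt_shape_factor
from ebavbmc.fixtures import synth_umbrella_data
from ebavbmc.free_energy import addition_free_energy
from ebavbmc.units import KB_EV

kT = KB_EV * 298.15
print(f"reference slope: {reference_slope(71.97, 0.997, 298.15):.3f} kT")

n = np.arange(1, 31)
ddg_in = -2.00 + 8.26 * cnt_shape_factor(n[:-1])
dg_in = np.concatenate([[0.0], np.cumsum(ddg_in)])

rng = np.random.default_rng(1)
biases_kt = [np.zeros(30), -dg_in]
samples = synth_umbrella_data(dg_in, biases_kt, 500_000, rng)
profile = wham_combine(samples, [b * kT for b in biases_kt], 30, 298.15)
print(f"WHAM rms error: {np.sqrt(np.mean((profile.delta_g - dg_in)**2)):.3f} kT")

fit = cnt_fit(n[:-1], addition_free_energy(profile), n_min=9)
print(f"slope m = {fit.slope:.2f} +- {fit.slope_stderr:.2f} kT")
print(f"intercept b = {fit.intercept:.2f} +- {fit.intercept_stderr:.2f} kT")
print(f"surface tension: {fit.surface_tension(0.997, 298.15):.1f} mN/m")
print(f"critical cluster size n* = {critical_size(profile)}")
```

prints

```
reference slope: 8.166 kT
WHAM rms error: 0.009 kT
slope m = 8.21 +- 0.12 kT
intercept b = -1.99 +- 0.03 kT
surface tension: 72.4 mN/m
critical cluster size n* = 21
```

Read: the unit machinery reproduces the planar-interface reference
slope (8.166 k_BT from experimental γ = 71.97 mN/m and
ρ_l = 0.997 g/cm³); WHAM recovers the known profile to ~0.01 k_BT; the
CNT fit recovers the generating slope/intercept within its standard
errors and converts them into a surface tension and (through
ρ_eq = ρ_v·e^(b/kT)) a saturated gas density; the barrier top of this
profile sits at n* = 21 molecules.

To run actual simulations, the `ebavbmc` CLI wraps the same library:

```bash
ebavbmc fixtures --out-dir fx          # example parameter file + inputs
ebavbmc run run.yaml --out-prefix w0   # one walker: trajectory + bias + summary
ebavbmc refine w0.bias.json            # one self-adaptive bias refinement
ebavbmc wham w0.traj:w0.bias.json --n-max 30 --out profile.dat
ebavbmc analyze profile.dat            # CNT report (m, b, gamma, rho_eq, n*)
```

The shipped parameter file is an illustrative Vashishta-form water set
(monomer at 0.960 Å / 104.4°, dimer bound by ~0.25 eV) for exercising
the pipeline; production work should load its own parameter file
(documented flat key=value schema, strict parsing).

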