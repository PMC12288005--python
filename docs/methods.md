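# Methods

## The physical model

The simulated object is a single cluster of water molecules exchanging
monomers with a fictitious ideal-gas reservoir — the grand-canonical
cluster ensemble. Because the cluster is an open (non-periodic) set of
atoms and the reservoir enters only through its number density ρ_v, the
simulation has no box and no volume dependence. Cluster membership uses
the Stillinger criterion: molecules are neighbors when their oxygens are
within r_cl (default 4 Å), and the configuration is constrained to stay
a single connected cluster, which keeps the cluster size n — the
reaction coordinate — well defined.

Interactions are the Vashishta form: pairwise steric repulsion
H_ij/r^η_ij, screened Coulomb Z_iZ_j e^(−r/r_1s)/r, screened
charge–dipole −D_ij e^(−r/r_4s)/r⁴ and van der Waals −W_ij/r⁶ terms,
truncated at r_c with a linear shift so both the energy and its first
derivative vanish at the cutoff; plus a three-body stretch×bend term
B·exp(ξ/(r_ij−r_0) + ξ/(r_ik−r_0))·(cosθ − cosθ⁰)² applied to every
H–O–H triple whose two O–H distances are below r_0. Triples are
selected purely geometrically, never from the bookkept bond topology:
that is what makes the model dissociative — a hydrogen can drift from
one oxygen toward another and the energy follows continuously.

Units: Å, eV, K; k_B = 8.617333262×10⁻⁵ eV/K; Coulomb prefactor
14.399645 eV·Å for charges in units of e; water molar mass 18.02 g/mol
(this rounding reproduces the standard planar-interface slope of
8.166 k_BT from γ = 71.97 mN/m and ρ_l = 0.997 g/cm³ at 298.15 K
exactly to the printed precision; 18.015 gives 8.164).

## Bond topology in a dissociative model

Molecule identity is bookkeeping: every hydrogen is assigned to exactly
one oxygen and every oxygen holds exactly two hydrogens. The assignment
is the fixed point of iterative nearest-oxygen reassignment,
implemented as capacity-2 deferred acceptance (hydrogens propose to
oxygens in distance order; an oversubscribed oxygen keeps its two
nearest proposers). With strict distance preferences the fixed point is
unique and independent of atom input order; exact ties are broken by
lower atom index. The assignment is recomputed after every accepted
move, so proton transfer appears as a hydrogen changing owner.

A molecule may be deleted only when it is an unambiguous structural
unit: the two hydrogens nearest (system-wide) to its oxygen are exactly
its assigned pair, and both lie within a 2 Å bond length. This blocks
the deletion of transiently dissociated molecules, whose removal would
not correspond to taking one water monomer out of the cluster.

## Monte Carlo moves

Three trial moves, mixed 1 swap : 10 translations, with insertions and
deletions attempted in equal proportion:

- **Translation.** Uniform molecule, uniform atom of it, each
  coordinate displaced uniformly within ±0.05 Å (default); Metropolis
  acceptance min(1, e^(−βΔU)). Proposals that fragment the Stillinger
  cluster are rejected before any energy evaluation.
- **Insertion (configurational bias).** A target molecule is chosen
  with energy-biased probability e^(αU_i)/Σe^(αU_j) over the molecules'
  intermolecular energies U_i (α = 0.1β by default), which steers
  insertions toward weakly bound surface molecules. K trial monomers
  (default 50) are grown in the target's bonded sphere (V_in =
  4πr_cl³/3): bond lengths and the H–O–H angle from Gaussians fitted to
  the gas-phase monomer distribution, uniform orientation, oxygen
  uniform in the sphere. One trial is selected with Rosenbluth
  probability P_sel = e^(−βU_k)/W, W = Σ_k e^(−βU_k), with U_k the
  trial's interaction energy with the cluster.
- **Deletion.** A target is chosen with weight e^(βU_i); one of its
  bonded-region neighbors is chosen with weight e^(βU_j) (a
  deterministic highest-energy variant is available behind a flag);
  the move aborts if the victim fails the dissociation constraint or
  its removal would fragment the cluster. The reverse-insertion
  Rosenbluth weight W_old combines the actual monomer with K−1 freshly
  grown ghost trials.

The acceptance ratios are, writing Δη for the umbrella-bias difference
and μ for the reservoir chemical potential (βμ = ln ρ_vΛ³ with Λ³ fixed
at 1 Å³ — only the consistent ±μ pairing between the two rules is
observable):

    insert:  min[1, (P_remove/P_insert) · (1/(K·P_sel)) · e^(−β(ΔU − U_intra − μ + Δη))]
    delete:  min[1, (P_insert/P_remove) · (K·P_sel^old)  · e^(−β(ΔU + U_intra + μ + Δη))]

with P_insert = P_target·(1/V_in), P_remove = P_target·P_neighbor, each
evaluated in the *destination* state of its move. The correction for
the Rosenbluth selection enters inversely on the forward proposal and
directly on the reverse one; this is the unique pairing for which the
insertion and deletion transition densities satisfy detailed balance
with respect to the grand-canonical cluster measure. The test suite
verifies this numerically: the Monte-Carlo-estimated transition-density
ratio for a pinned monomer equals e^(−β(ΔU − U_intra − μ + Δη)) within
three standard errors, in both a weakly and a strongly interacting
configuration.

Because the model is all-atom, the monomer's internal (intramolecular)
energy U_intra — its three pair terms plus its own H–O–H triple — is
subtracted from ΔU on insertion and added on deletion. Combined with
growing monomers from the gas-phase geometry distribution, this makes
the reservoir's internal-coordinate measure the generation distribution
itself: a monomer costs only its interaction energy when it enters the
cluster, and its internal Boltzmann weight never biases the exchange.

## Gas-phase geometry calibration

The generation Gaussians (μ_r, σ_r, μ_θ, σ_θ) are produced by Metropolis
sampling of a single isolated molecule under the loaded potential at
the run temperature and fitting Gaussians to the bond-length and angle
marginals. For the shipped example parameter set at 298.15 K this gives
μ_r ≈ 0.977 Å, σ_r ≈ 0.045 Å, μ_θ ≈ 105.6°, σ_θ ≈ 6.0°. The calibration
is validated against an equipartition oracle (marginal variances from
the inverse internal-coordinate Hessian at the minimum). The values are
ordinary config keys and can be overridden.

## Umbrella sampling and WHAM

A bias table η(n) over integer cluster sizes is added to the swap
acceptance (Δη = η(n_new) − η(n_old)). Self-adaptive refinement pushes
sampling toward flat: visited bins get η ← η + k_BT·ln(h/h̄) (h̄ the mean
count over visited bins), unvisited bins inherit the nearest visited
update, the table is re-anchored to η(1) = 0 and the histogram reset.
The fixed point of this iteration under p(n) ∝ e^(−(ΔG+η)/k_BT) is
η = −ΔG + const, i.e. flat sampling; the tests verify convergence to
within 0.2 k_BT per bin on a known profile. Overlapping windows in n
are supported (moves leaving a walker's window are rejected); walkers
are embarrassingly parallel with independent seeds.

Biased histograms are combined by discrete WHAM: trajectories are
chunked into segments (default 100 000 points) that each enter as their
own histogram, and the self-consistency equations are iterated until
the largest change in any segment free-energy constant is below 1e−7
k_BT (at most 30 000 iterations; a non-converged result is returned
flagged, never silently). ΔG(n) = −k_BT ln P(n) is anchored at the
monomer, ΔG(1) = 0. Per-bin uncertainty is the scatter of
single-segment reweighted estimates. Single-window/zero-bias input
degenerates exactly to Boltzmann inversion, and per-window constant
bias offsets leave the profile unchanged (gauge invariance) — both are
asserted in the tests.

## CNT analysis

The addition free energy δΔG(n) = ΔG(n+1) − ΔG(n) is fitted by ordinary
least squares against x(n) = (n+1)^(2/3) − n^(2/3) for n > 9 (the
small-cluster shoulder below n ≈ 8–10 is excluded; the threshold is a
flag). The slope measures the surface tension through
m = γ(36π/ρ_l²)^(1/3)/k_BT with ρ_l a molecular number density (mass
densities converted via 18.02 g/mol); the intercept is
b = Δμ = −k_BT ln(ρ_v/ρ_eq), inverted for the saturated gas density
ρ_eq = ρ_v e^(b/k_BT). Both conversions are validated against
independent single-unit-system recomputations and are exact inverses to
better than 1e−10. The critical size n* is the argmax of ΔG(n), ties
toward smaller n, with a warning when the maximum sits on the n_max
boundary (barrier not contained).

## Synthetic data and the example parameter set

The fixtures module builds every test input programmatically: random
single-cluster configurations (oxygens by rejection sampling inside the
Stillinger radius with a minimum O–O spacing, intact monomers at
0.96 Å / 104.5°), exact biased multinomial samples of a known ΔG(n) for
WHAM validation, and the gas-geometry calibration above.

The shipped parameter file (`data/water_example.params`) is an
illustrative Vashishta-form set tuned so that the isolated monomer
relaxes to O–H = 0.960 Å, H–O–H = 104.4° (E = −3.157 eV) and the dimer
is bound by ≈0.25 eV at O–O ≈ 2.45 Å. It is *not* an optimized
literature parameterization: its dimer is slightly overbound and short
compared to real water, and no claim is made that its free-energy
profile matches published water results. Everything the tests assert —
energy bookkeeping, detailed balance, topology determinism, WHAM and
CNT recovery — is parameter-agnostic; quantitative liquid–vapor
properties require loading a production parameter file through the same
documented format.

What the synthetic tests do not show: agreement of the example model's
ΔG(n) with real water, finite-size effects at large caps, or the
statistical quality reachable with production-scale sampling
(~128 walkers × 1.5×10⁷ steps); the shipped runs are scaled down to
seconds-to-minutes problem sizes (tens of steps × tens of moves,
cluster caps of 5–30, 10⁵–10⁶ synthetic samples per window) as the
package's own test-scale choice.

## Numerical choices and edge cases

- All Boltzmann-weighted selections are computed with max-shifted
  exponents (logsumexp), so arbitrarily large |U| cannot overflow.
- A swap whose K trials all overlap existing atoms has zero Rosenbluth
  weight and is rejected and counted separately.
- Pair distances below 1e−6 Å raise an invalid-geometry error rather
  than returning a huge number.
- The translation move checks cluster connectivity before energies
  (only needed when the moved atom is an oxygen: adjacency is O–O).
- Distance ties in the topology assignment break toward lower atom
  index; the deletion bond-length threshold (2.0 Å), r_cl (4.0 Å), K
  (50), α (0.1β) and the move mix are all config keys.
- Never deleting the last molecule keeps n ≥ 1, matching the ΔG(1) = 0
  anchor.

## Known limitations

- `update_after_move` recomputes the full assignment rather than
  patching it; at production cluster sizes (≤ 70 molecules) this is
  negligible next to the energy evaluation.
- WHAM uncertainties come from segment scatter, not from a covariance
  treatment; across-walker scatter is available by passing walkers as
  separate trajectories.
- The deletion neighbor rule implements stochastic Boltzmann selection
  by default; the deterministic highest-energy variant changes the
  proposal distribution and is provided for comparison only.
- No forces are computed (Monte Carlo only), no Ewald summation
  (screened Coulomb per the potential form), no periodic systems, and
  no intercluster transfer or rigid-molecule moves.
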