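"""Trial moves: selection biases, monomer growth, swap acceptance structure."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import logsumexp

from ebavbmc.cluster import bonded_region_members
from ebavbmc.fixtures import _monomer_local, single_molecule
from ebavbmc.moves import (
    GasGeometryModel,
    ReservoirModel,
    _random_rotation,
    _trial_interaction_energy,
    avbmc_delete,
    cbmc_insert,
    deletion_log_acceptance,
    grow_monomer,
    insertion_log_acceptance,
    rosenbluth_probabilities,
    select_deletion_neighbor,
    select_insertion_target,
    translate_atom,
    trial_selection_probability,
)
from ebavbmc.potential import AtomicConfiguration, all_molecule_interaction_energies
from ebavbmc.topology import assign_hydrogens

from conftest import random_cluster


def test_chemical_potential_convention():
    res = ReservoirModel(rho_v=6e-7, T=298.15)
    kT = 8.617333262e-5 * 298.15
    assert res.mu == pytest.approx(kT * math.log(6e-7), rel=1e-12)
    assert res.beta == pytest.approx(1 / kT, rel=1e-12)


class TestEnergyBiasedSelection:
    def test_equal_energies_is_uniform(self, rng):
        u = np.zeros(7)
        idx, p = select_insertion_target(u, 3.0, rng)
        assert p == pytest.approx(1 / 7)

    def test_zero_alpha_is_uniform(self, rng):
        u = rng.normal(size=5)
        _, p = select_insertion_target(u, 0.0, rng)
        assert p == pytest.approx(1 / 5)

    def test_two_molecule_closed_form(self, rng):
        # alpha (U2 - U1) = 1: probabilities (1, e)/(1 + e)
        u = np.array([0.0, 1.0])
        seen = {}
        for _ in range(50):
            idx, p = select_insertion_target(u, 1.0, rng)
            seen[idx] = p
        e = math.e
        assert seen[1] == pytest.approx(e / (1 + e), rel=1e-12)
        if 0 in seen:
            assert seen[0] == pytest.approx(1 / (1 + e), rel=1e-12)

    def test_neighbor_selection_shapes(self, rng):
        _, p = select_deletion_neighbor(np.array([1.23]), 5.0, rng)
        assert p == 1.0
        _, p = select_deletion_neighbor(np.zeros(4), 5.0, rng)
        assert p == pytest.approx(0.25)
        # energies (0, kT): probabilities (1, e)/(1 + e)
        beta = 2.0
        idx, p = select_deletion_neighbor(np.array([0.0, 0.5]), beta, rng, deterministic=True)
        assert idx == 1 and p == pytest.approx(math.e / (1 + math.e), rel=1e-12)

    def test_overflow_guarded(self, rng):
        u = np.array([0.0, 5000.0])
        idx, p = select_insertion_target(u, 1.0, rng)
        assert idx == 1 and p == pytest.approx(1.0)


class TestRosenbluth:
    def test_probabilities_normalize(self, rng):
        u = rng.normal(scale=3.0, size=50)
        p = rosenbluth_probabilities(u, 38.9)
        assert p.sum() == pytest.approx(1.0, rel=1e-12)

    def test_single_trial_probability_is_one(self):
        assert trial_selection_probability(np.array([-3.7]), 0, 38.9) == pytest.approx(1.0)

    def test_scaling_by_trial_count(self, rng):
        u = np.zeros(10)
        assert trial_selection_probability(u, 4, 1.0) == pytest.approx(1 / 100)


class TestGrowMonomer:
    def test_degenerate_gaussians_give_exact_geometry(self, rng):
        gm = GasGeometryModel(0.96, 0.0, 104.5, 0.0)
        for _ in range(10):
            mono = grow_monomer(gm, np.zeros(3), 4.0, rng)
            r1 = np.linalg.norm(mono[1] - mono[0])
            r2 = np.linalg.norm(mono[2] - mono[0])
            cos = np.dot(mono[1] - mono[0], mono[2] - mono[0]) / (r1 * r2)
            assert r1 == pytest.approx(0.96, abs=1e-12)
            assert r2 == pytest.approx(0.96, abs=1e-12)
            assert math.degrees(math.acos(cos)) == pytest.approx(104.5, abs=1e-9)

    def test_placement_uniform_in_sphere(self, rng):
        gm = GasGeometryModel(0.96, 0.0, 104.5, 0.0)
        center = np.array([1.0, -2.0, 0.5])
        r = np.array([
            np.linalg.norm(grow_monomer(gm, center, 4.0, rng)[0] - center)
            for _ in range(20000)
        ])
        # CDF of the radial coordinate for uniform-in-sphere: (r/R)^3
        res = sps.kstest(r, lambda x: (x / 4.0) ** 3)
        assert res.pvalue > 0.01

    def test_bond_lengths_match_gaussian(self, rng):
        gm = GasGeometryModel(0.97, 0.03, 104.5, 0.0)
        r1 = np.array([
            np.linalg.norm((m := grow_monomer(gm, np.zeros(3), 4.0, rng))[1] - m[0])
            for _ in range(5000)
        ])
        res = sps.kstest(r1, sps.norm(0.97, 0.03).cdf)
        assert res.pvalue > 0.01

    def test_rotations_are_uniform(self, rng):
        # the O-H1 direction should be uniform on the sphere: its z
        # component uniform on [-1, 1]
        gm = GasGeometryModel(1.0, 0.0, 104.5, 0.0)
        z = np.array([
            ((m := grow_monomer(gm, np.zeros(3), 4.0, rng))[1] - m[0])[2]
            for _ in range(20000)
        ])
        assert sps.kstest(z, sps.uniform(-1, 2).cdf).pvalue > 0.01


class TestTranslate:
    def test_bookkeeping_and_validity(self, water_params, gas_model, rng):
        config, topo = random_cluster(4, rng)
        beta = 1 / (8.617333262e-5 * 298.15)
        accepted = rejected = 0
        for _ in range(300):
            out = translate_atom(config, topo, water_params, 0.05, rng, beta)
            assert out.move == "translate"
            if out.accepted:
                accepted += 1
                config, topo = out.new_config, out.new_topology
                topo.validate()
            else:
                rejected += 1
                assert out.reason in {"metropolis", "fragmented", "overlap"}
        assert accepted + rejected == 300
        assert accepted > 0

    def test_fragmenting_translation_rejected(self, water_params, rng):
        # two molecules at 3.9 A: moving one oxygen 0.3 A outward breaks
        # the Stillinger criterion, so such proposals must never be accepted
        species = np.array(["O", "H", "H"] * 2)
        m = _monomer_local(0.96, 0.96, 104.5)
        pos = np.vstack([m, m + np.array([3.95, 0, 0])])
        config = AtomicConfiguration(species, pos)
        topo = assign_hydrogens(config)
        beta = 1 / (8.617333262e-5 * 298.15)
        fragmented = 0
        for _ in range(200):
            out = translate_atom(config, topo, water_params, 0.4, rng, beta)
            if out.accepted:
                state_ok = np.linalg.norm(
                    out.new_config.positions[0] - out.new_config.positions[3]
                ) <= 4.0
                assert state_ok
            elif out.reason == "fragmented":
                fragmented += 1
        assert fragmented > 0


def _pinned_swap_states(water_params, gas_model, rng, want_strong=False):
    """A dimer x, a pinned monomer within reach of only molecule 1, and x+monomer."""
    m1 = _monomer_local(0.96, 0.96, 104.5)
    m2 = _monomer_local(0.96, 0.96, 104.5) @ _random_rotation(rng).T + np.array([3.5, 0, 0])
    x = AtomicConfiguration(np.array(["O", "H", "H"] * 2), np.vstack([m1, m2]))
    topo_x = assign_hydrogens(x)
    while True:
        omega = grow_monomer(gas_model, x.positions[3], 4.0, rng)
        d2 = np.linalg.norm(omega[0] - x.positions[3])
        d1 = np.linalg.norm(omega[0] - x.positions[0])
        if not (d2 <= 4.0 and d1 > 4.0 and 2.4 < d2 < 3.6):
            continue
        u_int = _trial_interaction_energy(x, water_params, omega)[0]
        if math.isfinite(u_int) and (u_int < -0.15 if want_strong else -0.05 < u_int < 0.05):
            break
    return x, topo_x, omega


def test_insert_delete_roundtrip_log_acceptances_cancel(water_params, gas_model, rng):
    # with K = 1 there is no Rosenbluth randomness: the raw log
    # acceptance ratios of the forward insertion and the exact reverse
    # deletion must cancel identically
    res = ReservoirModel(rho_v=6e-7, T=298.15)
    beta, alpha = res.beta, 0.1 * res.beta
    x, topo_x, omega = _pinned_swap_states(water_params, gas_model, rng)
    u_mol = all_molecule_interaction_energies(x, topo_x, water_params)
    p_ti = float(np.exp(alpha * u_mol[1] - logsumexp(alpha * u_mol)))
    ev_i = insertion_log_acceptance(x, topo_x, water_params, res, 1, omega, p_ti, 1.0, 1, 4.0)

    xp, topo_xp = ev_i.new_config, ev_i.new_topology
    u_mol_p = all_molecule_interaction_energies(xp, topo_xp, water_params)
    p_td = float(np.exp(res.beta * u_mol_p[1] - logsumexp(res.beta * u_mol_p)))
    neighbors, _ = bonded_region_members(xp, topo_xp, 1, 4.0)
    lw = res.beta * u_mol_p[neighbors]
    pos = int(np.flatnonzero(neighbors == 2)[0])
    p_sd = float(np.exp(lw[pos] - logsumexp(lw)))
    ev_d = deletion_log_acceptance(
        xp, topo_xp, water_params, res, gas_model, 1, 2, p_td, p_sd, 1, alpha, rng, 4.0
    )
    assert ev_i.log_acceptance + ev_d.log_acceptance == pytest.approx(0.0, abs=1e-9)
    assert ev_i.d_u == pytest.approx(-ev_d.d_u, rel=1e-9)
    assert ev_i.u_intra == pytest.approx(ev_d.u_intra, rel=1e-9)
    # P_insert/P_remove are evaluated in each move's destination state,
    # so the two moves see identical values
    assert ev_i.log_p_insert == pytest.approx(ev_d.log_p_insert, rel=1e-12)
    assert ev_i.log_p_remove == pytest.approx(ev_d.log_p_remove, rel=1e-12)


class TestSwapMoveGuards:
    def test_insertion_capped_at_n_max(self, water_params, gas_model, reservoir, rng):
        config, topo = random_cluster(3, rng)
        out = cbmc_insert(
            config, topo, water_params, reservoir, gas_model, 5, 0.1 * reservoir.beta,
            rng, n_max=3,
        )
        assert not out.accepted and out.reason == "cap"

    def test_never_delete_last_molecule(self, water_params, gas_model, reservoir, rng):
        config = single_molecule()
        topo = assign_hydrogens(config)
        out = avbmc_delete(
            config, topo, water_params, reservoir, gas_model, 5, 0.1 * reservoir.beta, rng
        )
        assert not out.accepted and out.reason == "floor"

    def test_dissociated_molecule_never_deleted(self, water_params, gas_model, reservoir, rng):
        # molecule 0 has an assigned H at 2.3 A: every deletion attempt
        # that lands on it must be rejected before any trial evaluation
        species = np.array(["O", "H", "H"] * 2)
        pos = np.array(
            [[0, 0, 0], [0.96, 0, 0], [0, 2.3, 0],
             [3.2, 0, 0], [3.2, 0.96, 0], [3.2, -0.96, 0]]
        )
        config = AtomicConfiguration(species, pos)
        topo = assign_hydrogens(config)
        reasons = set()
        for _ in range(100):
            out = avbmc_delete(
                config, topo, water_params, reservoir, gas_model, 5,
                0.1 * reservoir.beta, rng,
            )
            if out.accepted:
                # only the intact molecule 1 may ever go
                assert out.new_config.n_molecules == 1
                assert np.allclose(out.new_config.positions[0], [0, 0, 0])
            else:
                reasons.add(out.reason)
        assert "dissociated" in reasons
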