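from itertools import combinations

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from ionspike.lattice import (EnergyParams, MCState, MoveMix, count_open,
                              membrane_current, set_voltage, total_energy)
from reference_mc import ref_run, ref_total_energy

SENSORS_ONLY = MoveMix(sensor=1.0, inact=0.0, lipid=0.0, translate=0.0, rotate=0.0)
LIPIDS_ONLY = MoveMix(sensor=0.0, inact=0.0, lipid=1.0, translate=0.0, rotate=0.0)
ALL_MOVES = MoveMix(sensor=0.25, inact=0.05, lipid=0.4, translate=0.2, rotate=0.1)


def tiny_lipid_state(lat, params, temperature_c=30.0):
    """Hand-built channel-free state on an arbitrary small lattice."""
    st = MCState.create(L=8, n_na=0, n_k=0, params=params, rng_seed=0)
    st.lat = np.asarray(lat, dtype=np.int8)
    st.owner = np.full(st.lat.shape, -1, dtype=np.int64)
    st.temperature_c = temperature_c
    return st


class TestEnergy:
    def test_uniform_lipid_lattice_energy(self):
        """All-like lipids on the torus: one −J_ll per bond, 2·L² bonds."""
        p = EnergyParams()
        st = MCState.create(L=16, n_na=0, n_k=0, params=p, frac_unsat=0.0,
                            rng_seed=0)
        assert st.total_energy() == pytest.approx(-p.j_ll * 2 * 16 * 16)

    def test_sensor_flip_is_free_at_half_activation(self):
        p = EnergyParams(a=0.0, j_cl_open_unsat=0.0, j_cl_closed_sat=0.0,
                         inactivation=False)
        st = MCState.create(L=12, n_na=1, n_k=0, params=p, vm=p.v_half_na,
                            rng_seed=1)
        e0 = st.total_energy()
        st.ch_sens[0, 2] = 1
        assert st.total_energy() == pytest.approx(e0, abs=1e-12)

    def test_energy_matches_independent_reference(self, rng):
        p = EnergyParams(a=0.7, j_cl_open_unsat=-0.8, j_cl_closed_sat=-0.3)
        st = MCState.create(L=12, n_na=4, n_k=3, params=p, vm=-30.0, rng_seed=5)
        st.ch_sens[:] = rng.integers(0, 2, st.ch_sens.shape)
        st.ch_inact[:4] = rng.integers(0, 2, 4)
        assert st.total_energy() == pytest.approx(ref_total_energy(st), abs=1e-9)

    def test_translation_invariance_under_periodic_shift(self):
        p = EnergyParams(a=0.7, j_cl_open_unsat=-0.8)
        st = MCState.create(L=12, n_na=3, n_k=2, params=p, vm=-30.0, rng_seed=2)
        e0 = st.total_energy()
        st.lat = np.roll(st.lat, (3, 5), axis=(0, 1))
        st.owner = np.roll(st.owner, (3, 5), axis=(0, 1))
        st.ch_x = (st.ch_x + 3) % 12
        st.ch_y = (st.ch_y + 5) % 12
        assert st.total_energy() == pytest.approx(e0, abs=1e-9)


class TestMetropolisAgainstReference:
    def test_kernel_replays_identically_to_full_recompute_oracle(self):
        """Every move's locally computed ΔE agrees with a from-scratch
        Hamiltonian difference: replaying an identical uniform-draw stream
        through the kernel and a plain-Python reference lands in the exact
        same state."""
        p = EnergyParams(a=0.5, j_cl_open_unsat=-0.9, j_cl_closed_sat=-0.3,
                         j_ll=0.88)
        st = MCState.create(L=12, n_na=3, n_k=2, params=p, temperature_c=22.0,
                            vm=-35.0, rng_seed=7)
        ref = st.copy()
        buf = np.random.default_rng(42).uniform(size=60_000)
        st.run_moves(6000, ALL_MOVES, rand_buf=buf)
        ref_run(ref, 6000, ALL_MOVES, buf.tolist())
        for attr in ("lat", "owner", "ch_sens", "ch_inact", "ch_x", "ch_y"):
            assert np.array_equal(getattr(st, attr), getattr(ref, attr)), attr

    def test_overlapping_translation_always_rejected(self):
        """A channel can never move onto another channel's footprint."""
        p = EnergyParams()
        st = MCState.create(L=16, n_na=6, n_k=6, params=p, rng_seed=3)
        mix = MoveMix(sensor=0.0, inact=0.0, lipid=0.0, translate=1.0, rotate=0.0)
        st.run_moves(50_000, mix)
        # footprints still disjoint: every channel owns exactly 4 sites
        counts = np.bincount(st.owner[st.owner >= 0], minlength=12)
        assert np.all(counts == 4)


class TestBoltzmannEquilibrium:
    def test_two_by_two_lipid_histogram_matches_enumeration(self):
        """Kawasaki dynamics on an enumerable 2×2 mixture reproduces the
        exact Boltzmann weights (chi-square, α=0.01)."""
        p = EnergyParams(j_ll=0.6)
        st = tiny_lipid_state([[0, 0], [1, 1]], p)

        def energy_of(cfg):
            l = np.array(cfg).reshape(2, 2)
            e = 0.0
            for x in range(2):
                for y in range(2):
                    for nx, ny in (((x + 1) % 2, y), (x, (y + 1) % 2)):
                        if l[nx, ny] == l[x, y]:
                            e -= p.j_ll
            return e

        configs = []
        for pos in combinations(range(4), 2):
            cfg = [0] * 4
            for q in pos:
                cfg[q] = 1
            configs.append(tuple(cfg))
        w = np.array([np.exp(-energy_of(c) * st.beta_rel) for c in configs])
        w /= w.sum()
        counts = dict.fromkeys(configs, 0)
        n_samp = 20_000
        for _ in range(n_samp):
            st.run_moves(200, LIPIDS_ONLY)
            counts[tuple(st.lat.flatten())] += 1
        obs = np.array([counts[c] for c in configs])
        chi2 = float((((obs - w * n_samp) ** 2) / (w * n_samp)).sum())
        assert chi2 < chi2_dist.ppf(0.99, len(configs) - 1)

    def test_sensor_activation_matches_two_state_sigmoid(self):
        """Decoupled sensors (a=0, J_cl=0): long-run activation equals the
        Boltzmann two-state probability, and open fraction equals p⁴."""
        p = EnergyParams(a=0.0, j_cl_open_unsat=0.0, j_cl_closed_sat=0.0,
                         inactivation=False)
        vm = -36.0
        st = MCState.create(L=16, n_na=4, n_k=4, params=p, vm=vm, rng_seed=3)
        st.run_moves(40_000, SENSORS_ONLY)  # burn-in
        acts, opens = [], []
        n_samp = 600
        for _ in range(n_samp):
            st.run_moves(2000, SENSORS_ONLY)
            acts.append(st.ch_sens.mean())
            oc = st.count_open()
            opens.append(oc["Na"] + oc["K"])

        def p_act(v_half):
            de = -p.q_s * (vm - v_half) / p.kt_mv
            return 1.0 / (1.0 + np.exp(de * st.beta_rel))

        p_na, p_k = p_act(p.v_half_na), p_act(p.v_half_k)
        expect_act = 0.5 * (p_na + p_k)
        expect_open = 4 * p_na ** 4 + 4 * p_k ** 4
        # 3 sigma bands using an effective sample size that discounts the
        # autocorrelation of consecutive snapshots
        n_eff = n_samp / 10
        se_act = np.std(acts) / np.sqrt(n_eff)
        se_open = np.std(opens) / np.sqrt(n_eff)
        assert abs(np.mean(acts) - expect_act) < 3 * se_act + 0.01
        assert abs(np.mean(opens) - expect_open) < 3 * se_open + 0.05

    @pytest.mark.parametrize("vm,expect", [(100.0, 1.0), (-200.0, 0.0)])
    def test_extreme_voltage_saturates_activation(self, vm, expect):
        p = EnergyParams(a=0.0, j_cl_open_unsat=0.0, j_cl_closed_sat=0.0,
                         inactivation=False)
        st = MCState.create(L=12, n_na=2, n_k=2, params=p, vm=vm, rng_seed=0)
        st.run_moves(30_000, SENSORS_ONLY)
        assert st.ch_sens.mean() == pytest.approx(expect, abs=0.02)

    def test_activation_increases_with_temperature_below_v_half(self):
        """Below half-activation the gating term is an energy penalty, so
        raising T softens it and increases activation (default parameters,
        frozen lipids)."""
        fracs = []
        for T in (20.0, 30.0, 40.0):
            p = EnergyParams(j_cl_open_unsat=0.0, j_cl_closed_sat=0.0,
                             inactivation=False)
            st = MCState.create(L=16, n_na=6, n_k=6, params=p, vm=-55.0,
                                temperature_c=T, rng_seed=9)
            st.run_moves(40_000, SENSORS_ONLY)
            vals = []
            for _ in range(200):
                st.run_moves(2000, SENSORS_ONLY)
                vals.append(st.ch_sens.mean())
            fracs.append(np.mean(vals))
        assert fracs[0] < fracs[1] < fracs[2]


class TestConservation:
    def test_lipid_and_channel_counts_conserved_over_1e6_moves(self):
        p = EnergyParams()
        st = MCState.create(L=32, n_na=8, n_k=8, params=p, vm=-30.0, rng_seed=4)
        before = st.lipid_counts()
        n_ch = st.n_channels
        st.run_moves(1_000_000, ALL_MOVES)
        assert st.lipid_counts() == before
        assert st.n_channels == n_ch
        counts = np.bincount(st.owner[st.owner >= 0], minlength=n_ch)
        assert np.all(counts == 4)
        assert np.isfinite(st.total_energy())


class TestObservables:
    def test_count_open_on_hand_built_state(self):
        p = EnergyParams()
        st = MCState.create(L=16, n_na=3, n_k=4, params=p, rng_seed=1)
        assert st.count_open() == {"Na": 0, "K": 0}
        st.ch_sens[3:6] = 1  # three K channels fully activated
        assert count_open(st) == {"Na": 0, "K": 3}
        st.ch_sens[0] = 1
        st.ch_inact[0] = 1  # activated but inactivated Na does not conduct
        assert count_open(st)["Na"] == 0

    def test_count_open_matches_brute_force(self, rng):
        p = EnergyParams()
        st = MCState.create(L=16, n_na=5, n_k=5, params=p, rng_seed=2)
        st.ch_sens[:] = rng.integers(0, 2, st.ch_sens.shape)
        st.ch_inact[:5] = rng.integers(0, 2, 5)
        expect = {"Na": 0, "K": 0}
        for c in range(st.n_channels):
            if st.ch_sens[c].sum() == 4:
                sp = "Na" if st.ch_species[c] == 0 else "K"
                if sp == "Na" and st.ch_inact[c]:
                    continue
                expect[sp] += 1
        assert st.count_open() == expect

    def test_membrane_current_values(self):
        p = EnergyParams(gamma_na=20.0, gamma_k=20.0, e_na=50.0, e_k=-77.0)
        assert membrane_current({"Na": 0, "K": 0}, -65.0, p) == 0.0
        assert membrane_current({"Na": 0, "K": 3}, -77.0, p) == pytest.approx(0.0)
        assert membrane_current({"Na": 5, "K": 0}, -65.0, p) == pytest.approx(-11.5)

    def test_set_voltage_round_trip_and_validation(self):
        st = MCState.create(L=8, n_na=1, n_k=1, rng_seed=0)
        set_voltage(st, -12.5)
        assert st.vm == -12.5
        with pytest.raises(ValueError):
            st.set_voltage(float("nan"))

    def test_total_energy_wrapper(self):
        st = MCState.create(L=8, n_na=1, n_k=1, rng_seed=0)
        assert total_energy(st) == pytest.approx(st.total_energy())


class TestMoveMixValidation:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MoveMix(sensor=0.5, inact=0.0, lipid=0.5, translate=0.2, rotate=0.0)
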