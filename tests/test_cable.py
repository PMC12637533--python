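import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ionspike.cable import (CableSim, Compartment, CompartmentModel, HHMechanism,
                            NumericalInstabilityError, PassiveMechanism,
                            advance, build_from_morphology,
                            build_two_compartment, detect_spikes, hh_rates,
                            place_synapses)
from ionspike.morphology import sample_distributed
from ionspike.stimulus import CurrentClampSpec
from ionspike.synapses import BiExpParams


def single_compartment(mech, length=20.0, diam=20.0):
    m = CompartmentModel()
    m.add_compartment(Compartment(length, diam, mech, -1))
    return m


def hh_oracle_trace(i_clamp_pA, onset, offset, t_stop, area_cm2,
                    mech=HHMechanism(), v0=-65.0):
    """High-accuracy adaptive integration of the identical HH equations."""
    C = 1.0 * area_cm2 * 1e3
    gna, gk, gl = (mech.gbar_na * area_cm2 * 1e3, mech.gbar_k * area_cm2 * 1e3,
                   mech.gbar_leak * area_cm2 * 1e3)

    def rhs(t, y):
        v, m, h, n = y
        am, bm, ah, bh, an, bn = (float(x[0]) for x in hh_rates(np.array([v])))
        iinj = i_clamp_pA * 1e-3 if onset <= t < offset else 0.0
        i_ion = (gna * m ** 3 * h * (v - mech.e_na)
                 + gk * n ** 4 * (v - mech.e_k) + gl * (v - mech.e_leak))
        return [(-i_ion + iinj) / C, am * (1 - m) - bm * m,
                ah * (1 - h) - bh * h, an * (1 - n) - bn * n]

    am, bm, ah, bh, an, bn = (float(x[0]) for x in hh_rates(np.array([v0])))
    y0 = [v0, am / (am + bm), ah / (ah + bh), an / (an + bn)]
    sol = solve_ivp(rhs, (0, t_stop), y0, method="LSODA", rtol=1e-10, atol=1e-10,
                    dense_output=True, max_step=0.5)
    t = np.arange(0.0, t_stop, 0.001)
    return t, sol.sol(t)[0]


class TestBuilders:
    def test_two_compartment_layout(self):
        m = build_two_compartment()
        assert m.n == 2
        assert m.compartments[1].parent == 0
        assert isinstance(m.compartments[0].mechanism, HHMechanism)
        assert isinstance(m.compartments[1].mechanism, PassiveMechanism)

    def test_decoupled_compartments_evolve_independently(self):
        leak_a = PassiveMechanism(g_leak=0.1, e_leak=-60.0)
        leak_b = PassiveMechanism(g_leak=0.1, e_leak=-70.0)
        m = build_two_compartment(leak_a, leak_b, coupled=False)
        tr = advance(m, dt=0.05, t_stop=100.0, record=(0, 1), v_init=-65.0)
        assert tr.trace(0)[-1] == pytest.approx(-60.0, abs=0.01)
        assert tr.trace(1)[-1] == pytest.approx(-70.0, abs=0.01)

    def test_morphology_discretization_bound(self, ball_and_stick):
        model, seg_map = build_from_morphology(ball_and_stick,
                                               max_compartment_length=20.0)
        dend = [c for c in model.compartments if c.tag != "soma"]
        assert len(dend) >= 30
        assert all(c.length_um <= 20.0 + 1e-9 for c in dend)

    def test_mechanism_map_assigns_hh_to_soma_only(self, ball_and_stick):
        model, _ = build_from_morphology(ball_and_stick)
        assert isinstance(model.compartments[0].mechanism, HHMechanism)
        assert all(isinstance(c.mechanism, PassiveMechanism)
                   for c in model.compartments[1:])

    def test_refining_discretization_converges(self, ball_and_stick):
        """Steady-state soma voltage under distal current is discretization-
        converged below 0.1 mV."""
        vals = []
        for bound in (40.0, 10.0):
            model, _ = build_from_morphology(
                ball_and_stick, max_compartment_length=bound,
                mechanism_map={"soma": PassiveMechanism(g_leak=0.1)})
            model.attach_clamp(model.n - 1, CurrentClampSpec(30.0, 0.0, 1e9))
            tr = advance(model, dt=0.05, t_stop=300.0)
            vals.append(tr.trace()[-1])
        assert abs(vals[0] - vals[1]) < 0.1


class TestAdvance:
    def test_passive_exponential_relaxation(self):
        """Zero-current decay toward e_leak with τ = c_m/g_leak."""
        mech = PassiveMechanism(g_leak=0.2, e_leak=-65.0)
        m = single_compartment(mech)
        tr = advance(m, dt=0.01, t_stop=20.0, v_init=-55.0)
        tau = 1.0 / 0.2  # μF/cm² over mS/cm² = ms
        expect = -65.0 + 10.0 * np.exp(-tr.t / tau)
        assert np.max(np.abs(tr.trace() - expect)) < 0.05

    def test_passive_step_response_matches_analytic(self):
        """Charge balance: RC step response to < 0.1 mV."""
        mech = PassiveMechanism(g_leak=0.1, e_leak=-65.0)
        m = single_compartment(mech)
        m.attach_clamp(0, CurrentClampSpec(50.0, onset_ms=0.0, duration_ms=1e9))
        tr = advance(m, dt=0.01, t_stop=60.0)
        area = math.pi * 20 * 20 * 1e-8
        g = 0.1 * area * 1e3  # μS
        dv = 50.0 * 1e-3 / g  # mV
        tau = 1.0 / 0.1
        expect = -65.0 + dv * (1 - np.exp(-tr.t / tau))
        assert np.max(np.abs(tr.trace() - expect)) < 0.1

    def test_hh_spike_train_matches_adaptive_oracle(self):
        """80 pA step on an HH soma: spike count and times match an
        independent high-accuracy ODE integration."""
        m = single_compartment(HHMechanism())
        m.attach_clamp(0, CurrentClampSpec(80.0, onset_ms=10.0, duration_ms=300.0))
        tr = advance(m, dt=0.0025, t_stop=120.0)
        ours = detect_spikes(tr)
        area = math.pi * 20 * 20 * 1e-8
        t_ref, v_ref = hh_oracle_trace(80.0, 10.0, 310.0, 120.0, area)
        theirs = detect_spikes((t_ref, v_ref))
        assert len(ours) == len(theirs) and len(ours) >= 2
        assert np.max(np.abs(ours - theirs)) < 0.05

    def test_dt_halving_converges_spike_times(self):
        m = single_compartment(HHMechanism())
        m.attach_clamp(0, CurrentClampSpec(80.0, onset_ms=5.0, duration_ms=100.0))
        s1 = detect_spikes(advance(m, dt=0.005, t_stop=60.0))
        s2 = detect_spikes(advance(m, dt=0.0025, t_stop=60.0))
        assert len(s1) == len(s2)
        assert np.max(np.abs(s1 - s2)) < 0.05

    def test_spike_count_nondecreasing_in_amplitude(self):
        counts = []
        for amp in (40.0, 80.0, 120.0, 160.0):
            m = single_compartment(HHMechanism())
            m.attach_clamp(0, CurrentClampSpec(amp, onset_ms=5.0, duration_ms=200.0))
            counts.append(len(detect_spikes(advance(m, dt=0.01, t_stop=150.0))))
        assert counts == sorted(counts)

    def test_deterministic_output(self):
        m = build_two_compartment()
        m.attach_clamp(0, CurrentClampSpec(80.0, onset_ms=5.0, duration_ms=50.0))
        a = advance(m, dt=0.025, t_stop=80.0)
        b = advance(m, dt=0.025, t_stop=80.0)
        assert np.array_equal(a.vm, b.vm)

    def test_instability_reports_compartment_and_time(self):
        m = single_compartment(PassiveMechanism(g_leak=0.1))
        m.attach_clamp(0, CurrentClampSpec(1e18, onset_ms=0.0, duration_ms=1e9))
        with pytest.raises(NumericalInstabilityError) as err:
            advance(m, dt=1e3, t_stop=3e5, theta=0.0)  # explicit Euler blow-up
        assert err.value.compartment == 0


class TestExternalCurrent:
    def test_constant_source_equals_clamp(self):
        a = single_compartment(PassiveMechanism())
        a.attach_clamp(0, CurrentClampSpec(60.0, onset_ms=0.0, duration_ms=1e9))
        b = single_compartment(PassiveMechanism())
        b.attach_external_current(0, lambda t: 60.0)
        ta = advance(a, dt=0.05, t_stop=50.0)
        tb = advance(b, dt=0.05, t_stop=50.0)
        assert np.allclose(ta.vm, tb.vm, atol=1e-12)

    def test_zero_source_is_noop(self):
        a = single_compartment(PassiveMechanism())
        b = single_compartment(PassiveMechanism())
        b.attach_external_current(0, lambda t: 0.0)
        assert np.array_equal(advance(a, t_stop=20.0).vm,
                              advance(b, t_stop=20.0).vm)

    def test_sources_superpose_in_passive_regime(self):
        def run(sources):
            m = single_compartment(PassiveMechanism())
            for s in sources:
                m.attach_external_current(0, s)
            return advance(m, dt=0.05, t_stop=50.0).trace() + 65.0

        f1 = lambda t: 30.0
        f2 = lambda t: 25.0 * math.sin(t / 5.0)
        both = run([f1, f2])
        assert np.allclose(both, run([f1]) + run([f2]), atol=1e-9)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 100, 0.1)
        assert detect_spikes((t, np.full_like(t, -65.0))).size == 0

    def test_synthetic_three_peak_trace(self):
        t = np.arange(0, 300, 0.1)
        v = np.full_like(t, -65.0)
        for centre in (50, 150, 250):
            v += 40 * np.exp(-((t - centre) / 5.0) ** 2)
        assert detect_spikes((t, v), threshold=-50.0).size == 3

    def test_threshold_above_maximum_gives_zero(self):
        t = np.arange(0, 300, 0.1)
        v = -65 + 10 * np.sin(t / 10)
        assert detect_spikes((t, v), threshold=-40.0).size == 0

    def test_refractory_interval_merges_crossings(self):
        t = np.arange(0, 10, 0.01)
        v = -65 + 30 * (np.sin(2 * np.pi * t) > 0.9)  # rapid double crossings
        many = detect_spikes((t, v), threshold=-50, min_interval=0.0)
        few = detect_spikes((t, v), threshold=-50, min_interval=2.0)
        assert few.size < many.size

    def test_negative_min_interval_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes((np.arange(3.0), np.zeros(3)), min_interval=-1.0)


class TestSynapsesInSolver:
    def test_synaptic_drive_depolarizes(self, binary_tree):
        model, seg_map = build_from_morphology(binary_tree)
        sites = sample_distributed(binary_tree, 5, rng_seed=0)
        place_synapses(model, seg_map, sites, BiExpParams(weight=0.05),
                       [np.array([10.0])] * 5)
        tr = advance(model, t_stop=50.0)
        v = tr.trace()
        assert v.max() > -64.0
        assert abs(v[-1] + 65.0) < 1.0  # returns to rest
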