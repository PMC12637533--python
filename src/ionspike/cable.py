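"""Compartmental cable-equation solver with Hodgkin–Huxley membranes.

The neurite tree is discretized into cylindrical compartments coupled by
axial conductances.  Each compartment carries a leak conductance and,
optionally, classic Hodgkin–Huxley Na/K channels whose rates are scaled by
a Q10 temperature factor.  Attachments: bi-exponential synapses driven by
spike trains, square current clamps, and arbitrary external current
sources (used by the lattice Monte Carlo coupling).

Integration is the standard staggered implicit scheme: gate variables are
advanced half a step with exact exponential (Rush–Larsen) updates at the
current voltage, synapse states are advanced exactly to the step midpoint,
and the voltage is then updated implicitly (Crank–Nicolson by default,
backward Euler with ``theta=1``) by solving the tree-structured linear
system with Hines elimination (O(n) per step).

Units: mV, ms, μm, μS, nA, nF; mechanism densities in mS/cm² and μF/cm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stimulus import CurrentClampSpec, SpikeTrain
from .synapses import BiExpParams


class NumericalInstabilityError(RuntimeError):
    """Non-finite solver state, reported with compartment and time."""

    def __init__(self, compartment: int, t_ms: float):
        super().__init__(
            f"non-finite membrane potential in compartment {compartment} at t={t_ms:.4g} ms"
        )
        self.compartment = compartment
        self.t_ms = t_ms


@dataclass(frozen=True)
class HHMechanism:
    """Classic Hodgkin–Huxley Na/K/leak membrane (densities in mS/cm²)."""

    gbar_na: float = 120.0
    gbar_k: float = 36.0
    gbar_leak: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.3
    q10: float = 3.0
    t_ref_c: float = 6.3  # temperature at which the classic rates were measured


@dataclass(frozen=True)
class PassiveMechanism:
    """Leak-only membrane."""

    g_leak: float = 0.1  # mS/cm²
    e_leak: float = -65.0


@dataclass
class Compartment:
    length_um: float
    diam_um: float
    mechanism: HHMechanism | PassiveMechanism
    parent: int  # -1 for root
    cm: float = 1.0  # μF/cm²
    ra: float = 100.0  # Ω·cm
    tag: str = "soma"


class CompartmentModel:
    """Tree of compartments plus synapse/clamp/external-current attachments."""

    def __init__(self):
        self.compartments: list[Compartment] = []
        self.synapses: list[tuple[int, BiExpParams, np.ndarray]] = []
        self.clamps: list[tuple[int, CurrentClampSpec]] = []
        self.external_sources: list[tuple[int, object]] = []

    def add_compartment(self, comp: Compartment) -> int:
        if comp.parent >= len(self.compartments):
            raise ValueError("parent index must precede child")
        if comp.length_um <= 0 or comp.diam_um <= 0 or comp.cm <= 0 or comp.ra <= 0:
            raise ValueError("geometric/electrical parameters must be positive")
        self.compartments.append(comp)
        return len(self.compartments) - 1

    @property
    def n(self) -> int:
        return len(self.compartments)

    def attach_synapse(self, compartment: int, params: BiExpParams,
                       train: SpikeTrain | np.ndarray) -> None:
        self._check(compartment)
        times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
        self.synapses.append((compartment, params, np.sort(times)))

    def attach_clamp(self, compartment: int, clamp: CurrentClampSpec) -> None:
        self._check(compartment)
        self.clamps.append((compartment, clamp))

    def attach_external_current(self, compartment: int, source) -> "CompartmentModel":
        """Attach a callback ``t_ms -> pA`` queried at each step midpoint."""
        self._check(compartment)
        self.external_sources.append((compartment, source))
        return self

    def _check(self, compartment: int) -> None:
        if not (0 <= compartment < self.n):
            raise ValueError(f"no compartment {compartment}")

    def compartments_with_tag(self, tag: str) -> list[int]:
        return [i for i, c in enumerate(self.compartments) if c.tag == tag]


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_two_compartment(
    soma_mechanism: HHMechanism | PassiveMechanism | None = None,
    dendrite_mechanism: PassiveMechanism | HHMechanism | None = None,
    soma_length_um: float = 20.0,
    soma_diam_um: float = 20.0,
    dendrite_length_um: float = 200.0,
    dendrite_diam_um: float = 2.0,
    cm: float = 1.0,
    ra: float = 100.0,
    coupled: bool = True,
) -> CompartmentModel:
    """Soma + dendrite, each a single cylindrical volume, axially coupled.

    Defaults: HH+leak soma, passive dendrite.  ``coupled=False`` severs the
    axial link (both compartments evolve independently; for tests).
    """
    m = CompartmentModel()
    m.add_compartment(Compartment(soma_length_um, soma_diam_um,
                                  soma_mechanism or HHMechanism(), -1, cm, ra, "soma"))
    m.add_compartment(Compartment(dendrite_length_um, dendrite_diam_um,
                                  dendrite_mechanism or PassiveMechanism(), 0 if coupled else -1,
                                  cm, ra, "dendrite"))
    m.decoupled = not coupled
    return m


def build_from_morphology(
    morph,
    max_compartment_length: float = 40.0,
    mechanism_map: dict | None = None,
    cm: float = 1.0,
    ra: float = 100.0,
) -> tuple[CompartmentModel, dict[int, list[int]]]:
    """Discretize a morphology: each segment split into compartments ≤ the bound.

    ``mechanism_map`` assigns mechanisms by type tag (default: HH on soma,
    passive everywhere else).  Returns the model and a map
    segment_id -> list of compartment indices (proximal to distal order),
    used to place synapse sites.
    """
    mech_map = {"soma": HHMechanism(), "default": PassiveMechanism()}
    if mechanism_map:
        mech_map.update(mechanism_map)

    model = CompartmentModel()
    root = morph.root
    model.add_compartment(Compartment(
        length_um=2 * root.radius, diam_um=2 * root.radius,
        mechanism=mech_map.get("soma", mech_map["default"]),
        parent=-1, cm=cm, ra=ra, tag="soma"))

    # walk segments in order; they are topologically sorted by construction
    node_to_comp = {root.id: 0}
    seg_to_comps: dict[int, list[int]] = {}
    for seg in morph.segments:
        tag = morph.segment_tag(seg.segment_id)
        mech = mech_map.get(tag, mech_map["default"])
        length = morph.segment_length(seg.segment_id)
        prox_node = morph.nodes[seg.proximal]
        dist_node = morph.nodes[seg.distal]
        diam = prox_node.radius + dist_node.radius  # mean of the two diameters
        n_pieces = max(1, math.ceil(length / max_compartment_length))
        parent = node_to_comp[seg.proximal]
        comps = []
        for _ in range(n_pieces):
            parent = model.add_compartment(Compartment(
                length_um=length / n_pieces, diam_um=diam, mechanism=mech,
                parent=parent, cm=cm, ra=ra, tag=tag))
            comps.append(parent)
        node_to_comp[seg.distal] = parent
        seg_to_comps[seg.segment_id] = comps
    return model, seg_to_comps


def place_synapses(model: CompartmentModel, seg_to_comps, sites, params, trains) -> None:
    """Attach one synapse per site, mapping arc fraction to the compartment index."""
    for site, train in zip(sites, trains):
        comps = seg_to_comps[site.segment_id]
        idx = min(int(site.arc_fraction * len(comps)), len(comps) - 1)
        model.attach_synapse(comps[idx], params, train)


# ---------------------------------------------------------------------------
# HH rate functions (classic squid parameterization, V in mV)
# ---------------------------------------------------------------------------

def _vtrap(x, y):
    """x / (exp(x/y) − 1) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    out = np.empty_like(x)
    out[small] = y * (1 - x[small] / y / 2.0)
    out[~small] = x[~small] / (np.exp(x[~small] / y) - 1.0)
    return out


def hh_rates(v):
    """(αm, βm, αh, βh, αn, βn) at voltage(s) ``v`` in 1/ms."""
    v = np.asarray(v, dtype=float)
    a_m = 0.1 * _vtrap(-(v + 40.0), 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    a_n = 0.01 * _vtrap(-(v + 55.0), 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class VoltageTrace:
    """Uniformly sampled membrane potential per recorded compartment."""

    t: np.ndarray  # ms
    vm: np.ndarray  # (n_recorded, n_samples) mV
    recorded: tuple[int, ...]

    def trace(self, compartment: int | None = None) -> np.ndarray:
        if compartment is None:
            return self.vm[0]
        return self.vm[self.recorded.index(compartment)]

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"t_ms": self.t}
        for k, c in enumerate(self.recorded):
            cols[f"vm_mV_comp{c}"] = self.vm[k]
        pd.DataFrame(cols).to_csv(path, index=False)


class CableSim:
    """Stateful stepping engine behind :func:`advance` and the MC coupling.

    The model must be fully assembled (synapses, clamps, sources attached)
    before a ``CableSim`` is created.  Stepping is delegated to a compiled
    kernel; models with external-current callbacks are stepped one step at
    a time so the callbacks can be evaluated at each step midpoint.
    """

    def __init__(self, model: CompartmentModel, dt: float = 0.025,
                 v_init: float = -65.0, celsius: float | None = None,
                 theta: float = 0.5, record: tuple[int, ...] = (0,)):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.model = model
        self.dt = dt
        self.theta = theta
        self.record = tuple(record)
        n = model.n
        comps = model.compartments

        area = np.array([math.pi * c.diam_um * c.length_um * 1e-8 for c in comps])  # cm²
        self.c_nF = np.array([c.cm for c in comps]) * area * 1e3  # μF → nF
        self.area_cm2 = area

        # per-compartment mechanism arrays (μS): density mS/cm² × cm² × 1e3
        def dens(attr, default=0.0):
            return np.array([float(getattr(c.mechanism, attr, default))
                             for c in comps])

        self.g_leak = (dens("gbar_leak") + dens("g_leak")) * area * 1e3
        self.e_leak = np.array([c.mechanism.e_leak for c in comps])
        self.gbar_na = dens("gbar_na") * area * 1e3
        self.gbar_k = dens("gbar_k") * area * 1e3
        self.e_na = dens("e_na", 50.0)
        self.e_k = dens("e_k", -77.0)
        self.is_hh = np.array(
            [isinstance(c.mechanism, HHMechanism) for c in comps], dtype=np.uint8)

        # temperature factor on HH rates
        self.phi = np.ones(n)
        for i, c in enumerate(comps):
            if isinstance(c.mechanism, HHMechanism) and celsius is not None:
                self.phi[i] = c.mechanism.q10 ** ((celsius - c.mechanism.t_ref_c) / 10.0)

        # axial coupling to parent: series half-cylinder resistances
        self.parent = np.array([c.parent for c in comps], dtype=np.int64)
        g_ax = np.zeros(n)
        for i, c in enumerate(comps):
            p = c.parent
            if p < 0:
                continue
            cp = comps[p]

            def half_r(cc):  # Ω
                area_x = math.pi * (cc.diam_um / 2 * 1e-4) ** 2  # cm²
                return cc.ra * (cc.length_um / 2 * 1e-4) / area_x

            g_ax[i] = 1.0 / (half_r(c) + half_r(cp)) * 1e6  # S → μS
        self.g_ax = g_ax

        # state
        self.v = np.full(n, float(v_init))
        a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(self.v)
        self.m = a_m / (a_m + b_m)
        self.h = a_h / (a_h + b_h)
        self.n_gate = a_n / (a_n + b_n)
        self.t = 0.0
        self._step_idx = 0

        # synapse bank: exact bi-exponential states with a global event list
        syn = model.synapses
        self.syn_comp = np.array([s[0] for s in syn], dtype=np.int64)
        self.syn_tau_d = np.array([s[1].tau_d for s in syn], dtype=float)
        self.syn_tau_r = np.array([s[1].tau_r for s in syn], dtype=float)
        self.syn_e = np.array([s[1].e_rev for s in syn], dtype=float)
        # increments in μS (synapse parameters are in nS)
        self.syn_inc = np.array([s[1].weight * s[1].g0 * s[1].norm * 1e-3
                                 for s in syn], dtype=float)
        self.syn_A = np.zeros(len(syn))
        self.syn_B = np.zeros(len(syn))
        events = [(ts, k) for k, s in enumerate(syn) for ts in s[2]]
        events.sort()
        self._event_times = np.array([e[0] for e in events], dtype=float)
        self._event_syn = np.array([e[1] for e in events], dtype=np.int64)
        self._ev_ptr = 0

        self._clamp_comp = np.array([c[0] for c in model.clamps], dtype=np.int64)
        self._clamp_amp = np.array([c[1].amplitude_pA for c in model.clamps],
                                   dtype=float)
        self._clamp_on = np.array([c[1].onset_ms for c in model.clamps],
                                  dtype=float)
        self._clamp_off = np.array([c[1].onset_ms + c[1].duration_ms
                                    for c in model.clamps], dtype=float)
        self._rec_idx = np.array(self.record, dtype=np.int64)

        # recording buffers
        self._rec_chunks = [self.v[self._rec_idx].copy().reshape(-1, 1)]

    def _advance(self, n_steps: int, inject_nA: np.ndarray) -> None:
        from . import _cable_kernels as _ck

        rec_out = np.empty((len(self.record), n_steps))
        err = np.full(2, -1, dtype=np.int64)
        self._ev_ptr = _ck.run_steps(
            n_steps, self._step_idx, self.dt, self.theta,
            self.parent, self.g_ax, self.c_nF,
            self.g_leak, self.e_leak, self.gbar_na, self.gbar_k,
            self.e_na, self.e_k, self.is_hh, self.phi,
            self.v, self.m, self.h, self.n_gate,
            self.syn_comp, self.syn_tau_d, self.syn_tau_r, self.syn_e,
            self.syn_inc, self.syn_A, self.syn_B,
            self._event_times, self._event_syn, self._ev_ptr,
            self._clamp_comp, self._clamp_amp, self._clamp_on, self._clamp_off,
            inject_nA, self._rec_idx, rec_out, err)
        if err[0] >= 0:
            raise NumericalInstabilityError(int(err[0]), float(err[1] * self.dt))
        self._rec_chunks.append(rec_out)
        self._step_idx += n_steps
        self.t = self._step_idx * self.dt

    def run_until(self, t_stop: float, inject_nA: np.ndarray | None = None) -> None:
        """Step until ``t_stop`` (within half a step), recording each sample."""
        n_total = int(round(t_stop / self.dt)) - self._step_idx
        if n_total <= 0:
            return
        base = (np.zeros(self.model.n) if inject_nA is None
                else np.asarray(inject_nA, dtype=float))
        if self.model.external_sources:
            for _ in range(n_total):
                inj = base.copy()
                t_mid = (self._step_idx + 0.5) * self.dt
                for comp, src in self.model.external_sources:
                    inj[comp] += src(t_mid) * 1e-3  # pA → nA
                self._advance(1, inj)
        else:
            self._advance(n_total, base)

    def result(self) -> VoltageTrace:
        vm = np.concatenate(self._rec_chunks, axis=1)
        t = np.arange(vm.shape[1]) * self.dt
        return VoltageTrace(t=t, vm=vm, recorded=self.record)


def advance(
    model: CompartmentModel, dt: float = 0.025, t_stop: float = 100.0,
    record: tuple[int, ...] = (0,), v_init: float = -65.0,
    celsius: float | None = None, theta: float = 0.5,
) -> VoltageTrace:
    """Simulate the model from rest to ``t_stop`` and return recorded voltages.

    ``theta=0.5`` is Crank–Nicolson, ``theta=1.0`` backward Euler.
    """
    sim = CableSim(model, dt=dt, v_init=v_init, celsius=celsius, theta=theta,
                   record=record)
    sim.run_until(t_stop)
    return sim.result()


def detect_spikes(
    trace, threshold: float = -50.0, min_interval: float = 2.0,
    compartment: int | None = None,
) -> np.ndarray:
    """Upward threshold-crossing times (linearly interpolated), with a
    refractory separation of ``min_interval`` ms.

    ``trace`` is a :class:`VoltageTrace` or a (t, v) pair.
    """
    if min_interval < 0:
        raise ValueError("min_interval must be >= 0")
    if isinstance(trace, VoltageTrace):
        t, v = trace.t, trace.trace(compartment)
    else:
        t, v = trace
        t, v = np.asarray(t, float), np.asarray(v, float)
    above = v >= threshold
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    times = []
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if not times or tc - times[-1] >= min_interval:
            times.append(tc)
    return np.array(times)
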