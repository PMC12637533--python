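"""Bidirectional coupling of the lattice Monte Carlo gating model and the
cable solver.

Per exchange window of Δt_ex milliseconds: the soma voltage is written
into the Monte Carlo gating term; ν·Δt_ex sweeps of lattice dynamics run;
the window-averaged open-channel counts give the patch current Im, which
(sign-flipped, optionally scaled from patch to cell) is injected into the
soma compartment; the solver then advances by Δt_ex.  Replica ensembles
differ only in the Monte Carlo seed and are aggregated as the pointwise
median with a first/third-quartile envelope.

Spike-shape metrics per trace: peak depolarization of the first spike,
repolarization time (peak until the voltage first returns within 5 mV of
rest), and width (time above the detection threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cable import (CableSim, CompartmentModel, PassiveMechanism, VoltageTrace,
                    build_two_compartment, detect_spikes)
from .lattice import EnergyParams, MCState, MoveMix, membrane_current
from .stimulus import CurrentClampSpec


@dataclass(frozen=True)
class CouplingConfig:
    """Protocol and numerics of a coupled run."""

    dt_exchange: float = 0.1        # ms between voltage/current exchanges
    solver_dt: float = 0.025        # cable solver step, ms
    duration: float = 120.0         # ms
    clamp: CurrentClampSpec = field(
        default_factory=lambda: CurrentClampSpec(80.0, onset_ms=5.0, duration_ms=10.0))
    temperature_c: float = 30.0
    n_replicas: int = 100
    base_seed: int = 0
    current_scale: float = 50.0     # patch-to-cell current multiplier
    v_init: float = -65.0
    rest: float = -65.0
    lattice_L: int = 64
    n_na: int = 30
    n_k: int = 20
    burn_in_sweeps: int = 400       # lipid pre-equilibration at the run temperature
    move_mix: MoveMix = field(default_factory=MoveMix)

    def __post_init__(self):
        if self.dt_exchange < self.solver_dt:
            raise ValueError("exchange interval must be >= solver dt")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")


@dataclass
class SpikeShapeMetrics:
    """Shape of the first spike in a trace; ``has_spike`` marks traces with none."""

    has_spike: bool
    peak_mV: float = math.nan
    repolarization_ms: float = math.nan
    width_ms: float = math.nan
    spike_count: int = 0


@dataclass
class EnsembleResult:
    """Replica ensemble of coupled runs at one temperature."""

    t: np.ndarray
    traces: np.ndarray            # (n_replicas, n_samples)
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    metrics: pd.DataFrame         # one row per replica
    temperature_c: float
    seeds: list[int]

    def median_metric(self, name: str) -> float:
        vals = self.metrics.loc[self.metrics.has_spike, name]
        return float(vals.median()) if len(vals) else math.nan


def default_patch_model(cfg: CouplingConfig) -> CompartmentModel:
    """Soma + dendrite cell used for coupled runs: passive membrane; the
    active Na/K currents come from the lattice patch."""
    leak = PassiveMechanism(g_leak=0.2, e_leak=cfg.rest)
    model = build_two_compartment(soma_mechanism=leak, dendrite_mechanism=leak,
                                  dendrite_length_um=100.0, dendrite_diam_um=1.5)
    model.attach_clamp(0, cfg.clamp)
    return model


def run_coupled(model: CompartmentModel, mc: MCState, cfg: CouplingConfig,
                record: tuple[int, ...] = (0,)) -> VoltageTrace:
    """One bidirectional MC/cable run; returns the recorded voltage trace."""
    sim = CableSim(model, dt=cfg.solver_dt, v_init=cfg.v_init, record=record)
    nu = mc.params.nu_at(mc.temperature_c)
    n_moves = max(1, int(round(nu * cfg.dt_exchange * mc.L ** 2)))
    n_windows = int(round(cfg.duration / cfg.dt_exchange))
    steps_per_exchange = int(round(cfg.dt_exchange / cfg.solver_dt))
    inject = np.zeros(model.n)
    for w in range(n_windows):
        vm = float(sim.v[0])
        mc.set_voltage(vm)
        if mc.n_channels > 0:
            mean_na, mean_k, _ = mc.run_moves(n_moves, cfg.move_mix)
            im_pA = membrane_current((mean_na, mean_k), vm, mc.params)
            # inward (negative) membrane current depolarizes: inject −Im
            inject[0] = -im_pA * cfg.current_scale * 1e-3  # pA → nA
        try:
            sim.run_until((w + 1) * cfg.dt_exchange, inject)
        except Exception as exc:
            raise RuntimeError(
                f"solver failure in exchange window {w} "
                f"(t={w * cfg.dt_exchange:.3f} ms)") from exc
    return sim.result()


def spike_shape_metrics(trace, rest: float = -65.0, threshold: float = -50.0,
                        margin: float = 5.0) -> SpikeShapeMetrics:
    """Shape metrics of the first spike (see module docstring)."""
    if isinstance(trace, VoltageTrace):
        t, v = trace.t, trace.trace()
    else:
        t, v = np.asarray(trace[0], float), np.asarray(trace[1], float)
    spikes = detect_spikes((t, v), threshold=threshold)
    if spikes.size == 0:
        return SpikeShapeMetrics(has_spike=False)
    t0 = spikes[0]
    i0 = int(np.searchsorted(t, t0))
    # first spike ends when v falls back below threshold (or at trace end)
    below = np.nonzero(v[i0:] < threshold)[0]
    i_end = i0 + (below[0] if below.size else v.size - i0 - 1)
    i_peak = i0 + int(np.argmax(v[i0:i_end + 1]))
    peak = float(v[i_peak])
    # repolarization: first return to within `margin` of rest after the peak
    back = np.nonzero(np.abs(v[i_peak:] - rest) <= margin)[0]
    repol = float(t[i_peak + back[0]] - t[i_peak]) if back.size else math.nan
    width = float(t[i_end] - t0)
    return SpikeShapeMetrics(has_spike=True, peak_mV=peak,
                             repolarization_ms=repol, width_ms=width,
                             spike_count=int(spikes.size))


def run_replica(cfg: CouplingConfig, seed: int,
                params: EnergyParams | None = None,
                model_factory=None) -> VoltageTrace:
    """One replica: fresh model and MC state from ``seed``."""
    params = params or EnergyParams()
    model = (model_factory or default_patch_model)(cfg)
    mc = MCState.create(L=cfg.lattice_L, n_na=cfg.n_na, n_k=cfg.n_k,
                        params=params, temperature_c=cfg.temperature_c,
                        vm=cfg.v_init, rng_seed=seed)
    if cfg.burn_in_sweeps > 0 and mc.n_channels > 0:
        mc.equilibrate_lipids(cfg.burn_in_sweeps)
    return run_coupled(model, mc, cfg)


def run_ensemble(cfg: CouplingConfig, params: EnergyParams | None = None,
                 model_factory=None) -> EnsembleResult:
    """Replica ensemble at ``cfg.temperature_c``; replicas differ only in
    the Monte Carlo seed (spawned deterministically from ``base_seed``)."""
    if cfg.n_replicas >= 2:
        pass  # quartile envelope meaningful
    seq = np.random.SeedSequence(cfg.base_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seq.spawn(cfg.n_replicas)]
    traces = []
    metrics = []
    t = None
    for seed in seeds:
        tr = run_replica(cfg, seed, params=params, model_factory=model_factory)
        t = tr.t
        v = tr.trace()
        traces.append(v)
        m = spike_shape_metrics((t, v), rest=cfg.rest)
        metrics.append({"seed": seed, "has_spike": m.has_spike, "peak_mV": m.peak_mV,
                        "repolarization_ms": m.repolarization_ms,
                        "width_ms": m.width_ms, "spike_count": m.spike_count})
    traces = np.array(traces)
    return EnsembleResult(
        t=t, traces=traces,
        median=np.median(traces, axis=0),
        q1=np.quantile(traces, 0.25, axis=0),
        q3=np.quantile(traces, 0.75, axis=0),
        metrics=pd.DataFrame(metrics),
        temperature_c=cfg.temperature_c,
        seeds=seeds,
    )


def repolarization_ratio(cold: EnsembleResult, warm: EnsembleResult) -> float:
    """Ratio of ensemble-median repolarization times (cold / warm)."""
    return cold.median_metric("repolarization_ms") / warm.median_metric("repolarization_ms")
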