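"""Lattice Monte Carlo model of voltage-gated Na/K channel gating.

A periodic L×L square lattice coarse-grains a patch of neuronal membrane:
every site holds either a lipid (saturated or unsaturated species) or part
of a channel footprint.  Each channel has four allosterically linked
two-state voltage sensors; the channel conducts when all four are
activated (Na channels additionally carry an optional slow inactivation
flag).  The Ising-like Hamiltonian, in units of kT at the reference
temperature T_ref, combines

* a *gating* term, −q_s·(Vm − V_half)/kT_mV per activated sensor (and an
  analogous term for the Na inactivation flag), representing the intrinsic
  voltage-dependent energy of the channel states;
* an *allosteric* penalty a per unlike sensor pair within a channel;
* an *interaction* term J_cl(channel state, lipid species) for each lipid
  in the 8-site perimeter of the channel footprint, making the channel's
  state energy depend on its local lipid environment;
* a lipid–lipid term −J_ll per like-species neighbour bond, which drives
  phase separation of the two lipid species (critical near J_ll ≈ 0.88 for
  a 50/50 mixture).

Dynamics are Metropolis: sensor/inactivation flips, Kawasaki exchanges of
unlike neighbour lipids (conserving composition), and channel translation
and rotation.  Acceptance uses exp(−ΔE·T_ref/T), so lowering the bath
temperature both stiffens every energy scale and pushes the lipid mixture
deeper into demixing.

The observable is the open-channel count per species, converted to a
membrane current Im = ΣN_open·γ·(Vm − E) (conventional sign: outward
positive), which the coupling layer injects into the cable solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _mc_kernels as _k

KB_MV_PER_K = 0.08617333  # Boltzmann constant in mV per kelvin per elementary charge


@dataclass(frozen=True)
class MoveMix:
    """Proposal probabilities per attempted Monte Carlo move.

    ``sensor`` flips voltage sensors (fast activation kinetics); ``inact``
    flips the slow Na inactivation flag and is deliberately rare — its share
    sets the milliseconds-scale inactivation clock relative to sub-ms sensor
    activation, mirroring the kinetic separation in real channels.
    """

    sensor: float = 0.2
    inact: float = 1.5e-5
    lipid: float = 0.549985
    translate: float = 0.2
    rotate: float = 0.05

    def __post_init__(self):
        total = self.sensor + self.inact + self.lipid + self.translate + self.rotate
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"move probabilities must sum to 1, got {total}")


@dataclass(frozen=True)
class EnergyParams:
    """Energetic and kinetic parameters of the lattice model.

    Energies are in kT at ``t_ref_c``; voltages in mV; conductances in pS.
    ``nu`` converts Monte Carlo sweeps (L² attempted moves) to wall-clock
    milliseconds for the coupling to the cable solver.
    """

    q_s: float = 2.0            # gating charge per sensor, elementary charges
    v_half_na: float = -40.0    # sensor half-activation voltage, Na
    v_half_k: float = -30.0     # sensor half-activation voltage, K
    a: float = 0.5              # allosteric penalty per unlike sensor pair
    j_ll: float = 0.88          # like-lipid bond energy (critical ≈ 0.881 at 50/50)
    j_cl_open_unsat: float = -0.2   # open channel / unsaturated lipid contact
    j_cl_open_sat: float = 0.0
    j_cl_closed_unsat: float = 0.0
    j_cl_closed_sat: float = -0.2   # closed channel / saturated lipid contact
    gamma_na: float = 20.0      # single-channel conductance, pS
    gamma_k: float = 20.0
    e_na: float = 50.0          # reversal potentials, mV
    e_k: float = -77.0
    nu: float = 10.0            # sweeps per millisecond at t_ref_c
    q10_nu: float = 2.8         # Arrhenius factor on the attempt rate per 10 °C
    inactivation: bool = True   # Na channels carry a slow inactivation flag
    q_inact: float = 6.0        # inactivation gating charge (steep voltage dependence)
    v_half_inact: float = -50.0  # inactivation midpoint before lipid shifts, mV
    t_ref_c: float = 30.0

    @property
    def kt_mv(self) -> float:
        """Thermal voltage kT_ref/e in mV."""
        return KB_MV_PER_K * (273.15 + self.t_ref_c)

    @property
    def j_cl(self) -> np.ndarray:
        """(2, 2) contact matrix indexed [channel state][lipid species]."""
        return np.array(
            [[self.j_cl_closed_sat, self.j_cl_closed_unsat],
             [self.j_cl_open_sat, self.j_cl_open_unsat]]
        )

    def v_half(self, species: str) -> float:
        return self.v_half_na if species == "Na" else self.v_half_k

    def nu_at(self, temperature_c: float) -> float:
        """Attempt rate in sweeps/ms at the given bath temperature (Arrhenius Q10)."""
        return self.nu * self.q10_nu ** ((temperature_c - self.t_ref_c) / 10.0)

    def __post_init__(self):
        if self.gamma_na <= 0 or self.gamma_k <= 0:
            raise ValueError("single-channel conductances must be > 0")
        if self.nu <= 0:
            raise ValueError("nu must be > 0")


class MCState:
    """Mutable Monte Carlo state: lattice, channels, voltage, temperature, RNG."""

    def __init__(self, lat, owner, ch_species, ch_x, ch_y, ch_sens, ch_inact,
                 params: EnergyParams, temperature_c: float, vm: float,
                 rng: np.random.Generator):
        self.lat = lat
        self.owner = owner
        self.ch_species = ch_species
        self.ch_x = ch_x
        self.ch_y = ch_y
        self.ch_sens = ch_sens
        self.ch_inact = ch_inact
        self.params = params
        self.temperature_c = float(temperature_c)
        self.vm = float(vm)
        self.rng = rng

    # -- construction -------------------------------------------------------
    @classmethod
    def create(cls, L: int = 64, n_na: int = 30, n_k: int = 30,
               params: EnergyParams | None = None, temperature_c: float = 30.0,
               vm: float = -65.0, frac_unsat: float = 0.5,
               rng_seed: int | np.random.Generator = 0) -> "MCState":
        """Random initial state: channels on non-overlapping anchors, lipids
        mixed at exactly the requested composition."""
        params = params or EnergyParams()
        if L < 8:
            raise ValueError("lattice size must be at least 8")
        rng = np.random.default_rng(rng_seed)
        n_ch = n_na + n_k
        stride = 4
        slots = [(i * stride, j * stride) for i in range(L // stride)
                 for j in range(L // stride)]
        if n_ch > len(slots):
            raise ValueError("too many channels for the lattice size")
        chosen = rng.choice(len(slots), size=n_ch, replace=False)
        lat = np.zeros((L, L), dtype=np.int8)
        owner = np.full((L, L), -1, dtype=np.int64)
        ch_x = np.empty(n_ch, dtype=np.int64)
        ch_y = np.empty(n_ch, dtype=np.int64)
        for c, s in enumerate(chosen):
            x, y = slots[s]
            ch_x[c], ch_y[c] = x, y
            for dx in range(2):
                for dy in range(2):
                    lat[(x + dx) % L, (y + dy) % L] = 2
                    owner[(x + dx) % L, (y + dy) % L] = c
        free = np.argwhere(lat < 2)
        n_unsat = int(round(frac_unsat * len(free)))
        pick = rng.choice(len(free), size=n_unsat, replace=False)
        for p in pick:
            lat[free[p][0], free[p][1]] = 1
        ch_species = np.array([0] * n_na + [1] * n_k, dtype=np.int8)
        ch_sens = np.zeros((n_ch, 4), dtype=np.int8)
        ch_inact = np.zeros(n_ch, dtype=np.int8)
        return cls(lat, owner, ch_species, ch_x, ch_y, ch_sens, ch_inact,
                   params, temperature_c, vm, rng)

    # -- properties ---------------------------------------------------------
    @property
    def L(self) -> int:
        return self.lat.shape[0]

    @property
    def n_channels(self) -> int:
        return self.ch_species.size

    @property
    def beta_rel(self) -> float:
        """T_ref[K] / T[K]: rescales kT_ref-unit energies to the bath temperature."""
        return (273.15 + self.params.t_ref_c) / (273.15 + self.temperature_c)

    def lipid_counts(self) -> tuple[int, int]:
        return int(np.sum(self.lat == 0)), int(np.sum(self.lat == 1))

    def copy(self) -> "MCState":
        return MCState(self.lat.copy(), self.owner.copy(), self.ch_species.copy(),
                       self.ch_x.copy(), self.ch_y.copy(), self.ch_sens.copy(),
                       self.ch_inact.copy(), self.params, self.temperature_c,
                       self.vm, self.rng)

    # -- operations ---------------------------------------------------------
    def set_voltage(self, vm: float) -> "MCState":
        """Update the membrane voltage entering the gating term."""
        if not math.isfinite(vm):
            raise ValueError("Vm must be finite")
        self.vm = float(vm)
        return self

    def total_energy(self) -> float:
        """Full Hamiltonian in kT_ref units."""
        p = self.params
        return float(_k.total_energy(
            self.lat, self.owner, self.ch_species, self.ch_x, self.ch_y,
            self.ch_sens, self.ch_inact, self.vm, p.q_s, p.v_half_na, p.v_half_k,
            p.kt_mv, p.a, p.j_ll, p.j_cl, p.q_inact, p.v_half_inact,
            p.inactivation))

    def run_moves(self, n_moves: int, move_mix: MoveMix | None = None,
                  rand_buf: np.ndarray | None = None) -> tuple[float, float, int]:
        """Attempt ``n_moves`` Metropolis moves.

        Returns (mean open Na count, mean open K count, accepted moves),
        the means being time averages over all attempts.  ``rand_buf``
        optionally replays an explicit uniform stream (testing hook).
        """
        mix = move_mix or MoveMix()
        p = self.params
        seed = int(self.rng.integers(0, 2**31 - 1))
        buf = np.empty(0) if rand_buf is None else np.asarray(rand_buf, dtype=float)
        sum_na, sum_k, acc = _k.run_moves(
            self.lat, self.owner, self.ch_species, self.ch_x, self.ch_y,
            self.ch_sens, self.ch_inact, n_moves, self.vm, self.beta_rel,
            p.q_s, p.v_half_na, p.v_half_k, p.kt_mv, p.a, p.j_ll, p.j_cl,
            p.q_inact, p.v_half_inact, p.inactivation,
            mix.sensor, mix.inact, mix.lipid, mix.translate, seed, buf)
        return sum_na / n_moves, sum_k / n_moves, int(acc)

    def metropolis_sweep(self, n_sweeps: int = 1, move_mix: MoveMix | None = None
                         ) -> tuple[float, float, int]:
        """Run ``n_sweeps`` sweeps of L² attempted moves each."""
        return self.run_moves(n_sweeps * self.L ** 2, move_mix)

    def equilibrate_lipids(self, n_sweeps: int) -> None:
        """Burn in the lipid background (exchange moves only, channels frozen)."""
        self.run_moves(n_sweeps * self.L ** 2,
                       MoveMix(sensor=0.0, inact=0.0, lipid=1.0,
                               translate=0.0, rotate=0.0))

    def count_open(self) -> dict[str, int]:
        """Open channels per species (all four sensors activated; Na also
        requires the inactivation flag to be clear)."""
        na = k = 0
        for c in range(self.n_channels):
            if self.ch_sens[c].sum() == 4 and not (
                    self.params.inactivation and self.ch_species[c] == 0
                    and self.ch_inact[c]):
                if self.ch_species[c] == 0:
                    na += 1
                else:
                    k += 1
        return {"Na": na, "K": k}


def count_open(state: MCState) -> dict[str, int]:
    return state.count_open()


def set_voltage(state: MCState, vm: float) -> MCState:
    return state.set_voltage(vm)


def total_energy(state: MCState, params: EnergyParams | None = None) -> float:
    if params is not None and params is not state.params:
        state = state.copy()
        state.params = params
    return state.total_energy()


def membrane_current(open_counts, vm: float, params: EnergyParams) -> float:
    """Patch membrane current in pA from open-channel counts.

    Im = N_Na·γ_Na·(Vm − E_Na) + N_K·γ_K·(Vm − E_K); pS·mV = fA, so ×1e−3.
    Conventional membrane sign: outward current positive, so at rest an open
    Na channel gives a negative Im (inward, depolarizing once injected into
    the solver with the sign flipped by the coupling layer).
    """
    if isinstance(open_counts, dict):
        n_na, n_k = open_counts.get("Na", 0), open_counts.get("K", 0)
    else:
        n_na, n_k = open_counts
    return (n_na * params.gamma_na * (vm - params.e_na)
            + n_k * params.gamma_k * (vm - params.e_k)) * 1e-3
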