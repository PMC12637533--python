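"""Bi-exponential AMPAR synapse model and variant conductance scaling.

The effective synaptic conductance following a presynaptic spike at ``ts``
is a normalized difference of exponentials,

    g(t) = g0 · N · [exp(−(t−ts)/τd) − exp(−(t−ts)/τr)],   t ≥ ts,

with rise constant τr, decay constant τd and normalization
N = 1/[exp(−tp/τd) − exp(−tp/τr)] at the peak time
tp = τr·τd/(τd−τr) · ln(τd/τr), so that a single spike peaks at exactly g0.
Responses to spike trains superpose linearly; the same waveform is obtained
from two coupled linear ODEs (states A, B) stepped with exact exponential
updates, which is how the cable solver integrates synapses.

Variant scaling: coarse-grained or atomistic molecular simulation gives a
mean single-channel conductance g_MD per receptor variant.  Each variant's
synaptic waveform is the baseline waveform scaled by
g_MD,variant / g_MD,baseline, where the baseline is the RNA-edited Q586R
form of the GluA2 subunit.  The bundled default table covers wild-type and
the Q586R/G/E disease-associated variants.

The synaptic current is I(t) = g(t)·(Vm(t) − E) with reversal E = 0 mV, so
at typical resting potentials it is inward (depolarizing).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BiExpParams:
    """Bi-exponential synapse parameters.

    g0 : peak conductance of a unit-weight single-spike response, nS
    tau_r, tau_d : rise / decay time constants, ms (0 < tau_r < tau_d)
    e_rev : reversal potential, mV
    weight : dimensionless multiplier applied to each spike's increment
    """

    g0: float = 3.5
    tau_r: float = 0.5
    tau_d: float = 2.0
    e_rev: float = 0.0
    weight: float = 1.0

    def __post_init__(self):
        if self.g0 <= 0:
            raise ValueError("g0 must be > 0")
        if not (0 < self.tau_r < self.tau_d):
            raise ValueError("need 0 < tau_r < tau_d")

    @property
    def t_peak(self) -> float:
        """Time to peak of the single-spike response, ms."""
        return (self.tau_r * self.tau_d / (self.tau_d - self.tau_r)
                * math.log(self.tau_d / self.tau_r))

    @property
    def norm(self) -> float:
        """Peak normalization N such that the single-spike peak equals g0."""
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / self.tau_d) - math.exp(-tp / self.tau_r))


def conductance_waveform(t, spike_times, p: BiExpParams) -> np.ndarray:
    """Closed-form conductance g(t) in nS for a spike train (superposition)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    g = np.zeros_like(t)
    amp = p.weight * p.g0 * p.norm
    for ts in np.atleast_1d(spike_times):
        dt = t - ts
        mask = dt >= 0
        g[mask] += amp * (np.exp(-dt[mask] / p.tau_d) - np.exp(-dt[mask] / p.tau_r))
    return g if g.size > 1 else g


@dataclass
class SynapseState:
    """ODE state of one bi-exponential synapse: g = A − B (both in nS)."""

    params: BiExpParams
    A: float = 0.0
    B: float = 0.0
    t: float = 0.0

    @property
    def g(self) -> float:
        return self.A - self.B


def step_synapse(s: SynapseState, dt: float, spikes=()) -> SynapseState:
    """Advance a synapse state by ``dt`` ms with spikes arriving in [t, t+dt).

    The update is the exact solution of the two uncoupled linear ODEs, with
    each spike applied at its exact offset inside the step: the result
    matches :func:`conductance_waveform` to machine precision for any dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = s.params
    inc = p.weight * p.g0 * p.norm
    A, B, t0 = s.A, s.B, s.t
    cursor = t0
    for ts in sorted(np.atleast_1d(spikes)) if len(np.atleast_1d(spikes)) else []:
        if not (t0 <= ts < t0 + dt):
            raise ValueError(f"spike at {ts} outside step [{t0}, {t0 + dt})")
        lag = ts - cursor
        A *= math.exp(-lag / p.tau_d)
        B *= math.exp(-lag / p.tau_r)
        A += inc
        B += inc
        cursor = ts
    lag = t0 + dt - cursor
    A *= math.exp(-lag / p.tau_d)
    B *= math.exp(-lag / p.tau_r)
    return SynapseState(params=p, A=A, B=B, t=t0 + dt)


def synaptic_current(g_nS: float, vm_mV: float, e_rev_mV: float = 0.0):
    """Synaptic current I = g·(Vm − E), returned in nA (nS × mV = pA × 1e-3).

    With E = 0 mV and Vm < 0 the current is negative, i.e. inward and
    depolarizing under the usual membrane sign convention.
    """
    return np.asarray(g_nS) * (np.asarray(vm_mV) - e_rev_mV) * 1e-3


def scaled_params(base: BiExpParams, factor: float) -> BiExpParams:
    """Variant parameters: peak conductance multiplied by ``factor``."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return replace(base, g0=base.g0 * factor)


# ---------------------------------------------------------------------------
# Variant conductance table
# ---------------------------------------------------------------------------

_DEFAULT_TABLE_CSV = """\
variant,g_MD_pS,stderr_pS
Wild-Type,10.2,4.6
Q586R,3.3,1.3
Q586G,11.7,5.4
Q586E.0,92.4,18.3
Q586E.1,19.8,6.2
Q586E.2,19.8,9.8
"""


def coarse_round(x: float) -> int:
    """Coarse integer rounding used to pick simulation scaling factors.

    Below 10: nearest integer with half-integer ties rounded down
    (3.5 → 3).  10 and above: nearest multiple of ten with the same tie
    rule (28 → 30).
    """
    if x < 10:
        return int(math.ceil(x - 0.5))
    return 10 * int(math.ceil(x / 10 - 0.5))


class VariantTable:
    """Per-variant mean single-channel conductances and derived scaling factors."""

    def __init__(self, df: pd.DataFrame, baseline: str = "Q586R"):
        required = {"variant", "g_MD_pS", "stderr_pS"}
        if not required.issubset(df.columns):
            raise ValueError(f"variant table needs columns {sorted(required)}")
        if baseline not in set(df["variant"]):
            raise ValueError(f"baseline {baseline!r} not in table")
        if (df["g_MD_pS"] <= 0).any():
            raise ValueError("all g_MD values must be > 0")
        self.df = df.reset_index(drop=True)
        self.baseline = baseline

    @classmethod
    def default(cls) -> "VariantTable":
        """Bundled table of MD-averaged conductances for GluA2 variants."""
        return cls(pd.read_csv(io.StringIO(_DEFAULT_TABLE_CSV)))

    @classmethod
    def from_csv(cls, path, baseline: str = "Q586R") -> "VariantTable":
        return cls(pd.read_csv(path), baseline=baseline)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def g_md(self, variant: str) -> float:
        row = self.df.loc[self.df.variant == variant]
        if row.empty:
            raise KeyError(f"unknown variant {variant!r}")
        return float(row["g_MD_pS"].iloc[0])

    def scaling_factor(self, variant: str) -> tuple[float, int]:
        """(one-decimal factor, coarse integer factor) relative to the baseline."""
        ratio = self.g_md(variant) / self.g_md(self.baseline)
        one_decimal = round(ratio, 1)
        return one_decimal, coarse_round(one_decimal)

    def factors(self) -> pd.DataFrame:
        """Scaling factors for every variant, mirroring the bundled table layout."""
        rows = []
        for v in self.df["variant"]:
            f, c = self.scaling_factor(v)
            rows.append((v, f, c))
        return pd.DataFrame(rows, columns=["variant", "factor", "coarse_factor"])


def scaling_factor(vt: VariantTable, variant: str) -> tuple[float, int]:
    """Module-level convenience wrapper around :meth:`VariantTable.scaling_factor`."""
    return vt.scaling_factor(variant)
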