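# ionspike

Multiscale simulation of how molecular-level changes in ion channels shape
neuronal membrane potentials and spiking. The package is aimed at
computational neuroscientists and biophysicists who want to connect
channel-level quantities — single-channel conductances of receptor
variants, or stochastic gating of voltage-gated channels in a lipid
membrane — to the membrane-potential time course `Vm(t)` of a compartmental
neuron model.

Two pipelines form the core:

1. **Variant excitability.** AMPA-receptor variants (GluA2 Q586R/G/E and
   wild type) are characterized by a mean single-channel conductance
   `g_MD`. Each variant scales a bi-exponential synaptic conductance

       g(t) = g0·N·[exp(−t/τd) − exp(−t/τr)],   [g]_variant = [g]_baseline · g_MD,variant / g_MD,baseline

   (g0 = 3.5 nS, τr = 0.5 ms, τd = 2 ms, E = 0 mV, baseline = the edited
   Q586R form). Ten synapses — clustered within a 50 μm sphere
   ("localized") or spread over the dendritic tree ("distributed") —
   receive 10 Hz Poisson input, correlated or uncorrelated, on a
   compartmental neuron with Hodgkin–Huxley soma, and spikes are counted.
   A calibration step fixes the synaptic weight so the baseline variant is
   silent under uncorrelated input; gain-of-function variants then reveal
   themselves as spiking.

2. **Coupled gating.** A lattice Monte Carlo model of voltage-gated
   Na⁺/K⁺ channels — four allosterically linked voltage sensors per
   channel, embedded in a near-critical two-species lipid mixture with an
   Ising-like energy — exchanges current and voltage with a two-compartment
   cable solver every 0.1 ms: open-channel counts give
   `Im = Σ N_open·γ·(Vm − E)`, which drives the membrane; the updated
   soma voltage feeds back into the gating energies. Replica ensembles
   under an 80 pA current clamp at 40/30/20 °C show how cooling slows
   spike repolarization several-fold while leaving the spike height
   nearly unchanged.

A third module estimates single-channel current and conductance from ion
axial-coordinate tracks by two-plane crossing counting (`g = I/Vm`), the
post-processing used on molecular-dynamics permeation runs.

See `docs/methods.md` for the models, assumptions, and calibration.

## Worked example

```python
>>> from ionspike import VariantTable, BiExpParams, conductance_waveform
>>> vt = VariantTable.default()
>>> vt.scaling_factor("Q586E.0")     # (one-decimal, coarse simulation factor)
(28.0, 30)
>>> p = BiExpParams()                # g0=3.5 nS, τr=0.5 ms, τd=2 ms
>>> float(conductance_waveform([p.t_peak], [0.0], p)[0])
3.5
```

The variant grid end to end (spike counts per conductance factor ×
placement × input statistics; ~10 s):

```python
>>> from ionspike.workflows import variant_excitability
>>> res = variant_excitability(seed=0)
>>> res["spike_counts"].pivot_table(index="factor",
...     columns=["placement", "correlation"], values="spike_count")
placement   distributed               localized
correlation  correlated uncorrelated correlated uncorrelated
factor
1                  12.0          0.0       11.0          0.0
3                  12.0         21.0       12.0         17.0
6                  12.0         29.0       12.0         28.0
30                 12.0         42.0       12.0         36.0
```

The calibrated baseline (factor 1) is silent under uncorrelated input;
a three-fold conductance increase already fires under correlated input;
spike counts grow with the conductance factor.

The same from the command line:

```
ionspike variant-excitability --seed 0 --out results/variants
ionspike coupled-spike --seed 1 --replicas 50 --out results/coupled
ionspike permeation --seed 0 --out results/permeation
ionspike fixtures --out fixtures
```

`coupled-spike` prints, per temperature, the ensemble-median
repolarization time and peak, e.g. (seed 1, 50 replicas): 59.7 ms at
40 °C, 153.1 ms at 30 °C, 386.8 ms at 20 °C — repolarization slows ≈6.5×
from 40 °C to 20 °C while the median spike height changes by ≈5%.

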