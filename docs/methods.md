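# Methods

`ionspike` links molecular-level descriptions of ion channels to neuronal
membrane-potential time courses through two pipelines: (i) receptor-variant
conductance scaling driving a compartmental neuron model to spikes, and
(ii) a lattice Monte Carlo (MC) model of voltage-gated Na⁺/K⁺ channel
gating in a two-species lipid membrane, coupled bidirectionally to a
cable/Hodgkin–Huxley (HH) solver. A third, independent module estimates
single-channel conductance from ion-permeation counting. This note
documents the models, their assumptions, the defaults that matter, and
what the synthetic-data generators do and do not emulate.

## Synaptic conductance and variant scaling

The effective synaptic conductance after a presynaptic spike at time
`ts` is the normalized difference of exponentials

    g(t) = g0 · N · [exp(−(t−ts)/τd) − exp(−(t−ts)/τr)],  t ≥ ts,

with defaults g0 = 3.5 nS, τr = 0.5 ms, τd = 2 ms and reversal E = 0 mV.
The raw difference of exponentials is negative for τr < τd and does not
peak at g0; because g0 is defined as the *peak* conductance, we use the
standard normalization N = 1/[exp(−tp/τd) − exp(−tp/τr)] with the sign
giving a positive transient, where tp = τr·τd/(τd−τr)·ln(τd/τr) is the
peak time (≈ 0.9242 ms for the defaults). Responses superpose linearly;
the solver integrates each synapse as two exponentially decaying states
(g = A − B) with *exact* updates, including events at their true sub-step
offsets, so stepping reproduces the closed form to machine precision at
any step size.

Receptor variants scale the baseline waveform by the ratio of their mean
single-channel conductance to the baseline (Q586R-edited) form,
`g_MD,variant / g_MD,baseline`. The bundled table covers the wild-type
and Q586R/G/E GluA2 forms; factors are reported both at one decimal and
as the coarse integers used for simulation grids. The coarse rule is:
below ten, nearest integer with half-integer ties rounded down; ten and
above, nearest multiple of ten — this reproduces every printed coarse
factor in the bundled table.

A synaptic `weight` multiplies each event's conductance increment. A
literature value for this weight is stated in units (μS) inconsistent
with the nS-scale peak conductance, so the weight is treated as a
dimensionless multiplier and *calibrated*: bisection (on a log scale)
finds the weight at which the baseline variant's peak depolarization
touches the spike threshold under uncorrelated input, and 0.9× that
weight is used. This realizes the stated intent of the calibration — the
baseline is silent under uncorrelated 10 Hz input, so gain-of-function
variants reveal themselves as spiking.

## Morphologies and input statistics

Morphologies are SWC trees; multiple soma contour rows are merged into a
single root node (centroid, mean radius) — a common dialect decision.
Synthetic fixtures stand in for a reconstructed pyramidal cell: a
ball-and-stick cell, and a random binary tree whose default depth and
segment lengths give an apical tree several hundred μm tall (the real
cell fits a ~1300 μm cylinder; the soma height default is 20 μm).

"Random segment" sampling is uniform over segment *count*, not
length-weighted, because the measure is not otherwise pinned down; the
region filter defaults to all dendrite types with an apical-only option.
Localized (clustered) placement picks a random dendritic centre segment
and samples without replacement among segments whose *midpoints* lie
within a 50 μm sphere of the centre midpoint, falling back to replacement
(logged) when the candidate set is small. Point-in-sphere on midpoints is
a deliberate simplification for extended segments.

Inputs are homogeneous Poisson trains (conditional-uniform construction).
"Correlated" input is a single mother train shared identically by all
sites — the strongest correlation consistent with a shared-source
interpretation — with an optional per-site Gaussian jitter. Uncorrelated
sites draw from disjoint child streams of the seed. The default window is
1000 ms.

## Cable solver

The neurite tree is discretized into cylinders (compartments ≤ a length
bound, default 40 μm) with specific capacitance 1 μF/cm², axial
resistivity 100 Ω·cm, and per-compartment mechanisms: leak everywhere
and, where configured, classic HH Na/K kinetics (g̅Na = 120, g̅K = 36,
g̅leak = 0.3 mS/cm², ENa = 50, EK = −77, Eleak = −54.3 mV) with a Q10 = 3
factor on rates relative to the 6.3 °C reference. Integration is the
staggered implicit scheme: Rush–Larsen exponential gate updates at the
pre-step voltage, membrane conductances evaluated at the step midpoint,
and a θ-implicit voltage solve (Crank–Nicolson, θ = 0.5, by default;
backward Euler via θ = 1) using Hines elimination on the tree, O(n) per
step. Default dt = 0.025 ms; initial voltage −65 mV; gates start at
steady state.

Verification: passive step responses match the RC closed form to
< 0.1 mV; an HH soma under an 80 pA step reproduces the spike count and
spike times (±0.05 ms) of an adaptive high-accuracy integration of the
same equations. Spike detection is upward threshold crossing (default
−50 mV, inside the −53…−45 mV range typical of pyramidal cells) with
linear interpolation and a 2 ms refractory separation.

## Lattice Monte Carlo of voltage-gated channels

A periodic L×L lattice (default L = 64) holds saturated/unsaturated
lipids (50/50) and channel footprints (2×2 sites; 30 Na and 20 K channels
by default). Each channel carries four two-state voltage sensors; it
conducts when all four are activated. The Hamiltonian, in kT units at
T_ref = 30 °C:

* **gating**: −q_s·(Vm − V_half)/kT_mV per activated sensor
  (q_s = 2 e; V_half,Na = −40 mV, V_half,K = −30 mV);
* **allosteric**: a = 0.5 per unlike sensor pair within a channel
  (all six pairs);
* **channel–lipid interaction**: J_cl(state, species) per lipid in the
  8-site footprint perimeter. Defaults: open–unsaturated −0.2,
  closed–saturated −0.2, others 0, so a channel's state energy depends
  on its local lipid configuration and state changes are damped by an
  adapted halo;
* **lipid–lipid**: −J_ll per like-species bond, J_ll = 0.88, placing the
  50/50 mixture near its demixing point at 30 °C (the exact critical
  coupling is ln(1+√2) ≈ 0.881 in these units): at 20 °C the mixture is
  weakly demixing, at 40 °C weakly mixing.

Moves are Metropolis with acceptance exp(−ΔE·T_ref/T): sensor flips,
Kawasaki exchanges of unlike neighbour lipids (conserving composition),
channel translation by one site (displaced lipids back-fill the vacated
strip), and channel rotation (a cyclic sensor permutation, energy-neutral
under the default Hamiltonian). Na channels additionally carry a slow
inactivation flag — an extension beyond the minimal resting/activated
scheme, included because spike repolarization in the coupled model would
otherwise be leak/K-only. Its energy term mirrors the sensor gating term
with q_inact = 6 e and V_half = −50 mV (steeply favouring inactivation
when depolarized, recovery near rest), and its proposal share in the move
mix (1.5·10⁻⁵) is deliberately small so that inactivation is a
milliseconds-scale process while sensor activation is sub-millisecond,
mirroring the kinetic separation in real channels.

Correctness is enforced by a replay oracle: the production kernel and an
independent plain-Python reference that recomputes the *total*
Hamiltonian for every proposal consume the same uniform-draw stream and
must land in the identical state; equilibrium tests check exact Boltzmann
statistics on enumerable lattices and the two-state sensor sigmoid
(open probability = p⁴) in the decoupled limit.

### Temperature model

Temperature enters the lattice dynamics in two ways. First, Metropolis
acceptance rescales all energies by T_ref/T, which sharpens gating
sigmoids, deepens lipid demixing, and slows uphill transitions as the
bath cools. Second, the sweep-to-time conversion ν (default 10 sweeps/ms
at 30 °C) carries an Arrhenius factor Q10 = 2.8, the same order used for
the HH rate Q10: molecular attempt frequencies slow as the membrane
cools. Both are needed: acceptance-ratio effects alone change kinetics by
tens of percent over a 20 K span, far less than the several-fold slowing
of repolarization the coupled model is calibrated to show; the attempt
rate supplies the bulk of the slow-down and the lipid/Boltzmann terms
modulate it.

## Bidirectional coupling and the temperature experiment

Per exchange window (Δt_ex = 0.1 ms): the soma voltage enters the MC
gating term; ν(T)·Δt_ex sweeps run; the window-averaged open counts give
the patch current Im = ΣN_open·γ·(Vm − E) (γ = 20 pS, ENa = +50 mV,
EK = −77 mV, outward-positive sign); −Im, scaled by a patch-to-cell
factor of 50 (one lattice channel standing for a cluster of 50 on the
whole cell), is injected into the soma; the solver advances Δt_ex.
Window-averaged rather than endpoint current reduces exchange noise, and
halving Δt_ex moves the median peak by < 2 mV. With zero channels the
loop is bit-identical to the standalone solver.

The cell is a passive soma (20×20 μm) plus dendrite (100×1.5 μm), leak
0.2 mS/cm² at −65 mV — the active Na/K currents come entirely from the
lattice patch. The protocol is an 80 pA, 10 ms current clamp from 5 ms.
Lipids are pre-equilibrated for 400 sweeps at the run temperature before
t = 0. Ensembles repeat the run with different MC seeds (spawned
deterministically from a base seed) and aggregate as the pointwise median
with a first/third-quartile envelope. Spike-shape metrics per replica:
peak of the first spike, repolarization time (peak until the voltage
first returns within 5 mV of rest), width (time above threshold); traces
without a spike carry an explicit no-spike marker. Spike *height* is
measured from the −65 mV rest when comparing peaks across temperatures.

The default parameter set is a *calibrated* set: the literature defers
the lattice parameter values to earlier work, so the defaults above were
chosen so that (i) the 80 pA clamp reliably elicits a spike at all three
temperatures, (ii) the median spike height varies by < 10% across
40/30/20 °C, and (iii) the 20 °C/40 °C median repolarization ratio falls
in the several-fold (≈ 5–6×) range, with repolarization time strictly
increasing as temperature falls. Recording windows grow as temperature
drops (150/350/650 ms at 40/30/20 °C) so the slower cold-temperature
repolarization is fully captured. The mechanism of the slow-down in the
model: the spike plateau ends when Na channels inactivate; the
inactivation clock scales with the Arrhenius attempt rate, and its
effective barrier is raised at low temperature by the stiffened
Boltzmann factor and by open-state stabilization from the lipid halo,
while the peak height, set by the quasi-equilibrium balance of the fully
recruited conductances, is nearly temperature-independent.

## Permeation counting

A permeation event is a full traversal of the membrane slab
[z_lower, z_upper]: the ion must enter from one side and exit on the
other (+1 upward, −1 downward); partial entries and oscillation inside
the slab count zero, and a jump between the two outside regions without
visiting the slab is treated as recycling (a periodic-image wrap) and not
counted. Current is I = net·q·e/duration and conductance g = I/Vm. The
synthetic track generator composes deliberate traversals, feints, and
recycling jumps with bounded noise, so the ground-truth count is known by
construction rather than measured — the counter is tested against both
this ground truth and an independent event-scan reference.

## Synthetic data: what it does and does not emulate

The generators provide morphologies with realistic gross scale but not
reconstructed anatomy; Poisson inputs without rate adaptation or
network structure; lattice membranes with two lipid species and rigid
2×2 channels rather than molecular detail; and ion tracks with idealized
traversal statistics. Passing tests therefore demonstrate the internal
consistency and calibration of the framework — not that a particular
biological cell or channel would show the same numbers. In particular
the variant grid's spike counts depend on the synthetic cell and the
calibrated weight, and only their qualitative ordering (silent baseline,
spiking gain-of-function variants, monotone counts in the conductance
factor) is meaningful.

## Numerical choices and limitations

* Solver: Crank–Nicolson default, dt = 0.025 ms (0.0025 ms in
  oracle-grade comparisons); exact exponential synapse and gate updates;
  voltage instabilities raise an error naming compartment and time.
* MC: all randomness flows from a single integer seed through spawned
  child streams; kernel runs are reproducible bit-for-bit given
  (state, seed).
* Ties in Metropolis: |ΔE| < 10⁻⁹ kT is treated as downhill so that
  exact-zero proposals do not consume acceptance draws (keeps the replay
  oracle exact across implementations).
* Ensemble medians of repolarization are computed over replicas with a
  detected spike; windows are sized so that in practice all replicas
  repolarize within the trace.
* No calcium dynamics, plasticity, networks, NMDA/GABA kinetics,
  receptor desensitization, or trajectory-format parsing; the coupled
  cell is deliberately two compartments.
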