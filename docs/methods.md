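# Methods

## Model

All biological cells are conductance-based leaky integrate-and-fire neurons.
Sub-threshold dynamics follow

    τ_m dv/dt = (v_rest − v) + ĝ_e (E_exc − v) + ĝ_i (E_inh − v) + î

where ĝ = g·τ_m/C_m is the synaptic conductance normalized by the leak
conductance (dimensionless) and î = I_offset·τ_m/C_m (mV).  Both conductances
decay exponentially (dĝ/dt = −ĝ/τ_syn) and jump by a normalized weight on
each afferent spike.  Reversal potentials are E_exc = 0 mV and
E_inh = −90 mV for every cell type.  When v reaches v_thresh the neuron
emits a spike, v is clamped to v_reset for τ_refract, and conductances keep
evolving.  Cell constants (C_m, I_offset, τ_m, τ_refract, τ_syn_E, τ_syn_I,
v_reset, v_rest, v_thresh) are the published per-type values, in PyNN units
(nF, nA, ms, mV, µS); `model.canonical_model()` is the single source of
truth and can be exported/overridden as JSON.

Glomeruli are spike relays: they emit prescribed trains and never integrate.

## Numerical scheme

State advances on a Δt = 0.1 ms clock by exact integration: with
conductances frozen over an interval h, the membrane equation is linear and
solved in closed form via

    v_∞ = (v_rest + ĝ_e E_exc + ĝ_i E_inh + î)/(1 + ĝ_e + ĝ_i),
    v(h) = v_∞ + (v − v_∞)·exp(−h (1 + ĝ_e + ĝ_i)/τ_m).

Because conductances are *not* constant within a step, each Δt is split into
N_sc sub-cycles of h = Δt/N_sc.  A sub-cycle decays the conductances by h/2,
propagates the membrane over h, then decays by the remaining h/2 — midpoint
sampling of the decaying conductance, which makes the frozen-conductance
approximation second-order accurate.  With the simpler decay-then-propagate
order, a step's input is only seen after a full e^(−h/τ_syn) decay; for the
fastest synapses here (τ_syn_E = 0.5 ms = 5h at N_sc = 1) that under-weights
input by ~5% and shifts threshold crossings by whole timesteps.  With
midpoint sampling and the default N_sc = 2, the solver's first-spike step
matches a continuous-time adaptive-ODE reference (scipy `solve_ivp`,
rtol 1e−8, event detection) exactly on all sixteen single-projection
single-spike tests; the test suite enforces agreement within one timestep.

Thresholds are checked once per full Δt (after the last sub-cycle), so
spike times are resolved at timestep granularity.  The refractory clamp
lasts round(τ_refract/Δt) timesteps, ties rounding up.  Membrane potentials
are initialized at v_rest.

Spike delivery uses per-neuron circular delay buffers with 64 slots of Δt
(delays up to 6.4 ms; the model's largest printed delay is 5 ms).  Within a
timestep the order is: drain the matured buffer slot into the conductances,
update all neurons, detect spikes, then enqueue the new deliveries.  All
deliveries complete before any neuron update observes them; the model's
minimum delay of 1 ms makes this synchronous order exact.  Delivered and
enqueued conductance totals are tracked so event conservation is assertable.

## Arithmetic back-ends

The same update code runs under two interchangeable back-ends:

* **float64** — the double-precision reference, playing the baseline role.
* **fixed** — emulated s16.15 "accum" arithmetic: after every update stage
  (conductance decay, increment accumulation, membrane propagation) the
  state is rounded to the nearest multiple of 2^−15, ties to even;
  out-of-range values saturate and increment a diagnostic counter that is
  part of every run record (saturation is never silent).  Decay constants
  are quantized once at setup.  This emulates the *precision* of the
  hardware numerics, not any particular device's rounding pipeline;
  bit-exact agreement with hardware is explicitly not claimed.

Synaptic weights in fixed mode pass through a 16-bit codec with a
power-of-two scale: the quantum is the smallest 2^k such that 65,535·2^k
covers the peak per-timestep summed conductance of the target population's
channel (excitatory and inhibitory synapses share a channel accumulator, so
a projection's codec must cover coincident input from *all* projections of
its sign onto that target).  Under the default Poisson protocol the Purkinje
excitatory channel peaks near 1.7 µS — dominated by coincident
ascending-axon spikes at 0.075 µS each — which forces the 2·10⁻⁵ µS
parallel-fiber weight onto a single bit, +52.6% above its prescribed value;
every other weight encodes within 5%.  `bits_required(peak, w_min)` =
log₂(peak/w_min) quantifies the dynamic range a format must span (19.93 bits
for the ~20 µS peak under fully synchronized periodic stimulation).

## Synthetic wiring

The published circuit comes from a scaffold algorithm (bounded
self-avoiding-walk placement, anisotropic proximity wiring) that is not
available; the generator reproduces its statistics instead.  Cells are
placed uniformly inside per-population layer slabs stacked along the 900 µm
axis (deep nuclei 0–100 µm, granular layer 100–550, a thin Purkinje plate
550–580, molecular layer 580–900; the slab thicknesses are package defaults,
used only by spatial stimulus selection and spatial partitioning, both of
which have count-based fallbacks).  Each projection draws exactly its
printed synapse count: `uniform` mode samples source and target
independently (in-degrees are binomial, deviating from the mean by
O(√mean)); `spatial` mode samples the source with probability
exp(−d²/2w²) of the lateral distance to the target (default w = 100 µm),
recovering the uniform mode as w → ∞.  Multiple synapses between a pair are
permitted — dense projections could not otherwise realize exact counts.
Everything is a pure function of (specs, mode, seed).

What this does *not* emulate: the scaffold's over-dispersed in-degree
distributions, its center–surround and other spatial motifs, and mossy-fiber
branching anatomy.  Consequently network-level rates that depend on wiring
correlations (e.g. the exact excited-cell fractions per population) are
reproduced only approximately, and spatial-placement gains in the profiler
are directional rather than exact.  `scale_network(f)` shrinks sizes and
synapse counts together (preserving mean fan-ins of scaled populations);
PC and DCNC keep their printed sizes by default, so their in-degrees shrink
with f — at small scales the diluted PC→DCNC fan-in no longer silences the
deep nuclei, which is expected.

## Stimulation protocol

All 7,073 glomeruli fire 1 Hz Poisson background over the 1 s protocol
(realized as independent per-step Bernoulli draws, at most one spike per
source per step).  From 300 to 350 ms the selected subset fires at f_peak
(default 150 Hz) instead — the burst *replaces* the background for selected
cells; the 1 Hz difference is far below any resolvable tolerance.  Selection
is count-based by default (the 2,915 Gloms nearest the population centroid,
41.21% of the population, pinning the published active count exactly) since
sphere capture depends on the unpublished layer geometry; a sphere mode
(default radius 140 µm) is available.  The `periodic` encoding emits
identical, synchronized, regularly spaced trains on all selected cells.

## Validation statistics

Per-neuron rates are measured in three windows — pre [0, 300), stimulation
[300, 350), post [350, 1000) ms — with every boundary shifted by the
population's input-propagation latency (GrC/GoC 4 ms, PC 6 ms, SC/BC 9 ms,
DCNC 10 ms, Glom 0).  A neuron is *excited* if its stimulation rate at least
doubles its pre rate (a silent-to-active neuron counts as excited — the
doubling rule is vacuous at zero and this choice is isolated in one
predicate), *inhibited* if it falls below half.  Reports give, per
population, the counts of each class and mean ± population-σ rates over the
dominant class.  ISIs and CV = σ(ISI)/mean(ISI) cover the full run (neurons
with fewer than 2/3 spikes are omitted, not zero-filled); cross-run
correlations are Pearson coefficients of 5 ms-binned stimulation-window
counts between matched neurons, omitting zero-variance neurons; the PSTH
bins population spikes at timestep resolution.

## Single-cell experiments

The single-spike test delivers one afferent spike (arriving at t = 10 ms,
connection delay ignored) weighted by one projection to a fresh cell of the
target type, in both arithmetic modes, reporting sub-threshold traces, the
first-spike step and the lead/lag of the 100th spike.  Tonic crossings of
cell types whose current-driven asymptote grazes threshold (the Golgi
asymptote sits 0.17 mV above threshold) are tangential: arbitrarily small
arithmetic differences move those spike times by milliseconds, so
fixed-vs-float agreement is asserted on synaptically driven crossings.

The representative-rate test rebuilds each cell type's published peak
fan-in configuration (afferent source counts over 100 reduced to a tenth at
10× rate) and drives it with Poisson trains for 10 s per seed.  Because all
sources of one projection share rate, weight and delay, the number of spikes
arriving per timestep is Binomial(n_sources, rate·Δt); the engine draws the
per-projection counts directly, which is statistically identical to relaying
the individual sources and far cheaper.  Seeds advance together as a
vectorized batch.

A reproducibility note: the granule and deep-nucleus tests reproduce their
published output rates closely (DCNC to 0.04 Hz), and an independent
continuous-time oracle confirms the solver on every configuration; the
published Golgi-low, stellate/basket and (to ~9%) Purkinje-high output
rates, however, are not consistent with the stated equations and printed
parameters under any interpretation we found — e.g. the published
stellate-high single-cell rate is far below the same paper's network-level
stellate stimulation rate despite the test receiving *more* input.  The
package reports what the stated model actually produces.

## Communication profiling

Neurons map onto abstract cores — 64 per core, except Purkinje cells at 1
per core — by index order, by Morton (z-order) spatial sort, or randomly
permuted (the comparison baseline).  The canonical model occupies exactly
1,583 cores.  A spike is one multicast packet per *distinct* core hosting at
least one of its targets; the profiler records per-core per-timestep counts
and summarizes per-population peak statistics (mean, σ, max, 95th percentile
of per-core maxima).  Router internals (drops, reinjection, DMA contention)
are out of scope; packet counts are the proxy, and the published 41%
peak reduction from spatial placement is treated as directional (the exact
partitioning scheme behind it is unpublished).

## Problem sizes and defaults

Defaults: Δt = 0.1 ms, N_sc = 2, v(0) = v_rest, uniform wiring, Poisson
encoding, nearest-n selection.  The full-size network (96,737 neurons,
4.2 M synapses) runs the 450 ms protocol in well under a minute vectorized;
property-style checks (packet monotonicity, encoding comparisons, placement
comparisons) use 5%-scale networks, and codec peaks are measured on a
20%-scale pilot with pinned-population peaks scaled conservatively by 1/f.
Trace recording is opt-in per neuron subset and guarded against
whole-network requests.
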