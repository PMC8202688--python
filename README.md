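# cerebsim

A desk-scale simulator for a biophysically constrained spiking network model
of the cerebellar microcircuit, with two arithmetic back-ends: a
double-precision reference and an emulated s16.15 fixed-point mode that
mirrors the numerics of digital neuromorphic hardware.  It is aimed at
computational neuroscientists and neuromorphic engineers who want to study
(a) how fixed-point arithmetic and synaptic-weight quantization affect the
dynamics of a realistic cerebellar circuit, and (b) the multicast
communication load such a circuit places on a many-core machine.

## The model

The circuit is a 400 × 400 × 900 µm patch of cerebellar cortex plus its
deep-nucleus targets: 96,737 cells in seven populations — glomeruli (Glom,
input relays), granule cells (GrC, 91% of all cells), Golgi cells (GoC),
stellate and basket cells (SC, BC), Purkinje cells (PC, with ~28,000 parallel
fiber synapses each) and deep-cerebellar-nucleus cells (DCNC) — wired by
sixteen projections totalling ~4.2 million synapses.  Every biological cell
is a conductance-based leaky integrate-and-fire neuron with exponential
synapses:

    τ_m dv/dt = (v_rest − v) + g_exc (E_exc − v) + g_inh (E_inh − v) + I/g_L
    dg/dt     = −g/τ_syn + Σ_i g_syn,i s_i(t − d_i)

with E_exc = 0 mV, E_inh = −90 mV, and conductances normalized by the leak
g_L = C_m/τ_m.  The equations are solved by exact integration (the
closed-form propagator of the linear ODE with frozen conductances) on a
Δt = 0.1 ms clock, with N_sc sub-cycles per step sampling the decaying
conductance at sub-step midpoints.  Spikes travel through per-neuron
64-slot delay ring buffers (delays up to 6.4 ms).

Because the original scaffold's placement and anisotropic wiring algorithm is
not public, the network generator reproduces the circuit's *statistics*
exactly — population sizes, per-projection synapse counts, hence mean
fan-ins — with uniform or distance-dependent (Gaussian-kernel) wiring.

The fixed-point mode quantizes state variables to the signed 16.15 "accum"
format and encodes synaptic weights in 16 bits with a power-of-two scale
covering the peak per-timestep input of the target's conductance channel;
the communication profiler maps neurons onto abstract 64-neuron cores (1 for
PC) and counts multicast packets per core per timestep.

## Worked example

Tonic deep-nucleus activity under its published low-activity afferent
configuration (14 excitatory glomerular sources at 0.92 Hz, 30 Purkinje
inhibitory sources at 47.68 Hz, 10 s of biological time per seed):

```
$ cerebsim run-single-cell DCNC --condition low --seeds 0,1,2,3,4
DCNC low: 15.8 Hz ± 0.1 over 5 seeds
```

The cell's intrinsic rate (injected current alone) would be 25.8 Hz; the
Purkinje inhibition at its resting rate brings it down to ~15.7 Hz, matching
the published value for this test.

A reduced network run (5% scale, 450 ms protocol: 300 ms of 1 Hz background,
then 150 Hz stimulation of the central glomeruli for 50 ms, then 100 ms
post):

```
$ cerebsim run-network --scale 0.05 --duration 450 --seed 1 --out-dir demo
population   cells     subset   count     pct       pre (Hz)      stim (Hz)      post (Hz)
Glom           354    excited     354 100.00%    0.77 ± 1.7   147.74 ± 56.4    1.19 ± 3.3
GrC           4408    excited    2758  62.57%    1.87 ± 2.8    97.27 ± 104.0    3.00 ± 5.6
GoC             11    excited      11 100.00%   25.15 ± 7.2   185.45 ± 82.7   31.25 ± 7.7
SC              30    excited      30 100.00%   28.89 ± 9.4   350.00 ± 39.6   35.53 ± 12.6
BC              30    excited      30 100.00%   30.33 ± 10.4  324.67 ± 58.6   34.80 ± 10.6
PC              69    excited      51  73.91%   37.45 ± 1.6   124.71 ± 32.3   37.55 ± 5.3
DCNC            12    excited       0   0.00%    0.00 ± 0.0     0.00 ± 0.0     0.00 ± 0.0
outputs in demo/
```

Each row gives the excited (or inhibited) subset of a population — cells
whose stimulation-window rate at least doubles (or falls below half of) the
pre-stimulation rate, with per-population latency-shifted windows — and its
mean rate per window.  The granule layer responds to the burst (1.9 → 97 Hz),
the inhibitory interneurons and Purkinje cells follow, and spiking returns
to baseline afterwards.  At full scale (`--scale 1`, ~25 s of wall time)
Purkinje bursting silences all 12 deep-nucleus cells during stimulation;
at 5% scale the diluted PC→DCNC fan-in no longer can, which is why the DCNC
row is empty here.

The `profile-comms` subcommand reports peak multicast packets per core, and
`run-single-spike` compares the two arithmetic back-ends on one afferent
spike.

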