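"""Clock-driven network simulation with delay-buffered spike delivery.

The engine advances the whole network on a fixed 0.1 ms clock.  Each neuron
owns a circular delay buffer of 64 slots (one per timestep, so delays up to
6.4 ms): when a source spikes at step t, its weight is accumulated into slot
(t + d) of every target's buffer, and the slot maturing at a given step is
drained into the target's synaptic conductance before the first sub-cycle of
that step.  Within a step the order is strictly: drain matured slot, update
all neurons (sub-cycled exact integration), detect spikes, then enqueue the
new spikes' deliveries — all deliveries complete before any neuron sees them,
which is safe because the smallest delay in the model is 1 ms.

Relay populations (glomeruli, and the artificial sources of single-cell
tests) occupy the leading global ids; they never integrate, their spikes come
from prescribed input trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Mapping, Sequence

import numpy as np

from . import dynamics
from .dynamics import NeuronState, SimConfig, refractory_steps
from .fixed_point import WeightCodec, normalize_weight, quantize, S16_15
from .model import PopulationSpec, ProjectionSpec
from .network import SynapseList
from .stimulus import SpikeTrainSet

__all__ = [
    "CompiledNetwork",
    "SpikeRaster",
    "RunRecord",
    "compile_network",
    "run",
    "run_single_cell",
    "AfferentSpec",
    "N_DELAY_SLOTS",
]

#: Delay ring size: 64 slots of dt, i.e. delays of at most 6.4 ms at 0.1 ms.
N_DELAY_SLOTS = 64

# trace recording guard: n_recorded * n_steps * 3 floats must stay below this
_TRACE_BUDGET = 5e7


@dataclass
class SpikeRaster:
    """(neuron id, timestep) spike events plus layout metadata.

    The universal currency between engine, analysis and profiler.  ``ids`` and
    ``steps`` are parallel arrays sorted by step; ``pop_slices`` maps each
    population name to its [start, stop) global-id range.
    """

    ids: np.ndarray
    steps: np.ndarray
    dt: float
    n_steps: int
    pop_slices: dict[str, tuple[int, int]]

    def population_events(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(local ids, steps) of one population's spikes."""
        lo, hi = self.pop_slices[name]
        m = (self.ids >= lo) & (self.ids < hi)
        return self.ids[m] - lo, self.steps[m]

    def population_size(self, name: str) -> int:
        lo, hi = self.pop_slices[name]
        return hi - lo

    def write_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# id\ttime_ms\n")
            for i, s in zip(self.ids, self.steps):
                fh.write(f"{i}\t{s * self.dt:.1f}\n")


@dataclass
class RunRecord:
    """Everything one simulation produced: raster, optional traces, diagnostics."""

    raster: SpikeRaster
    config: SimConfig
    traces: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    saturations: int = 0
    delivered_conductance: tuple[float, float] = (0.0, 0.0)
    expected_conductance: tuple[float, float] = (0.0, 0.0)
    seed: int | None = None


@dataclass
class CompiledNetwork:
    """Flattened, simulation-ready network: parameter arrays plus CSR edges."""

    populations: list[PopulationSpec]
    offsets: dict[str, int]
    n_total: int
    n_relay: int
    params: SimpleNamespace          # per-bio-neuron arrays, dynamics-compatible
    indptr: np.ndarray               # CSR over global source id
    edge_tgt: np.ndarray
    edge_w: np.ndarray               # normalized weight magnitude (dimensionless)
    edge_ch: np.ndarray              # 0 = excitatory, 1 = inhibitory
    edge_dsteps: np.ndarray
    dt: float

    @property
    def pop_slices(self) -> dict[str, tuple[int, int]]:
        return {p.name: (self.offsets[p.name], self.offsets[p.name] + p.size)
                for p in self.populations}


def compile_network(populations: Sequence[PopulationSpec],
                    projections: Sequence[ProjectionSpec],
                    synapses: Sequence[SynapseList],
                    sim_config: SimConfig = SimConfig(),
                    codecs: Mapping[str, WeightCodec] | None = None
                    ) -> CompiledNetwork:
    """Flatten populations and edge lists into the engine's internal layout.

    Relay populations (no cell parameters) must precede integrating ones.
    Edge weights are normalized by the target's tau_m / cm at compile time;
    when ``codecs`` is given, each projection's weight is first passed through
    its 16-bit codec, and under the fixed backend the normalized weight is
    additionally quantized to s16.15.
    """
    offsets: dict[str, int] = {}
    n = 0
    n_relay = 0
    seen_bio = False
    for p in populations:
        offsets[p.name] = n
        n += p.size
        if p.params is None:
            if seen_bio:
                raise ValueError("relay populations must precede integrating ones")
            n_relay += p.size
        else:
            seen_bio = True

    dt = sim_config.dt
    params_by_pop = {p.name: p.params for p in populations}

    # per-bio-neuron parameter arrays (attribute names match CellParams)
    n_bio = n - n_relay
    fields = ("cm", "i_offset", "tau_m", "tau_refract", "tau_syn_e",
              "tau_syn_i", "v_reset", "v_rest", "v_thresh", "e_rev_e", "e_rev_i")
    arrays = {f: np.empty(n_bio) for f in fields}
    for p in populations:
        if p.params is None:
            continue
        lo = offsets[p.name] - n_relay
        for f in fields:
            arrays[f][lo:lo + p.size] = getattr(p.params, f)
    params = SimpleNamespace(**arrays)

    # edges: concatenate projections, convert to global ids, sort by source
    srcs, tgts, ws, chs, ds = [], [], [], [], []
    quantize_weights = sim_config.arithmetic == "fixed"
    for syn in synapses:
        pr = syn.projection
        if len(syn) == 0:
            continue
        tgt_params = params_by_pop[pr.target]
        if tgt_params is None:
            raise ValueError(f"projection {pr.name} targets a relay population")
        w_mag = abs(pr.weight)
        if codecs is not None and pr.name in codecs:
            c = codecs[pr.name]
            w_mag = c.decode(c.encode(w_mag))
        w_norm = normalize_weight(w_mag, tgt_params)
        if quantize_weights:
            w_norm = quantize(w_norm, S16_15)
        d_steps = int(round(pr.delay / dt))
        if not (1 <= d_steps <= N_DELAY_SLOTS):
            raise ValueError(
                f"projection {pr.name}: delay {pr.delay} ms outside the "
                f"{N_DELAY_SLOTS}-slot buffer at dt={dt}")
        m = len(syn)
        srcs.append(syn.sources.astype(np.int64) + offsets[pr.source])
        tgts.append(syn.targets.astype(np.int64) + offsets[pr.target])
        ws.append(np.full(m, w_norm))
        chs.append(np.full(m, 1 if pr.inhibitory else 0, dtype=np.int8))
        ds.append(np.full(m, d_steps, dtype=np.int16))

    if srcs:
        src = np.concatenate(srcs)
        order = np.argsort(src, kind="stable")
        src = src[order]
        edge_tgt = np.concatenate(tgts)[order]
        edge_w = np.concatenate(ws)[order]
        edge_ch = np.concatenate(chs)[order]
        edge_dsteps = np.concatenate(ds)[order]
        indptr = np.searchsorted(src, np.arange(n + 1))
    else:
        edge_tgt = np.empty(0, dtype=np.int64)
        edge_w = np.empty(0)
        edge_ch = np.empty(0, dtype=np.int8)
        edge_dsteps = np.empty(0, dtype=np.int16)
        indptr = np.zeros(n + 1, dtype=np.int64)

    return CompiledNetwork(
        populations=list(populations), offsets=offsets, n_total=n,
        n_relay=n_relay, params=params, indptr=indptr, edge_tgt=edge_tgt,
        edge_w=edge_w, edge_ch=edge_ch, edge_dsteps=edge_dsteps, dt=dt)


def _gather_ranges(indptr: np.ndarray, srcs: np.ndarray) -> np.ndarray:
    """Concatenated edge indices for the given source ids (CSR slices)."""
    starts = indptr[srcs]
    lens = indptr[srcs + 1] - starts
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offs = np.repeat(starts - np.concatenate(([0], np.cumsum(lens)[:-1])), lens)
    return np.arange(total, dtype=np.int64) + offs


def run(network: CompiledNetwork,
        input_trains: SpikeTrainSet,
        sim_config: SimConfig = SimConfig(),
        duration: float | None = None,
        record_trace_ids: Sequence[int] = (),
        seed: int | None = None) -> RunRecord:
    """Simulate the network for ``duration`` ms (default: the input length).

    ``input_trains`` drives the relay neurons (ids must be < n_relay).
    ``record_trace_ids`` opts specific global neuron ids into v/g_exc/g_inh
    trace recording (recording everything at full scale is refused — the
    memory guard).  Deterministic given (network, inputs, config).
    """
    dt = network.dt
    if sim_config.dt != dt:
        raise ValueError("sim_config.dt differs from the compiled network's dt")
    n_steps = input_trains.n_steps if duration is None else int(round(duration / dt))
    if input_trains.n_steps < n_steps:
        raise ValueError("input trains shorter than the requested duration")
    if np.any(np.asarray(input_trains.ids) >= network.n_relay):
        raise ValueError("input train ids must address relay neurons")
    if len(record_trace_ids) * n_steps * 3 > _TRACE_BUDGET:
        raise ValueError("trace recording request exceeds the memory guard; "
                         "record fewer neurons or a shorter run")

    backend = sim_config.make_backend()
    n = network.n_total
    n_relay = network.n_relay
    p = network.params

    state = NeuronState(
        v=p.v_rest.copy(),
        g_exc=np.zeros(n - n_relay),
        g_inh=np.zeros(n - n_relay),
        refract_left=np.zeros(n - n_relay, dtype=np.int64),
    )
    h = dt / sim_config.n_sc
    # half-sub-step propagators: step_subcycled samples conductances at the
    # sub-step midpoint (decay h/2, membrane h, decay h/2)
    syn_factors = (dynamics.decay_factor(p.tau_syn_e, h / 2, backend),
                   dynamics.decay_factor(p.tau_syn_i, h / 2, backend))

    buf = np.zeros((N_DELAY_SLOTS, n, 2))
    buf_flat = buf.reshape(-1)

    in_steps = np.asarray(input_trains.steps)
    in_ids = np.asarray(input_trains.ids, dtype=np.int64)
    in_indptr = np.searchsorted(in_steps, np.arange(n_steps + 1))

    trace_ids = np.asarray(sorted(record_trace_ids), dtype=np.int64)
    bio_trace = trace_ids[trace_ids >= n_relay] - n_relay
    traces_v = np.zeros((n_steps, len(bio_trace)))
    traces_ge = np.zeros_like(traces_v)
    traces_gi = np.zeros_like(traces_v)

    out_ids: list[np.ndarray] = []
    out_steps: list[np.ndarray] = []
    delivered = [0.0, 0.0]
    expected = [0.0, 0.0]

    for t in range(n_steps):
        slot = buf[t % N_DELAY_SLOTS]
        inc = slot[n_relay:]
        state.g_exc = backend.q(state.g_exc + inc[:, 0])
        state.g_inh = backend.q(state.g_inh + inc[:, 1])
        delivered[0] += float(inc[:, 0].sum())
        delivered[1] += float(inc[:, 1].sum())
        slot[:] = 0.0

        _, spiked = dynamics.step_subcycled(state, p, dt, sim_config.n_sc,
                                            backend, syn_factors=syn_factors)
        bio_spikers = np.nonzero(spiked)[0] + n_relay

        relay_spikers = in_ids[in_indptr[t]:in_indptr[t + 1]]
        sources = np.concatenate([relay_spikers, bio_spikers])

        if len(sources):
            idx = _gather_ranges(network.indptr, sources)
            if len(idx):
                tgt = network.edge_tgt[idx]
                ch = network.edge_ch[idx].astype(np.int64)
                w = network.edge_w[idx]
                slot_idx = (t + network.edge_dsteps[idx].astype(np.int64)) \
                    % N_DELAY_SLOTS
                flat = (slot_idx * n + tgt) * 2 + ch
                np.add.at(buf_flat, flat, w)
                expected[0] += float(w[ch == 0].sum())
                expected[1] += float(w[ch == 1].sum())
            out_ids.append(sources)
            out_steps.append(np.full(len(sources), t, dtype=np.int64))

        if len(bio_trace):
            traces_v[t] = np.asarray(state.v)[bio_trace]
            traces_ge[t] = np.asarray(state.g_exc)[bio_trace]
            traces_gi[t] = np.asarray(state.g_inh)[bio_trace]

    ids = np.concatenate(out_ids) if out_ids else np.empty(0, dtype=np.int64)
    steps = np.concatenate(out_steps) if out_steps else np.empty(0, dtype=np.int64)
    raster = SpikeRaster(ids=ids, steps=steps, dt=dt, n_steps=n_steps,
                         pop_slices=network.pop_slices)
    traces = {int(gid): {"v": traces_v[:, k], "g_exc": traces_ge[:, k],
                         "g_inh": traces_gi[:, k]}
              for k, gid in enumerate(trace_ids[trace_ids >= n_relay])}
    sat = backend.saturation.count if backend.saturation is not None else 0
    return RunRecord(raster=raster, config=sim_config, traces=traces,
                     saturations=sat,
                     delivered_conductance=tuple(delivered),
                     expected_conductance=tuple(expected), seed=seed)


@dataclass(frozen=True)
class AfferentSpec:
    """One afferent projection of a single-cell test.

    ``n_sources`` Poisson sources fire at ``rate`` Hz; each spike delivers
    ``weight`` (uS, sign selects the conductance channel) after ``delay`` ms.
    """

    name: str
    n_sources: int
    rate: float
    weight: float
    delay: float


def simulate_single_neuron(params, inc_e: np.ndarray, inc_i: np.ndarray,
                           sim_config: SimConfig = SimConfig(),
                           record_traces: bool = False):
    """Drive one cell type with prescribed per-step conductance increments.

    ``inc_e``/``inc_i`` have shape (n_steps, k): k independent realizations
    (e.g. seeds) advance in lock-step as a k-element population.  Increments
    are *normalized* conductances, already scaled by tau_m / cm.  Returns
    (spikes boolean (n_steps, k), traces dict or None, saturation count).
    """
    n_steps, k = inc_e.shape
    backend = sim_config.make_backend()
    state = NeuronState(v=np.full(k, params.v_rest), g_exc=np.zeros(k),
                        g_inh=np.zeros(k), refract_left=np.zeros(k, dtype=np.int64))
    h = sim_config.dt / sim_config.n_sc
    syn_factors = (dynamics.decay_factor(params.tau_syn_e, h / 2, backend),
                   dynamics.decay_factor(params.tau_syn_i, h / 2, backend))
    spikes = np.zeros((n_steps, k), dtype=bool)
    traces = None
    if record_traces:
        traces = {"v": np.zeros((n_steps, k)), "g_exc": np.zeros((n_steps, k)),
                  "g_inh": np.zeros((n_steps, k))}
    for t in range(n_steps):
        state.g_exc = backend.q(state.g_exc + inc_e[t])
        state.g_inh = backend.q(state.g_inh + inc_i[t])
        _, spiked = dynamics.step_subcycled(state, params, sim_config.dt,
                                            sim_config.n_sc, backend,
                                            syn_factors=syn_factors)
        spikes[t] = spiked
        if record_traces:
            traces["v"][t] = state.v
            traces["g_exc"][t] = state.g_exc
            traces["g_inh"][t] = state.g_inh
    sat = backend.saturation.count if backend.saturation is not None else 0
    return spikes, traces, sat


def run_single_cell(params, afferents: Sequence[AfferentSpec],
                    duration: float = 10_000.0,
                    sim_config: SimConfig = SimConfig(),
                    seeds: Sequence[int] = (0,),
                    record_traces: bool = False) -> dict:
    """Representative single-cell test: one neuron under Poisson afferents.

    All sources of one afferent share rate, weight and delay, so the number
    of afferent spikes landing per timestep is Binomial(n_sources, rate*dt);
    the increment streams are drawn per projection per step, which is
    statistically identical to relaying individual sources (at most one spike
    per source per step) and far cheaper.  One independent stream per seed;
    seeds advance together as a vectorized batch.

    Returns a dict with per-seed output ``rates`` (Hz), the spike matrix,
    optional traces and the fixed-mode saturation count.
    """
    dt = sim_config.dt
    n_steps = int(round(duration / dt))
    k = len(seeds)
    inc_e = np.zeros((n_steps, k))
    inc_i = np.zeros((n_steps, k))
    for j, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        for aff in afferents:
            p_spike = aff.rate * dt / 1000.0
            if p_spike >= 1.0:
                raise ValueError(f"afferent {aff.name}: rate too high for "
                                 "per-step Bernoulli sources")
            if p_spike == 0.0 or aff.n_sources == 0:
                continue
            counts = rng.binomial(aff.n_sources, p_spike, size=n_steps)
            w_norm = normalize_weight(abs(aff.weight), params)
            if sim_config.arithmetic == "fixed":
                w_norm = quantize(w_norm, S16_15)
            d = int(round(aff.delay / dt))
            target = inc_i if aff.weight < 0 else inc_e
            if d < n_steps:
                target[d:, j] += counts[:n_steps - d] * w_norm
    spikes, traces, sat = simulate_single_neuron(
        params, inc_e, inc_i, sim_config, record_traces=record_traces)
    rates = spikes.sum(axis=0) / (duration / 1000.0)
    return {"rates": rates, "spikes": spikes, "traces": traces,
            "saturations": sat, "seeds": list(seeds)}


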