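"""Reproducible experiment drivers.

Three experiment families, mirroring the validation pipeline:

* single-spike tests: one target cell per projection receives one afferent
  spike (arriving at t = 10 ms, delay ignored) weighted by that projection,
  run for 10 s of biological time under both arithmetic back-ends; reports
  sub-threshold traces, the first-spike timestep and the lead/lag of the
  100th spike between the back-ends.
* representative single-cell tests: one cell per type is driven by Poisson
  sources at its published peak fan-in configuration, in a "low" and a "high"
  activity condition (afferent counts over 100 are reduced to a tenth with
  10x rates); 10 s per seed, reporting the mean output rate.
* the large-scale run: the full (or scaled) synthetic network under the
  standard stimulation protocol, producing a raster, a validation report and
  optionally packet statistics and cross-mode correlations.

Every experiment is a pure function of (configuration, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from . import analysis, comm
from .dynamics import SimConfig
from .engine import (AfferentSpec, compile_network, run, run_single_cell,
                     simulate_single_neuron, RunRecord)
from .fixed_point import build_codec
from .model import canonical_model
from .network import build_all_synapses, place_cells, scale_network
from .stimulus import StimulusProtocol, build_protocol_input

__all__ = [
    "SINGLE_CELL_TESTS",
    "exp_single_spike",
    "exp_single_cell",
    "exp_large_scale",
    "ExperimentConfig",
    "load_config",
]

# Published single-cell test configurations: per cell type, per afferent:
# (projection name, n_sources, low rate Hz, high rate Hz).  Weights and
# delays come from the canonical projection table.
SINGLE_CELL_TESTS: dict[str, list[tuple[str, int, float, float]]] = {
    "GrC": [("Glom-GrC", 4, 0.92, 144.38),
            ("GoC-GrC", 4, 18.63, 135.13)],
    "GoC": [("Glom-GoC", 11, 9.20, 1443.80),
            ("aa-GoC", 40, 20.50, 895.90),
            ("pf-GoC", 160, 20.50, 895.90),
            ("GoC-GoC", 50, 18.63, 135.13)],
    "SC": [("pf-SC", 137, 20.50, 895.90),
           ("SC-SC", 11, 31.68, 220.75)],
    "BC": [("pf-BC", 134, 20.50, 895.90),
           ("BC-BC", 12, 27.93, 193.04)],
    "PC": [("aa-PC", 27, 20.50, 895.90),
           ("pf-PC", 2919, 20.50, 895.90),
           ("SC-PC", 20, 31.68, 220.75),
           ("BC-PC", 20, 27.93, 193.04)],
    "DCNC": [("Glom-DCNC", 14, 0.92, 144.38),
             ("PC-DCNC", 30, 47.68, 381.82)],
}


def _model_maps():
    pops, projs = canonical_model()
    return ({p.name: p for p in pops}, {p.name: p for p in projs})


def exp_single_spike(projection_name: str, scale: float = 1.0,
                     duration: float = 10_000.0,
                     dt: float = 0.1, n_sc: int = 2) -> dict:
    """Single-spike test for one projection, run in both arithmetic modes.

    A spike carrying the projection's weight (optionally scaled by ``scale``
    to emulate the empirically recorded peak input) arrives at t = 10 ms;
    the connection delay is ignored.  Returns per-mode spike steps, voltage
    traces (first 100 ms), the first-spike step and the lead/lag of the
    100th spike (or the count if fewer than 100 spikes occur).
    """
    pops, projs = _model_maps()
    pr = projs[projection_name]
    params = pops[pr.target].params
    from .fixed_point import normalize_weight, quantize, S16_15
    n_steps = int(round(duration / dt))
    arrival = int(round(10.0 / dt))
    out: dict = {"projection": projection_name, "modes": {}}
    for mode in ("float64", "fixed"):
        cfg = SimConfig(dt=dt, n_sc=n_sc, arithmetic=mode)
        w = normalize_weight(abs(pr.weight) * scale, params)
        if mode == "fixed":
            w = quantize(w, S16_15)
        inc_e = np.zeros((n_steps, 1))
        inc_i = np.zeros((n_steps, 1))
        (inc_i if pr.inhibitory else inc_e)[arrival, 0] = w
        spikes, traces, sat = simulate_single_neuron(
            params, inc_e, inc_i, cfg, record_traces=True)
        steps = np.nonzero(spikes[:, 0])[0]
        out["modes"][mode] = {
            "spike_steps": steps,
            "n_spikes": int(len(steps)),
            "first_spike_step": int(steps[0]) if len(steps) else None,
            "spike_100_step": int(steps[99]) if len(steps) >= 100 else None,
            "v_trace_100ms": traces["v"][:int(100 / dt), 0],
            "saturations": sat,
        }
    a, b = out["modes"]["float64"], out["modes"]["fixed"]
    if a["spike_100_step"] is not None and b["spike_100_step"] is not None:
        out["lead_lag_100th_ms"] = (b["spike_100_step"] - a["spike_100_step"]) * dt
    else:
        out["lead_lag_100th_ms"] = None
        out["note"] = "fewer than 100 spikes"
    if a["first_spike_step"] is not None and b["first_spike_step"] is not None:
        out["first_spike_diff_steps"] = b["first_spike_step"] - a["first_spike_step"]
    return out


def exp_single_cell(cell_type: str, condition: str = "low",
                    seeds: Sequence[int] = (0, 1, 2, 3, 4),
                    duration: float = 10_000.0,
                    sim_config: SimConfig = SimConfig()) -> dict:
    """Representative-rate single-cell test (the published configuration).

    Builds the afferents of ``cell_type`` verbatim — source counts and rates
    from the published table, weights and delays from the projection table —
    runs 10 s of biological time per seed and reports mean +/- sd of the
    output rate across seeds.
    """
    if condition not in ("low", "high"):
        raise ValueError("condition must be 'low' or 'high'")
    if cell_type not in SINGLE_CELL_TESTS:
        raise KeyError(f"no single-cell test for {cell_type!r}")
    pops, projs = _model_maps()
    col = 2 if condition == "low" else 3
    afferents = [
        AfferentSpec(name=row[0], n_sources=row[1], rate=row[col],
                     weight=projs[row[0]].weight, delay=projs[row[0]].delay)
        for row in SINGLE_CELL_TESTS[cell_type]
    ]
    res = run_single_cell(pops[cell_type].params, afferents,
                          duration=duration, sim_config=sim_config,
                          seeds=seeds)
    rates = res["rates"]
    return {
        "cell_type": cell_type,
        "condition": condition,
        "rates": rates,
        "mean_hz": float(rates.mean()),
        "sd_hz": float(rates.std()),
        "seeds": list(seeds),
        "saturations": res["saturations"],
    }


def estimate_memory_bytes(populations, projections) -> int:
    """Rough memory footprint of a compiled network plus its delay buffer."""
    n = sum(p.size for p in populations)
    m = sum(p.n_synapses for p in projections)
    return 64 * n * 2 * 8 + m * 28 + n * 12 * 8


def exp_large_scale(scale: float = 1.0,
                    protocol: StimulusProtocol = StimulusProtocol(),
                    sim_config: SimConfig = SimConfig(),
                    seed: int = 0,
                    wiring: str = "uniform",
                    kernel_width: float = 100.0,
                    with_packets: bool = False,
                    window: analysis.WindowSpec | None = None,
                    memory_limit_bytes: float = 6e9) -> dict:
    """Build the (optionally scaled) synthetic circuit, stimulate, validate.

    Returns the run record, the per-population validation report, and — when
    ``with_packets`` — packet statistics under the index partition.  Refuses
    to start if the estimated memory footprint exceeds ``memory_limit_bytes``.
    """
    pops, projs = canonical_model()
    pops, projs = scale_network(pops, projs, scale)
    need = estimate_memory_bytes(pops, projs)
    if need > memory_limit_bytes:
        raise MemoryError(f"estimated footprint {need/1e9:.1f} GB exceeds the "
                          f"limit; reduce the scale factor")
    rng = np.random.SeedSequence(seed)
    s_place, s_wire, s_stim = [int(np.random.default_rng(s).integers(2**31))
                               for s in rng.spawn(3)]
    positions = place_cells(pops, seed=s_place)
    synapses = build_all_synapses(pops, projs, mode=wiring, seed=s_wire,
                                  positions=positions,
                                  kernel_width=kernel_width)
    net = compile_network(pops, projs, synapses, sim_config)
    if protocol.selection == "nearest_n" and protocol.n_selected > pops[0].size:
        protocol = StimulusProtocol(**{**asdict(protocol),
                                       "n_selected": pops[0].size})
    protocol = StimulusProtocol(**{**asdict(protocol), "seed": s_stim})
    trains, selected = build_protocol_input(protocol, positions["Glom"],
                                            dt=sim_config.dt)
    record = run(net, trains, sim_config, seed=seed)
    if window is None:
        window = analysis.WindowSpec(t_pre=protocol.t_pre,
                                     t_stim=protocol.t_stim,
                                     t_post=protocol.t_post)
    report = analysis.validation_report(record.raster, window)
    out = {"record": record, "report": report, "selected": selected,
           "network": net, "populations": pops, "projections": projs,
           "synapses": synapses, "positions": positions,
           "protocol": protocol, "window": window}
    if with_packets:
        cm = comm.partition(pops, strategy="index")
        out["packets"] = comm.count_packets(record.raster, net, cm)
        out["core_map"] = cm
    return out


def measure_projection_peaks(raster, populations, projections, synapses,
                             scale: float = 1.0) -> dict[str, float]:
    """Peak per-timestep summed conductance (uS) each projection must cover.

    Synapses of one sign share their target's conductance channel, so the
    quantity a weight codec must represent is the peak summed input of the
    whole (target population, channel) accumulator, not of one projection in
    isolation: coincident ascending-axon spikes dominate the excitatory peak
    a Purkinje cell sees, and the tiny parallel-fiber weight must still live
    in the same 16-bit word.  Delays are ignored — they only shift the peak
    in time.  When the raster comes from a network scaled by ``scale`` with
    pinned output populations, peaks onto those populations are multiplied by
    1/scale, a conservative estimate of the full-scale peak (their in-degrees
    shrink with the scale factor).

    Returns, per projection name, the peak of its (target, channel) group.
    """
    pinned = {"PC", "DCNC"}
    sizes = {p.name: p.size for p in populations}
    spikes_by_pop: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    # accumulate weighted per-(target neuron, step) conductance per group
    groups: dict[tuple[str, bool], np.ndarray] = {}
    for syn in synapses:
        pr = syn.projection
        gkey = (pr.target, pr.inhibitory)
        if gkey not in groups:
            # float32 accumulator: peaks need ~3 digits, memory matters here
            groups[gkey] = np.zeros(sizes[pr.target] * raster.n_steps,
                                    dtype=np.float32)
        if pr.source not in spikes_by_pop:
            spikes_by_pop[pr.source] = raster.population_events(pr.source)
        ids, steps = spikes_by_pop[pr.source]
        if len(ids) == 0 or len(syn) == 0:
            continue
        order = np.argsort(syn.sources, kind="stable")
        s_sorted = syn.sources[order]
        t_sorted = syn.targets[order]
        indptr = np.searchsorted(s_sorted, np.arange(sizes[pr.source] + 1))
        starts = indptr[ids]
        lens = indptr[ids + 1] - starts
        total = int(lens.sum())
        if total == 0:
            continue
        offs = np.repeat(starts - np.concatenate(([0], np.cumsum(lens)[:-1])),
                         lens)
        idx = np.arange(total, dtype=np.int64) + offs
        tgt = t_sorted[idx].astype(np.int64)
        stp = np.repeat(steps, lens)
        np.add.at(groups[gkey], tgt * raster.n_steps + stp, abs(pr.weight))
    peaks: dict[str, float] = {}
    group_peak = {k: float(v.max()) if v.size else 0.0
                  for k, v in groups.items()}
    for pr in projections:
        factor = 1.0 / scale if pr.target in pinned else 1.0
        peak = group_peak.get((pr.target, pr.inhibitory), 0.0) * factor
        peaks[pr.name] = max(peak, abs(pr.weight))
    return peaks


def exp_cross_mode(scale: float = 0.1,
                   protocol: StimulusProtocol = StimulusProtocol(),
                   seed: int = 0,
                   n_sc: int = 2) -> dict:
    """Run float64 and fixed modes on identical inputs; correlate spike trains.

    Builds one synthetic network and one input realization, simulates it under
    both arithmetic back-ends, and returns the per-population median Pearson
    correlation of 5 ms-binned stimulation-window spike counts between matched
    neurons, plus both reports.
    """
    pops, projs = canonical_model()
    pops, projs = scale_network(pops, projs, scale)
    rng = np.random.SeedSequence(seed)
    s_place, s_wire, s_stim = [int(np.random.default_rng(s).integers(2**31))
                               for s in rng.spawn(3)]
    positions = place_cells(pops, seed=s_place)
    synapses = build_all_synapses(pops, projs, seed=s_wire)
    if protocol.selection == "nearest_n" and protocol.n_selected > pops[0].size:
        protocol = StimulusProtocol(**{**asdict(protocol),
                                       "n_selected": pops[0].size})
    protocol = StimulusProtocol(**{**asdict(protocol), "seed": s_stim})
    trains, _ = build_protocol_input(protocol, positions["Glom"])
    out: dict = {"modes": {}}
    rasters = {}
    for mode in ("float64", "fixed"):
        cfg = SimConfig(n_sc=n_sc, arithmetic=mode)
        net = compile_network(pops, projs, synapses, cfg)
        rec = run(net, trains, cfg, seed=seed)
        rasters[mode] = rec.raster
        out["modes"][mode] = {
            "report": analysis.validation_report(rec.raster),
            "saturations": rec.saturations,
        }
    window = analysis.WindowSpec(t_pre=protocol.t_pre, t_stim=protocol.t_stim,
                                 t_post=protocol.t_post)
    medians = {}
    for p in pops:
        cc = analysis.correlation(rasters["float64"], rasters["fixed"],
                                  p.name, window=window)
        medians[p.name] = float(np.median(list(cc.values()))) if cc else None
    out["correlation_medians"] = medians
    return out


@dataclass
class ExperimentConfig:
    """A declarative experiment description loadable from JSON or YAML."""

    kind: str                       # single_spike | single_cell | large_scale
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    cell_type: str = "GrC"
    condition: str = "low"
    projection: str = "Glom-GrC"
    scale: float = 1.0
    duration: float = 10_000.0
    dt: float = 0.1
    n_sc: int = 2
    arithmetic: str = "float64"
    f_peak: float = 150.0
    encoding: str = "poisson"
    wiring: str = "uniform"
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seeds must be non-empty")
        if self.kind not in ("single_spike", "single_cell", "large_scale"):
            raise ValueError(f"unknown experiment kind {self.kind!r}")

    def sim_config(self) -> SimConfig:
        return SimConfig(dt=self.dt, n_sc=self.n_sc, arithmetic=self.arithmetic)


def load_config(path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a JSON or YAML file."""
    text = open(path).read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError:
        import yaml
        doc = yaml.safe_load(text)
    return ExperimentConfig(**doc)
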