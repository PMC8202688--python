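"""Validation statistics for network runs.

Quantitative validation is based on per-neuron firing rates in three windows —
pre-stimulation, stimulation, post-stimulation — with every window boundary
shifted by a per-population latency that accounts for spike propagation from
the input (GrC/GoC 4 ms, PC 6 ms, SC/BC 9 ms, DCNC 10 ms, Glom 0).  A neuron
is *excited* when its stimulation-window rate at least doubles its
pre-stimulation rate, *inhibited* when it falls below half of it.  Further
spike-train statistics: inter-spike intervals and their coefficient of
variation over the whole run, Pearson correlation of 5 ms-binned stimulation
window spike counts between matched neurons of two runs, and a PSTH at
timestep resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SpikeRaster

__all__ = [
    "WindowSpec",
    "DEFAULT_SHIFTS",
    "window_rates",
    "classify",
    "isi_cv",
    "correlation",
    "psth",
    "validation_report",
    "format_report",
]

#: Per-population latency shifts (ms) applied to every window boundary.
DEFAULT_SHIFTS = {"Glom": 0.0, "GrC": 4.0, "GoC": 4.0, "PC": 6.0,
                  "SC": 9.0, "BC": 9.0, "DCNC": 10.0}


@dataclass(frozen=True)
class WindowSpec:
    """Analysis windows (ms): [0, pre), [pre, pre+stim), [pre+stim, end)."""

    t_pre: float = 300.0
    t_stim: float = 50.0
    t_post: float = 650.0
    shifts: dict = field(default_factory=lambda: dict(DEFAULT_SHIFTS))

    def bounds(self, population: str, run_end: float
               ) -> tuple[tuple[float, float], ...]:
        """Shifted (pre, stim, post) boundaries clipped to the run end."""
        s = self.shifts.get(population, 0.0)
        edges = (0.0 + s, self.t_pre + s, self.t_pre + self.t_stim + s,
                 self.t_pre + self.t_stim + self.t_post + s)
        clip = lambda x: min(x, run_end)
        return ((clip(edges[0]), clip(edges[1])),
                (clip(edges[1]), clip(edges[2])),
                (clip(edges[2]), clip(edges[3])))


def window_rates(raster: SpikeRaster, window: WindowSpec,
                 population: str) -> np.ndarray:
    """Per-neuron (pre, stim, post) firing rates in Hz, shape (n, 3)."""
    ids, steps = raster.population_events(population)
    n = raster.population_size(population)
    times = steps * raster.dt
    run_end = raster.n_steps * raster.dt
    out = np.zeros((n, 3))
    for k, (t0, t1) in enumerate(window.bounds(population, run_end)):
        if t1 <= t0:
            raise ValueError(f"empty analysis window [{t0}, {t1}) for "
                             f"{population}: run too short")
        m = (times >= t0) & (times < t1)
        counts = np.bincount(ids[m], minlength=n)
        out[:, k] = counts / ((t1 - t0) / 1000.0)
    return out


def classify(rates: np.ndarray) -> np.ndarray:
    """Label each neuron 'excited', 'inhibited' or 'neither'.

    Excited: stimulation rate at least doubles the pre rate (and is nonzero —
    a silent-to-active neuron counts as excited).  Inhibited: stimulation rate
    below half the pre rate.  The partition is exhaustive and exclusive.
    """
    rates = np.asarray(rates)
    pre, stim = rates[..., 0], rates[..., 1]
    excited = (stim >= 2.0 * pre) & (stim > 0)
    inhibited = stim < 0.5 * pre
    out = np.full(pre.shape, "neither", dtype=object)
    out[excited] = "excited"
    out[inhibited] = "inhibited"
    return out


def isi_cv(raster: SpikeRaster, population: str
           ) -> tuple[dict[int, np.ndarray], dict[int, float]]:
    """Per-neuron ISIs (ms) and CV = std(ISI)/mean(ISI) over the full run.

    Neurons with fewer than 2 spikes have no ISI entry; fewer than 3 spikes,
    no CV entry (omitted rather than zero-filled).
    """
    ids, steps = raster.population_events(population)
    order = np.lexsort((steps, ids))
    ids, steps = ids[order], steps[order]
    isis: dict[int, np.ndarray] = {}
    cvs: dict[int, float] = {}
    for nid in np.unique(ids):
        t = steps[ids == nid] * raster.dt
        if len(t) < 2:
            continue
        d = np.diff(t)
        isis[int(nid)] = d
        if len(t) >= 3:
            cvs[int(nid)] = float(d.std() / d.mean())
    return isis, cvs


def correlation(raster_a: SpikeRaster, raster_b: SpikeRaster,
                population: str, bin_width: float = 5.0,
                window: WindowSpec = WindowSpec()) -> dict[int, float]:
    """Pearson correlation of binned stim-window counts per matched neuron.

    Both rasters must describe the same population layout.  Spike times are
    binned at ``bin_width`` ms over the population's shifted stimulation
    window; neurons whose counts have zero variance on either side are
    omitted (the coefficient is undefined there).
    """
    if raster_a.population_size(population) != raster_b.population_size(population):
        raise ValueError("rasters describe different population sizes")
    run_end = min(raster_a.n_steps * raster_a.dt, raster_b.n_steps * raster_b.dt)
    (_, _), (t0, t1), (_, _) = window.bounds(population, run_end)
    edges = np.arange(t0, t1 + bin_width, bin_width)
    out: dict[int, float] = {}
    binned = []
    for raster in (raster_a, raster_b):
        ids, steps = raster.population_events(population)
        times = steps * raster.dt
        m = (times >= t0) & (times < t1)
        n = raster.population_size(population)
        mat = np.zeros((n, len(edges) - 1))
        for nid, tt in zip(ids[m], times[m]):
            mat[nid, min(int((tt - t0) // bin_width), mat.shape[1] - 1)] += 1
        binned.append(mat)
    a, b = binned
    for nid in range(a.shape[0]):
        if a[nid].std() == 0 or b[nid].std() == 0:
            continue
        out[nid] = float(np.corrcoef(a[nid], b[nid])[0, 1])
    return out


def psth(raster: SpikeRaster, population: str,
         bin_width: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Population spike counts per time bin (default: one bin per timestep)."""
    _, steps = raster.population_events(population)
    times = steps * raster.dt
    run_end = raster.n_steps * raster.dt
    edges = np.arange(0.0, run_end + bin_width, bin_width)
    counts, _ = np.histogram(times, bins=edges)
    return counts, edges


def validation_report(raster: SpikeRaster,
                      window: WindowSpec = WindowSpec()) -> dict:
    """Per-population response summary of one experimental trial.

    For each population: counts and fractions of excited and inhibited cells,
    and mean +/- population-std rates per window over the *dominant* subset
    (inhibited when inhibited cells outnumber excited ones — the deep-nucleus
    case — excited otherwise).
    """
    report: dict = {}
    for name in raster.pop_slices:
        rates = window_rates(raster, window, name)
        labels = classify(rates)
        n = len(rates)
        n_exc = int((labels == "excited").sum())
        n_inh = int((labels == "inhibited").sum())
        subset_name = "inhibited" if n_inh > n_exc else "excited"
        sel = labels == subset_name
        entry = {
            "n_cells": n,
            "n_excited": n_exc,
            "n_inhibited": n_inh,
            "frac_excited": n_exc / n,
            "frac_inhibited": n_inh / n,
            "subset": subset_name,
        }
        for k, win in enumerate(("pre", "stim", "post")):
            vals = rates[sel, k]
            entry[f"{win}_hz"] = float(vals.mean()) if len(vals) else 0.0
            entry[f"{win}_sd"] = float(vals.std()) if len(vals) else 0.0
        report[name] = entry
    return report


def format_report(report: dict) -> str:
    """Columnar text rendering of :func:`validation_report`."""
    lines = [f"{'population':<10} {'cells':>7} {'subset':>10} {'count':>7} "
             f"{'pct':>7} {'pre (Hz)':>14} {'stim (Hz)':>14} {'post (Hz)':>14}"]
    for name, e in report.items():
        count = e["n_inhibited"] if e["subset"] == "inhibited" else e["n_excited"]
        pct = 100.0 * count / e["n_cells"]
        lines.append(
            f"{name:<10} {e['n_cells']:>7} {e['subset']:>10} {count:>7} "
            f"{pct:>6.2f}% "
            f"{e['pre_hz']:>7.2f} ± {e['pre_sd']:<4.1f} "
            f"{e['stim_hz']:>7.2f} ± {e['stim_sd']:<4.1f} "
            f"{e['post_hz']:>7.2f} ± {e['post_sd']:<4.1f}")
    return "\n".join(lines)
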