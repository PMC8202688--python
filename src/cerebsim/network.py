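"""Synthetic realization of the cerebellar wiring diagram.

The published circuit is produced by a scaffold algorithm (bounded
self-avoiding-walk placement plus anisotropic proximity wiring) that is not
reproduced here.  Instead this module generates networks that match the
printed *statistics* exactly: population sizes, per-projection synapse counts
(hence mean fan-ins), and cell positions inside the 400 x 400 x 900 um volume.
Two wiring modes are provided: ``uniform`` (sources and targets drawn
uniformly; in-degrees are binomial, deviating from the mean by O(sqrt(mean)))
and ``spatial`` (source choice decays with lateral distance to the target
under a Gaussian kernel, preserving the exact edge count).  Multiple edges
between the same pair are permitted — dense projections could not otherwise
realize their exact counts.

Everything is a pure function of (specs, mode, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .model import PopulationSpec, ProjectionSpec

__all__ = [
    "SynapseList",
    "place_cells",
    "build_synapses",
    "build_all_synapses",
    "scale_network",
    "write_edge_list",
]


@dataclass
class SynapseList:
    """Realized edges of one projection (population-local indices)."""

    projection: ProjectionSpec
    sources: np.ndarray  # int32, len n_synapses
    targets: np.ndarray  # int32, len n_synapses

    def __post_init__(self) -> None:
        if len(self.sources) != len(self.targets):
            raise ValueError("sources and targets must have equal length")

    def __len__(self) -> int:
        return len(self.sources)


def place_cells(populations: Sequence[PopulationSpec],
                seed: int) -> dict[str, np.ndarray]:
    """Uniform-random (x, y, z) positions inside each population's layer slab.

    Deterministic per seed.  Purkinje cells end up in a thin planar slab by
    construction of their layer bounds.
    """
    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    for pop in populations:
        lo = np.array([b[0] for b in pop.layer_bounds])
        hi = np.array([b[1] for b in pop.layer_bounds])
        positions[pop.name] = rng.uniform(lo, hi, size=(pop.size, 3))
    return positions


def build_synapses(projection: ProjectionSpec,
                   populations: Sequence[PopulationSpec],
                   mode: str = "uniform",
                   seed: int = 0,
                   positions: Mapping[str, np.ndarray] | None = None,
                   kernel_width: float = 100.0) -> SynapseList:
    """Draw exactly ``projection.n_synapses`` edges for one projection.

    ``uniform`` draws source and target independently and uniformly.
    ``spatial`` draws the target uniformly and then the source with
    probability proportional to exp(-d^2 / (2 w^2)) of the lateral (x, y)
    distance, with ``kernel_width`` w in um; as w -> inf this reduces to the
    uniform mode.  The spatial mode loops over target neurons and costs
    O(n_sources * n_targets); it is intended for reduced-scale networks.
    """
    sizes = {p.name: p.size for p in populations}
    n_src, n_tgt = sizes[projection.source], sizes[projection.target]
    m = projection.n_synapses
    rng = np.random.default_rng(seed)
    if m == 0:
        empty = np.empty(0, dtype=np.int32)
        return SynapseList(projection, empty, empty.copy())
    if mode == "uniform":
        src = rng.integers(0, n_src, size=m, dtype=np.int32)
        tgt = rng.integers(0, n_tgt, size=m, dtype=np.int32)
        return SynapseList(projection, src, tgt)
    if mode != "spatial":
        raise ValueError(f"unknown wiring mode {mode!r}")
    if positions is None:
        raise ValueError("spatial mode requires cell positions")
    src_xy = positions[projection.source][:, :2]
    tgt_xy = positions[projection.target][:, :2]
    tgt = np.sort(rng.integers(0, n_tgt, size=m)).astype(np.int32)
    counts = np.bincount(tgt, minlength=n_tgt)
    src = np.empty(m, dtype=np.int32)
    pos = 0
    inv_two_w2 = 1.0 / (2.0 * kernel_width * kernel_width)
    for t in range(n_tgt):
        k = counts[t]
        if k == 0:
            continue
        d2 = np.sum((src_xy - tgt_xy[t]) ** 2, axis=1)
        logp = -d2 * inv_two_w2
        p = np.exp(logp - logp.max())
        p /= p.sum()
        src[pos:pos + k] = rng.choice(n_src, size=k, p=p)
        pos += k
    return SynapseList(projection, src, tgt)


def build_all_synapses(populations: Sequence[PopulationSpec],
                       projections: Sequence[ProjectionSpec],
                       mode: str = "uniform",
                       seed: int = 0,
                       positions: Mapping[str, np.ndarray] | None = None,
                       kernel_width: float = 100.0) -> list[SynapseList]:
    """Realize every projection; each gets an independent seed stream."""
    seeds = np.random.SeedSequence(seed).spawn(len(projections))
    return [
        build_synapses(proj, populations, mode=mode,
                       seed=np.random.default_rng(s).integers(2**31),
                       positions=positions, kernel_width=kernel_width)
        for proj, s in zip(projections, seeds)
    ]


def scale_network(populations: Sequence[PopulationSpec],
                  projections: Sequence[ProjectionSpec],
                  factor: float,
                  keep_output_sizes: bool = True
                  ) -> tuple[list[PopulationSpec], list[ProjectionSpec]]:
    """Shrink the circuit for desk-scale runs while preserving its balance.

    Population sizes and synapse counts are both scaled by ``factor`` (minimum
    1), so mean fan-ins of scaled populations are preserved; weights and
    delays are untouched.  PC and DCNC — the small output populations whose
    behavior the large-scale validation targets — keep their printed sizes
    unless ``keep_output_sizes`` is False, in which case their fan-ins shrink
    with the synapse counts.
    """
    if not (0 < factor <= 1):
        raise ValueError("factor must lie in (0, 1]")
    if factor == 1:
        return list(populations), list(projections)
    pinned = {"PC", "DCNC"} if keep_output_sizes else set()
    new_pops = [
        p if p.name in pinned else
        replace(p, size=max(int(round(p.size * factor)), 1))
        for p in populations
    ]
    new_projs = [
        replace(pr, n_synapses=max(int(round(pr.n_synapses * factor)), 1))
        for pr in projections
    ]
    return new_pops, new_projs


def write_edge_list(synapses: SynapseList, path) -> None:
    """Write one projection's edges as columnar text: source target weight delay."""
    pr = synapses.projection
    with open(path, "w") as fh:
        fh.write(f"# {pr.name}: {pr.source} -> {pr.target}, "
                 f"weight {pr.weight} uS, delay {pr.delay} ms\n")
        for s, t in zip(synapses.sources, synapses.targets):
            fh.write(f"{s}\t{t}\t{pr.weight}\t{pr.delay}\n")
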