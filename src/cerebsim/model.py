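"""Canonical cerebellar microcircuit description.

The model is a 0.077 mm^3 patch of mouse cerebellar cortex plus its deep-nucleus
targets: seven populations (glomeruli Glom, granule cells GrC, Golgi cells GoC,
stellate SC, basket BC, Purkinje PC and deep-cerebellar-nucleus cells DCNC)
wired by sixteen projections.  Glomeruli are relay inputs — they emit prescribed
spike trains and never integrate.  All other cells are conductance-based leaky
integrate-and-fire neurons with exponential synapses.

Units follow the PyNN convention: capacitance in nF, currents in nA, times in
ms, potentials in mV, conductances in uS.  The leak conductance is cm / tau_m
(uS) and i_offset / g_leak is therefore in mV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

__all__ = [
    "CellParams",
    "PopulationSpec",
    "ProjectionSpec",
    "canonical_model",
    "mean_fan_in",
    "model_to_json",
    "model_from_json",
    "E_REV_EXC",
    "E_REV_INH",
    "TOTAL_NEURONS",
    "VOLUME_UM",
]

#: Reversal potentials shared by every cell type (mV).
E_REV_EXC = 0.0
E_REV_INH = -90.0

#: Total neuron count of the canonical circuit.
TOTAL_NEURONS = 96_737

#: Tissue volume the circuit occupies, (x, y, z) in micrometres.
VOLUME_UM = (400.0, 400.0, 900.0)


@dataclass(frozen=True)
class CellParams:
    """Membrane and synapse constants of one conductance-based LIF cell type."""

    cm: float          # membrane capacitance, nF
    i_offset: float    # constant injected current, nA
    tau_m: float       # membrane time constant, ms
    tau_refract: float # refractory period, ms
    tau_syn_e: float   # excitatory conductance decay, ms
    tau_syn_i: float   # inhibitory conductance decay, ms
    v_reset: float     # reset potential, mV
    v_rest: float      # resting potential, mV
    v_thresh: float    # spike threshold, mV
    e_rev_e: float = E_REV_EXC
    e_rev_i: float = E_REV_INH

    def __post_init__(self) -> None:
        if min(self.cm, self.tau_m, self.tau_syn_e, self.tau_syn_i) <= 0:
            raise ValueError("cm, tau_m and synaptic time constants must be positive")
        if self.tau_refract < 0:
            raise ValueError("tau_refract must be non-negative")
        if not (self.v_reset <= self.v_rest < self.v_thresh):
            raise ValueError("require v_reset <= v_rest < v_thresh")

    @property
    def g_leak(self) -> float:
        """Leak conductance cm / tau_m in uS."""
        return self.cm / self.tau_m


@dataclass(frozen=True)
class PopulationSpec:
    """One neural population: size, cell constants and the slab it occupies.

    ``layer_bounds`` is an axis-aligned box ((x0, x1), (y0, y1), (z0, z1)) in
    micrometres.  Glomeruli carry no ``params`` — they relay input spikes.
    """

    name: str
    size: int
    params: CellParams | None
    layer_bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("population size must be >= 1")
        if self.name == "Glom" and self.params is not None:
            raise ValueError("Glom is a spike relay and carries no cell parameters")


@dataclass(frozen=True)
class ProjectionSpec:
    """One named projection: shared weight, delay, and exact synapse count.

    A negative weight marks an inhibitory projection (accumulates into g_inh);
    positive weights accumulate into g_exc.
    """

    name: str
    source: str
    target: str
    weight: float      # uS; sign encodes E/I
    delay: float       # ms
    n_synapses: int

    def __post_init__(self) -> None:
        if not (0.0 < self.delay <= 6.4):
            raise ValueError("delay must lie in (0, 6.4] ms (64 slots of 0.1 ms)")
        if self.n_synapses < 0:
            raise ValueError("n_synapses must be non-negative")

    @property
    def inhibitory(self) -> bool:
        return self.weight < 0


# Default layer slabs stacked along the 900 um axis.  Only the z extent is
# constrained by the tissue: deep nuclei below, then the granular layer
# (Glom, GrC, GoC), the thin Purkinje plate, and the molecular layer (SC, BC).
# The per-layer thicknesses are package defaults, not measured anatomy; they
# matter only for spatial stimulus selection and spatial core partitioning.
_XY = ((0.0, 400.0), (0.0, 400.0))
_LAYER_Z = {
    "DCNC": (0.0, 100.0),
    "Glom": (100.0, 550.0),
    "GrC": (100.0, 550.0),
    "GoC": (100.0, 550.0),
    "PC": (550.0, 580.0),
    "SC": (580.0, 900.0),
    "BC": (580.0, 900.0),
}

_CELL_PARAMS = {
    #        cm      i_off   tau_m  t_ref  tsE   tsI   v_res  v_rest v_thr
    "GrC": (0.003, 0.0, 2.0, 1.5, 0.5, 10.0, -84.0, -74.0, -42.0),
    "GoC": (0.076, 0.0368, 21.0, 2.0, 0.5, 10.0, -75.0, -65.0, -55.0),
    "SC": (0.0146, 0.0156, 14.6, 1.6, 0.64, 2.0, -78.0, -68.0, -53.0),
    "BC": (0.0146, 0.0156, 14.6, 1.6, 0.64, 2.0, -78.0, -68.0, -53.0),
    "PC": (0.62, 0.6, 88.0, 0.8, 0.5, 1.6, -72.0, -62.0, -47.0),
    "DCNC": (0.089, 0.0558, 57.0, 3.7, 7.1, 13.6, -69.0, -59.0, -48.0),
}

_POP_SIZES = {
    "Glom": 7_073,
    "GrC": 88_158,
    "GoC": 219,
    "SC": 603,
    "BC": 603,
    "PC": 69,
    "DCNC": 12,
}

# name, source, target, weight (uS), delay (ms), n_synapses
_PROJECTIONS = [
    ("Glom-GrC", "Glom", "GrC", 9.0e-3, 4.0, 352_474),
    ("Glom-GoC", "Glom", "GoC", 2.0e-3, 4.0, 14_302),
    ("Glom-DCNC", "Glom", "DCNC", 0.006e-3, 4.0, 1_763),
    ("aa-GoC", "GrC", "GoC", 20.0e-3, 2.0, 79_072),
    ("pf-GoC", "GrC", "GoC", 0.4e-3, 5.0, 350_399),
    ("pf-SC", "GrC", "SC", 0.2e-3, 5.0, 615_177),
    ("pf-BC", "GrC", "BC", 0.2e-3, 5.0, 604_489),
    ("aa-PC", "GrC", "PC", 75.0e-3, 2.0, 17_256),
    ("pf-PC", "GrC", "PC", 0.02e-3, 5.0, 1_957_902),
    ("GoC-GrC", "GoC", "GrC", -5.0e-3, 2.0, 206_092),
    ("GoC-GoC", "GoC", "GoC", -8.0e-3, 1.0, 7_395),
    ("SC-SC", "SC", "SC", -2.0e-3, 1.0, 2_411),
    ("SC-PC", "SC", "PC", -8.5e-3, 2.0, 1_379),
    ("BC-BC", "BC", "BC", -2.5e-3, 4.0, 2_411),
    ("BC-PC", "BC", "PC", -9.0e-3, 4.0, 1_379),
    ("PC-DCNC", "PC", "DCNC", -0.03e-3, 4.0, 314),
]

POPULATION_ORDER = ("Glom", "GrC", "GoC", "SC", "BC", "PC", "DCNC")


def canonical_model() -> tuple[list[PopulationSpec], list[ProjectionSpec]]:
    """Return the seven populations and sixteen projections of the circuit.

    Population sizes, cell constants, projection weights, delays and exact
    synapse counts are the published values of the scaffold-derived model;
    the total is 96,737 neurons and ~4.2 million synapses.
    """
    populations = []
    for name in POPULATION_ORDER:
        params = None if name == "Glom" else CellParams(*_CELL_PARAMS[name])
        bounds = (_XY[0], _XY[1], _LAYER_Z[name])
        populations.append(
            PopulationSpec(name=name, size=_POP_SIZES[name], params=params,
                           layer_bounds=bounds)
        )
    projections = [ProjectionSpec(*row) for row in _PROJECTIONS]
    return populations, projections


def mean_fan_in(pop_name: str,
                projections: Sequence[ProjectionSpec],
                populations: Sequence[PopulationSpec] | None = None) -> float:
    """Mean number of afferent synapses per neuron of a population.

    Sums ``n_synapses`` over projections targeting ``pop_name`` and divides by
    the population size.  Glomeruli receive nothing and are rejected.
    """
    if populations is None:
        populations, _ = canonical_model()
    sizes = {p.name: p.size for p in populations}
    if pop_name not in sizes:
        raise KeyError(f"unknown population {pop_name!r}")
    if pop_name == "Glom":
        raise ValueError("Glom is an input relay with no afferent synapses")
    total = sum(p.n_synapses for p in projections if p.target == pop_name)
    return total / sizes[pop_name]


def model_to_json(populations: Sequence[PopulationSpec],
                  projections: Sequence[ProjectionSpec]) -> str:
    """Serialize the model constants to a JSON string (round-trippable)."""
    doc = {
        "populations": [asdict(p) for p in populations],
        "projections": [asdict(p) for p in projections],
    }
    return json.dumps(doc, indent=2)


def model_from_json(text: str) -> tuple[list[PopulationSpec], list[ProjectionSpec]]:
    """Rebuild model constants from :func:`model_to_json` output.

    Experiments may edit the JSON to override any parameter before loading.
    """
    doc = json.loads(text)
    pops = []
    for p in doc["populations"]:
        params = None if p["params"] is None else CellParams(**p["params"])
        bounds = tuple(tuple(b) for b in p["layer_bounds"])
        pops.append(PopulationSpec(name=p["name"], size=p["size"], params=params,
                                   layer_bounds=bounds))
    projs = [ProjectionSpec(**p) for p in doc["projections"]]
    return pops, projs
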