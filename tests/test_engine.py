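"""Engine: delay bookkeeping, delivery conservation, determinism, modes."""

import numpy as np
import pytest

from cerebsim.dynamics import SimConfig
from cerebsim.engine import (AfferentSpec, compile_network, run,
                             run_single_cell)
from cerebsim.model import PopulationSpec, ProjectionSpec, canonical_model
from cerebsim.network import SynapseList
from cerebsim.stimulus import SpikeTrainSet


def _relay(name, size, bounds=((0, 400), (0, 400), (100, 550))):
    return PopulationSpec(name, size, None, bounds)


def _trains(ids, steps, n_sources, n_steps, dt=0.1):
    ids = np.asarray(ids, dtype=np.int64)
    steps = np.asarray(steps, dtype=np.int64)
    order = np.argsort(steps, kind="stable")
    return SpikeTrainSet(ids[order], steps[order], n_sources, dt, n_steps)


@pytest.fixture()
def tiny_net(pop_map, proj_map):
    """One Glom relay feeding one GrC through a single 4 ms synapse."""
    glom = _relay("Glom", 1)
    grc = PopulationSpec("GrC", 1, pop_map["GrC"].params,
                         pop_map["GrC"].layer_bounds)
    pr = ProjectionSpec("Glom-GrC", "Glom", "GrC", 9.0e-3, 4.0, 1)
    syn = SynapseList(pr, np.array([0], dtype=np.int32),
                      np.array([0], dtype=np.int32))
    return compile_network([glom, grc], [pr], [syn])


class TestDelivery:
    def test_no_input_no_spikes(self, tiny_net):
        trains = _trains([], [], 1, 1000)
        rec = run(tiny_net, trains)
        _, steps = rec.raster.population_events("GrC")
        assert len(steps) == 0  # GrC has no injected current

    def test_delay_bookkeeping_exact(self, tiny_net):
        """A 4 ms synapse changes the target's g_exc exactly 40 steps later."""
        trains = _trains([0], [10], 1, 200)
        rec = run(tiny_net, trains, record_trace_ids=[1])
        ge = rec.traces[1]["g_exc"]
        assert np.all(ge[:50] == 0.0)
        assert ge[50] > 0.0

    def test_delivery_conservation(self, pop_map, proj_map):
        """Injected conductance equals sum of |weight| over delivered spikes."""
        glom = _relay("Glom", 10)
        grc = PopulationSpec("GrC", 20, pop_map["GrC"].params,
                             pop_map["GrC"].layer_bounds)
        pr = ProjectionSpec("Glom-GrC", "Glom", "GrC", 9.0e-3, 4.0, 60)
        rng = np.random.default_rng(0)
        syn = SynapseList(pr, rng.integers(0, 10, 60).astype(np.int32),
                          rng.integers(0, 20, 60).astype(np.int32))
        net = compile_network([glom, grc], [pr], [syn])
        # all input spikes early; run long enough to mature every buffer slot
        trains = _trains(np.arange(10), np.arange(10), 10, 500)
        rec = run(net, trains)
        assert rec.delivered_conductance[0] == pytest.approx(
            rec.expected_conductance[0])
        assert rec.expected_conductance[1] == 0.0

    def test_inhibitory_channel_selected_by_sign(self, pop_map):
        glom = _relay("Glom", 1)
        grc = PopulationSpec("GrC", 1, pop_map["GrC"].params,
                             pop_map["GrC"].layer_bounds)
        pr = ProjectionSpec("GoC-GrC", "Glom", "GrC", -5.0e-3, 2.0, 1)
        syn = SynapseList(pr, np.zeros(1, np.int32), np.zeros(1, np.int32))
        net = compile_network([glom, grc], [pr], [syn])
        rec = run(net, _trains([0], [5], 1, 100), record_trace_ids=[1])
        assert rec.traces[1]["g_exc"].max() == 0.0
        assert rec.traces[1]["g_inh"].max() > 0.0

    def test_delay_overflow_rejected(self, pop_map):
        glom = _relay("Glom", 1)
        grc = PopulationSpec("GrC", 1, pop_map["GrC"].params,
                             pop_map["GrC"].layer_bounds)
        with pytest.raises(ValueError):
            ProjectionSpec("bad", "Glom", "GrC", 1e-3, 7.0, 1)

    def test_trace_memory_guard(self, tiny_net):
        trains = _trains([], [], 1, 10_000_000)
        with pytest.raises(ValueError):
            run(tiny_net, trains, record_trace_ids=list(range(100)))


class TestDeterminism:
    def test_identical_rasters_per_seed(self, model):
        from cerebsim import experiments
        from cerebsim.stimulus import StimulusProtocol
        kw = dict(scale=0.02, protocol=StimulusProtocol(t_post=50.0), seed=9)
        a = experiments.exp_large_scale(**kw)
        b = experiments.exp_large_scale(**kw)
        assert np.array_equal(a["record"].raster.ids, b["record"].raster.ids)
        assert np.array_equal(a["record"].raster.steps,
                              b["record"].raster.steps)


class TestIntrinsicActivity:
    def test_dcnc_tonic_rate(self, pop_map):
        """Deafferented deep-nucleus cells fire ~25.8 Hz on injected current."""
        glom = _relay("Glom", 1)
        dcnc = PopulationSpec("DCNC", 12, pop_map["DCNC"].params,
                              pop_map["DCNC"].layer_bounds)
        net = compile_network([glom, dcnc], [], [])
        rec = run(net, _trains([], [], 1, 20_000))  # 2 s
        _, steps = rec.raster.population_events("DCNC")
        rate = len(steps) / 12 / 2.0
        assert rate == pytest.approx(25.8, abs=0.5)

    def test_grc_silent_without_input(self, pop_map):
        res = run_single_cell(pop_map["GrC"].params, [], duration=1000.0,
                              seeds=[0])
        assert res["rates"][0] == 0.0


class TestSingleCell:
    def test_zero_rate_afferents_are_inert(self, pop_map, proj_map):
        aff = [AfferentSpec("Glom-GrC", 4, 0.0, 9e-3, 4.0)]
        res = run_single_cell(pop_map["GrC"].params, aff, duration=1000.0,
                              seeds=[0, 1])
        assert np.all(res["rates"] == 0.0)

    def test_seed_batch_matches_individual_runs(self, pop_map):
        aff = [AfferentSpec("Glom-GrC", 4, 50.0, 9e-3, 4.0),
               AfferentSpec("GoC-GrC", 4, 20.0, -5e-3, 2.0)]
        batch = run_single_cell(pop_map["GrC"].params, aff, duration=2000.0,
                                seeds=[3, 4])
        singles = [run_single_cell(pop_map["GrC"].params, aff,
                                   duration=2000.0, seeds=[s])["rates"][0]
                   for s in (3, 4)]
        assert batch["rates"].tolist() == singles

    def test_fixed_mode_runs_and_counts_saturations(self, pop_map):
        aff = [AfferentSpec("Glom-GrC", 4, 100.0, 9e-3, 4.0)]
        res = run_single_cell(pop_map["GrC"].params, aff, duration=1000.0,
                              seeds=[0],
                              sim_config=SimConfig(arithmetic="fixed"))
        assert res["saturations"] == 0  # nothing near the s16.15 limit here
        assert res["rates"][0] > 0


class TestModeAgreement:
    # Glom-GoC is excluded: GoC's current-driven asymptote sits 0.17 mV above
    # threshold, so its tonic crossing is tangential and any arithmetic
    # perturbs the spike time by milliseconds; the synaptically driven
    # aa-GoC case covers that cell type robustly instead.
    @pytest.mark.parametrize("proj", ["Glom-GrC", "aa-PC", "aa-GoC"])
    def test_single_spike_first_spike_agreement(self, proj):
        """Fixed and float back-ends spike in (nearly) the same timestep.

        Slow, near-tangential threshold approaches (PC's current-driven ramp)
        accumulate s16.15 rounding of the decay constants over a hundred
        steps, so up to 0.2 ms of lead/lag is tolerated here.
        """
        from cerebsim.experiments import exp_single_spike
        res = exp_single_spike(proj, duration=2000.0)
        a = res["modes"]["float64"]["first_spike_step"]
        b = res["modes"]["fixed"]["first_spike_step"]
        assert a is not None and b is not None
        assert abs(a - b) <= 2
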