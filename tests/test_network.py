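"""Circuit construction and the simulation engine.

The central quantitative claims live here: the pacemaker population clock
equals the chopper-chopper synaptic delay, per-neuron ISIs equal
n_fast * delay, and slow choppers reduce the clock to integer multiples of
0.4 ms according to their refractory periods.
"""

import numpy as np
import pytest

from chopnet.analysis import isi_histogram, isis
from chopnet.anfibers import ANFiberParams
from chopnet.network import (
    CurrentInput,
    EngineConfig,
    NetworkSpec,
    Synapse,
    attach_step_drive,
    attach_tone_drive,
    build_interval_bank,
    build_pacemaker,
    simulate,
    stop_condition,
)
from chopnet.neurons import LIFParams, lif_run
from chopnet.stimulus import ToneBurstSpec, make_tone_burst, step_drive
from chopnet.synapse import SynapseParams, chopper_synapse

from conftest import BANK_REFRACTORIES


def merged_intervals(result, ids):
    trains = [result.spikes[i].trials[0] for i in ids]
    merged = np.sort(np.concatenate(trains))
    return np.diff(merged)


class TestPacemaker:
    def test_population_clock_equals_synaptic_delay(self, pacemaker2_result):
        _, res = pacemaker2_result
        pop = merged_intervals(res, ["fast0", "fast1"])
        assert np.median(pop) == pytest.approx(0.4, abs=1e-9)
        assert np.allclose(pop, 0.4, atol=1e-9)

    def test_per_neuron_isi_twice_the_clock(self, pacemaker2_result):
        _, res = pacemaker2_result
        for nid in ("fast0", "fast1"):
            gaps = np.diff(res.spikes[nid].trials[0])
            assert np.allclose(gaps, 0.8, atol=1e-9)

    def test_three_ring_isi_and_population(self):
        spec = build_pacemaker(n_fast=3)
        attach_step_drive(spec, t_off=50.0)
        res = simulate(spec, EngineConfig(duration=50.0))
        for nid in ("fast0", "fast1", "fast2"):
            assert np.allclose(np.diff(res.spikes[nid].trials[0]), 1.2, atol=1e-9)
        pop = merged_intervals(res, ["fast0", "fast1", "fast2"])
        assert np.allclose(pop, 0.4, atol=1e-9)

    def test_nerve_drive_alone_cannot_start_chopping(self):
        """Enabling vs initiating: the summed nerve weight (1/8 of the
        chopper weight) depolarizes but never reaches threshold."""
        spec = build_pacemaker()
        attach_step_drive(spec, t_off=50.0, include_onset=False)
        res = simulate(spec, EngineConfig(duration=50.0))
        assert res.spikes["fast0"].n_spikes == 0
        assert res.spikes["fast1"].n_spikes == 0

    def test_invalid_ring_size(self):
        with pytest.raises(ValueError):
            build_pacemaker(n_fast=4)


def slow_isi_oracle(refractory, clock=0.4, horizon=50.0):
    """Brute-force event trace: suprathreshold inputs at every clock tick;
    fire at each tick strictly beyond the refractory period."""
    out, last = [], None
    t = clock
    while t < horizon:
        if last is None or t - last > refractory + 1e-12:
            if last is not None:
                out.append(t - last)
            last = t
        t += clock
    return np.median(out)


class TestIntervalBank:
    @pytest.mark.parametrize("refractory", [0.3, 0.5, 0.9, 1.0, 1.3, 1.7, 2.1, 3.3])
    def test_interval_reduction_matches_event_oracle(self, refractory):
        spec = build_pacemaker()
        attach_step_drive(spec, t_off=60.0)
        spec = build_interval_bank([refractory], spec)
        res = simulate(spec, EngineConfig(duration=60.0))
        gaps = np.diff(res.spikes["slow0"].trials[0])
        assert np.allclose(gaps, gaps[0], atol=1e-9)  # perfectly regular
        assert gaps[0] == pytest.approx(slow_isi_oracle(refractory), abs=1e-9)
        # closed form for non-multiples of the clock
        if not np.isclose(refractory % 0.4, 0.0):
            assert gaps[0] == pytest.approx(np.ceil(refractory / 0.4) * 0.4, abs=1e-9)

    def test_every_third_input_example(self, bank_result):
        """Refractory 1.0 ms on the 0.4 ms clock: ISI 1.2 ms."""
        spec = build_pacemaker()
        attach_step_drive(spec, t_off=50.0)
        spec = build_interval_bank([1.0], spec)
        res = simulate(spec, EngineConfig(duration=50.0))
        assert np.allclose(np.diff(res.spikes["slow0"].trials[0]), 1.2, atol=1e-9)

    def test_all_isis_multiples_of_clock(self, bank_result):
        _, res = bank_result
        for j in range(len(BANK_REFRACTORIES)):
            vals = isis(res.spikes[f"slow{j}"])[:, 1]
            ratio = vals / 0.4
            np.testing.assert_allclose(ratio, np.round(ratio), atol=1e-6)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            build_interval_bank([], build_pacemaker())


class TestJitteredProtocol:
    def test_pacemaker_isi_histogram_peaks_on_lattice(self, fig5_result):
        """With delay jitter SD 0.26 ms over 500 trials, the pacemaker
        units' ISI-histogram peaks stay within 0.1 ms of multiples of 0.4."""
        _, res = fig5_result
        for nid in ("fast0", "fast1"):
            h = isi_histogram(res.spikes[nid], 0.1, t_max=3.0)
            peaks = h.peak_locations(min_count=0.25 * h.counts.max())
            assert peaks.size >= 1
            for p in peaks:
                assert abs(p - 0.4 * round(p / 0.4)) <= 0.1

    def test_chopping_survives_most_trials(self, fig5_result):
        _, res = fig5_result
        started = np.mean([t.size > 0 for t in res.spikes["fast0"].trials])
        assert started > 0.8


class TestStopCondition:
    def test_chopping_stops_after_drive_offset(self):
        spec = build_pacemaker()
        attach_step_drive(spec, t_off=25.0)
        res = simulate(spec, EngineConfig(duration=40.0))
        assert stop_condition(spec, res)
        last = max(t.max() for nid in ("fast0", "fast1")
                   for t in res.spikes[nid].trials)
        assert last < 25.0 + 10 * 0.8

    def test_sustained_drive_reports_false(self):
        spec = build_pacemaker()
        attach_step_drive(spec, t_off=40.0)
        res = simulate(spec, EngineConfig(duration=40.0))
        assert not stop_condition(spec, res)

    def test_zero_weight_network_trivially_stops(self):
        spec = build_pacemaker()
        for i, syn in enumerate(spec.synapses):
            if syn.pre.startswith("fast"):
                from dataclasses import replace

                spec.synapses[i] = Synapse(
                    syn.pre, syn.post, replace(syn.params, weight=0.0)
                )
        attach_step_drive(spec, t_off=25.0)
        res = simulate(spec, EngineConfig(duration=40.0))
        assert stop_condition(spec, res)


class TestEngine:
    def test_empty_network(self):
        res = simulate(NetworkSpec(), EngineConfig(duration=5.0))
        assert res.spikes == {}

    def test_determinism_same_master_seed(self):
        tone = make_tone_burst(ToneBurstSpec(2890.0, 25.0, 1.6))
        spec = build_pacemaker(jitter_sd=0.26)
        attach_tone_drive(spec, tone, ANFiberParams())
        cfg = EngineConfig(duration=30.0, n_trials=5, master_seed=99)
        r1, r2 = simulate(spec, cfg), simulate(spec, cfg)
        for nid in r1.spikes:
            for a, b in zip(r1.spikes[nid].trials, r2.spikes[nid].trials):
                np.testing.assert_array_equal(a, b)

    def test_euler_convergence_on_pacemaker(self):
        """Halving dt from 25 us changes every spike time by < 0.025 ms."""
        spec = build_pacemaker()
        attach_step_drive(spec, t_off=50.0)
        a = simulate(spec, EngineConfig(duration=50.0, dt=0.025)).spikes["fast0"].trials[0]
        b = simulate(spec, EngineConfig(duration=50.0, dt=0.0125)).spikes["fast0"].trials[0]
        n = min(a.size, b.size)
        assert abs(a.size - b.size) <= 1
        assert np.max(np.abs(a[:n] - b[:n])) < 0.025

    def test_engine_agrees_with_single_neuron_reference(self):
        """A one-neuron network under a waveform drive reproduces lif_run."""
        params = LIFParams(relative_refractory_amplitude=0.0, absolute_refractory=0.0)
        wave = step_drive(2.0, 0.0, 20.0, duration=20.0)
        spec = NetworkSpec(neurons={"n": params})
        spec.add_input("n", CurrentInput(wave, gain=1.0))
        res = simulate(spec, EngineConfig(duration=20.0))
        n_steps = int(round(20.0 / 0.025))
        times = (np.arange(n_steps) + 1) * 0.025
        current = np.where(times <= 20.0, 2.0, 0.0)
        current[times > 20.0] = 0.0
        # replicate the engine's sampling of the waveform
        idx = np.floor((times - 1e-12) / 0.025).astype(int)
        current = np.where(idx < wave.samples.size, wave.samples[np.minimum(idx, wave.samples.size - 1)], 0.0)
        ref = lif_run(current, 0.025, params)
        np.testing.assert_allclose(res.spikes["n"].trials[0], ref, atol=1e-9)

    def test_refractory_invariant_on_all_outputs(self, bank_result):
        spec, res = bank_result
        for nid, train in res.spikes.items():
            train.validate()

    def test_wiring_errors_detected(self):
        spec = NetworkSpec(neurons={"a": LIFParams()})
        spec.synapses.append(Synapse("a", "ghost", chopper_synapse()))
        with pytest.raises(ValueError):
            simulate(spec, EngineConfig(duration=1.0))
        spec2 = NetworkSpec(neurons={"a": LIFParams()})
        spec2.synapses.append(Synapse("a", "a", chopper_synapse()))
        with pytest.raises(ValueError):
            simulate(spec2, EngineConfig(duration=1.0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EngineConfig(dt=0.0)
        with pytest.raises(ValueError):
            EngineConfig(duration=-5.0)
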