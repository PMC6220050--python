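"""Circuit construction and the clock-driven simulation engine.

Topologies: the fast-chopper *pacemaker* (two or three mutually excitatory
leaky integrate-and-fire choppers whose 0.4 ms synaptic delay sets the
population clock), the *interval bank* of slow choppers that skip
suprathreshold pacemaker inputs according to their refractory periods, the
onset/trigger neuron that initiates chopping, and the auditory-nerve fan-in
whose summed weight is one eighth of the chopper synapse weight: it
depolarizes the membrane enough to *enable* chopping but cannot initiate it.

The engine advances all neurons on a common grid (default 25 us), delivers
delayed synaptic events, and derives all per-trial randomness
deterministically from one master seed, so identical (spec, config) pairs
produce bit-identical results and trials are independent of execution order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .anfibers import ANFiberParams, an_spikes
from .neurons import LIFParams, OnsetParams, onset_time, _hh_onset_spikes
from .spiketrain import SpikeTrain
from .stimulus import StimulusWaveform, step_drive
from .synapse import (
    AN_WEIGHT_RATIO,
    CHOPPER_WEIGHT,
    SynapseParams,
    an_fiber_synapse,
    chopper_synapse,
    draw_delays,
    pacemaker_to_slow_synapse,
)

__all__ = [
    "NetworkSpec",
    "EngineConfig",
    "SimulationResult",
    "Synapse",
    "CurrentInput",
    "ANInput",
    "SpikeInput",
    "build_pacemaker",
    "build_interval_bank",
    "attach_step_drive",
    "attach_tone_drive",
    "simulate",
    "stop_condition",
]


# ---------------------------------------------------------------------------
# Declarative wiring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Synapse:
    pre: str
    post: str
    params: SynapseParams
    allow_self: bool = False


@dataclass(frozen=True)
class CurrentInput:
    """Waveform injected directly as a current: I(t) = gain * amplitude(t).

    This is the step-drive mode where the auditory-nerve input is reduced to
    a signal step; the gain plays the role of the summed nerve weight.
    """

    waveform: StimulusWaveform
    gain: float = CHOPPER_WEIGHT / AN_WEIGHT_RATIO


@dataclass(frozen=True)
class ANInput:
    """Stochastic auditory-nerve fan-in: per trial, a fresh bank of fiber
    spike trains is generated from the waveform and passed through graded
    synapses (one per fiber)."""

    waveform: StimulusWaveform
    fibers: ANFiberParams
    synapse: SynapseParams


@dataclass(frozen=True)
class SpikeInput:
    """Externally supplied spike train delivered through a synapse."""

    train: SpikeTrain
    synapse: SynapseParams


@dataclass
class NetworkSpec:
    neurons: dict = field(default_factory=dict)   # id -> LIFParams | OnsetParams
    synapses: list = field(default_factory=list)  # list[Synapse]
    external_inputs: dict = field(default_factory=dict)  # id -> list of inputs
    topology_label: str = ""

    def validate(self) -> None:
        for syn in self.synapses:
            if syn.pre not in self.neurons or syn.post not in self.neurons:
                raise ValueError(
                    f"synapse {syn.pre}->{syn.post}: endpoint not in network"
                )
            if syn.pre == syn.post and not syn.allow_self:
                raise ValueError(f"self-synapse on {syn.pre} not flagged")
        for nid in self.external_inputs:
            if nid not in self.neurons:
                raise ValueError(f"external input targets unknown neuron {nid!r}")

    def add_input(self, neuron_id: str, inp) -> None:
        self.external_inputs.setdefault(neuron_id, []).append(inp)

    def digest(self) -> str:
        """Stable hash of the wiring, for run manifests."""

        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, StimulusWaveform):
                return {
                    "label": o.label,
                    "sample_interval": o.sample_interval,
                    "n": int(o.samples.size),
                    "sha": hashlib.sha256(o.samples.tobytes()).hexdigest()[:16],
                }
            if isinstance(o, SpikeTrain):
                return {"unit": o.unit_id, "n_spikes": o.n_spikes}
            if hasattr(o, "__dataclass_fields__"):
                return {k: enc(getattr(o, k)) for k in o.__dataclass_fields__}
            return o

        payload = json.dumps(
            {
                "neurons": {k: enc(v) for k, v in sorted(self.neurons.items())},
                "synapses": [enc(s) for s in self.synapses],
                "inputs": {
                    k: [enc(i) for i in v]
                    for k, v in sorted(self.external_inputs.items())
                },
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class EngineConfig:
    dt: float = 0.025        # ms; 25 us resolves all relevant time scales
    duration: float = 50.0   # ms
    n_trials: int = 1
    master_seed: int = 0
    record_state: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("EngineConfig: dt must be positive")
        if self.duration <= 0:
            raise ValueError("EngineConfig: duration must be positive")
        if self.n_trials < 1:
            raise ValueError("EngineConfig: n_trials must be >= 1")


@dataclass
class SimulationResult:
    spikes: dict                 # id -> SpikeTrain
    state_traces: dict | None    # id -> (n_trials, n_steps) potential arrays
    config_echo: dict


# ---------------------------------------------------------------------------
# Topology builders
# ---------------------------------------------------------------------------

def build_pacemaker(
    n_fast: int = 2,
    delay: float = 0.4,
    jitter_sd: float = 0.0,
) -> NetworkSpec:
    """Pacemaker microcircuit: a ring of mutually excitatory fast choppers
    (membrane time constant 0.8 ms) with chopper-chopper delay ``delay``,
    plus one onset neuron wired to exactly one fast chopper.

    The population clock equals ``delay`` (0.4 ms at default); each neuron's
    own ISI is ``n_fast * delay``.
    """
    if n_fast not in (2, 3):
        raise ValueError("build_pacemaker: n_fast must be 2 or 3")
    spec = NetworkSpec(topology_label=f"pacemaker{n_fast}")
    spec.neurons["onset"] = OnsetParams()
    for i in range(n_fast):
        spec.neurons[f"fast{i}"] = LIFParams.fast_chopper()
    for i in range(n_fast):
        spec.synapses.append(
            Synapse(f"fast{i}", f"fast{(i + 1) % n_fast}",
                    chopper_synapse(delay=delay, jitter_sd=jitter_sd))
        )
    # jitter applies to the chopper-chopper interconnections only; the
    # trigger synapse keeps a deterministic delay
    spec.synapses.append(Synapse("onset", "fast0", chopper_synapse(delay=delay)))
    return spec


def build_interval_bank(
    refractory_list: list[float],
    pacemaker: NetworkSpec | None = None,
    jitter_sd: float = 0.0,
    slow_receive_an: bool = False,
) -> NetworkSpec:
    """Attach one slow chopper per refractory value to a pacemaker.

    Each slow chopper receives the full (suprathreshold) pacemaker output,
    so its ISIs are the integer multiples of the clock admitted by its
    refractory period: ``ISI = ceil(r / clock) * clock`` for ``r`` not a
    multiple of the clock. Slow choppers do not receive direct
    auditory-nerve input by default (the pacemaker projection substitutes);
    set ``slow_receive_an`` to wire the AN ports through as well.
    """
    if not refractory_list:
        raise ValueError("build_interval_bank: refractory list is empty")
    if any(r <= 0 for r in refractory_list):
        raise ValueError("build_interval_bank: refractory values must be positive")
    spec = pacemaker if pacemaker is not None else build_pacemaker(jitter_sd=jitter_sd)
    fast_ids = [nid for nid in spec.neurons if nid.startswith("fast")]
    for j, r in enumerate(refractory_list):
        sid = f"slow{j}"
        spec.neurons[sid] = LIFParams.slow_chopper(absolute_refractory=r)
        for fid in fast_ids:
            spec.synapses.append(
                Synapse(fid, sid, pacemaker_to_slow_synapse(jitter_sd=jitter_sd))
            )
        if slow_receive_an:
            for inp in spec.external_inputs.get(fast_ids[0], []):
                spec.add_input(sid, inp)
    spec.topology_label += f"+bank{len(refractory_list)}"
    return spec


def attach_step_drive(
    spec: NetworkSpec,
    t_on: float = 0.0,
    t_off: float = 50.0,
    amplitude: float = 1.0,
    include_onset: bool = True,
    dt: float = 0.025,
) -> NetworkSpec:
    """Wire a current step onto every fast chopper's nerve port (and, when
    ``include_onset``, the same step as the onset neuron's broadband drive).

    At the default gain and unit amplitude the steady-state depolarization
    is ~0.83 of threshold: chopping is enabled, not initiated.
    """
    wave = step_drive(amplitude, t_on, t_off, sample_interval=dt * 1e-3)
    for nid in spec.neurons:
        if nid.startswith("fast"):
            spec.add_input(nid, CurrentInput(wave))
    if include_onset and "onset" in spec.neurons:
        spec.add_input("onset", CurrentInput(wave, gain=1.0))
    return spec


def attach_tone_drive(
    spec: NetworkSpec,
    waveform: StimulusWaveform,
    fibers: ANFiberParams | None = None,
) -> NetworkSpec:
    """Wire a stochastic auditory-nerve fan-in driven by ``waveform`` onto
    every fast chopper, and the waveform itself onto the onset neuron."""
    if fibers is None:
        fibers = ANFiberParams()
    for nid in spec.neurons:
        if nid.startswith("fast"):
            spec.add_input(
                nid, ANInput(waveform, fibers, an_fiber_synapse(fibers.n_fibers))
            )
    if "onset" in spec.neurons:
        spec.add_input("onset", CurrentInput(waveform, gain=1.0))
    return spec


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

def _waveform_current(wave: StimulusWaveform, gain: float, times: np.ndarray) -> np.ndarray:
    """Sample a waveform as a current on the engine grid (zero outside support)."""
    idx = np.floor((times - 1e-12) / (wave.sample_interval * 1e3)).astype(int)
    out = np.zeros(times.size)
    ok = (idx >= 0) & (idx < wave.samples.size)
    out[ok] = gain * wave.samples[idx[ok]]
    return out


def _graded_current(
    arrival_steps: np.ndarray, params: SynapseParams, n_steps: int, dt: float
) -> np.ndarray:
    """Leaky-integrator transmitter trace -> tanh conductance current."""
    deposits = np.zeros(n_steps)
    ok = (arrival_steps >= 0) & (arrival_steps < n_steps)
    np.add.at(deposits, arrival_steps[ok], params.quanta_per_spike)
    decay = np.exp(-dt / params.transmitter_decay_tau)
    conc = lfilter([1.0], [1.0, -decay], deposits)
    return params.weight * np.tanh(conc / params.saturation_scale)


def simulate(spec: NetworkSpec, config: EngineConfig) -> SimulationResult:
    """Clock-driven simulation of a network specification.

    Per step: deliver delayed synaptic events scheduled for that step
    (simultaneous deliveries are summed before the neuron update), advance
    every LIF neuron one Euler step, record threshold crossings, and
    schedule the outgoing events of the spikes just emitted. Onset-neuron
    spikes are computed up front from their broadband drive. Identical
    (spec, config) pairs give bit-identical results.
    """
    spec.validate()
    dt, n_steps = config.dt, int(round(config.duration / config.dt))
    times = (np.arange(n_steps) + 1) * dt

    lif_ids = [nid for nid, p in spec.neurons.items() if isinstance(p, LIFParams)]
    onset_ids = [nid for nid, p in spec.neurons.items() if isinstance(p, OnsetParams)]
    lif_index = {nid: i for i, nid in enumerate(lif_ids)}
    n_lif = len(lif_ids)

    # per-neuron parameter arrays
    P = [spec.neurons[nid] for nid in lif_ids]
    tau = np.array([p.membrane_tau for p in P])
    theta = np.array([p.threshold for p in P])
    v_reset = np.array([p.reset for p in P])
    e_leak = np.array([p.leak_reversal for p in P])
    abs_ref = np.array([p.absolute_refractory for p in P])
    rel_amp = np.array([p.relative_refractory_amplitude for p in P])
    rel_tau = np.array([p.relative_refractory_tau for p in P])

    # internal synapses with a LIF target, grouped by presynaptic neuron
    internal = [s for s in spec.synapses if s.post in lif_index]
    outgoing: dict[str, list[int]] = {}
    for k, s in enumerate(internal):
        outgoing.setdefault(s.pre, []).append(k)

    root = np.random.SeedSequence(config.master_seed)
    trial_seqs = root.spawn(config.n_trials)

    all_spikes: dict[str, list[np.ndarray]] = {nid: [] for nid in spec.neurons}
    traces = (
        {nid: np.zeros((config.n_trials, n_steps)) for nid in lif_ids}
        if config.record_state
        else None
    )

    for trial in range(config.n_trials):
        children = trial_seqs[trial].spawn(len(internal) + 1)
        syn_rngs = [np.random.default_rng(children[k]) for k in range(len(internal))]
        an_seq = children[-1]

        # --- external drive, precomputed per trial --------------------------
        i_ext = np.zeros((n_lif, n_steps))
        an_count = 0
        for nid in sorted(spec.external_inputs):
            if nid not in lif_index:
                continue
            row = lif_index[nid]
            for inp in spec.external_inputs[nid]:
                if isinstance(inp, CurrentInput):
                    i_ext[row] += _waveform_current(inp.waveform, inp.gain, times)
                elif isinstance(inp, ANInput):
                    fib_seed = int(an_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
                    an_count += 1
                    fibers = replace(inp.fibers, seed=fib_seed)
                    for ftrain in an_spikes(inp.waveform, fibers):
                        spk = ftrain.trials[0]
                        delays = draw_delays(
                            spk.size, inp.synapse,
                            rng=np.random.default_rng(fib_seed + 1), floor=dt,
                        )
                        steps = np.round((spk + delays) / dt).astype(int) - 1
                        i_ext[row] += _graded_current(steps, inp.synapse, n_steps, dt)
                elif isinstance(inp, SpikeInput):
                    spk = inp.train.trials[min(trial, inp.train.n_trials - 1)]
                    delays = draw_delays(
                        spk.size, inp.synapse,
                        rng=np.random.default_rng(
                            int(trial_seqs[trial].generate_state(1)[0] % (2**31)) + 7
                        ),
                        floor=dt,
                    )
                    steps = np.round((spk + delays) / dt).astype(int) - 1
                    if inp.synapse.mode == "graded":
                        i_ext[row] += _graded_current(steps, inp.synapse, n_steps, dt)
                    else:
                        pass  # handled below through pending charges
                else:
                    raise ValueError(f"unresolved input port on {nid!r}: {inp!r}")

        # --- pending event buffers -----------------------------------------
        pending_charge = np.zeros((n_steps, n_lif))  # impulse-mode deposits
        graded_deposits = {
            k: np.zeros(n_steps)
            for k, s in enumerate(internal)
            if s.params.mode == "graded"
        }
        graded_conc = {k: 0.0 for k in graded_deposits}
        graded_decay = {
            k: np.exp(-dt / internal[k].params.transmitter_decay_tau)
            for k in graded_deposits
        }

        def schedule(pre_id: str, t_spike: float) -> None:
            for k in outgoing.get(pre_id, []):
                s = internal[k]
                d = draw_delays(1, s.params, rng=syn_rngs[k], floor=dt)[0]
                step = int(round((t_spike + d) / dt)) - 1
                if step >= n_steps:
                    continue
                if s.params.mode == "impulse":
                    pending_charge[step, lif_index[s.post]] += s.params.impulse_charge
                else:
                    graded_deposits[k][step] += s.params.quanta_per_spike

        # impulse-mode external SpikeInputs
        for nid in sorted(spec.external_inputs):
            if nid not in lif_index:
                continue
            for inp in spec.external_inputs[nid]:
                if isinstance(inp, SpikeInput) and inp.synapse.mode == "impulse":
                    spk = inp.train.trials[min(trial, inp.train.n_trials - 1)]
                    delays = draw_delays(
                        spk.size, inp.synapse,
                        rng=np.random.default_rng(
                            int(trial_seqs[trial].generate_state(1)[0] % (2**31)) + 7
                        ),
                        floor=dt,
                    )
                    steps = np.round((spk + delays) / dt).astype(int) - 1
                    ok = (steps >= 0) & (steps < n_steps)
                    for st in steps[ok]:
                        pending_charge[st, lif_index[nid]] += inp.synapse.impulse_charge

        # --- onset neurons: spikes known in advance -------------------------
        for nid in onset_ids:
            op: OnsetParams = spec.neurons[nid]
            drive = None
            for inp in spec.external_inputs.get(nid, []):
                if isinstance(inp, CurrentInput):
                    drive = inp.waveform
                    break
            if drive is None or not np.any(drive.samples):
                all_spikes[nid].append(np.empty(0))
                continue
            if op.mode == "single_spike":
                t0 = onset_time(drive, op.onset_fraction)
                spk = np.array([t0 + op.spike_latency]) if t0 is not None else np.empty(0)
            else:
                spk = _hh_onset_spikes(drive, op)
            spk = spk[spk <= config.duration]
            all_spikes[nid].append(spk)
            for t_spike in spk:
                schedule(nid, t_spike)

        # --- main loop -------------------------------------------------------
        v = v_reset.copy()
        last_spike = np.full(n_lif, -np.inf)
        trial_spikes: list[list[float]] = [[] for _ in range(n_lif)]
        for i in range(n_steps):
            t = times[i]
            i_syn = i_ext[:, i].copy()
            for k in graded_deposits:
                graded_conc[k] = graded_conc[k] * graded_decay[k] + graded_deposits[k][i]
                s = internal[k]
                i_syn[lif_index[s.post]] += s.params.weight * np.tanh(
                    graded_conc[k] / s.params.saturation_scale
                )
            active = (t - last_spike) > abs_ref
            v_new = v + dt * ((e_leak - v) / tau + i_syn) + pending_charge[i]
            v = np.where(active, v_new, v_reset)
            theta_eff = theta + rel_amp * np.exp((last_spike - t) / rel_tau)
            fired = active & (v >= theta_eff)
            if np.any(fired):
                idx = np.nonzero(fired)[0]
                v[idx] = v_reset[idx]
                last_spike[idx] = t
                for j in idx:
                    trial_spikes[j].append(t)
                    schedule(lif_ids[j], t)
            if traces is not None:
                for j, nid in enumerate(lif_ids):
                    traces[nid][trial, i] = v[j]
        for j, nid in enumerate(lif_ids):
            all_spikes[nid].append(np.asarray(trial_spikes[j]))

    spikes = {
        nid: SpikeTrain(
            unit_id=nid,
            trials=all_spikes[nid],
            t_stop=config.duration,
            refractory=(
                spec.neurons[nid].absolute_refractory
                if isinstance(spec.neurons[nid], LIFParams)
                else 0.0
            ),
        )
        for nid in spec.neurons
    }
    echo = {
        "dt": dt,
        "duration": config.duration,
        "n_trials": config.n_trials,
        "master_seed": config.master_seed,
        "topology": spec.topology_label,
        "spec_digest": spec.digest(),
    }
    return SimulationResult(spikes=spikes, state_traces=traces, config_echo=echo)


def stop_condition(
    spec: NetworkSpec, result: SimulationResult, k_tau: float = 10.0
) -> bool:
    """True iff network self-excitation terminates after the drive's offset.

    The criterion is that no spike occurs later than the last nonzero drive
    sample plus ``k_tau`` membrane time constants (largest in the network).
    Returns False when the drive is sustained to the end of the simulation,
    since stopping cannot then be assessed.
    """
    offset = 0.0
    for inputs in spec.external_inputs.values():
        for inp in inputs:
            wave = getattr(inp, "waveform", None)
            if wave is None:
                continue
            nz = np.nonzero(wave.samples)[0]
            if nz.size:
                offset = max(offset, (nz[-1] + 1) * wave.sample_interval * 1e3)
    tau_max = max(
        (p.membrane_tau for p in spec.neurons.values() if isinstance(p, LIFParams)),
        default=0.0,
    )
    horizon = offset + k_tau * tau_max
    duration = result.config_echo["duration"]
    if horizon >= duration:
        return False
    for nid, train in result.spikes.items():
        if isinstance(spec.neurons[nid], LIFParams):
            for trial in train.trials:
                if trial.size and trial.max() > horizon:
                    return False
    return True
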