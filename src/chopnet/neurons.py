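"""Single-neuron dynamics.

Chopper neurons (T-stellate cells of the ventral cochlear nucleus) are leaky
integrate-and-fire units with absolute plus exponentially decaying relative
refractoriness, advanced by the forward-Euler method at 25 us steps. The
onset neuron (D-stellate-like trigger) is by default a single-spike generator
firing once at stimulus onset; an optional conductance-based mode with
sodium, low-threshold potassium and leak currents (the classic phasic
ventral-cochlear-nucleus formulation) is provided for reference.

Membrane potentials are dimensionless: leak reversal 0, reset 0, threshold 1.
The closed-form steady state for constant current I is ``E + tau * I``, i.e.
the current is expressed in threshold-units per (membrane time constant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spiketrain import SpikeTrain
from .stimulus import StimulusWaveform

__all__ = [
    "LIFParams",
    "LIFState",
    "OnsetParams",
    "lif_step",
    "lif_run",
    "onset_response",
]


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire chopper parameters.

    The fast-chopper membrane time constant is 0.8 ms; slow choppers use
    larger time constants and longer absolute refractory periods, which is
    what makes them skip pacemaker inputs. Threshold, reset and leak values
    are calibration constants (see docs/methods.md), chosen so that the
    auditory-nerve input alone is subthreshold while one chopper EPSP on top
    of that depolarization is suprathreshold.
    """

    membrane_tau: float = 0.8         # ms
    threshold: float = 1.0            # a.u.
    reset: float = 0.0                # a.u.
    leak_reversal: float = 0.0        # a.u.
    absolute_refractory: float = 0.1  # ms
    relative_refractory_amplitude: float = 0.15  # threshold increment a.u.
    relative_refractory_tau: float = 0.25        # ms

    def __post_init__(self) -> None:
        if self.membrane_tau <= 0:
            raise ValueError("LIFParams: membrane_tau must be positive")
        if self.absolute_refractory < 0:
            raise ValueError("LIFParams: absolute_refractory must be >= 0")
        if not self.threshold > self.reset:
            raise ValueError("LIFParams: threshold must exceed reset")
        if self.relative_refractory_tau <= 0:
            raise ValueError("LIFParams: relative_refractory_tau must be positive")

    @staticmethod
    def fast_chopper() -> "LIFParams":
        """Pacemaker neuron: 0.8 ms membrane, short refractoriness."""
        return LIFParams()

    @staticmethod
    def slow_chopper(absolute_refractory: float, membrane_tau: float = 2.0) -> "LIFParams":
        """Interval-reducing neuron; the refractory period sets which
        multiples of the 0.4 ms clock it can follow."""
        return LIFParams(
            membrane_tau=membrane_tau,
            absolute_refractory=absolute_refractory,
        )


@dataclass
class LIFState:
    """Mutable integration state of one LIF unit."""

    v: float = 0.0
    last_spike: float | None = None
    t: float = 0.0


def effective_threshold(params: LIFParams, t: float, last_spike: float | None) -> float:
    """Spike threshold raised by the decaying relative-refractory increment."""
    if last_spike is None:
        return params.threshold
    return params.threshold + params.relative_refractory_amplitude * np.exp(
        -(t - last_spike) / params.relative_refractory_tau
    )


def lif_step(
    state: LIFState,
    input_current: float,
    dt: float,
    params: LIFParams,
    charge: float = 0.0,
) -> tuple[LIFState, bool]:
    """Advance one forward-Euler step of length ``dt`` ms.

    ``input_current`` is the graded synaptic/external current over the step;
    ``charge`` is an instantaneous quantal charge (direct potential
    increment) delivered at the end of the step. During the absolute
    refractory period the membrane is clamped at reset and input is
    discarded; a spike is emitted when the updated potential reaches the
    effective threshold, upon which the potential resets.
    """
    if dt <= 0:
        raise ValueError("lif_step: dt must be positive")
    t_new = state.t + dt
    in_refractory = (
        state.last_spike is not None
        and (t_new - state.last_spike) <= params.absolute_refractory
    )
    if in_refractory:
        return LIFState(v=params.reset, last_spike=state.last_spike, t=t_new), False
    v = state.v + dt * ((params.leak_reversal - state.v) / params.membrane_tau + input_current)
    v += charge
    if v >= effective_threshold(params, t_new, state.last_spike):
        return LIFState(v=params.reset, last_spike=t_new, t=t_new), True
    return LIFState(v=v, last_spike=state.last_spike, t=t_new), False


def lif_run(
    current: np.ndarray,
    dt: float,
    params: LIFParams,
    charges: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate a LIF over a sampled current; return spike times (ms).

    ``current[i]`` drives the step ending at ``t = (i + 1) * dt``; this is
    the single-neuron reference path that the network engine must agree
    with.
    """
    state = LIFState(v=params.reset)
    spikes = []
    for i, cur in enumerate(np.asarray(current, dtype=float)):
        q = 0.0 if charges is None else float(charges[i])
        state, fired = lif_step(state, float(cur), dt, params, charge=q)
        if fired:
            spikes.append(state.t)
    return np.asarray(spikes)


# ---------------------------------------------------------------------------
# Onset / trigger neuron
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetParams:
    """Trigger neuron. ``single_spike`` mode fires exactly once at stimulus
    onset plus ``spike_latency``; ``hh`` mode integrates a conductance model
    with Na, low-threshold K and leak currents whose low-threshold K
    conductance enforces phasic (onset-only) firing."""

    mode: str = "single_spike"        # "single_spike" | "hh"
    spike_latency: float = 0.7        # ms; stands in for the peripheral chain latency
    onset_fraction: float = 0.5       # onset = first sample >= this fraction of peak
    # conductance-based mode (nS, mV, pF); classic phasic VCN values
    g_na: float = 1000.0
    g_klt: float = 200.0
    g_leak: float = 2.0
    e_na: float = 55.0
    e_k: float = -70.0
    e_leak: float = -65.0
    capacitance: float = 12.0
    current_gain: float = 1000.0      # pA per unit waveform amplitude

    def __post_init__(self) -> None:
        if self.mode not in ("single_spike", "hh"):
            raise ValueError("OnsetParams: mode must be 'single_spike' or 'hh'")
        if self.spike_latency < 0:
            raise ValueError("OnsetParams: spike_latency must be >= 0")


def onset_time(drive: StimulusWaveform, onset_fraction: float = 0.1) -> float | None:
    """First time (ms) the drive reaches ``onset_fraction`` of its peak."""
    x = np.abs(drive.samples)
    peak = x.max() if x.size else 0.0
    if peak <= 0:
        return None
    idx = int(np.argmax(x >= onset_fraction * peak))
    return float(idx * drive.sample_interval * 1e3)


def onset_response(
    drive: StimulusWaveform, params: OnsetParams, n_trials: int = 1
) -> SpikeTrain:
    """Trigger-neuron response to a broadband drive.

    All-zero drive signals "no onset" and yields an empty train.
    """
    if drive.samples.size == 0:
        raise ValueError("onset_response: drive is empty")
    t_stop = drive.duration_ms
    if params.mode == "single_spike":
        t0 = onset_time(drive, params.onset_fraction)
        if t0 is None:
            trials = [np.empty(0)] * n_trials
        else:
            t_spk = min(t0 + params.spike_latency, t_stop)
            trials = [np.array([t_spk])] * n_trials
        return SpikeTrain("onset", trials=trials, t_stop=t_stop)
    spikes = _hh_onset_spikes(drive, params)
    return SpikeTrain("onset", trials=[spikes] * n_trials, t_stop=t_stop)


# -- conductance-based onset model ------------------------------------------

def _expit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _gate_inf_tau(v: float) -> tuple[float, float, float, float, float, float, float, float]:
    """Steady states and time constants (ms) of m, h (Na) and w, z (KLT)."""
    m_inf = _expit((v + 38.0) / 7.0)
    tau_m = 10.0 / (5 * np.exp((v + 60) / 18.0) + 36 * np.exp(-(v + 60) / 25.0)) + 0.04
    h_inf = _expit(-(v + 65.0) / 6.0)
    tau_h = 100.0 / (7 * np.exp((v + 60) / 11.0) + 10 * np.exp(-(v + 60) / 25.0)) + 0.6
    w_inf = _expit((v + 48.0) / 6.0) ** 0.25
    tau_w = 100.0 / (6 * np.exp((v + 60) / 6.0) + 16 * np.exp(-(v + 60) / 45.0)) + 1.5
    z_inf = 0.5 + 0.5 * _expit(-(v + 71.0) / 10.0)
    tau_z = 1000.0 / (np.exp((v + 60) / 20.0) + np.exp(-(v + 60) / 8.0)) + 50.0
    return m_inf, tau_m, h_inf, tau_h, w_inf, tau_w, z_inf, tau_z


def _hh_onset_spikes(drive: StimulusWaveform, params: OnsetParams) -> np.ndarray:
    """Euler-integrate the four-current onset model; spike = upward crossing
    of -20 mV. Integrated at a finer internal step than the network engine
    because the sodium activation gate is fast."""
    dt = 0.005  # ms
    t_total = drive.duration_ms
    n = int(round(t_total / dt))
    # resample drive onto the fine grid
    src_t = drive.times_ms
    fine_t = np.arange(n) * dt
    i_ext = params.current_gain * np.interp(fine_t, src_t, drive.samples)

    v = params.e_leak
    m_inf, _, h_inf, _, w_inf, _, z_inf, _ = _gate_inf_tau(v)
    m, h, w, z = m_inf, h_inf, w_inf, z_inf
    spikes = []
    above = False
    for i in range(n):
        m_inf, tau_m, h_inf, tau_h, w_inf, tau_w, z_inf, tau_z = _gate_inf_tau(v)
        m += dt * (m_inf - m) / tau_m
        h += dt * (h_inf - h) / tau_h
        w += dt * (w_inf - w) / tau_w
        z += dt * (z_inf - z) / tau_z
        i_na = params.g_na * m**3 * h * (v - params.e_na)
        i_klt = params.g_klt * w**4 * z * (v - params.e_k)
        i_lk = params.g_leak * (v - params.e_leak)
        v += dt * (-(i_na + i_klt + i_lk) + i_ext[i]) / params.capacitance
        if v >= -20.0 and not above:
            spikes.append((i + 1) * dt)
            above = True
        elif v < -20.0:
            above = False
    return np.asarray(spikes)
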