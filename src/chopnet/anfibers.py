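"""Phenomenological auditory-nerve fiber model.

The cochlea / inner-hair-cell / vesicle chain is replaced by a rate-modulated,
adapting, refractory point process: the instantaneous release rate follows the
half-wave-rectified stimulus waveform (phase locking), multiplied by a
single-exponential adaptation factor that decays after onset (vesicle
depletion), and spikes are thinned by an absolute dead time of ~1 ms.

The peak driven rate and the spontaneous rate are conventions, not values
taken from physiology-free first principles; defaults are in the range
commonly used for high-spontaneous-rate fibers. Stimulus level enters as a
scalar gain on the peak release rate (the ``level_gain`` field), which is how
"dB above threshold" is mapped onto the rate model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spiketrain import SpikeTrain
from .stimulus import StimulusWaveform

__all__ = ["ANFiberParams", "an_spikes", "vector_strength"]


@dataclass(frozen=True)
class ANFiberParams:
    """Parameters of the stochastic fiber bank (one record for all fibers)."""

    n_fibers: int = 5                  # fibers converging on one chopper
    release_rate_at_peak: float = 3000.0  # instantaneous events/s at waveform peak
    spont_rate: float = 0.0            # events/s in the absence of drive
    adaptation_tau: float = 10.0       # ms, onset adaptation time constant
    adaptation_floor: float = 0.55     # steady-state fraction of the onset rate
    refractory: float = 1.0            # ms absolute dead time
    phase_locking: bool = True         # rate follows rectified fine structure
    level_gain: float = 1.0            # scalar gain standing in for stimulus level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("ANFiberParams: n_fibers must be >= 1")
        if self.refractory <= 0:
            raise ValueError("ANFiberParams: refractory must be positive")
        if self.adaptation_tau <= 0:
            raise ValueError("ANFiberParams: adaptation_tau must be positive")
        if not 0.0 <= self.adaptation_floor <= 1.0:
            raise ValueError("ANFiberParams: adaptation_floor must lie in [0, 1]")


def _rate_profile(waveform: StimulusWaveform, params: ANFiberParams) -> np.ndarray:
    """Instantaneous rate (events/ms) on the waveform's sample grid."""
    x = waveform.samples
    peak = np.abs(x).max()
    if peak > 0:
        if params.phase_locking:
            drive = np.maximum(x, 0.0) / peak
        else:
            # envelope coding: rectified-and-smoothed drive
            from scipy.signal import hilbert

            drive = np.abs(hilbert(x)) / peak
    else:
        drive = np.zeros_like(x)
    t_ms = waveform.times_ms
    adapt = params.adaptation_floor + (1 - params.adaptation_floor) * np.exp(
        -t_ms / params.adaptation_tau
    )
    rate_per_ms = (
        params.spont_rate / 1e3
        + params.level_gain * params.release_rate_at_peak / 1e3 * adapt * drive
    )
    return rate_per_ms


def an_spikes(
    waveform: StimulusWaveform,
    params: ANFiberParams,
    n_trials: int = 1,
) -> list[SpikeTrain]:
    """Generate one stochastic spike train per fiber.

    Each fiber is an inhomogeneous Bernoulli process on the waveform grid
    (probability ``rate * dt`` per sample, a discrete-time inhomogeneous
    Poisson process), thinned by the absolute refractory period. The result
    is bit-identical for a given seed; distinct fibers and trials use
    independently derived seeds.
    """
    if waveform.samples.size == 0:
        raise ValueError("an_spikes: waveform is empty")
    rate = _rate_profile(waveform, params)
    dt_ms = waveform.sample_interval * 1e3
    t_ms = waveform.times_ms
    t_stop = waveform.duration_ms
    p = np.clip(rate * dt_ms, 0.0, 1.0)

    trains = []
    root = np.random.SeedSequence(params.seed)
    fiber_seqs = root.spawn(params.n_fibers)
    for f in range(params.n_fibers):
        rng_trials = [np.random.default_rng(s) for s in fiber_seqs[f].spawn(n_trials)]
        trials = []
        for rng in rng_trials:
            hits = t_ms[rng.random(p.size) < p]
            trials.append(_dead_time_thin(hits, params.refractory))
        trains.append(
            SpikeTrain(
                unit_id=f"an{f}",
                trials=trials,
                t_stop=t_stop,
                refractory=params.refractory,
            )
        )
    return trains


def _dead_time_thin(times: np.ndarray, refractory: float) -> np.ndarray:
    """Drop events closer than ``refractory`` ms to the previous kept event."""
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def vector_strength(train: SpikeTrain, frequency_hz: float) -> float:
    """Phase-locking index: |mean exp(2 pi i f t)| over all pooled spikes.

    1 for perfect locking to ``frequency_hz``, ~0 for uniform phases.
    """
    times_s = train.pooled() * 1e-3
    if times_s.size == 0:
        return 0.0
    phases = 2 * np.pi * frequency_hz * times_s
    return float(np.abs(np.mean(np.exp(1j * phases))))
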