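"""Stimulus waveforms: tone bursts, amplitude-modulated tones, current steps.

Stimuli are generated at a fixed sample interval and carried around as
:class:`StimulusWaveform` records. Tone bursts follow the standard
physiological protocol (short burst with linear onset/offset ramps at the
unit's characteristic frequency); AM tones are sinusoidally modulated
carriers parameterized by carrier period ``tau_c`` and modulation period
``tau_m``; step drives stand in for the auditory-nerve input when the
periphery is bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "StimulusWaveform",
    "ToneBurstSpec",
    "AMSpec",
    "make_tone_burst",
    "make_am",
    "step_drive",
    "write_waveform",
    "read_waveform",
]


@dataclass
class StimulusWaveform:
    """Sampled stimulus. Amplitudes in arbitrary units, times in seconds."""

    samples: np.ndarray
    sample_interval: float  # s
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D sequence")

    @property
    def duration(self) -> float:
        """Total support in seconds (length x sample_interval)."""
        return self.samples.size * self.sample_interval

    @property
    def duration_ms(self) -> float:
        return self.duration * 1e3

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sample_interval * 1e3


@dataclass(frozen=True)
class ToneBurstSpec:
    """Tone burst: carrier at ``frequency`` Hz gated by linear ramps.

    ``level_db`` is expressed relative to an arbitrary reference threshold;
    peak amplitude is ``10**(level_db/20)`` so level maps monotonically onto
    amplitude. ``level_db = -inf`` yields the all-zero waveform.
    """

    frequency: float      # Hz
    duration: float = 25.0    # ms
    rise_fall: float = 1.6    # ms, linear onset/offset ramp
    level_db: float = 0.0     # dB re threshold amplitude 1.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("ToneBurstSpec: frequency must be positive")
        if self.rise_fall < 0:
            raise ValueError("ToneBurstSpec: rise_fall must be non-negative")
        if self.duration <= 2 * self.rise_fall:
            raise ValueError(
                "ToneBurstSpec: duration must exceed twice the rise/fall time"
            )


@dataclass(frozen=True)
class AMSpec:
    """Amplitude-modulated tone with carrier period tau_c and modulation
    period tau_m (both ms): s(t) = (1 + depth sin(2 pi t / tau_m))
    sin(2 pi t / tau_c), scaled to unit peak."""

    tau_c: float          # ms, carrier period
    tau_m: float          # ms, modulation (envelope) period
    depth: float = 1.0    # modulation depth in [0, 1]
    duration: float = 25.0  # ms

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValueError("AMSpec: tau_c must be positive")
        if not self.tau_m > self.tau_c:
            raise ValueError("AMSpec: modulation period tau_m must exceed tau_c")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("AMSpec: depth must lie in [0, 1]")
        if self.duration <= 0:
            raise ValueError("AMSpec: duration must be positive")

    @property
    def carrier_hz(self) -> float:
        return 1e3 / self.tau_c

    @property
    def modulation_hz(self) -> float:
        return 1e3 / self.tau_m


def make_tone_burst(spec: ToneBurstSpec, sample_interval: float = 25e-6) -> StimulusWaveform:
    """Sinusoid at ``spec.frequency`` gated by linear rise/fall ramps.

    With ``rise_fall = 0`` the gate is rectangular and the envelope equals the
    peak amplitude throughout the burst.
    """
    n = int(round(spec.duration * 1e-3 / sample_interval))
    t = np.arange(n) * sample_interval
    amp = 10.0 ** (spec.level_db / 20.0) if np.isfinite(spec.level_db) else 0.0
    x = amp * np.sin(2 * np.pi * spec.frequency * t)
    env = np.ones(n)
    if spec.rise_fall > 0:
        n_ramp = int(round(spec.rise_fall * 1e-3 / sample_interval))
        if n_ramp > 0:
            ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
            env[:n_ramp] = ramp
            env[n - n_ramp:] = ramp[::-1]
    return StimulusWaveform(
        x * env, sample_interval, label=f"tone_{spec.frequency:g}Hz_{spec.duration:g}ms"
    )


def make_am(spec: AMSpec, sample_interval: float = 25e-6) -> StimulusWaveform:
    """Sinusoidally amplitude-modulated carrier, scaled to unit peak."""
    n = int(round(spec.duration * 1e-3 / sample_interval))
    t_ms = np.arange(n) * sample_interval * 1e3
    env = 1.0 + spec.depth * np.sin(2 * np.pi * t_ms / spec.tau_m)
    x = env * np.sin(2 * np.pi * t_ms / spec.tau_c)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak
    return StimulusWaveform(
        x, sample_interval,
        label=f"am_c{spec.carrier_hz:g}Hz_m{spec.modulation_hz:g}Hz",
    )


def step_drive(
    amplitude: float,
    t_on: float,
    t_off: float,
    duration: float | None = None,
    sample_interval: float = 25e-6,
) -> StimulusWaveform:
    """Piecewise-constant drive: ``amplitude`` on [t_on, t_off) ms, else zero.

    The step models the auditory-nerve input directly as a current when the
    stochastic fiber chain is bypassed.
    """
    if t_on < 0:
        raise ValueError("step_drive: t_on must be non-negative")
    if t_off <= t_on:
        raise ValueError("step_drive: t_off must exceed t_on")
    if duration is None:
        duration = t_off
    n = int(round(duration * 1e-3 / sample_interval))
    t_ms = np.arange(n) * sample_interval * 1e3
    x = np.where((t_ms >= t_on) & (t_ms < t_off), float(amplitude), 0.0)
    return StimulusWaveform(x, sample_interval, label=f"step_{amplitude:g}")


def write_waveform(w: StimulusWaveform, path: str | Path) -> None:
    """Two-column delimited text: time_ms, amplitude."""
    data = np.column_stack([w.times_ms, w.samples])
    np.savetxt(
        path, data, fmt="%.6f\t%.8g",
        header=f"time_ms\tamplitude (sample_interval_s={w.sample_interval:g}, label={w.label})",
    )


def read_waveform(path: str | Path) -> StimulusWaveform:
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    t_ms, x = data[:, 0], data[:, 1]
    if t_ms.size > 1:
        dt_s = float(t_ms[1] - t_ms[0]) * 1e-3
    else:
        dt_s = 25e-6
    return StimulusWaveform(x, dt_s)
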