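"""Periodicity analysis by coincidence detection.

The network comprises, per characteristic frequency (CF), a trigger neuron
fired once per modulation cycle of an amplitude-modulated (AM) stimulus, an
oscillator that emits a short burst of spikes at its intrinsic period
``tau_k`` after each trigger, an integrator that fires one delayed event
``n * tau_c`` after each trigger (n carrier periods), and a coincidence
neuron that fires when an oscillator spike and an integrator event align.

Coincidences therefore occur when

    m * tau_m = n * tau_c - k * tau_k

for small non-negative integers m, n, k: ``m`` is the number of modulation
cycles separating the oscillator's trigger from the integrator's trigger,
so ``m = 1`` marks the fundamental (the unit's best modulation frequency,
BMF) and ``m != 1`` marks harmonic/self coincidences. The inhibitor
(anatomically, the helical lemniscal input) vetoes the latter, sharpening
each unit's modulation tuning to its BMF.

The layer runs on idealized event times; an adapter from simulated chopper
trains is not required for the response-matrix experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import AMSpec

__all__ = [
    "PeriodicityUnit",
    "CoincidenceSolution",
    "ResponseMatrix",
    "solve_coincidence",
    "bmf_of_unit",
    "unit_response",
    "response_matrix",
]


@dataclass(frozen=True)
class PeriodicityUnit:
    """One periodicity-analysis channel.

    ``integrator_n`` is the number of carrier periods the integrator spans;
    ``oscillator_k`` designates which oscillator cycle realizes the unit's
    tuning, so the BMF is ``1 / (n tau_c - k tau_k)``. The oscillator burst
    is limited to ``oscillator_burst`` cycles (the "small integers"
    constraint made physical: the intrinsic oscillation dies out after a
    few cycles).
    """

    cf: float                      # Hz
    tau_k: float                   # ms, intrinsic oscillator period
    integrator_n: int = 8
    oscillator_k: int = 2
    oscillator_burst: int = 2      # oscillator emits spikes k = 0..burst
    coincidence_window: float | None = None  # ms; default 0.1 * tau_c
    inhibition_enabled: bool = False

    def __post_init__(self) -> None:
        if self.cf <= 0 or self.tau_k <= 0:
            raise ValueError("PeriodicityUnit: cf and tau_k must be positive")
        if self.integrator_n < 1:
            raise ValueError("PeriodicityUnit: integrator_n must be >= 1")

    @property
    def tau_c(self) -> float:
        """Carrier period (ms) at the unit's place."""
        return 1e3 / self.cf

    @property
    def window(self) -> float:
        return (
            self.coincidence_window
            if self.coincidence_window is not None
            else 0.1 * self.tau_c
        )

    @staticmethod
    def tuned(cf: float, cf_bmf_ratio: float = 6.0, integrator_n: int = 8,
              oscillator_k: int = 2, inhibition: bool = False) -> "PeriodicityUnit":
        """Construct a unit tuned so that CF / BMF equals the given ratio.

        With the coincidence equation at (m=1, n, k), the required intrinsic
        period is ``tau_k = (n - ratio) * tau_c / k``; at the defaults
        (n=8, k=2, ratio 6) this gives ``tau_k = tau_c``.
        """
        tau_c = 1e3 / cf
        tau_k = (integrator_n - cf_bmf_ratio) * tau_c / oscillator_k
        if tau_k <= 0:
            raise ValueError("tuned: require integrator_n > cf_bmf_ratio")
        return PeriodicityUnit(
            cf=cf, tau_k=tau_k, integrator_n=integrator_n,
            oscillator_k=oscillator_k, inhibition_enabled=inhibition,
        )


@dataclass(frozen=True)
class CoincidenceSolution:
    """One integer solution of the coincidence equation."""

    m: int
    n: int
    k: int
    tau_m: float    # ms
    residual: float  # ms, |m tau_m - (n tau_c - k tau_k)| for the quantized tau_m


def solve_coincidence(
    tau_c: float,
    tau_k: float,
    max_int: int = 10,
    tol: float = 0.05,
    tau_m: float | None = None,
) -> list[CoincidenceSolution]:
    """Enumerate small-integer solutions of ``m tau_m = n tau_c - k tau_k``.

    With ``tau_m`` given, solutions are triples whose implied modulation
    period matches it within ``tol`` ms; otherwise each (m, n, k) with a
    positive ``tau_m = (n tau_c - k tau_k) / m`` exceeding the carrier
    period is emitted exactly (residual 0). Ranges: 1 <= m, n <= max_int,
    0 <= k <= max_int. Sorted by (m, residual, n, k).
    """
    if tau_c <= 0 or tau_k <= 0:
        raise ValueError("solve_coincidence: periods must be positive")
    if max_int < 1:
        raise ValueError("solve_coincidence: max_int must be >= 1")
    out = []
    for m in range(1, max_int + 1):
        for n in range(1, max_int + 1):
            for k in range(0, max_int + 1):
                rhs = n * tau_c - k * tau_k
                if rhs <= 0:
                    continue
                if tau_m is None:
                    cand, res = rhs / m, 0.0
                else:
                    cand = tau_m
                    res = abs(m * tau_m - rhs)
                if cand > tau_c and res <= tol:
                    out.append(CoincidenceSolution(m, n, k, cand, res))
    out.sort(key=lambda s: (s.m, s.residual, s.n, s.k))
    return out


def bmf_of_unit(unit: PeriodicityUnit, tol: float = 0.05) -> float | None:
    """Best modulation frequency (Hz) of a unit.

    The BMF is ``1 / tau_m*`` for the fundamental (m = 1) solution at the
    unit's designated (integrator_n, oscillator_k); ``None`` ("untuned")
    when no such solution with a modulation slower than the carrier exists.
    """
    sols = [
        s
        for s in solve_coincidence(
            unit.tau_c, unit.tau_k,
            max_int=max(unit.integrator_n, unit.oscillator_k, 1), tol=tol,
        )
        if s.m == 1 and s.n == unit.integrator_n and s.k == unit.oscillator_k
    ]
    if not sols:
        return None
    return 1e3 / sols[0].tau_m


def _trigger_times(stimulus: AMSpec, duration: float, rng, jitter_sd: float) -> np.ndarray:
    """Trigger events: one per modulation cycle, at the envelope peak.

    The envelope ``1 + depth sin(2 pi t / tau_m)`` peaks at
    ``tau_m/4 + j tau_m``; with zero depth there is no envelope modulation
    and hence no trigger events.
    """
    if stimulus.depth == 0:
        return np.empty(0)
    peaks = np.arange(stimulus.tau_m / 4, duration, stimulus.tau_m)
    if jitter_sd > 0:
        peaks = peaks + rng.normal(0.0, jitter_sd, peaks.size)
        peaks.sort()
    return peaks


def unit_response(
    stimulus: AMSpec,
    unit: PeriodicityUnit,
    duration: float | None = None,
    seed: int = 0,
    trigger_jitter_sd: float = 0.0,
    max_m: int = 5,
) -> int:
    """Coincidence-spike count of one unit for one AM stimulus.

    Per modulation cycle the trigger fires at the envelope peak; the
    oscillator emits a burst at ``tau_k`` intervals from each trigger and
    the integrator one event ``n tau_c`` after each trigger. A coincidence
    is counted when an integrator event falls within half the coincidence
    window of an oscillator spike; each integrator event coincides at most
    once and is attributed to the smallest modulation-cycle separation
    ``m`` that explains it. With inhibition, only fundamental (m = 1)
    coincidences survive the veto.
    """
    if duration is None:
        duration = stimulus.duration
    if duration < stimulus.tau_m:
        raise ValueError("unit_response: duration shorter than one modulation period")
    rng = np.random.default_rng(seed)
    triggers = _trigger_times(stimulus, duration, rng, trigger_jitter_sd)
    if triggers.size == 0:
        return 0
    half = unit.window / 2
    count = 0
    n_delay = unit.integrator_n * unit.tau_c
    for j, t_j in enumerate(triggers):
        t_int = t_j + n_delay
        if t_int > duration:
            continue
        # oscillator bursts from triggers up to max_m cycles after trigger j
        for m in range(0, max_m + 1):
            jj = j + m
            if jj >= triggers.size:
                break
            dt_osc = t_int - triggers[jj]
            if dt_osc < -half:
                break
            k = int(round(dt_osc / unit.tau_k))
            if 0 <= k <= unit.oscillator_burst and abs(dt_osc - k * unit.tau_k) <= half:
                if not unit.inhibition_enabled or m == 1:
                    count += 1
                break
    return count


@dataclass
class ResponseMatrix:
    """Coincidence counts of CF-indexed units (rows) for modulation
    frequencies (columns); the Figure-3-style carrier x modulation grid."""

    carrier_freqs: np.ndarray   # Hz, one per row/unit
    mod_freqs: np.ndarray       # Hz, one per column
    response: np.ndarray        # (n_cf, n_mod) counts
    inhibition_enabled: bool

    def row_argmax_freqs(self) -> np.ndarray:
        """Modulation frequency of each row's maximal response."""
        return self.mod_freqs[np.argmax(self.response, axis=1)]


def response_matrix(
    n_units: int = 16,
    cf_list: np.ndarray | None = None,
    cf_bmf_ratio: float = 6.0,
    inhibition: bool = False,
    seed: int = 0,
    duration: float = 150.0,
    depth: float = 1.0,
    trigger_jitter_sd: float = 0.0,
) -> ResponseMatrix:
    """Simulate all carrier x modulation combinations (16 x 16 = 256 at the
    defaults).

    Each row is one unit whose CF equals the stimulus carrier; the
    modulation-frequency grid is the units' BMF grid (CF / ratio), so with
    inhibition every row peaks at the column nearest CF / ratio. The CF
    values are a convention (the figure the experiment follows does not
    print them): ``n_units`` values log-spaced over three octaves at five
    columns per octave, 1-8 kHz by default, so that each unit's second
    harmonic lies exactly on the grid and harmonic sidebands are visible
    without inhibition.
    """
    if cf_list is None:
        cf_list = 1000.0 * 2 ** (np.arange(n_units) / 5.0)
    cf_list = np.asarray(cf_list, dtype=float)
    if cf_list.size != n_units:
        raise ValueError("response_matrix: need one CF per unit")
    mod_freqs = cf_list / cf_bmf_ratio
    resp = np.zeros((n_units, mod_freqs.size))
    for i, cf in enumerate(cf_list):
        unit = PeriodicityUnit.tuned(cf, cf_bmf_ratio, inhibition=inhibition)
        for j, fm in enumerate(mod_freqs):
            if fm >= cf:
                continue  # modulation must be slower than the carrier
            stim = AMSpec(tau_c=1e3 / cf, tau_m=1e3 / fm, depth=depth,
                          duration=duration)
            resp[i, j] = unit_response(
                stim, unit, duration=duration,
                seed=seed + 1000 * i + j, trigger_jitter_sd=trigger_jitter_sd,
            )
    return ResponseMatrix(
        carrier_freqs=cf_list, mod_freqs=mod_freqs, response=resp,
        inhibition_enabled=inhibition,
    )
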