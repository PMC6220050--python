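"""Decoding ramping activity against nested fast/slow oscillations.

A slow oscillation (period ``tau_slow``) carries an excitation phase in
which ``n_nested`` cycles of a fast (gamma-band) oscillation are nested;
each fast cycle opens a brief excitation window (default 3 ms, the
excitatory fraction of a gamma cycle). A neuron with ramping (integrator-
like) activity reaches its threshold at some time t*; a downstream
coincidence detector fires at the first nested excitation window from t*
on. The time from ramp onset to that coincidence, the integration period,
therefore lies on the two-scale lattice

    integration period = p * tau_slow + q * tau_fast

for integers p >= 0 and 0 <= q < n_nested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OscillatorHierarchy",
    "RampSpec",
    "DecodeResult",
    "integration_period",
    "decode",
]


@dataclass(frozen=True)
class OscillatorHierarchy:
    """Nested oscillations: fast cycles q = 0..n_nested-1 exist only during
    the excitation phase at the start of each slow cycle. Only complete
    fast cycles are counted, so ``n_nested * tau_fast <= tau_slow``."""

    tau_slow: float = 100.0        # ms
    tau_fast: float = 25.0         # ms (gamma band)
    excitation_window: float = 3.0  # ms per fast cycle
    n_nested: int = 3

    def __post_init__(self) -> None:
        if not self.tau_slow > self.tau_fast > 0:
            raise ValueError("OscillatorHierarchy: require tau_slow > tau_fast > 0")
        if self.excitation_window > self.tau_fast:
            raise ValueError(
                "OscillatorHierarchy: excitation_window must not exceed tau_fast"
            )
        if self.n_nested < 1 or self.n_nested * self.tau_fast > self.tau_slow:
            raise ValueError(
                "OscillatorHierarchy: n_nested fast cycles must fit in one slow cycle"
            )


@dataclass(frozen=True)
class RampSpec:
    """Linear ramp from ``start_time``; threshold crossing at
    ``start_time + threshold / slope``."""

    start_time: float = 0.0  # ms
    slope: float = 1.0       # a.u./ms
    threshold: float = 1.0   # a.u.

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.threshold <= 0:
            raise ValueError("RampSpec: slope and threshold must be positive")

    @property
    def crossing_time(self) -> float:
        return self.start_time + self.threshold / self.slope


@dataclass(frozen=True)
class DecodeResult:
    coincidence_time: float  # ms; None-like NaN when no coincidence
    p: int
    q: int
    lattice_residual: float  # |coincidence_time - (p tau_slow + q tau_fast)|
    found: bool = True


def integration_period(p: int, q: int, h: OscillatorHierarchy) -> float:
    """Exact lattice time ``p * tau_slow + q * tau_fast``."""
    if p < 0 or q < 0:
        raise ValueError("integration_period: p and q must be non-negative")
    if q >= h.n_nested:
        raise ValueError(
            f"integration_period: q={q} but only {h.n_nested} nested cycles exist"
        )
    return p * h.tau_slow + q * h.tau_fast


def decode(
    ramp: RampSpec,
    h: OscillatorHierarchy,
    horizon: float | None = None,
) -> DecodeResult:
    """Earliest nested excitation window reached by a ramp.

    The threshold crossing t* is snapped to the first window center
    ``c = p tau_slow + q tau_fast`` (relative to ramp start) with
    ``c >= t* - window/2``: a crossing inside a window's first half still
    coincides with that window. Returns the lattice coordinates (p, q)
    recovered from the coincidence time; flags ``found=False`` when the
    ramp never reaches a window within the horizon.
    """
    t_star = ramp.crossing_time - ramp.start_time  # lattice is ramp-anchored
    if horizon is None:
        horizon = t_star + 2 * h.tau_slow
    half = h.excitation_window / 2
    p = max(0, int(np.floor((t_star - half) / h.tau_slow)))
    while p * h.tau_slow <= horizon:
        for q in range(h.n_nested):
            c = p * h.tau_slow + q * h.tau_fast
            if c >= t_star - half:
                return DecodeResult(
                    coincidence_time=ramp.start_time + c,
                    p=p, q=q,
                    lattice_residual=abs(c - (p * h.tau_slow + q * h.tau_fast)),
                )
        p += 1
    return DecodeResult(
        coincidence_time=float("nan"), p=-1, q=-1,
        lattice_residual=float("nan"), found=False,
    )
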