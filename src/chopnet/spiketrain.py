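"""Spike trains: the universal currency between all modules.

A :class:`SpikeTrain` holds the ordered spike times of one unit across one or
more trials, in milliseconds relative to stimulus onset. All analysis
(ISIs, PSTH, regularity) and all I/O operate on this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpikeTrain", "read_spikes", "write_spikes"]

# ms precision used when serializing spike times; finer than the engine's
# default integration step (0.025 ms) so round-trips are exact.
_TIME_DECIMALS = 6


@dataclass
class SpikeTrain:
    """Ordered spike times of one unit across one or more trials.

    Parameters
    ----------
    unit_id : str
        Identifier of the emitting unit.
    trials : list of array-like
        One array of strictly increasing spike times (ms) per trial.
    t_stop : float
        End of the observation window (ms). All times lie in ``[0, t_stop]``.
    refractory : float, optional
        Absolute refractory period (ms) declared by the generating unit.
        When positive, consecutive spikes within a trial must be separated
        by at least this much.
    """

    unit_id: str
    trials: list = field(default_factory=list)
    t_stop: float = 0.0
    refractory: float = 0.0

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.t_stop < 0:
            raise ValueError("t_stop must be non-negative")
        for i, times in enumerate(self.trials):
            if times.ndim != 1:
                raise ValueError(f"trial {i}: spike times must be 1-D")
            if times.size == 0:
                continue
            if times.min() < 0 or times.max() > self.t_stop:
                raise ValueError(
                    f"trial {i}: spike times outside [0, t_stop={self.t_stop}]"
                )
            d = np.diff(times)
            if np.any(d <= 0):
                raise ValueError(f"trial {i}: spike times not strictly increasing")
            if self.refractory > 0 and np.any(d < self.refractory * (1 - 1e-9)):
                raise ValueError(
                    f"trial {i}: inter-spike interval below declared "
                    f"refractory period {self.refractory} ms"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))

    def pooled(self) -> np.ndarray:
        """All spike times pooled (and sorted) across trials."""
        if not self.trials:
            return np.empty(0)
        return np.sort(np.concatenate(self.trials))

    def merged_with(self, other: "SpikeTrain", unit_id: str = "merged") -> "SpikeTrain":
        """Trial-wise merge of two units' spikes into one population train."""
        if self.n_trials != other.n_trials:
            raise ValueError("cannot merge trains with different trial counts")
        trials = [
            np.sort(np.concatenate([a, b]))
            for a, b in zip(self.trials, other.trials)
        ]
        t = SpikeTrain.__new__(SpikeTrain)  # skip monotonicity check: merged
        t.unit_id = unit_id                 # trains may contain coincidences
        t.trials = trials
        t.t_stop = max(self.t_stop, other.t_stop)
        t.refractory = 0.0
        return t


def write_spikes(train: SpikeTrain, path: str | Path, meta: dict | None = None) -> None:
    """Write a train as delimited text (trial, time_ms) plus a JSON sidecar.

    Times are written with fixed 6-decimal precision, sub-integration-step
    resolution, so ``read_spikes(write_spikes(t)) == t``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# trial\ttime_ms\n")
        for i, times in enumerate(train.trials):
            for t in times:
                fh.write(f"{i}\t{t:.{_TIME_DECIMALS}f}\n")
    sidecar = {
        "unit_id": train.unit_id,
        "t_stop": train.t_stop,
        "n_trials": train.n_trials,
        "refractory": train.refractory,
    }
    if meta:
        sidecar.update(meta)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_spikes(path: str | Path) -> SpikeTrain:
    """Read a train written by :func:`write_spikes`.

    Raises
    ------
    ValueError
        If times within a trial are non-monotone, naming the offending line.
    """
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    n_trials = int(sidecar["n_trials"])
    trials: list[list[float]] = [[] for _ in range(n_trials)]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            trial_s, time_s = line.split()
            trial, t = int(trial_s), float(time_s)
            if trial >= n_trials:
                trials.extend([] for _ in range(trial - n_trials + 1))
                n_trials = trial + 1
            if trials[trial] and t <= trials[trial][-1]:
                raise ValueError(
                    f"{path}:{lineno}: non-monotone spike time {t} in trial {trial}"
                )
            trials[trial].append(t)
    return SpikeTrain(
        unit_id=sidecar["unit_id"],
        trials=trials,
        t_stop=float(sidecar["t_stop"]),
        refractory=float(sidecar.get("refractory", 0.0)),
    )
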