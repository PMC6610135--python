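"""Core in-memory containers shared across the simulation and analysis modules.

``VmTraceSet`` holds regularly sampled membrane potentials for a set of cells;
``SpikeTrainSet`` holds per-unit spike times over a recording interval. Both
are deliberately thin wrappers around numpy arrays: analysis code operates on
the arrays directly, while the containers enforce the handful of invariants
that downstream algorithms rely on (equal trace lengths, ordered spike times,
times inside the recording interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VmTraceSet", "SpikeTrainSet"]


@dataclass
class VmTraceSet:
    """Sampled membrane potentials (mV) for a set of cells at a fixed rate.

    Parameters
    ----------
    cell_ids : list of str or int
        One identifier per cell, in row order of ``potentials``.
    fs : float
        Sampling rate in Hz.
    potentials : ndarray, shape (n_cells, n_samples)
        Membrane potential in mV.
    t0 : float
        Time of the first sample in seconds.
    """

    cell_ids: list
    fs: float
    potentials: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.potentials = np.atleast_2d(np.asarray(self.potentials, dtype=float))
        if len(self.cell_ids) != self.potentials.shape[0]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids but "
                f"{self.potentials.shape[0]} potential rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_cells(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def trace(self, cell_id) -> np.ndarray:
        return self.potentials[self.cell_ids.index(cell_id)]


@dataclass
class SpikeTrainSet:
    """Per-unit spike times (seconds) over a recording interval.

    ``trains`` maps unit id -> sorted 1-d array of spike times. Times must lie
    within ``interval`` (half-open ``[start, stop)``).
    """

    trains: dict
    interval: tuple = (0.0, np.inf)

    def __post_init__(self) -> None:
        start, stop = self.interval
        if stop <= start:
            raise ValueError("empty recording interval")
        clean = {}
        for unit, times in self.trains.items():
            t = np.asarray(times, dtype=float).ravel()
            t = np.sort(t)
            if t.size and (t[0] < start or t[-1] >= stop):
                raise ValueError(
                    f"unit {unit!r}: spike times outside interval {self.interval}"
                )
            clean[unit] = t
        self.trains = clean

    @property
    def unit_ids(self) -> list:
        return list(self.trains.keys())

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def counts(self) -> dict:
        return {u: t.size for u, t in self.trains.items()}

    def merged(self, units=None) -> np.ndarray:
        """Pooled, sorted spike times of the selected units."""
        keys = self.unit_ids if units is None else list(units)
        if not keys:
            return np.empty(0)
        return np.sort(np.concatenate([self.trains[u] for u in keys]))

    def subset(self, units) -> "SpikeTrainSet":
        return SpikeTrainSet({u: self.trains[u] for u in units}, self.interval)
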