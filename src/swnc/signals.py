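"""Labeled multi-sensor biaxial signal container.

The universal in-memory object of the package: a stack of fixed-length
analysis windows, each observed simultaneously by every sensor of a body
network.  Acceleration is stored in units of G (1 G = 9.81 m/s², 1000 mG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledSignalSet"]


@dataclass
class LabeledSignalSet:
    """Windowed biaxial acceleration from ``M`` sensors with one activity label per window.

    Attributes
    ----------
    x, y : ndarray, shape (W, M, T)
        Acceleration along the two sensed axes, in G.  ``W`` windows,
        ``M`` sensors, ``T`` samples per window.
    labels : ndarray, shape (W,)
        Integer activity class id (1..N) of each window.
    subjects : ndarray, shape (W,)
        Integer subject id of each window.
    sensor_ids : ndarray, shape (M,)
        Sensor ids, in the column order of ``x``/``y``.
    rate : float
        Sampling rate in Hz.
    disturbed : ndarray of bool, shape (W, M)
        Provenance flags: True where a noise model has altered the window.
        Freshly generated data carries all-False flags.
    """

    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    sensor_ids: np.ndarray
    rate: float
    disturbed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subjects = np.asarray(self.subjects, dtype=int)
        self.sensor_ids = np.asarray(self.sensor_ids, dtype=int)
        if self.x.ndim != 3 or self.x.shape != self.y.shape:
            raise ValueError("x and y must both have shape (windows, sensors, samples)")
        w, m, _ = self.x.shape
        if self.labels.shape != (w,) or self.subjects.shape != (w,):
            raise ValueError("labels and subjects must have one entry per window")
        if self.sensor_ids.shape != (m,):
            raise ValueError("sensor_ids must have one entry per sensor column")
        if len(np.unique(self.sensor_ids)) != m:
            raise ValueError("sensor ids must be unique")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.disturbed is None:
            self.disturbed = np.zeros((w, m), dtype=bool)
        else:
            self.disturbed = np.asarray(self.disturbed, dtype=bool)
            if self.disturbed.shape != (w, m):
                raise ValueError("disturbed flags must have shape (windows, sensors)")

    # -- shape helpers -------------------------------------------------
    @property
    def n_windows(self) -> int:
        return self.x.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.x.shape[1]

    @property
    def n_samples(self) -> int:
        return self.x.shape[2]

    @property
    def class_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def sensor_index(self, sensor_id: int) -> int:
        """Column index of ``sensor_id``; raises for unknown ids."""
        hits = np.nonzero(self.sensor_ids == sensor_id)[0]
        if hits.size == 0:
            raise ValueError(f"unknown sensor id {sensor_id!r}")
        return int(hits[0])

    # -- subsetting ----------------------------------------------------
    def select_windows(self, index: np.ndarray) -> "LabeledSignalSet":
        index = np.asarray(index)
        return LabeledSignalSet(
            x=self.x[index].copy(),
            y=self.y[index].copy(),
            labels=self.labels[index].copy(),
            subjects=self.subjects[index].copy(),
            sensor_ids=self.sensor_ids.copy(),
            rate=self.rate,
            disturbed=self.disturbed[index].copy(),
        )

    def select_sensors(self, sensor_ids) -> "LabeledSignalSet":
        cols = [self.sensor_index(s) for s in sensor_ids]
        return LabeledSignalSet(
            x=self.x[:, cols].copy(),
            y=self.y[:, cols].copy(),
            labels=self.labels.copy(),
            subjects=self.subjects.copy(),
            sensor_ids=np.asarray([self.sensor_ids[c] for c in cols]),
            rate=self.rate,
            disturbed=self.disturbed[:, cols].copy(),
        )

    def copy(self) -> "LabeledSignalSet":
        return LabeledSignalSet(
            x=self.x.copy(),
            y=self.y.copy(),
            labels=self.labels.copy(),
            subjects=self.subjects.copy(),
            sensor_ids=self.sensor_ids.copy(),
            rate=self.rate,
            disturbed=self.disturbed.copy(),
        )

    def equals(self, other: "LabeledSignalSet") -> bool:
        """Bit-exact equality of signals, labels and metadata (flags excluded)."""
        return (
            self.x.shape == other.x.shape
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.subjects, other.subjects)
            and np.array_equal(self.sensor_ids, other.sensor_ids)
            and self.rate == other.rate
        )
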