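"""Readers/writers for the columnar signal format, model persistence and run configs.

Signal CSV schema: header ``subject,sensor,window,sample,ax,ay,label``,
acceleration in G as decimal floats, label as integer class id.  The
sampling rate is not part of the schema and is supplied by the caller.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from .evaluation import StudyConfig
from .fusion import FitConfig, TrainedSWNC
from .noise import DisturbanceSpec
from .signals import LabeledSignalSet
from .synthetic import SyntheticDatasetConfig

__all__ = [
    "ParseError",
    "RunConfig",
    "read_signals",
    "write_signals",
    "save_model",
    "load_model",
    "model_metadata",
]

_COLUMNS = ("subject", "sensor", "window", "sample", "ax", "ay", "label")
_INT_COLUMNS = ("subject", "sensor", "window", "sample", "label")


class ParseError(ValueError):
    """A signal file violates the columnar schema."""


def write_signals(dataset: LabeledSignalSet, path: str | Path) -> None:
    """Write a signal set to CSV, lossless to 9 significant digits."""
    w, m, t = dataset.x.shape
    frame = pd.DataFrame(
        {
            "subject": np.repeat(dataset.subjects, m * t),
            "sensor": np.tile(np.repeat(dataset.sensor_ids, t), w),
            "window": np.repeat(np.arange(w), m * t),
            "sample": np.tile(np.arange(t), w * m),
            "ax": dataset.x.ravel(),
            "ay": dataset.y.ravel(),
            "label": np.repeat(dataset.labels, m * t),
        }
    )
    frame.to_csv(path, index=False, float_format="%.9g")


def _coerce(frame: pd.DataFrame, column: str, kind: str) -> np.ndarray:
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = values.isna() & frame[column].notna()
    if bad.any() or values.isna().any():
        line = int(np.flatnonzero(values.isna())[0]) + 2  # +1 header, +1 one-based
        raise ParseError(f"column {column!r}, line {line}: not a valid number")
    if kind == "int":
        ints = values.astype(int)
        if not np.allclose(values, ints):
            line = int(np.flatnonzero(values != ints)[0]) + 2
            raise ParseError(f"column {column!r}, line {line}: expected an integer")
        return ints.to_numpy()
    return values.to_numpy(dtype=float)


def read_signals(path: str | Path, rate: float = 50.0) -> LabeledSignalSet:
    """Read a signal CSV back into a :class:`LabeledSignalSet`.

    Malformed rows are rejected with the offending column and line number.
    An empty file with a valid header yields an empty set.
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError("file is empty (missing header)") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing column(s): {', '.join(missing)}")
    if frame.empty:
        return LabeledSignalSet(
            x=np.empty((0, 0, 0)),
            y=np.empty((0, 0, 0)),
            labels=np.empty(0, dtype=int),
            subjects=np.empty(0, dtype=int),
            sensor_ids=np.empty(0, dtype=int),
            rate=rate,
        )
    cols = {c: _coerce(frame, c, "int" if c in _INT_COLUMNS else "float") for c in _COLUMNS}

    windows = np.unique(cols["window"])
    sensors = np.unique(cols["sensor"])
    samples = np.unique(cols["sample"])
    w, m, t = windows.size, sensors.size, samples.size
    if len(frame) != w * m * t:
        raise ParseError(
            "incomplete grid: every (window, sensor) must carry the same sample count"
        )
    wi = np.searchsorted(windows, cols["window"])
    si = np.searchsorted(sensors, cols["sensor"])
    ti = np.searchsorted(samples, cols["sample"])
    x = np.full((w, m, t), np.nan)
    y = np.full((w, m, t), np.nan)
    x[wi, si, ti] = cols["ax"]
    y[wi, si, ti] = cols["ay"]
    if np.isnan(x).any() or np.isnan(y).any():
        raise ParseError("duplicate or missing (window, sensor, sample) rows")
    labels = np.empty(w, dtype=int)
    subjects = np.empty(w, dtype=int)
    labels[wi] = cols["label"]
    subjects[wi] = cols["subject"]
    # consistency: one label/subject per window
    for name, arr in (("label", labels), ("subject", subjects)):
        per_row = cols[name]
        if not np.array_equal(arr[wi], per_row):
            raise ParseError(f"column {name!r}: inconsistent values within a window")
    return LabeledSignalSet(
        x=x, y=y, labels=labels, subjects=subjects, sensor_ids=sensors, rate=rate
    )


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedSWNC, path: str | Path) -> None:
    """Persist a trained model (binary companion) plus JSON metadata alongside."""
    path = Path(path)
    joblib.dump(model, path)
    meta_path = path.with_suffix(path.suffix + ".json")
    with open(meta_path, "w") as fh:
        json.dump(model_metadata(model), fh, indent=2)


def load_model(path: str | Path) -> TrainedSWNC:
    return joblib.load(path)


def model_metadata(model: TrainedSWNC) -> dict:
    """JSON-serializable summary: weights, selections, hyperparameters."""
    return {
        "class_labels": model.class_labels.tolist(),
        "mu": model.mu.tolist(),
        "rate": model.rate,
        "config": {**asdict(model.config), "k_grid": list(model.config.k_grid)},
        "nodes": [
            {
                "sensor_id": node.sensor_id,
                "lambda": node.lam.tolist(),
                "classifiers": [
                    {
                        "class": c.class_label,
                        "k": c.k,
                        "features": [s.name for s in c.selection],
                        "scores": [s.score for s in c.selection],
                    }
                    for c in node.classifiers
                ],
            }
            for node in model.nodes
        ],
    }


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """A complete, serializable description of one run.

    Round-trips losslessly through YAML; every run directory stores the
    exact configuration used.
    """

    scenario: SyntheticDatasetConfig = field(default_factory=SyntheticDatasetConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    study: StudyConfig = field(default_factory=StudyConfig)
    disturbance: DisturbanceSpec | None = None
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = {
            "scenario": asdict(self.scenario),
            "fit": {**asdict(self.fit), "k_grid": list(self.fit.k_grid)},
            "study": _study_to_dict(self.study),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        if self.disturbance is not None:
            d["disturbance"] = self.disturbance.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - {"scenario", "fit", "study", "disturbance", "seed", "out_dir"}
        if unknown:
            raise ValueError(f"unknown config section(s): {', '.join(sorted(unknown))}")
        fit = _fit_from_dict(d.get("fit", {}))
        return cls(
            scenario=SyntheticDatasetConfig(**d.get("scenario", {})),
            fit=fit,
            study=_study_from_dict(d.get("study", {}), fit),
            disturbance=(
                DisturbanceSpec.from_dict(d["disturbance"])
                if d.get("disturbance")
                else None
            ),
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "results")),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)


def _fit_from_dict(d: dict) -> FitConfig:
    d = dict(d)
    if "k_grid" in d:
        d["k_grid"] = tuple(d["k_grid"])
    return FitConfig(**d)


def _study_to_dict(s: StudyConfig) -> dict:
    d = asdict(s)
    for k in ("rot_levels", "add_levels", "kinds", "s_values"):
        if d.get(k) is not None:
            d[k] = list(d[k])
    d["fit"] = {**asdict(s.fit), "k_grid": list(s.fit.k_grid)}
    return d


def _study_from_dict(d: dict, fit: FitConfig) -> StudyConfig:
    d = dict(d)
    for k in ("rot_levels", "add_levels", "kinds", "s_values"):
        if d.get(k) is not None:
            d[k] = tuple(d[k])
    if "fit" in d:
        d["fit"] = _fit_from_dict(d["fit"])
    else:
        d["fit"] = fit
    return StudyConfig(**d)
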