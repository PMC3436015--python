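"""Robustness experiments: accuracy-vs-noise curves for single sensors and fusion.

The protocol mirrors a design-time/runtime mismatch study: models are
trained on clean data only (70% of the windows, stratified), disturbances
are injected into the *test* partition only, and the whole train/disturb/
score cycle is repeated with fresh random splits to obtain mean ± std
accuracy per noise level.  Fusion experiments disturb a random subset of
``S`` sensors, redrawn each repetition.

All randomness flows from one master seed through a fixed derivation
(`derive_seed`), so every curve is exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fusion import FitConfig, TrainedSWNC, fit
from .noise import ADDITIVE, ROTATIONAL, DisturbanceSpec, _disturb_sensor_arrays, disturb
from .signals import LabeledSignalSet

__all__ = [
    "ExperimentConfig",
    "StudyConfig",
    "RobustnessCurve",
    "StudyResult",
    "accuracy",
    "derive_seed",
    "stratified_split",
    "run_single_sensor",
    "run_fusion",
    "compare",
    "robustness_study",
    "sweep",
]

# fixed stream ids of the master-seed derivation
_STREAM_SPLIT = 1
_STREAM_FIT = 2
_STREAM_DISTURB = 3
_STREAM_SUBSET = 4
_KIND_CODE = {ROTATIONAL: 1, ADDITIVE: 2}


def derive_seed(master: int, *key: int) -> int:
    """Deterministically derive a component seed (< 2^31) from the master seed."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def accuracy(predictions: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of exact class matches."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    return float(np.mean(predictions == truth))


def stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified train/test split of window indices."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must lie in (0, 1)")
    train: list[int] = []
    test: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_tr = int(round(train_fraction * idx.size))
        n_tr = min(max(n_tr, 1), idx.size - 1)
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr:])
    return np.sort(np.array(train)), np.sort(np.array(test))


@dataclass(frozen=True)
class ExperimentConfig:
    """One robustness experiment: a noise kind, a level grid and a repetition count.

    ``levels`` must contain 0 (the clean baseline).  ``s`` is the number
    of simultaneously disturbed sensors in fusion mode (ignored in
    single-sensor mode).
    """

    kind: str
    levels: tuple[float, ...]
    s: int = 1
    repetitions: int = 20
    train_fraction: float = 0.7
    granularity: str = "window"
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if 0 not in self.levels:
            raise ValueError("level grid must contain 0 (the clean baseline)")
        if self.repetitions < 1:
            raise ValueError("need at least one repetition")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie in (0, 1)")
        if self.s < 0:
            raise ValueError("S must be non-negative")


@dataclass
class RobustnessCurve:
    """Accuracy mean ± std per noise level, plus the per-repetition samples."""

    kind: str
    levels: tuple[float, ...]
    accuracies: np.ndarray  # (repetitions, n_levels)
    meta: dict = field(default_factory=dict)

    @property
    def mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)

    @property
    def std(self) -> np.ndarray:
        if self.accuracies.shape[0] < 2:
            return np.zeros(self.accuracies.shape[1])
        return self.accuracies.std(axis=0, ddof=1)

    @property
    def repetitions(self) -> int:
        return self.accuracies.shape[0]

    def to_frame(self) -> pd.DataFrame:
        reps, nl = self.accuracies.shape
        return pd.DataFrame(
            {
                "rep": np.repeat(np.arange(reps), nl),
                "level": np.tile(self.levels, reps),
                "accuracy": self.accuracies.ravel(),
            }
        )


def _fit_clean(
    train: LabeledSignalSet, fit_config: FitConfig, seed: int
) -> TrainedSWNC:
    if train.disturbed.any():
        raise ValueError("training windows must be clean (never disturbed)")
    return fit(train, replace(fit_config, seed=seed))


def run_single_sensor(
    dataset: LabeledSignalSet, sensor_id: int, config: ExperimentConfig
) -> RobustnessCurve:
    """Accuracy-vs-level curve of a single-node pipeline on one sensor.

    Per repetition: fresh stratified split, fit on clean training
    windows, disturb only the test windows of ``sensor_id`` at each grid
    level, score.
    """
    sub = dataset.select_sensors([sensor_id])
    acc = np.empty((config.repetitions, len(config.levels)))
    for r in range(config.repetitions):
        split_rng = np.random.default_rng(derive_seed(config.seed, _STREAM_SPLIT, r))
        tr, te = stratified_split(sub.labels, config.train_fraction, split_rng)
        train, test = sub.select_windows(tr), sub.select_windows(te)
        model = _fit_clean(train, config.fit, derive_seed(config.seed, _STREAM_FIT, r))
        for li, level in enumerate(config.levels):
            spec = DisturbanceSpec(
                kind=config.kind,
                level=level,
                sensors=(sensor_id,),
                granularity=config.granularity,
                seed=derive_seed(
                    config.seed, _STREAM_DISTURB, _KIND_CODE[config.kind], r, li
                ),
            )
            pred = model.predict(disturb(test, spec))
            acc[r, li] = accuracy(pred.classes, test.labels)
    return RobustnessCurve(
        kind=config.kind,
        levels=config.levels,
        accuracies=acc,
        meta={"mode": "single", "sensor_id": sensor_id, "config": _config_dict(config)},
    )


def run_fusion(
    dataset: LabeledSignalSet, config: ExperimentConfig
) -> RobustnessCurve:
    """Accuracy-vs-level curve of the full SWNC with ``config.s`` disturbed sensors.

    The disturbed subset is redrawn per repetition and level.
    """
    if config.s > dataset.n_sensors:
        raise ValueError("S cannot exceed the number of sensors")
    acc = np.empty((config.repetitions, len(config.levels)))
    for r in range(config.repetitions):
        split_rng = np.random.default_rng(derive_seed(config.seed, _STREAM_SPLIT, r))
        tr, te = stratified_split(dataset.labels, config.train_fraction, split_rng)
        train, test = dataset.select_windows(tr), dataset.select_windows(te)
        model = _fit_clean(train, config.fit, derive_seed(config.seed, _STREAM_FIT, r))
        for li, level in enumerate(config.levels):
            subset_rng = np.random.default_rng(
                derive_seed(
                    config.seed, _STREAM_SUBSET, _KIND_CODE[config.kind], r, li
                )
            )
            sensors = tuple(
                subset_rng.choice(dataset.sensor_ids, size=config.s, replace=False)
            )
            spec = DisturbanceSpec(
                kind=config.kind,
                level=level,
                sensors=sensors,
                granularity=config.granularity,
                seed=derive_seed(
                    config.seed, _STREAM_DISTURB, _KIND_CODE[config.kind], r, li
                ),
            )
            pred = model.predict(disturb(test, spec))
            acc[r, li] = accuracy(pred.classes, test.labels)
    return RobustnessCurve(
        kind=config.kind,
        levels=config.levels,
        accuracies=acc,
        meta={"mode": "fusion", "s": config.s, "config": _config_dict(config)},
    )


def compare(fused: RobustnessCurve, singles: Sequence[RobustnessCurve]) -> pd.DataFrame:
    """Per-level comparison of a fused curve against single-sensor curves.

    Flags levels where fusion underperforms the best single sensor.
    """
    for s in singles:
        if tuple(s.levels) != tuple(fused.levels):
            raise ValueError("level grids of all curves must match")
    single_means = np.vstack([s.mean for s in singles])
    return pd.DataFrame(
        {
            "level": fused.levels,
            "fused_mean": fused.mean,
            "single_best": single_means.max(axis=0),
            "single_mean": single_means.mean(axis=0),
            "single_worst": single_means.min(axis=0),
            "fused_minus_best": fused.mean - single_means.max(axis=0),
            "fused_minus_mean": fused.mean - single_means.mean(axis=0),
            "fused_below_best": fused.mean < single_means.max(axis=0),
        }
    )


# ---------------------------------------------------------------------------
# shared-fit study driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """The full factorial robustness study (both kinds, all sensors, all S)."""

    rot_levels: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 90.0, 180.0)
    add_levels: tuple[float, ...] = (0.0, 50.0, 100.0, 200.0, 500.0)
    kinds: tuple[str, ...] = (ROTATIONAL, ADDITIVE)
    s_values: tuple[int, ...] | None = None  # default 1..M
    repetitions: int = 20
    train_fraction: float = 0.7
    granularity: str = "window"
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0

    def levels_of(self, kind: str) -> tuple[float, ...]:
        return self.rot_levels if kind == ROTATIONAL else self.add_levels


@dataclass
class StudyResult:
    """All curves of one study, sharing one model fit per repetition."""

    config: StudyConfig
    sensor_ids: np.ndarray
    s_values: tuple[int, ...]
    singles: dict  # kind -> (reps, n_levels, M)
    fused: dict  # kind -> (reps, n_levels, n_S)
    clean_single: np.ndarray  # (reps, M)
    clean_fused: np.ndarray  # (reps,)

    def single_curve(self, kind: str, sensor_id: int) -> RobustnessCurve:
        m = int(np.flatnonzero(self.sensor_ids == sensor_id)[0])
        return RobustnessCurve(
            kind=kind,
            levels=self.config.levels_of(kind),
            accuracies=self.singles[kind][:, :, m],
            meta={"mode": "single", "sensor_id": sensor_id},
        )

    def fused_curve(self, kind: str, s: int) -> RobustnessCurve:
        si = self.s_values.index(s)
        return RobustnessCurve(
            kind=kind,
            levels=self.config.levels_of(kind),
            accuracies=self.fused[kind][:, :, si],
            meta={"mode": "fusion", "s": s},
        )


def robustness_study(dataset: LabeledSignalSet, config: StudyConfig) -> StudyResult:
    """Run the full factorial study with one SWNC fit per repetition.

    The fitted network's nodes double as the single-sensor models: a node
    is trained by exactly the procedure a standalone single-sensor fit
    uses, so single-sensor and fusion curves share each repetition's fit,
    split and disturbance realizations.
    """
    m_sensors = dataset.n_sensors
    s_values = config.s_values or tuple(range(1, m_sensors + 1))
    if max(s_values) > m_sensors:
        raise ValueError("S cannot exceed the number of sensors")
    reps = config.repetitions

    singles = {
        k: np.empty((reps, len(config.levels_of(k)), m_sensors)) for k in config.kinds
    }
    fused = {
        k: np.empty((reps, len(config.levels_of(k)), len(s_values)))
        for k in config.kinds
    }
    clean_single = np.empty((reps, m_sensors))
    clean_fused = np.empty(reps)

    for r in range(reps):
        split_rng = np.random.default_rng(derive_seed(config.seed, _STREAM_SPLIT, r))
        tr, te = stratified_split(dataset.labels, config.train_fraction, split_rng)
        train, test = dataset.select_windows(tr), dataset.select_windows(te)
        model = _fit_clean(train, config.fit, derive_seed(config.seed, _STREAM_FIT, r))
        truth = test.labels

        clean_feats = model.features_per_sensor(test)
        n_classes = model.class_labels.size
        clean_scores = np.empty((test.n_windows, m_sensors, n_classes))
        for m, node in enumerate(model.nodes):
            clean_scores[:, m, :] = node.scores(clean_feats[m])
            clean_single[r, m] = accuracy(
                model.class_labels[np.argmax(clean_scores[:, m, :], axis=1)], truth
            )
        clean_fused[r] = accuracy(
            model.class_labels[
                np.argmax(np.einsum("m,wmn->wn", model.mu, clean_scores), axis=1)
            ],
            truth,
        )

        for kind in config.kinds:
            kc = _KIND_CODE[kind]
            for li, level in enumerate(config.levels_of(kind)):
                if level == 0:
                    singles[kind][r, li] = clean_single[r]
                    dist_scores = clean_scores
                else:
                    dist_scores = clean_scores.copy()
                    for m, node in enumerate(model.nodes):
                        rng_d = np.random.default_rng(
                            derive_seed(config.seed, _STREAM_DISTURB, kc, r, li, m)
                        )
                        xr, yr = _disturb_sensor_arrays(
                            test.x[:, m], test.y[:, m], kind, level, rng_d,
                            config.granularity,
                        )
                        f = model.extract_sensor_features(xr, yr)
                        dist_scores[:, m, :] = node.scores(f)
                        singles[kind][r, li, m] = accuracy(
                            model.class_labels[
                                np.argmax(dist_scores[:, m, :], axis=1)
                            ],
                            truth,
                        )
                for si, s in enumerate(s_values):
                    subset_rng = np.random.default_rng(
                        derive_seed(config.seed, _STREAM_SUBSET, kc, r, li, si)
                    )
                    cols = subset_rng.choice(m_sensors, size=s, replace=False)
                    scores = clean_scores.copy()
                    scores[:, cols, :] = dist_scores[:, cols, :]
                    pred = model.class_labels[
                        np.argmax(np.einsum("m,wmn->wn", model.mu, scores), axis=1)
                    ]
                    fused[kind][r, li, si] = accuracy(pred, truth)

    return StudyResult(
        config=config,
        sensor_ids=dataset.sensor_ids.copy(),
        s_values=tuple(s_values),
        singles=singles,
        fused=fused,
        clean_single=clean_single,
        clean_fused=clean_fused,
    )


# ---------------------------------------------------------------------------
# sweep: files and figures
# ---------------------------------------------------------------------------

def _config_dict(cfg) -> dict:
    from dataclasses import asdict

    d = asdict(cfg)
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _study_frames(result: StudyResult, kind: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    levels = result.config.levels_of(kind)
    reps = result.config.repetitions
    rows_s = []
    for r in range(reps):
        for li, level in enumerate(levels):
            for m, sid in enumerate(result.sensor_ids):
                rows_s.append((r, level, int(sid), result.singles[kind][r, li, m]))
    rows_f = []
    for r in range(reps):
        for li, level in enumerate(levels):
            for si, s in enumerate(result.s_values):
                rows_f.append((r, level, s, result.fused[kind][r, li, si]))
    return (
        pd.DataFrame(rows_s, columns=["rep", "level", "sensor", "accuracy"]),
        pd.DataFrame(rows_f, columns=["rep", "level", "S", "accuracy"]),
    )


def _plot_curves(path: Path, levels, series: dict, xlabel: str, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, (mean, std) in series.items():
        ax.errorbar(levels, mean, yerr=std, marker="o", capsize=3, label=name)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def sweep(
    dataset: LabeledSignalSet,
    config: StudyConfig,
    out_dir: str | Path,
    *,
    plots: bool = True,
) -> StudyResult:
    """Run the factorial study and write curves, tables and figures to ``out_dir``.

    Per-kind result files already present are treated as completed cells
    and are not recomputed; kinds whose files are missing are (re)run.
    Failures in one kind are recorded in ``summary.json`` and do not
    abort the remaining cells.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    missing = [
        k
        for k in config.kinds
        if not (out / f"singles_{k}.csv").exists()
        or not (out / f"fused_{k}.csv").exists()
    ]
    errors: dict[str, str] = {}
    result = None
    if missing:
        try:
            result = robustness_study(dataset, replace(config, kinds=tuple(missing)))
        except Exception as exc:  # pragma: no cover - defensive
            errors["study"] = f"{type(exc).__name__}: {exc}"
    summary: dict = {"config": _config_dict(config), "errors": errors, "curves": {}}
    for kind in config.kinds:
        singles_path = out / f"singles_{kind}.csv"
        fused_path = out / f"fused_{kind}.csv"
        if kind in missing and result is not None:
            df_s, df_f = _study_frames(result, kind)
            df_s.to_csv(singles_path, index=False)
            df_f.to_csv(fused_path, index=False)
        if not singles_path.exists() or not fused_path.exists():
            continue
        df_s = pd.read_csv(singles_path)
        df_f = pd.read_csv(fused_path)
        levels = sorted(df_s["level"].unique())
        gs = df_s.groupby(["sensor", "level"])["accuracy"]
        gf = df_f.groupby(["S", "level"])["accuracy"]
        summary["curves"][kind] = {
            "levels": levels,
            "singles": {
                str(s): {
                    "mean": gs.mean().loc[s].reindex(levels).tolist(),
                    "std": gs.std().loc[s].reindex(levels).fillna(0.0).tolist(),
                }
                for s in sorted(df_s["sensor"].unique())
            },
            "fused": {
                str(s): {
                    "mean": gf.mean().loc[s].reindex(levels).tolist(),
                    "std": gf.std().loc[s].reindex(levels).fillna(0.0).tolist(),
                }
                for s in sorted(df_f["S"].unique())
            },
        }
        if plots:
            xlabel = (
                "max rotation angle (deg)" if kind == ROTATIONAL else "sigma (mG)"
            )
            c = summary["curves"][kind]
            _plot_curves(
                out / f"singles_{kind}.png",
                levels,
                {
                    f"sensor {s}": (v["mean"], v["std"])
                    for s, v in c["singles"].items()
                },
                xlabel,
                f"single-sensor accuracy, {kind} noise",
            )
            _plot_curves(
                out / f"fused_{kind}.png",
                levels,
                {f"S={s}": (v["mean"], v["std"]) for s, v in c["fused"].items()},
                xlabel,
                f"fused accuracy, {kind} noise",
            )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return result
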