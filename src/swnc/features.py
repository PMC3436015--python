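"""Window segmentation, feature extraction and ROC-based feature ranking.

The feature bank spans the time and frequency domains: per axis — moments,
order statistics, zero crossings, signal magnitude area, spectral energy /
entropy / dominant frequency and the leading FFT magnitudes; across axes —
Pearson correlation and covariance.  Each base classifier receives its own
top-``L`` features ranked by one-vs-rest ROC AUC distance from chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "FeatureBank",
    "FeatureMatrix",
    "ScoredFeature",
    "default_feature_bank",
    "sliding_window",
    "extract_features",
    "roc_rank",
    "select_top",
]


def sliding_window(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    duration: float,
    overlap: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment a continuous biaxial stream into fixed-length windows.

    Windows have exactly ``floor(duration * rate)`` samples; consecutive
    start offsets are spaced ``floor(duration * rate * (1 - overlap))``
    samples apart; a trailing partial window is discarded.  Returns two
    arrays of shape (n_windows, window_length); a stream shorter than one
    window yields empty arrays.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D streams")
    length = int(math.floor(duration * rate))
    if length < 2:
        raise ValueError("window must contain at least 2 samples")
    step = int(math.floor(duration * rate * (1.0 - overlap)))
    step = max(step, 1)
    starts = range(0, x.size - length + 1, step)
    xw = np.array([x[s : s + length] for s in starts], dtype=float)
    yw = np.array([y[s : s + length] for s in starts], dtype=float)
    if xw.size == 0:
        xw = xw.reshape(0, length)
        yw = yw.reshape(0, length)
    return xw, yw


class FeatureBank:
    """An ordered, named set of window-to-scalar feature maps.

    ``extract`` operates on stacks of windows: inputs of shape (W, T)
    yield a (W, F) matrix in bank order.
    """

    def __init__(self, names: Sequence[str], extractor):
        self._names = tuple(names)
        if len(set(self._names)) != len(self._names):
            raise ValueError("feature names must be unique")
        self._extractor = extractor

    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    @property
    def size(self) -> int:
        return len(self._names)

    def extract(self, x: np.ndarray, y: np.ndarray, rate: float) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if x.shape != y.shape:
            raise ValueError("x and y window stacks must have equal shapes")
        if x.shape[1] < 2:
            raise ValueError("windows must contain at least 2 samples")
        values = self._extractor(x, y, rate)
        bad = ~np.isfinite(values)
        if bad.any():
            j = int(np.argwhere(bad)[0, 1])
            raise ArithmeticError(
                f"feature {self._names[j]!r} produced a non-finite value"
            )
        return values


_N_FFT_COEFF = 5


def _axis_features(a: np.ndarray, rate: float) -> tuple[np.ndarray, list[str]]:
    """All per-axis features for a (W, T) stack; returns (W, 19) block."""
    w, t = a.shape
    mean = a.mean(axis=1)
    centered = a - mean[:, None]
    std = a.std(axis=1)
    var = a.var(axis=1)
    median = np.median(a, axis=1)
    amin = a.min(axis=1)
    amax = a.max(axis=1)
    rng_ = amax - amin
    rms = np.sqrt(np.mean(a * a, axis=1))
    mad = np.mean(np.abs(centered), axis=1)
    # zero crossings of the mean-centered signal
    zc = np.sum(np.signbit(centered[:, 1:]) != np.signbit(centered[:, :-1]), axis=1)
    sma = np.mean(np.abs(a), axis=1)
    spectrum = np.abs(np.fft.rfft(a, axis=1))
    mags = spectrum[:, 1:]  # DC excluded: gravity lives there
    power = mags * mags
    energy = power.sum(axis=1) / t
    total = power.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = power / total[:, None]
        ent = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    ent = np.where(total > 0, ent, 0.0)
    dom = np.where(total > 0, (np.argmax(mags, axis=1) + 1) * rate / t, 0.0)
    coeffs = np.zeros((w, _N_FFT_COEFF))
    k = min(_N_FFT_COEFF, mags.shape[1])
    coeffs[:, :k] = mags[:, :k] / t
    block = np.column_stack(
        [mean, std, var, median, amin, amax, rng_, rms, mad, zc, sma,
         energy, ent, dom, coeffs]
    )
    names = [
        "mean", "std", "var", "median", "min", "max", "range", "rms",
        "mad", "zero_crossings", "sma", "spectral_energy",
        "spectral_entropy", "dominant_freq",
    ] + [f"fft_mag_{i}" for i in range(1, _N_FFT_COEFF + 1)]
    return block, names


def _default_extractor(x: np.ndarray, y: np.ndarray, rate: float) -> np.ndarray:
    bx, _ = _axis_features(x, rate)
    by, _ = _axis_features(y, rate)
    mx = x.mean(axis=1)
    my = y.mean(axis=1)
    cov = np.mean((x - mx[:, None]) * (y - my[:, None]), axis=1)
    sx = x.std(axis=1)
    sy = y.std(axis=1)
    denom = sx * sy
    corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return np.column_stack([bx, by, corr, cov])


def default_feature_bank() -> FeatureBank:
    """The standard ~40-feature time/frequency bank (19 per axis + 2 cross-axis)."""
    _, axis_names = _axis_features(np.zeros((1, 4)), 1.0)
    names = (
        [f"x_{n}" for n in axis_names]
        + [f"y_{n}" for n in axis_names]
        + ["xy_corr", "xy_cov"]
    )
    return FeatureBank(names, _default_extractor)


def extract_features(
    window: tuple[np.ndarray, np.ndarray], bank: FeatureBank, rate: float
) -> np.ndarray:
    """Feature vector (length F) of one biaxial window ``(x, y)``."""
    x, y = window
    return bank.extract(np.asarray(x)[None, :], np.asarray(y)[None, :], rate)[0]


@dataclass
class FeatureMatrix:
    """Per-window feature vectors with class labels for one sensor stream."""

    values: np.ndarray  # (W, F)
    names: tuple[str, ...]
    labels: np.ndarray  # (W,)
    sensor_id: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (windows, features) matching names")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("one label per row required")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ScoredFeature:
    name: str
    index: int
    auc: float
    score: float  # |AUC - 0.5|


def _auc_one_vs_rest(values: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Column-wise rank-statistic AUC of (W, F) ``values`` for the positive mask.

    Mid-ranks share ties, i.e. tied pairs count 1/2 — the Mann-Whitney
    formulation of the ROC area.
    """
    n1 = int(positive.sum())
    n0 = positive.size - n1
    ranks = rankdata(values, axis=0)  # average method: ties get mid-ranks
    r1 = ranks[positive].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def roc_rank(features: FeatureMatrix, target_class: int) -> list[ScoredFeature]:
    """Rank every feature by its one-vs-rest discriminative power for ``target_class``.

    Score is ``|AUC - 0.5|`` so that anti-correlated features rank as
    informative.  Descending score; ties keep bank order.
    """
    positive = features.labels == target_class
    if positive.all() or not positive.any():
        raise ValueError("both the target class and its complement must be present")
    auc = _auc_one_vs_rest(features.values, positive)
    score = np.abs(auc - 0.5)
    order = sorted(range(len(auc)), key=lambda i: (-score[i], i))
    return [
        ScoredFeature(features.names[i], i, float(auc[i]), float(score[i]))
        for i in order
    ]


def select_top(ranking: Sequence[ScoredFeature], n_features: int) -> list[ScoredFeature]:
    """The first ``min(n_features, len(ranking))`` entries of a ranking."""
    if n_features < 1:
        raise ValueError("must select at least one feature")
    return list(ranking[: min(n_features, len(ranking))])
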