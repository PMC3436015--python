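"""Sensor Weighted Network Classifier (SWNC).

A two-level accuracy-weighted decision-fusion ensemble over a body sensor
network with ``M`` sensors (nodes) and ``N`` activity classes:

* **Base level** — ``M x N`` binary one-vs-rest "class classifiers"
  ``c_mn`` (k-nearest-neighbour by default, pluggable), each specialized
  in accepting or rejecting class ``n`` from sensor ``m``'s features.

* **Node level** — not a learned model but a decision rule: each base
  classifier's binary outcome is encoded as a vote vector over all
  classes (an acceptance votes 1 for the specialization and 0 elsewhere;
  a rejection votes the complement, letting every classifier weigh in on
  every class), and votes are combined with class weights
  ``λ_mn = R̄_mn / Σ_k R̄_mk`` built from held-out base-classifier
  accuracies.

* **Network level** — node score vectors are fused with node weights
  ``μ_m = R̄_m / Σ_k R̄_k`` built from held-out node accuracies, and the
  class with the largest fused score wins (ties broken by the lowest
  class index).

Training follows the three-subset protocol: the training partition is
split into three equally-sampled stratified subsets — A trains the base
classifiers (after per-(sensor, class) feature selection on A), B yields
the binary accuracies behind λ, C yields the node accuracies behind μ.
A p-fold cross-validation mode replaces the B/C holdouts when data is
scarce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors

from .features import (
    FeatureBank,
    FeatureMatrix,
    ScoredFeature,
    default_feature_bank,
    roc_rank,
    select_top,
)
from .signals import LabeledSignalSet

__all__ = [
    "StratificationError",
    "DegenerateWeightsError",
    "FitConfig",
    "BaseClassifier",
    "NodeClassifier",
    "TrainedSWNC",
    "PredictionResult",
    "train_base",
    "class_weights",
    "node_weights",
    "vote",
    "node_output",
    "node_predict",
    "network_output",
    "network_predict",
    "fit",
    "predict",
]

VOTE_ENCODINGS = ("complement", "abstain")


class StratificationError(ValueError):
    """A class is missing from one of the stratified training subsets."""


class DegenerateWeightsError(ValueError):
    """All accuracies are zero; Eq-style normalization is undefined."""


# ---------------------------------------------------------------------------
# weight and vote algebra
# ---------------------------------------------------------------------------

def class_weights(accuracies: Sequence[float]) -> np.ndarray:
    """Normalize held-out accuracy rates into class weights: λ_n = R̄_n / Σ R̄."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 1 or acc.size == 0:
        raise ValueError("accuracies must be a non-empty 1-D sequence")
    if (acc < 0).any() or (acc > 1).any():
        raise ValueError("accuracy rates must lie in [0, 1]")
    total = acc.sum()
    if total == 0:
        raise DegenerateWeightsError("all accuracies are zero")
    return acc / total


def node_weights(accuracies: Sequence[float]) -> np.ndarray:
    """Normalize node accuracies into node weights: μ_m = R̄_m / Σ R̄."""
    return class_weights(accuracies)


def vote(
    accepted: bool, n: int, n_classes: int, encoding: str = "complement"
) -> np.ndarray:
    """Binary vote vector ``y_n.`` of classifier ``n`` (1-based) over all classes.

    ``complement`` (default): an acceptance is the indicator of class
    ``n``; a rejection votes 1 for every class *except* ``n``, so
    rejections contribute positive evidence to the other classes.
    ``abstain``: a rejection votes 0 everywhere.
    """
    if not 1 <= n <= n_classes:
        raise ValueError("classifier specialization out of range")
    if encoding not in VOTE_ENCODINGS:
        raise ValueError(f"unknown vote encoding {encoding!r}")
    v = np.zeros(n_classes)
    if accepted:
        v[n - 1] = 1.0
    elif encoding == "complement":
        v[:] = 1.0
        v[n - 1] = 0.0
    return v


def node_output(votes: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Node score vector ``O_mq = Σ_n λ_mn · y_nq`` from a (N, N) vote matrix."""
    votes = np.asarray(votes, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return lam @ votes


def node_predict(output: np.ndarray) -> int:
    """Winning class (1-based) of a node score vector; lowest index on ties."""
    return int(np.argmax(output)) + 1


def network_output(node_outputs: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Fused score vector ``O_q = Σ_p μ_p · O_pq`` from an (M, N) stack."""
    node_outputs = np.asarray(node_outputs, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return mu @ node_outputs


def network_predict(output: np.ndarray) -> int:
    """Winning class (1-based) of the fused score vector; lowest index on ties."""
    return int(np.argmax(output)) + 1


def _acceptance_to_scores(accept: np.ndarray, lam: np.ndarray, encoding: str) -> np.ndarray:
    """Vectorized node scores from a (W, N) acceptance matrix.

    Row ``w`` equals ``node_output`` applied to the vote matrix built from
    ``accept[w]`` — the (W,) batched form of the scalar vote algebra.
    """
    a = accept.astype(float)
    if encoding == "abstain":
        return a * lam[None, :]
    rej = 1.0 - a
    return a * lam[None, :] + (rej @ lam)[:, None] - rej * lam[None, :]


# ---------------------------------------------------------------------------
# base classifiers
# ---------------------------------------------------------------------------

def _grid_search_k(
    X: np.ndarray,
    y_bin: np.ndarray,
    k_grid: Sequence[int],
    n_folds: int,
) -> tuple[int, dict[int, float]]:
    """Cross-validated binary accuracy per k; best accuracy, smallest k on ties.

    One neighbour query per fold serves every k in the grid: the ordered
    neighbour-label table yields the k-NN majority vote for all k at once.
    """
    from sklearn.model_selection import StratifiedKFold

    k_grid = sorted(k_grid)
    max_k = k_grid[-1]
    counts = np.bincount(y_bin, minlength=2)
    n_folds = min(n_folds, int(counts[counts > 0].min()))
    if n_folds < 2:
        # too few samples of one class to cross-validate; smallest k wins
        return k_grid[0], {k: float("nan") for k in k_grid}
    correct = {k: 0 for k in k_grid}
    skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
    for tr, te in skf.split(X, y_bin):
        kk = min(max_k, len(tr))
        nn = NearestNeighbors(n_neighbors=kk).fit(X[tr])
        idx = nn.kneighbors(X[te], return_distance=False)
        neigh = y_bin[tr][idx]  # (n_te, kk) ordered by distance
        cum = np.cumsum(neigh, axis=1)
        for k in k_grid:
            j = min(k, kk)
            pred = cum[:, j - 1] * 2 > j
            correct[k] += int((pred == y_bin[te].astype(bool)).sum())
    table = {k: correct[k] / len(y_bin) for k in k_grid}
    best = max(table.values())
    chosen = next(k for k in k_grid if table[k] == best)
    return chosen, table


@dataclass
class BaseClassifier:
    """A frozen binary one-vs-rest class classifier ``c_mn``.

    Decisions are deterministic: odd ``k`` forbids vote ties and the
    neighbour search breaks distance ties by training order.  Features
    are standardized with training-subset statistics.
    """

    sensor_id: int
    class_label: int
    feature_indices: tuple[int, ...]
    selection: list[ScoredFeature]
    mean: np.ndarray
    scale: np.ndarray
    k: int
    predictor: KNeighborsClassifier
    cv_table: dict[int, float] = field(default_factory=dict)

    def decide(self, feature_rows: np.ndarray) -> np.ndarray:
        """Boolean acceptance of ``class_label`` per row of the full feature matrix."""
        X = (feature_rows[:, self.feature_indices] - self.mean) / self.scale
        return self.predictor.predict(X).astype(bool)


def train_base(
    features: FeatureMatrix,
    class_label: int,
    k_grid: Sequence[int] = (1, 3, 5, 7, 9),
    *,
    feature_indices: Sequence[int] | None = None,
    n_folds: int = 5,
) -> BaseClassifier:
    """Train one binary class classifier with grid-selected neighbour count.

    Labels are binarized to {``class_label``, rest}; ``k`` is chosen from
    the (odd-valued) grid by cross-validated binary accuracy, smallest
    ``k`` on ties; the returned classifier is frozen.
    """
    if len(k_grid) == 0 or any(k % 2 == 0 or k < 1 for k in k_grid):
        raise ValueError("k grid must be non-empty with odd positive values")
    labels = features.labels
    if np.unique(labels).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if features.n_windows < max(k_grid):
        raise ValueError("fewer training samples than the largest k in the grid")
    idx = (
        tuple(range(features.values.shape[1]))
        if feature_indices is None
        else tuple(feature_indices)
    )
    X = features.values[:, idx]
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - mean) / scale
    y_bin = (labels == class_label).astype(int)
    k, table = _grid_search_k(Xs, y_bin, k_grid, n_folds)
    predictor = KNeighborsClassifier(n_neighbors=k).fit(Xs, y_bin)
    return BaseClassifier(
        sensor_id=features.sensor_id if features.sensor_id is not None else -1,
        class_label=class_label,
        feature_indices=idx,
        selection=[],
        mean=mean,
        scale=scale,
        k=k,
        predictor=predictor,
        cv_table=table,
    )


# ---------------------------------------------------------------------------
# node and network containers
# ---------------------------------------------------------------------------

@dataclass
class NodeClassifier:
    """One sensor's decision-making aggregate: N base classifiers + λ weights."""

    sensor_id: int
    classifiers: list[BaseClassifier]  # ordered by class_labels
    lam: np.ndarray
    class_labels: np.ndarray
    vote_encoding: str = "complement"

    def acceptance(self, feature_rows: np.ndarray) -> np.ndarray:
        """(W, N) boolean acceptance matrix over this node's base classifiers."""
        return np.column_stack([c.decide(feature_rows) for c in self.classifiers])

    def scores(self, feature_rows: np.ndarray) -> np.ndarray:
        """(W, N) node score vectors ``O_m.`` for each feature row."""
        return _acceptance_to_scores(
            self.acceptance(feature_rows), self.lam, self.vote_encoding
        )

    def predict(self, feature_rows: np.ndarray) -> np.ndarray:
        """Per-row winning class labels of this node alone."""
        return self.class_labels[np.argmax(self.scores(feature_rows), axis=1)]


@dataclass
class PredictionResult:
    """Full fused prediction with all intermediate scores exposed."""

    classes: np.ndarray  # (W,) final class labels
    network_scores: np.ndarray  # (W, N)
    node_classes: np.ndarray  # (W, M)
    node_scores: np.ndarray  # (W, M, N)


@dataclass(frozen=True)
class FitConfig:
    """Training hyperparameters of the SWNC."""

    k_grid: tuple[int, ...] = (1, 3, 5, 7, 9)
    n_features: int = 10  # L: features per base classifier
    weight_mode: str = "holdout"  # "holdout" (three subsets) or "cv" (p-fold)
    cv_folds: int = 10  # p of the p-fold mode
    grid_cv_folds: int = 5  # folds of the per-classifier k search
    vote_encoding: str = "complement"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_mode not in ("holdout", "cv"):
            raise ValueError("weight_mode must be 'holdout' or 'cv'")
        if self.vote_encoding not in VOTE_ENCODINGS:
            raise ValueError(f"vote encoding must be one of {VOTE_ENCODINGS}")
        if self.n_features < 1:
            raise ValueError("n_features must be at least 1")


@dataclass
class TrainedSWNC:
    """The frozen two-level ensemble: nodes, λ per node, μ across nodes."""

    nodes: list[NodeClassifier]
    mu: np.ndarray
    class_labels: np.ndarray
    bank: FeatureBank
    rate: float
    config: FitConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def sensor_ids(self) -> np.ndarray:
        return np.array([n.sensor_id for n in self.nodes])

    def extract_sensor_features(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """(W, F) bank features for one sensor's (W, T) window stacks."""
        return self.bank.extract(x, y, self.rate)

    def features_per_sensor(self, dataset: LabeledSignalSet) -> list[np.ndarray]:
        feats = []
        for sensor_id in self.sensor_ids:
            j = dataset.sensor_index(int(sensor_id))
            feats.append(self.extract_sensor_features(dataset.x[:, j], dataset.y[:, j]))
        return feats

    def predict_from_features(self, feats: Sequence[np.ndarray]) -> PredictionResult:
        if len(feats) != len(self.nodes):
            raise ValueError("one feature matrix per node required")
        w = feats[0].shape[0]
        n = self.class_labels.size
        node_scores = np.empty((w, len(self.nodes), n))
        for m, (node, f) in enumerate(zip(self.nodes, feats)):
            if f.shape[1] != self.bank.size:
                raise ValueError("feature matrix width does not match the bank")
            node_scores[:, m, :] = node.scores(f)
        network_scores = np.einsum("m,wmn->wn", self.mu, node_scores)
        classes = self.class_labels[np.argmax(network_scores, axis=1)]
        node_classes = self.class_labels[np.argmax(node_scores, axis=2)]
        return PredictionResult(classes, network_scores, node_classes, node_scores)

    def predict(self, dataset: LabeledSignalSet) -> PredictionResult:
        return self.predict_from_features(self.features_per_sensor(dataset))


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------

def _stratified_three_way(
    labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split indices into three equally-sampled stratified subsets."""
    buckets: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i, w in enumerate(idx):
            buckets[i % 3].append(int(w))
    subsets = tuple(np.sort(np.array(b, dtype=int)) for b in buckets)
    for b in subsets:
        if np.unique(labels[b]).size != np.unique(labels).size:
            raise StratificationError(
                "every class must appear in each of the three training subsets"
            )
    return subsets


def _multiclass_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean(pred == truth))


def fit(train_set: LabeledSignalSet, config: FitConfig | None = None,
        bank: FeatureBank | None = None) -> TrainedSWNC:
    """Train a full SWNC on a clean training partition.

    Holdout mode (default): subset A trains all ``M x N`` base classifiers
    (feature selection included), subset B's binary accuracies give λ,
    subset C's node accuracies give μ.  CV mode: λ comes from the p-fold
    cross-validated binary accuracy of each base classifier on the whole
    training partition and μ from a p-fold cross-validation of each node.
    """
    config = config or FitConfig()
    bank = bank or default_feature_bank()
    labels = train_set.labels
    class_labels = np.unique(labels)
    if class_labels.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    rng = np.random.default_rng(config.seed)

    if config.weight_mode == "holdout":
        idx_a, idx_b, idx_c = _stratified_three_way(labels, rng)
    else:
        all_idx = np.arange(train_set.n_windows)
        idx_a = idx_b = idx_c = all_idx

    nodes: list[NodeClassifier] = []
    node_acc = np.empty(train_set.n_sensors)
    class_acc = np.empty((train_set.n_sensors, class_labels.size))

    for j, sensor_id in enumerate(train_set.sensor_ids):
        feats_all = bank.extract(train_set.x[:, j], train_set.y[:, j], train_set.rate)
        fm_a = FeatureMatrix(
            feats_all[idx_a], bank.names, labels[idx_a], sensor_id=int(sensor_id)
        )
        classifiers: list[BaseClassifier] = []
        accs = np.empty(class_labels.size)
        for q, cls in enumerate(class_labels):
            ranking = roc_rank(fm_a, int(cls))
            top = select_top(ranking, config.n_features)
            sel_idx = [s.index for s in top]
            clf = train_base(
                fm_a,
                int(cls),
                config.k_grid,
                feature_indices=sel_idx,
                n_folds=config.grid_cv_folds,
            )
            clf.selection = top
            classifiers.append(clf)
            if config.weight_mode == "holdout":
                decided = clf.decide(feats_all[idx_b])
                accs[q] = np.mean(decided == (labels[idx_b] == cls))
            else:
                accs[q] = _cv_binary_accuracy(
                    fm_a, int(cls), sel_idx, clf.k, config.cv_folds
                )
        lam = class_weights(accs)
        class_acc[j] = accs
        node = NodeClassifier(
            sensor_id=int(sensor_id),
            classifiers=classifiers,
            lam=lam,
            class_labels=class_labels,
            vote_encoding=config.vote_encoding,
        )
        if config.weight_mode == "holdout":
            node_acc[j] = _multiclass_accuracy(
                node.predict(feats_all[idx_c]), labels[idx_c]
            )
        else:
            node_acc[j] = _cv_node_accuracy(fm_a, node, config)
        nodes.append(node)

    mu = node_weights(node_acc)
    return TrainedSWNC(
        nodes=nodes,
        mu=mu,
        class_labels=class_labels,
        bank=bank,
        rate=train_set.rate,
        config=config,
        diagnostics={
            "subsets": (idx_a, idx_b, idx_c),
            "class_accuracies": class_acc,
            "node_accuracies": node_acc,
        },
    )


def _cv_binary_accuracy(
    fm: FeatureMatrix, cls: int, sel_idx: Sequence[int], k: int, folds: int
) -> float:
    """p-fold cross-validated binary accuracy of a fixed-(k, features) classifier."""
    from sklearn.model_selection import StratifiedKFold

    y_bin = (fm.labels == cls).astype(int)
    folds = min(folds, int(np.bincount(y_bin, minlength=2).min()))
    X = fm.values[:, list(sel_idx)]
    if folds < 2:
        # too few samples of one class to cross-validate: resubstitution accuracy
        mean = X.mean(axis=0)
        scale = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        clf = KNeighborsClassifier(n_neighbors=min(k, len(y_bin))).fit(
            (X - mean) / scale, y_bin
        )
        return float(np.mean(clf.predict((X - mean) / scale) == y_bin))
    hits = 0
    for tr, te in StratifiedKFold(n_splits=folds, shuffle=False).split(X, y_bin):
        mean = X[tr].mean(axis=0)
        scale = X[tr].std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        kk = min(k, len(tr))
        clf = KNeighborsClassifier(n_neighbors=kk).fit((X[tr] - mean) / scale, y_bin[tr])
        hits += int((clf.predict((X[te] - mean) / scale) == y_bin[te]).sum())
    return hits / len(y_bin)


def _cv_node_accuracy(fm: FeatureMatrix, node: NodeClassifier, config: FitConfig) -> float:
    """p-fold cross-validated multiclass accuracy of a node with fixed λ."""
    from sklearn.model_selection import StratifiedKFold

    y = fm.labels
    counts = np.bincount(y)
    counts = counts[counts > 0]
    folds = max(2, min(config.cv_folds, int(counts.min())))
    hits = 0
    for tr, te in StratifiedKFold(n_splits=folds, shuffle=False).split(fm.values, y):
        accept = np.empty((len(te), node.class_labels.size), dtype=bool)
        for q, clf in enumerate(node.classifiers):
            idx = list(clf.feature_indices)
            X = fm.values[:, idx]
            mean = X[tr].mean(axis=0)
            scale = X[tr].std(axis=0)
            scale = np.where(scale > 0, scale, 1.0)
            kk = min(clf.k, len(tr))
            y_bin = (y == clf.class_label).astype(int)
            knn = KNeighborsClassifier(n_neighbors=kk).fit(
                (X[tr] - mean) / scale, y_bin[tr]
            )
            accept[:, q] = knn.predict((X[te] - mean) / scale).astype(bool)
        scores = _acceptance_to_scores(accept, node.lam, node.vote_encoding)
        pred = node.class_labels[np.argmax(scores, axis=1)]
        hits += int((pred == y[te]).sum())
    return hits / len(y)


def predict(model: TrainedSWNC, dataset: LabeledSignalSet) -> PredictionResult:
    """Fused prediction for every window of ``dataset`` (module-level alias)."""
    return model.predict(dataset)
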