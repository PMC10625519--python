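"""Zone-routed classification models.

The sample-rich North China zone (a) uses a discriminatively trained
recurrent network: a two-layer GRU over the 7 x 10 monthly sequence,
optimized with Adam on a combined objective

    L = w1 * L_ce + w2 * L_center,      w1 = 1.0, w2 = 0.001

where L_ce is the batch-mean cross-entropy on the normalized sigmoid
outputs and L_center = 1/2 sum_i ||f(x_i) - c_{y_i}||^2 penalizes the
distance of each deep feature to its running class center (summed over the
batch).  The sparsely sampled zones (b-e) use per-zone random forests of
200 trees on the flattened 70-dimensional sequence; southern China, which
has too few samples of its own, borrows a forest trained on the pooled
samples of the adjacent zones b and c.

Samples are split 70:10:20 into train/validation/test, and the network
parameters from the epoch with the best validation overall accuracy are the
ones kept.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from . import _gru
from .constants import N_CHANNELS, N_MONTHS, SOUTH_ZONE, ZONES
from .preprocessing import SequenceFeaturizer
from .types import FeatureSequence, SampleRecord

__all__ = [
    "NetworkConfig",
    "SplitSpec",
    "ZoneModel",
    "cross_entropy_loss",
    "center_loss",
    "combined_loss",
    "update_centers",
    "split_samples",
    "route_zone",
    "GRUCenterLossClassifier",
    "ZoneRandomForestClassifier",
    "train_recurrent",
    "train_random_forest",
    "predict_pixels",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyper-parameters of the recurrent classifier (defaults are the
    published training protocol where one was published)."""

    n_recurrent_layers: int = 2
    hidden_size: int = 64
    n_dense_layers: int = 2
    n_classes: int = 3
    learning_rate: float = 0.001
    batch_size: int = 50
    w1: float = 1.0
    w2: float = 0.001
    max_epochs: int = 100
    center_update_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not 0.0 < self.center_update_rate <= 1.0:
            raise ValueError("center_update_rate must lie in (0, 1]")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (70:10:20) and split behaviour."""

    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    stratified_by_class: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _check_onehot(labels: np.ndarray, n: int, c: int) -> None:
    labels = np.asarray(labels)
    if labels.shape != (n, c):
        raise ValueError(f"labels must have shape ({n}, {c}); got {labels.shape}")
    if not np.all(np.isin(labels, (0, 1))) or not np.all(labels.sum(axis=1) == 1):
        raise ValueError("labels must be one-hot rows")


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Batch-mean cross-entropy -(1/N) sum_i sum_j y_ij log p_ij.

    ``labels`` is one-hot (N, C); probabilities are clamped at machine-eps
    so a confident wrong prediction yields a large finite loss.
    """
    p = np.asarray(probabilities, dtype=float)
    n, c = p.shape
    _check_onehot(labels, n, c)
    p = np.clip(p, _gru.EPS, 1.0)
    return float(-np.mean(np.sum(np.asarray(labels) * np.log(p), axis=1)))


def center_loss(
    features: np.ndarray, labels: np.ndarray, centers: np.ndarray
) -> float:
    """1/2 sum_i ||f(x_i) - c_{y_i}||^2, summed over the batch.

    ``labels`` may be one-hot (N, C) or integer class indices (N,).
    """
    f = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    y = labels.argmax(axis=1) if labels.ndim == 2 else labels.astype(int)
    centers = np.asarray(centers, dtype=float)
    if y.max(initial=-1) >= centers.shape[0] or y.min(initial=0) < 0:
        raise ValueError("label index outside the set of class centers")
    diff = f - centers[y]
    return float(0.5 * np.sum(diff * diff))


def combined_loss(
    ce: float, center: float, w1: float = 1.0, w2: float = 0.001
) -> float:
    """w1 * cross-entropy + w2 * center loss."""
    if not (np.isfinite(ce) and np.isfinite(center)):
        raise ValueError("losses must be finite")
    return w1 * ce + w2 * center


def update_centers(
    centers: np.ndarray,
    features: np.ndarray,
    labels: np.ndarray,
    rate: float = 0.5,
) -> np.ndarray:
    """Move each class center toward its batch feature mean by ``rate``.

    Classes absent from the batch keep their center unchanged.
    """
    if not 0.0 < rate <= 1.0:
        raise ValueError("rate must lie in (0, 1]")
    labels = np.asarray(labels)
    y = labels.argmax(axis=1) if labels.ndim == 2 else labels.astype(int)
    out = np.array(centers, dtype=float, copy=True)
    for k in np.unique(y):
        out[k] += rate * (features[y == k].mean(axis=0) - out[k])
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_samples(
    records: Sequence,
    spec: SplitSpec = SplitSpec(),
    label_fn: Callable | None = None,
) -> tuple[list, list, list]:
    """Partition records into train/validation/test lists.

    Stratified per class when requested; per stratum the validation and
    test counts are the half-up-rounded fractions and training takes the
    remainder, so each partition is within one record of its exact share.
    """
    if len(records) == 0:
        raise ValueError("cannot split an empty record list")
    if label_fn is None:
        label_fn = _default_label
    labels = np.array([label_fn(r) for r in records])
    if spec.stratified_by_class and len(np.unique(labels)) < 2:
        raise ValueError("stratified split needs at least two classes")
    rng = np.random.default_rng(spec.seed)
    strata = (
        [np.nonzero(labels == c)[0] for c in np.unique(labels)]
        if spec.stratified_by_class
        else [np.arange(len(records))]
    )
    parts: tuple[list, list, list] = ([], [], [])
    _, f_val, f_test = spec.fractions
    for idx in strata:
        idx = idx.copy()
        rng.shuffle(idx)
        n = len(idx)
        n_val = _round_half_up(f_val * n)
        n_test = _round_half_up(f_test * n)
        n_train = n - n_val - n_test
        if n_train < 0:
            raise ValueError("stratum too small for the requested fractions")
        parts[0].extend(records[i] for i in idx[:n_train])
        parts[1].extend(records[i] for i in idx[n_train : n_train + n_val])
        parts[2].extend(records[i] for i in idx[n_train + n_val :])
    return parts


def _default_label(record):
    if isinstance(record, SampleRecord):
        return record.class_label
    if isinstance(record, tuple) and isinstance(record[0], SampleRecord):
        return record[0].class_label
    raise TypeError(
        "cannot infer a class label from this record type; pass label_fn"
    )


def route_zone(zone_id: str) -> str:
    """Which model family maps a zone: GRU for (a), forests elsewhere."""
    if zone_id == "a":
        return "recurrent_net"
    if zone_id in ZONES or zone_id == SOUTH_ZONE:
        return "random_forest"
    raise ValueError(f"unknown zone {zone_id!r}")


def _as_sequences(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == N_MONTHS * N_CHANNELS:
        X = X.reshape(X.shape[0], N_MONTHS, N_CHANNELS)
    if X.ndim != 3 or X.shape[1:] != (N_MONTHS, N_CHANNELS):
        raise ValueError(
            f"expected (n, {N_MONTHS}, {N_CHANNELS}) sequences or their "
            f"flattened form; got {X.shape}"
        )
    return X


class GRUCenterLossClassifier(ClassifierMixin, BaseEstimator):
    """Two-layer GRU sequence classifier with center-loss regularization.

    fit accepts X of shape (n, 7, 10) or flattened (n, 70), plus an
    optional explicit validation set (the 70:10:20 protocol); without one a
    stratified ``validation_fraction`` is carved out of X.  The parameters
    kept are those of the epoch with the best validation overall accuracy
    (earliest epoch on ties).

    Attributes ending in ``_`` follow sklearn conventions: ``classes_``,
    ``centers_``, ``history_`` (per-epoch loss and validation OA),
    ``best_epoch_``.
    """

    def __init__(
        self,
        hidden_size: int = 64,
        n_recurrent_layers: int = 2,
        learning_rate: float = 0.001,
        batch_size: int = 50,
        w1: float = 1.0,
        w2: float = 0.001,
        max_epochs: int = 100,
        center_update_rate: float = 0.5,
        validation_fraction: float = 0.125,
        random_state: int = 0,
    ):
        self.hidden_size = hidden_size
        self.n_recurrent_layers = n_recurrent_layers
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.w1 = w1
        self.w2 = w2
        self.max_epochs = max_epochs
        self.center_update_rate = center_update_rate
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1 (zero-epoch budget)")
        X = _as_sequences(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.shape[0] < 2:
            raise ValueError("training set must span at least two classes")
        self.classes_ = classes
        class_to_idx = {c: i for i, c in enumerate(classes)}
        y_idx = np.array([class_to_idx[c] for c in y])
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            # carve a stratified validation subset out of the training data
            val_idx: list[int] = []
            for k in range(classes.shape[0]):
                idx = np.nonzero(y_idx == k)[0]
                rng.shuffle(idx)
                n_val = max(1, _round_half_up(self.validation_fraction * len(idx)))
                val_idx.extend(idx[:n_val])
            val_mask = np.zeros(len(y_idx), dtype=bool)
            val_mask[val_idx] = True
            X_val, yv_idx = X[val_mask], y_idx[val_mask]
            X, y_idx = X[~val_mask], y_idx[~val_mask]
        else:
            X_val = _as_sequences(X_val)
            y_val = np.asarray(y_val)
            unknown = set(np.unique(y_val)) - set(classes)
            if unknown:
                raise ValueError(f"validation labels not seen in training: {unknown}")
            yv_idx = np.array([class_to_idx[c] for c in y_val])

        n, _, d = X.shape
        params = _gru.init_params(
            d, self.hidden_size, classes.shape[0], self.n_recurrent_layers, rng
        )
        centers = np.zeros((classes.shape[0], self.hidden_size))
        opt = _gru.Adam(params, lr=self.learning_rate)
        best = (-np.inf, None, None, -1)
        history = {"epoch": [], "train_loss": [], "val_oa": []}
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                cache = _gru.forward(params, X[sel])
                ce, cen = _gru.losses(cache, y_idx[sel], centers)
                grads = _gru.backward(
                    params, cache, y_idx[sel], centers, self.w1, self.w2
                )
                opt.step(params, grads)
                centers = update_centers(
                    centers, cache["features"], y_idx[sel], self.center_update_rate
                )
                epoch_losses.append(combined_loss(ce, cen, self.w1, self.w2))
            val_cache = _gru.forward(params, X_val)
            val_oa = float(
                np.mean(val_cache["probs"].argmax(axis=1) == yv_idx)
            )
            history["epoch"].append(epoch)
            history["train_loss"].append(float(np.mean(epoch_losses)))
            history["val_oa"].append(val_oa)
            if val_oa > best[0]:
                best = (val_oa, copy.deepcopy(params), centers.copy(), epoch)
        self.params_ = best[1]
        self.centers_ = best[2]
        self.best_epoch_ = best[3]
        self.best_val_oa_ = best[0]
        self.history_ = history
        self.n_features_in_ = N_MONTHS * N_CHANNELS
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        cache = _gru.forward(self.params_, _as_sequences(X))
        return cache["probs"]

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def deep_features(self, X) -> np.ndarray:
        """Deep features f(x) of the kept parameters (the center-loss space)."""
        check_is_fitted(self, "params_")
        return _gru.forward(self.params_, _as_sequences(X))["features"]


class ZoneRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Per-zone random forest (200 trees) on flattened monthly sequences.

    ``fit`` optionally receives each record's zone and refuses samples from
    outside the model's zone; a ``south`` model accepts the pooled adjacent
    zones b and c.  Remaining forest parameters are the library defaults,
    recorded verbatim in ``metadata_``.
    """

    def __init__(self, zone_id: str | None = None, n_trees: int = 200,
                 random_state: int = 0):
        self.zone_id = zone_id
        self.n_trees = n_trees
        self.random_state = random_state

    def _allowed_zones(self) -> set[str] | None:
        if self.zone_id is None:
            return None
        if self.zone_id == SOUTH_ZONE:
            return {"b", "c"}
        if self.zone_id not in ZONES:
            raise ValueError(f"unknown zone {self.zone_id!r}")
        return {self.zone_id}

    def fit(self, X, y, zones=None):
        X = _as_sequences(X).reshape(len(X), -1)
        y = np.asarray(y)
        if np.unique(y).shape[0] < 2:
            raise ValueError("training set must span at least two classes")
        allowed = self._allowed_zones()
        if zones is not None and allowed is not None:
            offending = sorted(set(zones) - allowed)
            if offending:
                raise ValueError(
                    f"records from zones {offending} cannot train the "
                    f"zone-{self.zone_id} model (allowed: {sorted(allowed)})"
                )
        self.estimator_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state
        ).fit(X, y)
        self.classes_ = self.estimator_.classes_
        self.metadata_ = {
            "zone_id": self.zone_id,
            "n_trees": self.n_trees,
            "random_state": self.random_state,
            "forest_params": self.estimator_.get_params(),
        }
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(_as_sequences(X).reshape(len(X), -1))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(
            _as_sequences(X).reshape(len(X), -1)
        )


@dataclass
class ZoneModel:
    """A fitted zone model plus its training metadata."""

    zone_id: str
    model_kind: str
    model: GRUCenterLossClassifier | ZoneRandomForestClassifier
    metadata: dict = field(default_factory=dict)


def _featurize_records(records) -> tuple[np.ndarray, np.ndarray]:
    feats = SequenceFeaturizer(flatten=False)
    X = feats.transform([series for _, series in records])
    y = np.array([rec.class_label for rec, _ in records])
    return X, y


def train_recurrent(
    records, config: NetworkConfig = NetworkConfig(), split: SplitSpec | None = None
) -> ZoneModel:
    """70:10:20 split, mini-batch training, best-validation-OA selection.

    ``records`` are (SampleRecord, series) pairs; the held-out test
    partition and its overall accuracy land in the metadata.
    """
    split = split or SplitSpec(seed=config.seed)
    train, val, test = split_samples(records, split)
    X_tr, y_tr = _featurize_records(train)
    X_va, y_va = _featurize_records(val)
    clf = GRUCenterLossClassifier(
        hidden_size=config.hidden_size,
        n_recurrent_layers=config.n_recurrent_layers,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        w1=config.w1,
        w2=config.w2,
        max_epochs=config.max_epochs,
        center_update_rate=config.center_update_rate,
        random_state=config.seed,
    ).fit(X_tr, y_tr, X_val=X_va, y_val=y_va)
    X_te, y_te = _featurize_records(test) if test else (None, None)
    test_oa = (
        float(np.mean(clf.predict(X_te) == y_te)) if X_te is not None else None
    )
    zone = records[0][0].zone if records else "a"
    meta = {
        "config": config,
        "split_seed": split.seed,
        "n_train": len(train),
        "n_val": len(val),
        "n_test": len(test),
        "best_epoch": clf.best_epoch_,
        "best_val_oa": clf.best_val_oa_,
        "test_oa": test_oa,
        "history": clf.history_,
        "test_records": test,
    }
    return ZoneModel(zone, "recurrent_net", clf, meta)


def train_random_forest(
    records,
    zone_id: str,
    n_trees: int = 200,
    seed: int = 0,
    split: SplitSpec | None = None,
) -> ZoneModel:
    """Fit the zone's 200-tree forest on the training partition."""
    split = split or SplitSpec(seed=seed)
    train, val, test = split_samples(records, split)
    X_tr, y_tr = _featurize_records(train)
    clf = ZoneRandomForestClassifier(
        zone_id=zone_id, n_trees=n_trees, random_state=seed
    ).fit(X_tr, y_tr, zones=[rec.zone for rec, _ in records])
    X_te, y_te = _featurize_records(test) if test else (None, None)
    test_oa = (
        float(np.mean(clf.predict(X_te) == y_te)) if X_te is not None else None
    )
    meta = dict(
        clf.metadata_,
        split_seed=split.seed,
        n_train=len(train),
        n_val=len(val),
        n_test=len(test),
        test_oa=test_oa,
        test_records=test,
    )
    return ZoneModel(zone_id, "random_forest", clf, meta)


def predict_pixels(model: ZoneModel, sequences) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and row-normalized per-class probabilities.

    ``sequences`` may be FeatureSequence objects or an array of shape
    (n, 7, 10) / (n, 70).  Probability columns follow ``model.model.classes_``.
    """
    if isinstance(sequences, (list, tuple)) and sequences and isinstance(
        sequences[0], FeatureSequence
    ):
        X = np.stack([s.values for s in sequences])
    else:
        X = np.asarray(sequences, dtype=float)
    X = _as_sequences(X)
    probs = model.model.predict_proba(X)
    probs = probs / probs.sum(axis=1, keepdims=True)
    labels = model.model.classes_[probs.argmax(axis=1)]
    return labels, probs
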