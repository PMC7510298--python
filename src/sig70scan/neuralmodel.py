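"""The promoter classifier: a small fully-connected network over the 12
one-hot-encoded box nucleotides.

Architecture ("grid" wiring, the default): the first layer applies a dense
transform along the position axis (12 -> 30) independently per one-hot
channel, producing a 30 x 4 activation grid whose depth of 4 is a remnant of
the encoding; the second layer flattens the grid (120 -> 16); a single
sigmoid node outputs the promoter score in (0, 1). Hidden activations are
ReLU. An alternative "flat" wiring (48 -> 120 -> 16 -> 1) is available via
config. Training minimises binary cross-entropy with the Adam optimiser.

The forward/backward passes are written directly in numpy: the network is
small enough (a few thousand parameters) that explicit matrix arithmetic is
both the fastest and the most transparent implementation, and it keeps the
scoring path trivially portable.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import seqcore
from .datasets import PromoterDataset

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    """Raised for invalid configs, shapes, or containers."""


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    ``layer1_units`` counts units along the position axis of the first layer
    (30 by default, giving a 30 x 4 activation grid under the "grid"
    wiring). The output layer is a single sigmoid node; requesting anything
    else is an error — this is a binary classifier by contract.
    """

    layer1_units: int = 30
    layer2_units: int = 16
    output_units: int = 1
    architecture: str = "grid"  # "grid" | "flat"
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 64
    class_weighting: bool = True
    early_stopping_patience: Optional[int] = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_units != 1:
            raise ModelError("output_units must be 1 (binary classifier)")
        if self.layer1_units < 1 or self.layer2_units < 1:
            raise ModelError("all unit counts must be >= 1")
        if self.architecture not in ("grid", "flat"):
            raise ModelError(f"unknown architecture {self.architecture!r}")
        if self.epochs < 0 or self.batch_size < 1:
            raise ModelError("epochs must be >= 0 and batch_size >= 1")


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out

# scores are nudged inward only at the float-representable edges, so the
# (0,1) contract survives rounding without creating ties between distinct
# inputs (sigmoid underflows to exactly 1.0 for logits above ~37)
_SCORE_MIN = 1e-300
_SCORE_MAX = float(np.nextafter(1.0, 0.0))


class TrainedClassifier:
    """Network weights + config + training log, with a score contract in (0,1).

    Parameter layout (grid wiring): W1 (L1, 12), b1 (L1,), W2 (L2, 4*L1),
    b2 (L2,), W3 (1, L2), b3 (1,). Flat wiring replaces W1 with (4*L1, 48)
    acting on the flattened one-hot vector.
    """

    def __init__(self, config: NetworkConfig, params: Dict[str, np.ndarray],
                 training_log: Optional[List[dict]] = None):
        self.config = config
        self.params = params
        self.training_log: List[dict] = training_log or []
        self._check_shapes()

    # -- construction -------------------------------------------------------

    @classmethod
    def initialize(cls, config: NetworkConfig) -> "TrainedClassifier":
        """He-initialised weights, reproducible under config.seed."""
        rng = np.random.default_rng(config.seed)
        L1, L2 = config.layer1_units, config.layer2_units
        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        if config.architecture == "grid":
            params = {
                "W1": he((L1, seqcore.PAIR_LENGTH), seqcore.PAIR_LENGTH),
                "b1": np.zeros(L1),
                "W2": he((L2, 4 * L1), 4 * L1),
                "b2": np.zeros(L2),
            }
        else:
            params = {
                "W1": he((4 * L1, 48), 48),
                "b1": np.zeros(4 * L1),
                "W2": he((L2, 4 * L1), 4 * L1),
                "b2": np.zeros(L2),
            }
        params["W3"] = he((1, L2), L2)
        params["b3"] = np.zeros(1)
        return cls(config, params)

    def _check_shapes(self) -> None:
        L1, L2 = self.config.layer1_units, self.config.layer2_units
        expect = (
            {"W1": (L1, 12), "b1": (L1,)}
            if self.config.architecture == "grid"
            else {"W1": (4 * L1, 48), "b1": (4 * L1,)}
        )
        expect.update({"W2": (L2, 4 * L1), "b2": (L2,), "W3": (1, L2), "b3": (1,)})
        for name, shape in expect.items():
            if name not in self.params:
                raise ModelError(f"missing parameter {name}")
            got = np.asarray(self.params[name]).shape
            if got != shape:
                raise ModelError(f"parameter {name}: expected {shape}, got {got}")

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy(self) -> "TrainedClassifier":
        return TrainedClassifier(
            copy.deepcopy(self.config),
            {k: v.copy() for k, v in self.params.items()},
            copy.deepcopy(self.training_log),
        )

    # -- forward pass --------------------------------------------------------

    def _forward(self, X: np.ndarray, keep: bool = False):
        """X: (n, 12, 4) float. Returns scores (n,) and, if keep, the cache
        of intermediate activations for backprop."""
        p = self.params
        n = X.shape[0]
        if self.config.architecture == "grid":
            # position-axis dense per channel: (L1,12) x (n,12,4) -> (n,L1,4)
            Z1 = np.einsum("ui,nic->nuc", p["W1"], X) + p["b1"][None, :, None]
            A1 = _relu(Z1)
            F = A1.reshape(n, -1)
        else:
            Xf = X.reshape(n, -1)
            Z1 = Xf @ p["W1"].T + p["b1"]
            A1 = _relu(Z1)
            F = A1
        Z2 = F @ p["W2"].T + p["b2"]
        A2 = _relu(Z2)
        Z3 = A2 @ p["W3"].T + p["b3"]
        yhat = np.clip(_sigmoid(Z3).ravel(), _SCORE_MIN, _SCORE_MAX)
        if keep:
            return yhat, (X, Z1, A1, F, Z2, A2)
        return yhat

    def _backward(self, cache, yhat, y, sw) -> Dict[str, np.ndarray]:
        """Gradients of mean weighted binary cross-entropy."""
        p = self.params
        X, Z1, A1, F, Z2, A2 = cache
        n = X.shape[0]
        dZ3 = ((yhat - y) * sw / n)[:, None]           # (n,1)
        grads = {
            "W3": dZ3.T @ A2,
            "b3": dZ3.sum(axis=0),
        }
        dA2 = dZ3 @ p["W3"]                            # (n,L2)
        dZ2 = dA2 * (Z2 > 0)
        grads["W2"] = dZ2.T @ F
        grads["b2"] = dZ2.sum(axis=0)
        dF = dZ2 @ p["W2"]                             # (n, 4*L1)
        if self.config.architecture == "grid":
            dA1 = dF.reshape(A1.shape)
            dZ1 = dA1 * (Z1 > 0)
            grads["W1"] = np.einsum("nuc,nic->ui", dZ1, X)
            grads["b1"] = dZ1.sum(axis=(0, 2))
        else:
            dZ1 = dF * (Z1 > 0)
            grads["W1"] = dZ1.T @ X.reshape(n, -1)
            grads["b1"] = dZ1.sum(axis=0)
        return grads

    # -- public scoring ------------------------------------------------------

    def score(self, encoded) -> Union[float, np.ndarray]:
        """Promoter score(s) in (0, 1) for one or a batch of inputs.

        Accepts a single 12 x 4 one-hot matrix, an (n, 12, 4) batch, a
        :class:`~sig70scan.seqcore.BoxPair`, a 12-mer string, or a sequence
        of pairs/strings. Batch scoring equals element-wise single scoring.
        """
        single = False
        if isinstance(encoded, (seqcore.BoxPair, str)):
            X = seqcore.one_hot_encode(encoded)[None]
            single = True
        elif isinstance(encoded, np.ndarray):
            if encoded.shape == (seqcore.PAIR_LENGTH, 4):
                X = encoded[None]
                single = True
            elif encoded.ndim == 3 and encoded.shape[1:] == (seqcore.PAIR_LENGTH, 4):
                X = encoded
            else:
                raise ModelError(
                    f"expected (12,4) or (n,12,4) input, got {encoded.shape}"
                )
        else:
            X = seqcore.encode_batch(list(encoded))
        out = self._forward(X.astype(float))
        return float(out[0]) if single else out

    # -- persistence ---------------------------------------------------------

    @property
    def fingerprint(self) -> str:
        """Short stable identifier of (config, weights); ties a Monte-Carlo
        null sample to the exact model that produced it."""
        h = hashlib.sha256()
        h.update(json.dumps(asdict(self.config), sort_keys=True).encode())
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name], dtype=np.float64).tobytes())
        return h.hexdigest()[:16]

    def save(self, path: Union[str, Path]) -> None:
        """Write a portable JSON container: format version, config, named
        weight arrays (nested lists), training log."""
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "training_log": self.training_log,
            "fingerprint": self.fingerprint,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedClassifier":
        payload = json.loads(Path(path).read_text())
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ModelError(f"unsupported model format version {version!r}")
        config = NetworkConfig(**payload["config"])
        params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return cls(config, params, payload.get("training_log", []))


def build_network(config: Optional[NetworkConfig] = None) -> TrainedClassifier:
    """Initialise an untrained classifier (seeded, reproducible)."""
    return TrainedClassifier.initialize(config or NetworkConfig())


# ---------------------------------------------------------------------------
# Training


def _bce(yhat: np.ndarray, y: np.ndarray, sw: np.ndarray) -> float:
    return float(-np.mean(sw * (y * np.log(yhat) + (1 - y) * np.log(1 - yhat))))


def train(
    model: TrainedClassifier,
    data: PromoterDataset,
    epochs: Optional[int] = None,
) -> TrainedClassifier:
    """Fit the network on a labelled dataset; returns a new classifier.

    Minibatch Adam on binary cross-entropy. The dataset itself stays as
    imbalanced as genomes are (promoters are rare), but with
    ``class_weighting`` on (the default) samples are weighted inversely to
    class frequency, so the sigmoid output approximates the balanced-prior
    posterior and the conventional 0.5 threshold is a meaningful operating
    point; trained unweighted, the output approximates the imbalanced
    posterior and a 0.5 cutoff sits at likelihood-ratio ~ N_neg/N_pos, which
    caps sensitivity regardless of model quality. If early stopping is
    configured and the data supports a stratified validation split, the
    best-validation-loss weights (same class weights applied) are restored.
    """
    cfg = model.config
    X, y = data.feature_matrix()
    if len(np.unique(y)) < 2:
        raise ModelError("training data must contain both classes")
    X = X.astype(float)
    y = y.astype(float)
    n_epochs = cfg.epochs if epochs is None else epochs
    fitted = model.copy()
    if n_epochs == 0:
        return fitted

    rng = np.random.default_rng(cfg.seed + 1)
    # optional stratified validation split for early stopping
    val_idx = np.array([], dtype=int)
    patience = cfg.early_stopping_patience
    if patience is not None and cfg.validation_fraction > 0:
        from sklearn.model_selection import train_test_split

        idx = np.arange(len(y))
        n_val = int(round(len(y) * cfg.validation_fraction))
        if n_val >= 2 and min((y == 1).sum(), (y == 0).sum()) >= 2:
            tr_idx, val_idx = train_test_split(
                idx, test_size=cfg.validation_fraction,
                random_state=cfg.seed, stratify=y,
            )
        else:
            logger.info("dataset too small for validation split; early stopping off")
            patience = None
            tr_idx = np.arange(len(y))
    else:
        patience = None
        tr_idx = np.arange(len(y))

    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    if cfg.class_weighting:
        w_pos = len(ytr) / (2.0 * max(ytr.sum(), 1))
        w_neg = len(ytr) / (2.0 * max((1 - ytr).sum(), 1))
    else:
        w_pos = w_neg = 1.0
    sw_tr = np.where(ytr == 1, w_pos, w_neg)
    sw_val = np.where(yval == 1, w_pos, w_neg) if len(val_idx) else np.array([])

    # Adam state
    m = {k: np.zeros_like(v) for k, v in fitted.params.items()}
    v = {k: np.zeros_like(p) for k, p in fitted.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    best_val = np.inf
    best_params = None
    stall = 0
    for epoch in range(n_epochs):
        order = rng.permutation(len(ytr))
        for start in range(0, len(ytr), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            yhat, cache = fitted._forward(Xtr[batch], keep=True)
            grads = fitted._backward(cache, yhat, ytr[batch], sw_tr[batch])
            t += 1
            for k in fitted.params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                fitted.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        train_loss = _bce(fitted._forward(Xtr), ytr, sw_tr)
        entry = {"epoch": epoch, "train_loss": train_loss}
        if patience is not None:
            val_loss = _bce(fitted._forward(Xval), yval, sw_val)
            entry["val_loss"] = val_loss
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = {k: p.copy() for k, p in fitted.params.items()}
                stall = 0
            else:
                stall += 1
        fitted.training_log.append(entry)
        logger.debug("epoch %d: %s", epoch, entry)
        if patience is not None and stall > patience:
            logger.info("early stopping at epoch %d (best val %.4f)", epoch, best_val)
            break
    if best_params is not None:
        fitted.params = best_params
    return fitted


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and the two rates used throughout: sensitivity
    (true positive rate) and specificity (true negative rate). A rate whose
    class is absent is NaN, never silently 0."""

    tp: int
    fp: int
    tn: int
    fn: int
    fold_index: Optional[int] = None

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")


def evaluate(
    model: TrainedClassifier, data: PromoterDataset, threshold: float = 0.5
) -> EvalMetrics:
    """Confusion counts of the classifier at a score threshold.

    A site is called positive when its score is strictly greater than the
    threshold (so threshold 0 calls everything positive, 1 nothing).
    """
    X, y = data.feature_matrix()
    if len(y) == 0:
        raise ModelError("cannot evaluate on an empty dataset")
    pred = model.score(X.astype(float)) > threshold
    y = y.astype(bool)
    return EvalMetrics(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
        fn=int((~pred & y).sum()),
    )


@dataclass(frozen=True)
class CVResult:
    folds: Tuple[EvalMetrics, ...]
    mean_sensitivity: float
    mean_specificity: float


def cross_validate(
    data: PromoterDataset,
    k: int = 5,
    config: Optional[NetworkConfig] = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold cross-validation (default fivefold).

    Each labelled site appears in exactly one validation fold; a fresh
    network is trained on the remaining folds each time. Returns per-fold
    metrics and the mean sensitivity/specificity across folds.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ModelError(f"k must be >= 2, got {k}")
    cfg = config or NetworkConfig()
    _, y = data.feature_matrix()
    if min((y == 1).sum(), (y == 0).sum()) < k:
        raise ModelError(f"each class needs >= {k} members for {k}-fold CV")
    labelled_idx = [
        i for i, s in enumerate(data.sites) if s.label in ("positive", "negative")
    ]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: List[EvalMetrics] = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_cfg = copy.deepcopy(cfg)
        fold_cfg.seed = cfg.seed + fold
        net = build_network(fold_cfg)
        net = train(net, data.subset([labelled_idx[i] for i in tr]))
        metrics = evaluate(net, data.subset([labelled_idx[i] for i in va]), threshold)
        folds.append(
            EvalMetrics(metrics.tp, metrics.fp, metrics.tn, metrics.fn, fold_index=fold)
        )
    return CVResult(
        folds=tuple(folds),
        mean_sensitivity=float(np.mean([f.sensitivity for f in folds])),
        mean_specificity=float(np.mean([f.specificity for f in folds])),
    )
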