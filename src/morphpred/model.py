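"""The two-stage response classifier.

Stage 1 — non-linear dimensionality reduction. Raw regional features are
first binarized (per-feature median split on the *training* data by
default, rank-based and therefore scale-free across mm/mm²/mm³ features;
a min–max squashing to [0, 1] is available as an alternative). A stack of
sigmoid autoencoder layers is then pre-trained greedily — each layer
reconstructs the previous layer's activations under a cross-entropy loss —
and the resulting encoder is fine-tuned end-to-end with a 2-unit softmax
head on the responder labels. After training, the activations of the last
hidden layer (the layer before the output) are the compressed
representation of each subject.

Stage 2 — classification. A support-vector machine is fitted on the
compressed training representations (linear kernel, C = 1, balanced class
weights by default) and produces the final hard labels plus continuous
decision scores used for ROC analysis.

Everything fitted — binarization thresholds, network weights, SVM state —
depends only on the training rows; the entire fit is a deterministic
function of (data, config, seed). Optimization is plain minibatch SGD;
weights start from fan-based uniform (Glorot-style) initialization drawn
from the run seed.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.svm import SVC

from .errors import ConfigError, DivergenceError, SchemaMismatchError
from .features import FeatureTable

__all__ = [
    "TwoStageConfig",
    "BinarizerState",
    "SvmState",
    "TrainedTwoStageModel",
    "fit_binarizer",
    "apply_binarizer",
    "pretrain_stacked_autoencoders",
    "finetune_network",
    "extract_representations",
    "fit_two_stage",
    "predict",
    "save_model",
    "load_model",
]

BINARIZATIONS = ("median_split", "minmax_sigmoid")


@dataclass(frozen=True)
class TwoStageConfig:
    """Hyperparameters of the two-stage pipeline.

    The defaults (hidden widths 64→32→8, 100 pre-training and 200
    fine-tuning epochs, SGD learning rate 0.1, batch size 16) compress the
    150-dimensional input monotonically to a small code while keeping the
    final width well below the per-arm sample size, limiting SVM
    overfitting. ``layer_sizes=()`` disables the encoder entirely, feeding
    the binarized features straight to the SVM.
    """

    layer_sizes: tuple[int, ...] = (64, 32, 8)
    pretrain_epochs: int = 100
    finetune_epochs: int = 200
    learning_rate: float = 0.1
    batch_size: int = 16
    binarization: str = "median_split"
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    svm_class_weight: Optional[str] = "balanced"
    seed: int = 0

    def __post_init__(self):
        if self.binarization not in BINARIZATIONS:
            raise ConfigError(f"unknown binarization {self.binarization!r}")
        if self.svm_kernel not in ("linear", "rbf"):
            raise ConfigError(f"unsupported SVM kernel {self.svm_kernel!r}")
        if self.layer_sizes and self.layer_sizes[-1] < 2:
            raise ConfigError("last hidden width must be >= 2")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")

    def validate_input_dim(self, n_features: int) -> None:
        if any(w >= n_features for w in self.layer_sizes):
            raise ConfigError(
                f"all hidden widths must be smaller than the input dimension "
                f"({n_features}); got {self.layer_sizes}"
            )

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "pretrain_epochs": self.pretrain_epochs,
            "finetune_epochs": self.finetune_epochs,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "binarization": self.binarization,
            "svm_kernel": self.svm_kernel,
            "svm_c": self.svm_c,
            "svm_class_weight": self.svm_class_weight,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStageConfig":
        d = dict(d)
        d["layer_sizes"] = tuple(d["layer_sizes"])
        return cls(**d)


# ---------------------------------------------------------------------------
# binarization

@dataclass
class BinarizerState:
    method: str
    feature_names: list[str]
    thresholds: Optional[np.ndarray] = None  # median_split
    mins: Optional[np.ndarray] = None  # minmax_sigmoid
    maxs: Optional[np.ndarray] = None


def fit_binarizer(train: FeatureTable, method: str = "median_split") -> BinarizerState:
    """Fit per-feature binarization state on training rows only."""
    if method not in BINARIZATIONS:
        raise ConfigError(f"unknown binarization {method!r}")
    if train.n_subjects < 2:
        raise ConfigError("binarizer needs at least 2 training rows")
    values = train.values
    constant = np.nonzero(values.max(axis=0) == values.min(axis=0))[0]
    if constant.size:
        names = [train.feature_names[i] for i in constant[:5]]
        warnings.warn(
            f"{constant.size} constant training feature(s) (e.g. {names}); "
            "they carry no information after binarization",
            stacklevel=2,
        )
    if method == "median_split":
        return BinarizerState(
            method, list(train.feature_names), thresholds=np.median(values, axis=0)
        )
    return BinarizerState(
        method,
        list(train.feature_names),
        mins=values.min(axis=0),
        maxs=values.max(axis=0),
    )


def apply_binarizer(state: BinarizerState, table: FeatureTable) -> np.ndarray:
    """Map a feature table into the unit interval using frozen state."""
    if list(table.feature_names) != state.feature_names:
        raise SchemaMismatchError("table features do not match the fitted binarizer")
    if state.method == "median_split":
        return (table.values > state.thresholds).astype(np.float64)
    span = state.maxs - state.mins
    safe = np.where(span > 0, span, 1.0)
    squashed = (table.values - state.mins) / safe
    squashed = np.where(span > 0, squashed, 0.0)
    return np.clip(squashed, 0.0, 1.0)


# ---------------------------------------------------------------------------
# network primitives

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _cross_entropy(target: np.ndarray, prob: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(prob, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def forward_activations(encoder_weights, x: np.ndarray) -> list[np.ndarray]:
    """Activations of every encoder layer; acts[0] is the input itself."""
    acts = [x]
    for W, b in encoder_weights:
        acts.append(_sigmoid(acts[-1] @ W + b))
    return acts


def pretrain_stacked_autoencoders(
    binary_train: np.ndarray, config: TwoStageConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[list[float]]]:
    """Greedy layer-wise autoencoder pre-training.

    For each hidden layer a one-hidden-layer autoencoder with sigmoid
    units is trained by minibatch SGD to reconstruct the previous layer's
    activations under cross-entropy; its encoder half initializes the
    layer. Returns the encoder weights and per-layer epoch loss curves.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    weights: list[tuple[np.ndarray, np.ndarray]] = []
    histories: list[list[float]] = []
    current = np.asarray(binary_train, dtype=np.float64)
    lr = config.learning_rate
    for layer_idx, width in enumerate(config.layer_sizes):
        fan_in = current.shape[1]
        W = _glorot(rng, fan_in, width)
        b = np.zeros(width)
        W_dec = _glorot(rng, width, fan_in)
        b_dec = np.zeros(fan_in)
        history = []
        for epoch in range(config.pretrain_epochs):
            losses = []
            for idx in _minibatches(current.shape[0], config.batch_size, rng):
                x = current[idx]
                h = _sigmoid(x @ W + b)
                xhat = _sigmoid(h @ W_dec + b_dec)
                losses.append(_cross_entropy(x, xhat))
                m = x.shape[0]
                d_out = (xhat - x) / m  # sigmoid + CE output delta
                d_h = (d_out @ W_dec.T) * h * (1.0 - h)
                W_dec -= lr * (h.T @ d_out)
                b_dec -= lr * d_out.sum(axis=0)
                W -= lr * (x.T @ d_h)
                b -= lr * d_h.sum(axis=0)
            epoch_loss = float(np.mean(losses)) if losses else 0.0
            if not np.isfinite(epoch_loss):
                raise DivergenceError(
                    f"non-finite reconstruction loss in layer {layer_idx} "
                    f"at epoch {epoch}",
                    layer=layer_idx,
                    epoch=epoch,
                )
            history.append(epoch_loss)
        weights.append((W, b))
        histories.append(history)
        current = _sigmoid(current @ W + b)
    return weights, histories


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def finetune_network(
    encoder_weights,
    binary_train: np.ndarray,
    labels: np.ndarray,
    config: TwoStageConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], tuple[np.ndarray, np.ndarray], list[float]]:
    """Supervised fine-tuning of the whole stack with a 2-unit softmax head."""
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ConfigError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ConfigError("fine-tuning requires both classes present")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    x = np.asarray(binary_train, dtype=np.float64)
    weights = [(W.copy(), b.copy()) for W, b in encoder_weights]
    last_width = weights[-1][0].shape[1] if weights else x.shape[1]
    W_head = _glorot(rng, last_width, 2)
    b_head = np.zeros(2)
    onehot = np.eye(2)[labels]
    lr = config.learning_rate
    history: list[float] = []
    for epoch in range(config.finetune_epochs):
        losses = []
        for idx in _minibatches(x.shape[0], config.batch_size, rng):
            acts = forward_activations(weights, x[idx])
            logits = acts[-1] @ W_head + b_head
            prob = _softmax(logits)
            t = onehot[idx]
            eps = 1e-12
            losses.append(float(-np.mean(np.sum(t * np.log(prob + eps), axis=1))))
            m = idx.size
            d = (prob - t) / m
            grad_W_head = acts[-1].T @ d
            grad_b_head = d.sum(axis=0)
            d_hidden = d @ W_head.T
            W_head = W_head - lr * grad_W_head
            b_head = b_head - lr * grad_b_head
            for layer in range(len(weights) - 1, -1, -1):
                h = acts[layer + 1]
                d_pre = d_hidden * h * (1.0 - h)
                W, b = weights[layer]
                d_hidden = d_pre @ W.T
                weights[layer] = (
                    W - lr * (acts[layer].T @ d_pre),
                    b - lr * d_pre.sum(axis=0),
                )
        epoch_loss = float(np.mean(losses)) if losses else 0.0
        if not np.isfinite(epoch_loss):
            raise DivergenceError(
                f"non-finite fine-tuning loss at epoch {epoch}", epoch=epoch
            )
        history.append(epoch_loss)
    return weights, (W_head, b_head), history


# ---------------------------------------------------------------------------
# SVM second stage

@dataclass
class SvmState:
    """Frozen SVM decision function over last-hidden-layer representations.

    Decision scores are always computed from the stored arrays (never by
    re-entering sklearn), so serialized models reproduce predictions
    bitwise.
    """

    kernel: str
    classes: np.ndarray
    intercept: float
    coef: Optional[np.ndarray] = None  # linear
    support_vectors: Optional[np.ndarray] = None  # rbf
    dual_coef: Optional[np.ndarray] = None
    gamma: Optional[float] = None

    def decision(self, reps: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return reps @ self.coef + self.intercept
        diff = reps[:, None, :] - self.support_vectors[None, :, :]
        k = np.exp(-self.gamma * np.sum(diff * diff, axis=2))
        return k @ self.dual_coef + self.intercept

    def predict_labels(self, reps: np.ndarray) -> np.ndarray:
        scores = self.decision(reps)
        return np.where(scores > 0, self.classes[1], self.classes[0])


def _fit_svm(reps: np.ndarray, labels: np.ndarray, config: TwoStageConfig) -> SvmState:
    svc = SVC(
        kernel=config.svm_kernel,
        C=config.svm_c,
        class_weight=config.svm_class_weight,
        gamma="scale",
    )
    svc.fit(reps, labels)
    if config.svm_kernel == "linear":
        return SvmState(
            kernel="linear",
            classes=svc.classes_.astype(int),
            intercept=float(svc.intercept_[0]),
            coef=svc.coef_[0].copy(),
        )
    return SvmState(
        kernel="rbf",
        classes=svc.classes_.astype(int),
        intercept=float(svc.intercept_[0]),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        gamma=float(svc._gamma),
    )


# ---------------------------------------------------------------------------
# the assembled model

@dataclass
class TrainedTwoStageModel:
    config: TwoStageConfig
    binarizer_state: BinarizerState
    encoder_weights: list[tuple[np.ndarray, np.ndarray]]
    classifier_head: tuple[np.ndarray, np.ndarray]
    svm_state: SvmState
    feature_names: list[str]
    training_history: dict = field(default_factory=dict)

    @property
    def representation_dim(self) -> int:
        if self.encoder_weights:
            return self.encoder_weights[-1][0].shape[1]
        return len(self.feature_names)


def extract_representations(model: TrainedTwoStageModel, binary: np.ndarray) -> np.ndarray:
    """Last-hidden-layer activations under the frozen encoder (no refitting)."""
    binary = np.asarray(binary, dtype=np.float64)
    if binary.ndim == 1:
        binary = binary[None, :]
    if binary.shape[1] != len(model.feature_names):
        raise SchemaMismatchError(
            f"expected {len(model.feature_names)} features, got {binary.shape[1]}"
        )
    return forward_activations(model.encoder_weights, binary)[-1]


def fit_two_stage(
    train: FeatureTable, labels, config: TwoStageConfig
) -> TrainedTwoStageModel:
    """Fit the full pipeline: binarize → pre-train → fine-tune → SVM."""
    labels = np.asarray(labels).astype(int)
    if labels.shape[0] != train.n_subjects:
        raise ConfigError("labels length does not match table rows")
    if len(np.unique(labels)) < 2:
        raise ConfigError("training requires both classes present")
    config.validate_input_dim(train.n_features)
    rng = np.random.default_rng(config.seed)
    binarizer = fit_binarizer(train, config.binarization)
    binary = apply_binarizer(binarizer, train)
    encoder, pre_hist = pretrain_stacked_autoencoders(binary, config, rng)
    if config.finetune_epochs > 0 or config.layer_sizes:
        encoder, head, fine_hist = finetune_network(encoder, binary, labels, config, rng)
    else:
        head, fine_hist = (np.zeros((train.n_features, 2)), np.zeros(2)), []
    model = TrainedTwoStageModel(
        config=config,
        binarizer_state=binarizer,
        encoder_weights=encoder,
        classifier_head=head,
        svm_state=None,  # filled below
        feature_names=list(train.feature_names),
        training_history={"pretrain": pre_hist, "finetune": fine_hist},
    )
    reps = extract_representations(model, binary)
    model.svm_state = _fit_svm(reps, labels, config)
    return model


def predict(model: TrainedTwoStageModel, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and continuous decision scores for new subjects."""
    binary = apply_binarizer(model.binarizer_state, table)
    reps = extract_representations(model, binary)
    scores = model.svm_state.decision(reps)
    labels = model.svm_state.predict_labels(reps)
    return labels, scores


# ---------------------------------------------------------------------------
# serialization: single archive of a JSON header plus named numeric arrays

def save_model(model: TrainedTwoStageModel, path) -> None:
    header = {
        "config": model.config.to_dict(),
        "feature_names": model.feature_names,
        "binarizer_method": model.binarizer_state.method,
        "n_encoder_layers": len(model.encoder_weights),
        "svm_kernel": model.svm_state.kernel,
    }
    arrays = {"header_json": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    bs = model.binarizer_state
    if bs.thresholds is not None:
        arrays["bin_thresholds"] = bs.thresholds
    if bs.mins is not None:
        arrays["bin_mins"] = bs.mins
        arrays["bin_maxs"] = bs.maxs
    for i, (W, b) in enumerate(model.encoder_weights):
        arrays[f"enc_W{i}"] = W
        arrays[f"enc_b{i}"] = b
    arrays["head_W"], arrays["head_b"] = model.classifier_head
    ss = model.svm_state
    arrays["svm_classes"] = ss.classes
    arrays["svm_intercept"] = np.array([ss.intercept])
    if ss.kernel == "linear":
        arrays["svm_coef"] = ss.coef
    else:
        arrays["svm_support_vectors"] = ss.support_vectors
        arrays["svm_dual_coef"] = ss.dual_coef
        arrays["svm_gamma"] = np.array([ss.gamma])
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> TrainedTwoStageModel:
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    header = json.loads(io.BytesIO(arrays["header_json"].tobytes()).read().decode())
    config = TwoStageConfig.from_dict(header["config"])
    names = list(header["feature_names"])
    bs = BinarizerState(
        method=header["binarizer_method"],
        feature_names=names,
        thresholds=arrays.get("bin_thresholds"),
        mins=arrays.get("bin_mins"),
        maxs=arrays.get("bin_maxs"),
    )
    encoder = [
        (arrays[f"enc_W{i}"], arrays[f"enc_b{i}"])
        for i in range(header["n_encoder_layers"])
    ]
    if header["svm_kernel"] == "linear":
        ss = SvmState(
            kernel="linear",
            classes=arrays["svm_classes"],
            intercept=float(arrays["svm_intercept"][0]),
            coef=arrays["svm_coef"],
        )
    else:
        ss = SvmState(
            kernel="rbf",
            classes=arrays["svm_classes"],
            intercept=float(arrays["svm_intercept"][0]),
            support_vectors=arrays["svm_support_vectors"],
            dual_coef=arrays["svm_dual_coef"],
            gamma=float(arrays["svm_gamma"][0]),
        )
    return TrainedTwoStageModel(
        config=config,
        binarizer_state=bs,
        encoder_weights=encoder,
        classifier_head=(arrays["head_W"], arrays["head_b"]),
        svm_state=ss,
        feature_names=names,
    )
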