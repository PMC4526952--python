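"""Semi-supervised deep belief network classifier.

A stack of Bernoulli restricted Boltzmann machines is pretrained greedily on
unlabeled binary feature vectors with contrastive divergence (CD-k), unrolled
into a feed-forward network (sigmoid hidden layers, softmax output), and
fine-tuned on the labeled set with mini-batch back-propagation under inverted
dropout.  Default architecture: input -> 700 -> 700 -> 300 -> n_categories.

All parameters are float64 numpy arrays; every stochastic step draws from a
seeded generator, so a full pretrain + finetune replay with the same seed
reproduces weights bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RBMParams",
    "DBNModel",
    "PretrainConfig",
    "FinetuneConfig",
    "hidden_probs",
    "visible_probs",
    "cd_update",
    "train_rbm",
    "pretrain",
    "finetune",
    "predict_scores",
    "save_model",
    "load_model",
    "DBNClassifier",
]

MODEL_FORMAT = "tweetmine-dbn"
MODEL_VERSION = 1

DEFAULT_HIDDEN_SIZES = (700, 700, 300)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class RBMParams:
    """Bernoulli RBM parameters: W (visible x hidden), visible and hidden biases."""

    W: np.ndarray
    vbias: np.ndarray
    hbias: np.ndarray

    def __post_init__(self) -> None:
        nv, nh = self.W.shape
        if self.vbias.shape != (nv,) or self.hbias.shape != (nh,):
            raise ValueError("RBM bias shapes inconsistent with W")
        if not (
            np.isfinite(self.W).all()
            and np.isfinite(self.vbias).all()
            and np.isfinite(self.hbias).all()
        ):
            raise ValueError("RBM parameters must be finite")

    @classmethod
    def init_random(cls, nv: int, nh: int, rng: np.random.Generator,
                    weight_sd: float = 0.01) -> "RBMParams":
        # zero-mean Gaussian weights, zero biases: standard for RBM stacks
        return cls(rng.normal(0.0, weight_sd, size=(nv, nh)),
                   np.zeros(nv), np.zeros(nh))


@dataclass(frozen=True)
class PretrainConfig:
    """Layer-wise CD pretraining hyperparameters."""

    cd_k: int = 1
    learning_rate: float = 0.05
    epochs_per_layer: int = 10
    batch_size: int = 10
    weight_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cd_k < 1 or self.epochs_per_layer < 0 or self.batch_size < 1:
            raise ValueError("PretrainConfig values must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass(frozen=True)
class FinetuneConfig:
    """Back-propagation fine-tuning hyperparameters (batch 10, 200 epochs,
    dropout 0.5 on hidden layers by default)."""

    batch_size: int = 10
    epochs: int = 200
    learning_rate: float = 0.1
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("FinetuneConfig values must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass
class DBNModel:
    """Feed-forward stack: sigmoid hidden layers, softmax output.

    ``weights[l]`` maps layer l activations to layer l+1 pre-activations.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    categories: tuple[str, ...]
    pretrain_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = self.layer_sizes
        if len(sizes) < 3:
            raise ValueError("need at least input, one hidden, and output layer")
        if len(self.weights) != len(sizes) - 1 or len(self.biases) != len(sizes) - 1:
            raise ValueError("weight/bias count inconsistent with layer sizes")
        for l, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            if self.weights[l].shape != (a, b) or self.biases[l].shape != (b,):
                raise ValueError(f"layer {l}: shape mismatch")
        if len(self.categories) != sizes[-1]:
            raise ValueError("output dimension must equal the category count")

    @property
    def n_hidden_layers(self) -> int:
        return len(self.layer_sizes) - 2

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass returning softmax scores."""
        if X.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"input has {X.shape[1]} columns, model expects {self.layer_sizes[0]}"
            )
        a = X.astype(float)
        for l in range(self.n_hidden_layers):
            a = _sigmoid(a @ self.weights[l] + self.biases[l])
        return _softmax(a @ self.weights[-1] + self.biases[-1])

    def copy(self) -> "DBNModel":
        return DBNModel(
            self.layer_sizes,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.categories,
            dict(self.pretrain_log),
        )


def hidden_probs(rbm: RBMParams, V: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) = sigma(c_j + sum_i v_i W_ij), row-wise over a batch."""
    V = np.atleast_2d(V).astype(float)
    if V.shape[1] != rbm.W.shape[0]:
        raise ValueError(
            f"visible dimension {V.shape[1]} != RBM visible size {rbm.W.shape[0]}"
        )
    return _sigmoid(V @ rbm.W + rbm.hbias)


def visible_probs(rbm: RBMParams, H: np.ndarray) -> np.ndarray:
    """p(v_i = 1 | h) = sigma(b_i + sum_j h_j W_ij)."""
    H = np.atleast_2d(H).astype(float)
    if H.shape[1] != rbm.W.shape[1]:
        raise ValueError(
            f"hidden dimension {H.shape[1]} != RBM hidden size {rbm.W.shape[1]}"
        )
    return _sigmoid(H @ rbm.W.T + rbm.vbias)


def cd_update(
    rbm: RBMParams,
    batch: np.ndarray,
    cfg: PretrainConfig,
    rng: np.random.Generator,
) -> RBMParams:
    """One contrastive-divergence-k parameter step on a mini-batch (in place).

    Positive phase from the data; k alternating Gibbs steps for the negative
    phase with hidden states sampled, final visible and hidden phases taken
    as probabilities (mean-field).  Step = lr * (pos - neg associations) / m.
    """
    V0 = np.atleast_2d(batch).astype(float)
    if V0.shape[0] == 0:
        raise ValueError("cd_update: empty batch")
    m = V0.shape[0]
    H0 = hidden_probs(rbm, V0)
    Hs = (rng.random(H0.shape) < H0).astype(float)
    Vk = V0
    for _ in range(cfg.cd_k):
        Vk = visible_probs(rbm, Hs)
        Hk = hidden_probs(rbm, Vk)
        Hs = (rng.random(Hk.shape) < Hk).astype(float)
    Hk = hidden_probs(rbm, Vk)  # final hidden phase uses probabilities

    lr = cfg.learning_rate / m
    rbm.W += lr * (V0.T @ H0 - Vk.T @ Hk)
    rbm.vbias += lr * (V0.sum(axis=0) - Vk.sum(axis=0))
    rbm.hbias += lr * (H0.sum(axis=0) - Hk.sum(axis=0))
    return rbm


def train_rbm(
    X: np.ndarray,
    n_hidden: int,
    cfg: PretrainConfig,
    rng: np.random.Generator,
) -> tuple[RBMParams, list[float]]:
    """Train one RBM with mini-batch CD-k; returns params and the per-epoch
    mean squared reconstruction error."""
    n, nv = X.shape
    rbm = RBMParams.init_random(nv, n_hidden, rng, cfg.weight_sd)
    recon_log: list[float] = []
    for _ in range(cfg.epochs_per_layer):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            cd_update(rbm, X[order[start : start + cfg.batch_size]], cfg, rng)
        recon = visible_probs(rbm, hidden_probs(rbm, X))
        recon_log.append(float(((X - recon) ** 2).mean()))
    return rbm, recon_log


def pretrain(
    X_unlabeled: np.ndarray,
    layer_sizes: Sequence[int],
    cfg: PretrainConfig,
    categories: Sequence[str],
) -> DBNModel:
    """Greedy layer-wise RBM pretraining.

    RBM 1 trains on the data, each further RBM on the hidden-probability
    (mean-field) outputs of the previous one.  The RBM weights seed the
    feed-forward stack; the output layer is randomly initialized and stays
    untrained until :func:`finetune`.
    """
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 3:
        raise ValueError("layer_sizes must list input, hidden layer(s), and output")
    if X_unlabeled.shape[1] != sizes[0]:
        raise ValueError(
            f"X has {X_unlabeled.shape[1]} columns, input layer expects {sizes[0]}"
        )
    rng = np.random.default_rng(cfg.seed)
    weights: list[np.ndarray] = []
    biases: list[np.ndarray] = []
    log: dict = {"reconstruction_error": []}
    layer_input = X_unlabeled.astype(float)
    for l in range(len(sizes) - 2):
        rbm, recon = train_rbm(layer_input, sizes[l + 1], cfg, rng)
        weights.append(rbm.W.copy())
        biases.append(rbm.hbias.copy())
        log["reconstruction_error"].append(recon)
        layer_input = hidden_probs(rbm, layer_input)
        logger.info("pretrained layer %d (%d -> %d)", l + 1, sizes[l], sizes[l + 1])
    # output layer: random init, trained only by fine-tuning
    weights.append(rng.normal(0.0, cfg.weight_sd, size=(sizes[-2], sizes[-1])))
    biases.append(np.zeros(sizes[-1]))
    return DBNModel(sizes, weights, biases, tuple(categories), log)


def init_random_model(
    layer_sizes: Sequence[int],
    categories: Sequence[str],
    seed: int = 0,
    weight_sd: float = 0.01,
) -> DBNModel:
    """Randomly initialized stack (the no-pretraining baseline)."""
    sizes = tuple(int(s) for s in layer_sizes)
    rng = np.random.default_rng(seed)
    weights = [
        rng.normal(0.0, weight_sd, size=(a, b))
        for a, b in zip(sizes[:-1], sizes[1:])
    ]
    biases = [np.zeros(b) for b in sizes[1:]]
    return DBNModel(sizes, weights, biases, tuple(categories))


def _forward_train(
    model: DBNModel,
    X: np.ndarray,
    dropout_rate: float,
    rng: Optional[np.random.Generator],
) -> tuple[list[np.ndarray], list[np.ndarray], list[Optional[np.ndarray]], np.ndarray]:
    """Forward pass keeping post-dropout activations ``acts``, pre-dropout
    sigmoids ``sigs``, and the inverted-dropout masks."""
    acts = [X.astype(float)]
    sigs: list[np.ndarray] = []
    masks: list[Optional[np.ndarray]] = []
    a = acts[0]
    for l in range(model.n_hidden_layers):
        s = _sigmoid(a @ model.weights[l] + model.biases[l])
        sigs.append(s)
        if dropout_rate > 0.0 and rng is not None:
            mask = (rng.random(s.shape) >= dropout_rate) / (1.0 - dropout_rate)
            a = s * mask
            masks.append(mask)
        else:
            a = s
            masks.append(None)
        acts.append(a)
    scores = _softmax(a @ model.weights[-1] + model.biases[-1])
    return acts, sigs, masks, scores


def _backprop_batch(
    model: DBNModel,
    Xb: np.ndarray,
    yb: np.ndarray,
    lr: float,
    dropout_rate: float,
    rng: Optional[np.random.Generator],
) -> None:
    """One SGD step on mean cross-entropy of the softmax outputs."""
    m = Xb.shape[0]
    acts, sigs, masks, scores = _forward_train(model, Xb, dropout_rate, rng)
    delta = scores.copy()
    delta[np.arange(m), yb] -= 1.0  # d(mean CE)/d(logits), summed form
    delta /= m
    for l in range(len(model.weights) - 1, -1, -1):
        gW = acts[l].T @ delta
        gb = delta.sum(axis=0)
        if l > 0:
            back = delta @ model.weights[l].T
            if masks[l - 1] is not None:
                back = back * masks[l - 1]
            s = sigs[l - 1]
            delta = back * s * (1.0 - s)
        model.weights[l] -= lr * gW
        model.biases[l] -= lr * gb


def finetune(
    model: DBNModel,
    X: np.ndarray,
    y: Sequence[int] | np.ndarray,
    cfg: FinetuneConfig,
) -> DBNModel:
    """Fine-tune in place with mini-batch SGD on cross-entropy.

    Dropout masks hidden units during training with inverted scaling, so
    prediction-time forward passes need no rescaling.  Returns the model.
    """
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    if y.size and (y.min() < 0 or y.max() >= model.layer_sizes[-1]):
        raise ValueError("label index outside the category scheme")
    rng = np.random.default_rng(cfg.seed)
    Xf = X.astype(float)
    n = Xf.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            _backprop_batch(
                model, Xf[idx], y[idx], cfg.learning_rate, cfg.dropout_rate, rng
            )
    return model


def predict_scores(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Deterministic per-category scores; each row sums to 1 (softmax)."""
    return model.forward(np.asarray(X))


def save_model(model: DBNModel, path: str | Path) -> None:
    """Portable container: one JSON header line, then dense float64 arrays."""
    path = Path(path)
    header = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "categories": list(model.categories),
    }
    with path.open("wb") as fh:
        fh.write(json.dumps(header).encode("utf-8") + b"\n")
        for W, b in zip(model.weights, model.biases):
            fh.write(np.ascontiguousarray(W, dtype=np.float64).tobytes())
            fh.write(np.ascontiguousarray(b, dtype=np.float64).tobytes())


def load_model(path: str | Path) -> DBNModel:
    path = Path(path)
    with path.open("rb") as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}: not a {MODEL_FORMAT} file") from exc
        if header.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path}: not a {MODEL_FORMAT} file")
        if header.get("version") != MODEL_VERSION:
            raise ValueError(
                f"{path}: unsupported model version {header.get('version')}"
            )
        sizes = tuple(int(s) for s in header["layer_sizes"])
        blob = fh.read()
    weights, biases = [], []
    offset = 0
    for a, b in zip(sizes[:-1], sizes[1:]):
        need = (a * b + b) * 8
        if offset + need > len(blob):
            raise ValueError(f"{path}: truncated model file")
        W = np.frombuffer(blob, dtype=np.float64, count=a * b, offset=offset)
        offset += a * b * 8
        bias = np.frombuffer(blob, dtype=np.float64, count=b, offset=offset)
        offset += b * 8
        weights.append(W.reshape(a, b).copy())
        biases.append(bias.copy())
    if offset != len(blob):
        raise ValueError(f"{path}: trailing bytes in model file")
    return DBNModel(sizes, weights, biases, tuple(header["categories"]))


class DBNClassifier:
    """Estimator-style wrapper bundling pretraining and fine-tuning.

    ``initial_model`` lets several folds share one pretrained stack (the
    stack is copied before fine-tuning, so folds never interact).
    """

    def __init__(
        self,
        categories: Sequence[str],
        hidden_sizes: Sequence[int] = DEFAULT_HIDDEN_SIZES,
        pretrain_cfg: Optional[PretrainConfig] = None,
        finetune_cfg: Optional[FinetuneConfig] = None,
        X_unlabeled: Optional[np.ndarray] = None,
        initial_model: Optional[DBNModel] = None,
    ):
        self.categories = tuple(categories)
        self.hidden_sizes = tuple(hidden_sizes)
        self.pretrain_cfg = pretrain_cfg or PretrainConfig()
        self.finetune_cfg = finetune_cfg or FinetuneConfig()
        self.X_unlabeled = X_unlabeled
        self.initial_model = initial_model
        self.model: Optional[DBNModel] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DBNClassifier":
        sizes = (X.shape[1], *self.hidden_sizes, len(self.categories))
        if self.initial_model is not None:
            model = self.initial_model.copy()
        elif self.X_unlabeled is not None:
            model = pretrain(self.X_unlabeled, sizes, self.pretrain_cfg, self.categories)
        else:
            model = init_random_model(sizes, self.categories, self.pretrain_cfg.seed,
                                      self.pretrain_cfg.weight_sd)
        self.model = finetune(model, X, y, self.finetune_cfg)
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit() before predict_scores()")
        return predict_scores(self.model, X)
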