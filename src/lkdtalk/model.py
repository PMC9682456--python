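"""Recurrent binary comment classifier.

Architecture: a trainable embedding table feeds a single unidirectional
LSTM layer; the final hidden state feeds a two-logit output layer whose
softmax gives the probability that a comment is related to living kidney
donation.  Training minimizes cross-entropy with the Adam update rule.
A probability of at least 0.5 classifies a comment as related.

The network is implemented directly in numpy (forward pass and
backpropagation through time), which keeps training fully deterministic
under a seed and fast enough on one CPU at the corpus sizes this package
targets.  Padding uses index 0; padded steps are excluded from nothing
but the loss — the recurrence runs over the full padded length, with the
PAD embedding trained like any other row.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from lkdtalk.corpus_io import Label
from lkdtalk.vocab import PAD_INDEX, Vocabulary

__all__ = [
    "GRID",
    "ClassifierConfig",
    "TrainedClassifier",
    "train",
    "predict_proba",
    "predict_proba_batch",
    "classify",
]

#: The hyperparameter grid explored during model selection.
GRID = {
    "tokenization_level": ("word", "char_gram"),
    "embedding_size": (500, 600, 700, 1204, 2048),  # 1204 as published
    "hidden_size": (20, 30, 50, 100, 150, 200, 400, 500, 600),
    "learning_rate": (1e-2, 1e-3, 1e-4, 1e-5, 1e-6),
    "batch_size": (8, 16, 32, 64, 128),
}


@dataclass(frozen=True)
class ClassifierConfig:
    """One point of the hyperparameter grid plus training controls.

    Grid fields are restricted to the values in :data:`GRID` unless
    ``allow_off_grid`` is set (useful for small smoke configurations).
    """

    tokenization_level: Literal["word", "char_gram"] = "word"
    embedding_size: int = 500
    hidden_size: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    char_gram_n: int = 10
    allow_off_grid: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.allow_off_grid:
            for name in ("tokenization_level", "embedding_size", "hidden_size",
                         "learning_rate", "batch_size"):
                value = getattr(self, name)
                if value not in GRID[name]:
                    raise ValueError(
                        f"{name}={value!r} is off the experimental grid "
                        f"{GRID[name]}; pass allow_off_grid=True to override"
                    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierConfig":
        return cls(**d)


def _init_params(vocab_size: int, config: ClassifierConfig, rng: np.random.Generator) -> dict:
    E, H = config.embedding_size, config.hidden_size
    def uniform(shape, scale):
        return rng.uniform(-scale, scale, size=shape)
    params = {
        "emb": uniform((vocab_size, E), 0.1),
        "Wx": uniform((E, 4 * H), 1.0 / np.sqrt(E)),
        "Wh": uniform((H, 4 * H), 1.0 / np.sqrt(H)),
        "b": np.zeros(4 * H),
        "Wy": uniform((H, 2), 1.0 / np.sqrt(H)),
        "by": np.zeros(2),
    }
    params["b"][H : 2 * H] = 1.0  # forget-gate bias starts open
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _forward(params: dict, X: np.ndarray, keep_cache: bool = False):
    """Run the LSTM over a padded integer batch ``X`` of shape (B, T).

    Returns (probabilities of the positive class, logits, cache).
    """
    B, T = X.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = {"X": X, "steps": []} if keep_cache else None
    emb, Wx, Wh, b = params["emb"], params["Wx"], params["Wh"], params["b"]
    for t in range(T):
        x_t = emb[X[:, t]]                      # (B, E)
        z = x_t @ Wx + h @ Wh + b               # (B, 4H)
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        if keep_cache:
            cache["steps"].append((x_t, h, c, i, f, g, o, c_new))
        h, c = h_new, c_new
    logits = h @ params["Wy"] + params["by"]    # (B, 2)
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    if keep_cache:
        cache["h_final"] = h
    return probs, logits, cache


def _backward(params: dict, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict:
    """Gradients of mean cross-entropy w.r.t. every parameter (BPTT)."""
    X = cache["X"]
    B, T = X.shape
    H = params["Wh"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads["Wy"] = cache["h_final"].T @ dlogits
    grads["by"] = dlogits.sum(axis=0)
    dh = dlogits @ params["Wy"].T
    dc = np.zeros((B, H))
    Wx, Wh = params["Wx"], params["Wh"]
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, c_new = cache["steps"][t]
        tanh_c = np.tanh(c_new)
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        grads["Wx"] += x_t.T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dx = dz @ Wx.T
        np.add.at(grads["emb"], X[:, t], dx)
        dh = dz @ Wh.T
        dc = dc * f
    return grads


class _Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedClassifier:
    """A trained model: configuration, vocabulary, weights, loss history."""

    config: ClassifierConfig
    vocab: Optional[Vocabulary]
    parameters: dict
    training_history: list[float] = field(default_factory=list)
    validation_history: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def predict_proba(self, sequence: Sequence[int]) -> float:
        return predict_proba(self, sequence)

    def save(self, directory: str | Path) -> None:
        """Checkpoint: config JSON + vocabulary file + weight arrays."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "training_history": self.training_history,
            "validation_history": self.validation_history,
            "best_epoch": self.best_epoch,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        if self.vocab is not None:
            self.vocab.save(directory / "vocab.txt")
        np.savez(directory / "weights.npz", **self.parameters)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        vocab_path = directory / "vocab.txt"
        vocab = Vocabulary.load(vocab_path) if vocab_path.exists() else None
        with np.load(directory / "weights.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        return cls(
            config=ClassifierConfig.from_dict(meta["config"]),
            vocab=vocab,
            parameters=params,
            training_history=meta["training_history"],
            validation_history=meta["validation_history"],
            best_epoch=meta["best_epoch"],
        )


def _pad_batch(seqs: list[Sequence[int]]) -> np.ndarray:
    T = max(1, max(len(s) for s in seqs))
    X = np.full((len(seqs), T), PAD_INDEX, dtype=np.int64)
    for r, s in enumerate(seqs):
        X[r, : len(s)] = s
    return X


def _dataset_arrays(dataset: Sequence[tuple[Sequence[int], int]]):
    seqs = [list(s) if len(s) else [PAD_INDEX] for s, _ in dataset]
    labels = np.asarray([y for _, y in dataset], dtype=np.int64)
    return seqs, labels


def _mean_loss(params: dict, seqs, labels, batch_size: int) -> float:
    total, count = 0.0, 0
    for start in range(0, len(seqs), batch_size):
        chunk = seqs[start : start + batch_size]
        y = labels[start : start + batch_size]
        probs, _, _ = _forward(params, _pad_batch(chunk))
        p = np.clip(probs[np.arange(len(chunk)), y], 1e-12, None)
        total += float(-np.log(p).sum())
        count += len(chunk)
    return total / count


def train(
    config: ClassifierConfig,
    train_set: Sequence[tuple[Sequence[int], int]],
    valid_set: Sequence[tuple[Sequence[int], int]],
    vocab: Optional[Vocabulary] = None,
    vocab_size: Optional[int] = None,
) -> TrainedClassifier:
    """Train the classifier; deterministic given ``config.seed``.

    ``train_set`` and ``valid_set`` are sequences of ``(encoded tokens,
    label)`` pairs with label 1 = related, 0 = not related.  Epoch order is
    shuffled by a seeded generator; the returned model carries the weights
    of the epoch with the lowest validation loss.

    Raises
    ------
    ValueError
        If either set is empty or the training labels are single-class.
    RuntimeError
        If the loss becomes non-finite (diverged).
    """
    if not len(train_set) or not len(valid_set):
        raise ValueError("train_set and valid_set must both be nonempty")
    train_seqs, train_y = _dataset_arrays(train_set)
    valid_seqs, valid_y = _dataset_arrays(valid_set)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set contains a single class; loss is degenerate")
    if vocab is not None:
        vocab_size = vocab.size
    if vocab_size is None:
        vocab_size = int(max(max(max(s) for s in train_seqs),
                             max(max(s) for s in valid_seqs))) + 1

    rng = np.random.default_rng(config.seed)
    params = _init_params(vocab_size, config, rng)
    opt = _Adam(params, config.learning_rate)
    history: list[float] = []
    valid_history: list[float] = []
    best_loss, best_epoch = np.inf, 0
    best_params = {k: v.copy() for k, v in params.items()}

    n = len(train_seqs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            chunk = [train_seqs[i] for i in idx]
            y = train_y[idx]
            X = _pad_batch(chunk)
            probs, _, cache = _forward(params, X, keep_cache=True)
            p = np.clip(probs[np.arange(len(chunk)), y], 1e-12, None)
            batch_loss = float(-np.log(p).mean())
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            epoch_loss += batch_loss * len(chunk)
            seen += len(chunk)
            grads = _backward(params, probs, y, cache)
            opt.step(params, grads)
        history.append(epoch_loss / seen)
        v_loss = _mean_loss(params, valid_seqs, valid_y, config.batch_size)
        if not np.isfinite(v_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        valid_history.append(v_loss)
        if v_loss < best_loss:
            best_loss, best_epoch = v_loss, epoch
            best_params = {k: v.copy() for k, v in params.items()}

    return TrainedClassifier(
        config=config,
        vocab=vocab,
        parameters=best_params,
        training_history=history,
        validation_history=valid_history,
        best_epoch=best_epoch,
    )


def predict_proba(model: TrainedClassifier, sequence: Sequence[int]) -> float:
    """Probability that one encoded comment is related.

    The empty sequence is scored as a single-PAD input (documented
    behavior, not an error).
    """
    return predict_proba_batch(model, [sequence])[0]


def predict_proba_batch(
    model: TrainedClassifier, sequences: Sequence[Sequence[int]]
) -> np.ndarray:
    """Vectorized :func:`predict_proba` over many sequences."""
    seqs = [list(s) if len(s) else [PAD_INDEX] for s in sequences]
    out = np.empty(len(seqs))
    # Bucket by length so padding stays modest.
    order = sorted(range(len(seqs)), key=lambda i: len(seqs[i]))
    for start in range(0, len(order), 64):
        idx = order[start : start + 64]
        probs, _, _ = _forward(model.parameters, _pad_batch([seqs[i] for i in idx]))
        out[idx] = probs[:, 1]
    return out


def classify(prob: float) -> Label:
    """Apply the 0.5 decision threshold (0.5 itself maps to related)."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {prob}")
    return Label.RELATED if prob >= 0.5 else Label.NOT_RELATED
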