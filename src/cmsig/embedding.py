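"""Supervised subtype embedding.

A fully connected network classifies samples into the four consensus
molecular subtypes from their functional spectra; the activations of its
last hidden layer (width K, default 10) are the "deep features" — a learned
low-dimensional embedding of subtype biology that downstream distillation
converts into a measurable biomarker panel.

The network is implemented directly on NumPy (dense layers, ReLU, softmax
cross-entropy, Adam) so that training is exactly reproducible from a single
seed and hidden activations are first-class outputs rather than internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NOLBL, ModelBundle
from .spectra import FunctionalSpectra

CLASSES = ("CMS1", "CMS2", "CMS3", "CMS4")


@dataclass
class ClassifierConfig:
    """Architecture and optimization settings.

    The last hidden width fixes K, the number of deep features. Class
    weighting is uniform by default; ``class_weight="balanced"`` switches to
    inverse-frequency loss weights for heavily skewed label distributions.
    """

    hidden_layer_widths: tuple = (128, 32, 10)
    activation: str = "relu"
    max_epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    patience: int = 25
    class_weight: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        widths = tuple(int(w) for w in self.hidden_layer_widths)
        if any(w <= 0 for w in widths):
            raise ValueError("hidden layer widths must be positive integers")
        if widths[-1] < 2:
            raise ValueError("last hidden width (number of deep features) must be >= 2")
        if self.activation != "relu":
            raise ValueError("only the rectified-linear activation is supported")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        self.hidden_layer_widths = widths


@dataclass
class SubtypeClassifier:
    """Trained subtype classifier with access to its hidden embedding."""

    weights: list  # per layer, shape (fan_in, fan_out)
    biases: list
    set_names: list[str]  # input feature contract (spectra column names)
    classes: tuple = CLASSES
    input_mean: np.ndarray | None = None
    input_sd: np.ndarray | None = None
    history: dict = field(default_factory=dict)
    config: ClassifierConfig | None = None

    @property
    def n_deep_features(self) -> int:
        return self.weights[-1].shape[0]

    # -- forward passes -----------------------------------------------------

    def _align(self, spectra: FunctionalSpectra) -> np.ndarray:
        frame = spectra.to_frame()
        missing = [s for s in self.set_names if s not in frame.columns]
        if missing:
            raise ValueError(f"spectra lack required gene sets: {missing}")
        X = frame[self.set_names].to_numpy(dtype=float)
        return (X - self.input_mean) / self.input_sd

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = []
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        return acts, logits

    def to_bundle(self) -> ModelBundle:
        params = {
            "weights": list(self.weights),
            "biases": list(self.biases),
            "set_names": list(self.set_names),
            "classes": list(self.classes),
            "input_mean": self.input_mean,
            "input_sd": self.input_sd,
        }
        return ModelBundle("subtype_classifier", params)

    @classmethod
    def from_bundle(cls, bundle: ModelBundle) -> "SubtypeClassifier":
        if bundle.stage != "subtype_classifier":
            raise ValueError(f"bundle holds {bundle.stage!r}, not a subtype classifier")
        p = bundle.params
        return cls(
            weights=list(p["weights"]),
            biases=list(p["biases"]),
            set_names=list(p["set_names"]),
            classes=tuple(p["classes"]),
            input_mean=p["input_mean"],
            input_sd=p["input_sd"],
        )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_classifier(
    spectra: FunctionalSpectra,
    labels,
    config: ClassifierConfig | None = None,
) -> SubtypeClassifier:
    """Train the subtype classifier on labeled samples.

    ``labels`` is a per-sample sequence aligned with ``spectra.sample_ids``;
    samples labeled ``NOLBL`` are excluded from the loss (they can still be
    embedded afterwards). Training is mini-batch Adam on the softmax
    cross-entropy, with an internal stratified validation split, early
    stopping on validation loss, and best-weight restoration. Deterministic
    given ``config.seed``.
    """
    cfg = config or ClassifierConfig()
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(spectra.sample_ids):
        raise ValueError("labels length does not match spectra samples")
    keep = labels != NOLBL
    X_all = spectra.scores[keep]
    y_str = labels[keep]
    present = [c for c in CLASSES if c in set(y_str)]
    if len(present) < 2:
        raise ValueError("need at least 2 distinct subtype labels to train")
    unknown = set(y_str) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown subtype labels: {sorted(unknown)}")
    y = np.array([CLASSES.index(c) for c in y_str])

    mean = X_all.mean(axis=0)
    sd = X_all.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X_all - mean) / sd

    rng = np.random.default_rng(cfg.seed)
    # stratified validation split
    val_idx = []
    for c in np.unique(y):
        idx_c = np.flatnonzero(y == c)
        rng.shuffle(idx_c)
        n_val = max(1, int(round(cfg.validation_fraction * len(idx_c))))
        val_idx.extend(idx_c[:n_val])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    Xtr, ytr = X[~val_mask], y[~val_mask]
    Xva, yva = X[val_mask], y[val_mask]

    n_classes = len(CLASSES)
    if cfg.class_weight == "balanced":
        counts = np.bincount(ytr, minlength=n_classes).astype(float)
        counts[counts == 0] = 1.0
        cw = counts.sum() / (n_classes * counts)
    else:
        cw = np.ones(n_classes)

    widths = [X.shape[1], *cfg.hidden_layer_widths, n_classes]
    weights, biases = [], []
    n_layers = len(widths) - 1
    for layer, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:])):
        scale = np.sqrt(2.0 / fan_in)
        if layer == n_layers - 1:
            scale *= 0.1  # small-logit start: the net begins near the
            # prior-predicting baseline instead of a random classifier
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.full(fan_out, 0.01))
    # output bias = log of the (weighted) training class frequencies, so the
    # initial model is approximately the class-prior predictor
    counts = np.bincount(ytr, minlength=n_classes).astype(float) * cw
    counts = np.maximum(counts, 1e-12)
    biases[-1] = np.log(counts / counts.sum())

    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    def loss_of(Xs, ys):
        model_tmp = SubtypeClassifier(weights, biases, spectra.set_names)
        _, logits = model_tmp._forward(Xs)
        p = _softmax(logits)
        w = cw[ys]
        return float(-(w * np.log(p[np.arange(len(ys)), ys] + 1e-12)).sum() / w.sum())

    best_val = np.inf
    best_state = None
    since_best = 0
    train_losses, val_losses = [], []
    ntr = len(ytr)
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(ntr)
        for start in range(0, ntr, cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            xb, yb = Xtr[batch], ytr[batch]
            # forward
            hs = [xb]
            for W, b in zip(weights[:-1], biases[:-1]):
                hs.append(np.maximum(hs[-1] @ W + b, 0.0))
            logits = hs[-1] @ weights[-1] + biases[-1]
            p = _softmax(logits)
            wvec = cw[yb]
            wsum = wvec.sum()
            delta = p * wvec[:, None]
            delta[np.arange(len(yb)), yb] -= wvec
            delta /= wsum
            # backward
            grads_W, grads_b = [None] * len(weights), [None] * len(biases)
            for layer in range(len(weights) - 1, -1, -1):
                grads_W[layer] = hs[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (hs[layer] > 0)
            t += 1
            for layer in range(len(weights)):
                for grad, param, m, v in (
                    (grads_W[layer], weights[layer], mW, vW),
                    (grads_b[layer], biases[layer], mb, vb),
                ):
                    m[layer] = beta1 * m[layer] + (1 - beta1) * grad
                    v[layer] = beta2 * v[layer] + (1 - beta2) * grad**2
                    mhat = m[layer] / (1 - beta1**t)
                    vhat = v[layer] / (1 - beta2**t)
                    param -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        train_losses.append(loss_of(Xtr, ytr))
        val_losses.append(loss_of(Xva, yva))
        if val_losses[-1] < best_val - 1e-6:
            best_val = val_losses[-1]
            best_state = ([W.copy() for W in weights], [b.copy() for b in biases])
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        weights = best_state[0]
        biases = best_state[1]

    model = SubtypeClassifier(
        weights,
        biases,
        list(spectra.set_names),
        CLASSES,
        mean,
        sd,
        config=cfg,
    )
    _, logits = model._forward(Xva)
    val_acc = float((logits.argmax(axis=1) == yva).mean())
    model.history = {
        "train_loss": train_losses,
        "val_loss": val_losses,
        "val_accuracy": val_acc,
        "n_train": int(ntr),
        "n_val": int(len(yva)),
    }
    return model


def predict_subtype(
    model: SubtypeClassifier, spectra: FunctionalSpectra
) -> tuple[pd.DataFrame, pd.Series]:
    """Class probabilities (rows sum to 1) and argmax labels per sample."""
    X = model._align(spectra)
    _, logits = model._forward(X)
    probs = _softmax(logits)
    frame = pd.DataFrame(probs, index=spectra.sample_ids, columns=list(model.classes))
    labels = frame.idxmax(axis=1)
    return frame, labels


def extract_deep_features(
    model: SubtypeClassifier, spectra: FunctionalSpectra
) -> pd.DataFrame:
    """Last-hidden-layer activations: samples x K deep features."""
    X = model._align(spectra)
    acts, _ = model._forward(X)
    deep = acts[-1]
    cols = [f"DF{k + 1}" for k in range(deep.shape[1])]
    return pd.DataFrame(deep, index=spectra.sample_ids, columns=cols)
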