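"""Length-agnostic convolutional sequence classifier for evidence sequences.

A single fully convolutional network maps an evidence sequence — the
relative-evidence W sequence, or a descending-ordered p-value sequence — to a
per-position probability p-hat of belonging to the alternative set.  Because
every layer is a same-padded convolution and the head is a per-position
sigmoid, the network accepts any sequence length at inference, which is what
makes the train-once / transfer-everywhere usage possible.

Training minimises per-position binary cross-entropy on one labelled
training sequence.  An epoch is a pass over seeded random crops of that
sequence; the crops place the null/alternative boundary at varying offsets
inside the window, which pushes the network toward translation-invariant
features rather than memorising where the boundary sat in training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .nn import AdamState, ConvNet, LayerSpec, bce_with_logits

__all__ = [
    "Preprocessing",
    "ModelConfig",
    "SequenceClassifier",
    "build_model",
    "train",
    "predict",
    "feature_map",
    "save_model",
    "load_model",
]

# keep probabilities strictly inside (0, 1) while losing as little ordering
# information as floating point allows (hard clips create AUC-costing ties)
_P_LO = np.nextafter(0.0, 1.0)
_P_HI = np.nextafter(1.0, 0.0)

#: Default layer stack: dilated convolutions widen the receptive field to a
#: few hundred positions without any length-collapsing pooling; the last two
#: layers aggregate features into per-position logits and smooth them with a
#: fixed (non-trainable) moving average, which keeps the decision profile
#: from flickering across the null/alternative transition.
DEFAULT_LAYERS = (
    LayerSpec(64, 3, 1, "relu"),
    LayerSpec(64, 3, 2, "relu"),
    LayerSpec(48, 3, 4, "relu"),
    LayerSpec(48, 3, 8, "relu"),
    LayerSpec(32, 3, 16, "relu"),
    LayerSpec(32, 3, 32, "relu"),
    LayerSpec(24, 3, 64, "relu"),
    LayerSpec(1, 5, 16, "linear"),
    LayerSpec(1, 101, 1, "linear", trainable=False, init="uniform"),
)


@dataclass(frozen=True)
class Preprocessing:
    """Deterministic per-sequence transform applied before the network.

    ``clipped`` caps the sequence at its own ``clip_quantile`` quantile (the
    W sequence has one enormous spike at the separation point), rescales so
    the clipped sequence has unit mean (the absolute scale of W varies with
    sample size and carries no evidence), and log-compresses with log1p.
    ``raw`` feeds values unchanged — the right choice for ordered p-values,
    which already live in [0, 1].
    """

    kind: str = "clipped"
    clip_quantile: float = 0.9999

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "clipped"):
            raise ValueError(f"unknown preprocessing kind {self.kind!r}")
        if not 0.5 < self.clip_quantile <= 1.0:
            raise ValueError("clip_quantile must be in (0.5, 1]")

    def apply(self, seq: np.ndarray) -> np.ndarray:
        seq = np.asarray(seq, float)
        if not np.isfinite(seq).all():
            raise ValueError("non-finite values in input sequence")
        if self.kind == "raw":
            return seq
        capped = np.minimum(seq, np.quantile(seq, self.clip_quantile))
        mean = capped.mean()
        if mean <= 0:
            return capped
        return np.log1p(capped / mean)


@dataclass(frozen=True)
class ModelConfig:
    input_kind: str = "w"
    layers: tuple[LayerSpec, ...] = DEFAULT_LAYERS
    epochs: int = 30
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    preprocessing: Preprocessing = field(default_factory=Preprocessing)
    crop_length: int = 1024
    crops_per_epoch: int = 48
    batch_size: int = 4

    def __post_init__(self) -> None:
        if self.input_kind not in ("w", "ordered_pvalues"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if not layers:
            raise ValueError("need at least one layer")
        if layers[-1].filters != 1 or layers[-1].activation != "linear":
            raise ValueError("final layer must emit one linear value per position "
                             "(the sigmoid lives in the head)")
        if any(l.kernel_size < 2 for l in layers[:-1]):
            raise ValueError("convolutional layers need kernel_size >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def for_pvalues(cls, **kw) -> "ModelConfig":
        kw.setdefault("input_kind", "ordered_pvalues")
        kw.setdefault("preprocessing", Preprocessing(kind="raw"))
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layers"] = [asdict(l) for l in self.layers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["layers"] = tuple(LayerSpec(**l) for l in d["layers"])
        d["preprocessing"] = Preprocessing(**d["preprocessing"])
        return cls(**d)


class SequenceClassifier:
    """Architecture + (once trained) weights + training history."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.net = ConvNet(list(config.layers), in_channels=1, seed=config.seed)
        self.trained = False
        self.training_history: pd.DataFrame | None = None

    # -- identity -----------------------------------------------------------
    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256(json.dumps(self.config.to_dict(), sort_keys=True).encode())
        for name, arr in sorted(self.net.get_params().items()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    # -- training -----------------------------------------------------------
    def fit_sequence(self, sequence: np.ndarray, labels: np.ndarray,
                     epochs: int | None = None, seed: int | None = None) -> "SequenceClassifier":
        cfg = self.config
        sequence = np.asarray(sequence, float)
        labels = np.asarray(labels, float)
        if sequence.shape != labels.shape:
            raise ValueError("sequence and labels must have the same length")
        if not np.isin(labels, (0.0, 1.0)).all():
            raise ValueError("labels must be binary")
        x = cfg.preprocessing.apply(sequence)
        m = len(x)
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        opt = AdamState(self.net, lr=cfg.learning_rate)
        crop = min(cfg.crop_length, m)
        history = []
        for ep in range(epochs):
            starts = rng.integers(0, m - crop + 1, cfg.crops_per_epoch)
            for lo in range(0, cfg.crops_per_epoch, cfg.batch_size):
                sel = starts[lo:lo + cfg.batch_size]
                xb = np.stack([x[s:s + crop] for s in sel])[:, None, :]
                yb = np.stack([labels[s:s + crop] for s in sel])
                logits, caches = self.net.forward(xb, keep_cache=True)
                loss, dz = bce_with_logits(logits[:, 0, :], yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf training loss at epoch {ep}; check input scaling")
                gw, gb = self.net.backward(caches, dz[:, None, :])
                opt.step(self.net, gw, gb)
            p = self._proba_preprocessed(x)
            with np.errstate(divide="ignore"):
                full_loss = -np.mean(np.where(labels == 1, np.log(p), np.log1p(-p)))
            acc = float(np.mean((p > 0.5) == labels))
            history.append({"epoch": ep + 1, "loss": float(full_loss), "accuracy": acc})
        self.training_history = pd.DataFrame(history)
        self.trained = True
        return self

    # -- inference ----------------------------------------------------------
    def _proba_preprocessed(self, x: np.ndarray) -> np.ndarray:
        p = self.net.predict_proba(x)
        return np.clip(p, _P_LO, _P_HI)

    def predict_proba(self, sequence: np.ndarray) -> np.ndarray:
        """Per-position P(alternative) for a sequence of any length."""
        if not self.trained:
            raise RuntimeError("classifier is untrained; call fit_sequence first")
        sequence = np.asarray(sequence, float)
        return self._proba_preprocessed(self.config.preprocessing.apply(sequence))

    def feature_map(self, sequence: np.ndarray) -> np.ndarray:
        """First-layer activations, shape (filters, positions)."""
        sequence = self.config.preprocessing.apply(np.asarray(sequence, float))
        first = ConvNet(list(self.config.layers[:1]), in_channels=1, seed=0)
        first.weights[0] = self.net.weights[0]
        first.biases[0] = self.net.biases[0]
        z = first.predict_logits(sequence[None, None, :])[0]
        return np.maximum(z, 0.0) if self.config.layers[0].activation == "relu" else z


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig | None = None) -> SequenceClassifier:
    return SequenceClassifier(config or ModelConfig())


def train(model: SequenceClassifier, w: np.ndarray, labels: np.ndarray,
          epochs: int | None = None, seed: int | None = None) -> SequenceClassifier:
    return model.fit_sequence(w, labels, epochs=epochs, seed=seed)


def predict(model: SequenceClassifier, sequence: np.ndarray) -> np.ndarray:
    return model.predict_proba(sequence)


def feature_map(model: SequenceClassifier, sequence: np.ndarray) -> np.ndarray:
    return model.feature_map(sequence)


# ---------------------------------------------------------------------------
# persistence: directory with config.yaml + weights.npz + history.tsv
# ---------------------------------------------------------------------------

def save_model(model: SequenceClassifier, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump({"config": model.config.to_dict(),
                        "trained": model.trained,
                        "fingerprint": model.fingerprint}, fh)
    np.savez(directory / "weights.npz", **model.net.get_params())
    if model.training_history is not None:
        model.training_history.to_csv(directory / "history.tsv", sep="\t",
                                      index=False, float_format="%.17g")


def load_model(directory) -> SequenceClassifier:
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        blob = yaml.safe_load(fh)
    model = SequenceClassifier(ModelConfig.from_dict(blob["config"]))
    with np.load(directory / "weights.npz") as npz:
        model.net.set_params({k: npz[k] for k in npz.files})
    model.trained = bool(blob.get("trained", False))
    hist = directory / "history.tsv"
    if hist.exists():
        model.training_history = pd.read_csv(hist, sep="\t",
                                             float_precision="round_trip")
    if model.trained and blob.get("fingerprint") not in (None, model.fingerprint):
        raise ValueError("model artifact fingerprint mismatch")
    return model
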