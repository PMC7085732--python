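"""The fall-detection convolutional network: architecture, training, inference.

The classifier maps one peak-centered observation window (a flat vector of
acceleration features) to an ADL/fall decision.  Its fixed architecture is

    4 × [ conv(1×5, zero-pad 2, stride 1) → batch-norm → ReLU
          → max-pool(1×5, stride 5, blocks 1–3 only) ]
    → dropout → fully-connected(→ 2) → softmax → argmax

with 16/32/64/128 filters across the four blocks.  Training is stochastic
gradient descent with momentum on the cross-entropy loss, mini-batches of 64,
at most 20 epochs, validated once per epoch and stopped early when the
validation loss fails to improve on its running minimum for 3 consecutive
epochs ("validation patience"); the returned weights are those of the
best-validation epoch.

Usage follows the model/results convention: bind data to a
:class:`FallDetectorCNN`, call :meth:`~FallDetectorCNN.fit`, and work with the
returned :class:`FallDetectorResults` (predict / evaluate / summary / history).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .preprocess import ObservationWindow
from .trace_io import ADL, FALL

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "FallDetectorCNN",
    "FallDetectorResults",
    "build_network",
    "train",
    "predict",
    "MIN_INPUT_WIDTH",
]

#: Classes in logit order: index 0 = ADL (negative), index 1 = FALL (positive).
CLASSES = (ADL, FALL)

#: Narrowest admissible input (one pooling region).
MIN_INPUT_WIDTH = 5


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters of the four-block 1-D CNN."""

    n_blocks: int = 4
    filters_per_block: tuple[int, ...] = (16, 32, 64, 128)
    kernel_width: int = 5
    conv_zero_pad: int = 2
    conv_stride: int = 1
    pool_width: int = 5
    pool_stride: int = 5
    n_pooled_blocks: int = 3
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.filters_per_block) != self.n_blocks:
            raise ValueError(
                f"need {self.n_blocks} filter counts, got {self.filters_per_block}"
            )
        if any(b >= a for a, b in zip(self.filters_per_block[1:], self.filters_per_block)):
            raise ValueError(
                f"filter counts must strictly increase across blocks, "
                f"got {self.filters_per_block}"
            )
        if self.n_classes != 2:
            raise ValueError("the detector is a binary classifier (ADL vs FALL)")
        if self.conv_stride != 1:
            raise ValueError("convolutions are non-strided (stride 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (SGD with momentum, early stopping)."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    minibatch_size: int = 64
    max_epochs: int = 20
    validation_patience: int = 3
    l2_coefficient: float = 1e-4
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.validation_patience < 1:
            raise ValueError("validation_patience must be at least 1")
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be at least 1")


class _Network:
    """Layer stack plus state (de)serialization."""

    def __init__(self, input_width: int, config: NetworkConfig,
                 dropout_rate: float, rng: np.random.Generator):
        if input_width < MIN_INPUT_WIDTH:
            raise ValueError(
                f"input width {input_width} is too narrow for the four-block "
                f"architecture; minimum width is {MIN_INPUT_WIDTH}"
            )
        self.input_width = int(input_width)
        self.config = config
        self.layers: list[nn.Layer] = []
        w = self.input_width
        c_in = 1
        for block, c_out in enumerate(config.filters_per_block):
            conv = nn.Conv1d(c_in, c_out, kernel=config.kernel_width,
                             pad=config.conv_zero_pad, rng=rng)
            self.layers += [conv, nn.BatchNorm1d(c_out), nn.ReLU()]
            w = conv.out_width(w)
            if block < config.n_pooled_blocks:
                pool = nn.MaxPool1d(config.pool_width)
                self.layers.append(pool)
                w = pool.out_width(w)
            c_in = c_out
        self.dropout = nn.Dropout(dropout_rate)
        self.layers.append(self.dropout)
        self.layers.append(nn.Flatten())
        self.final_width = w
        self.fc = nn.Linear(w * c_in, config.n_classes, rng=rng, init="zero")
        self.layers.append(self.fc)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of flat windows, shape (B, width)."""
        h = x[:, None, :]
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self) -> list[dict]:
        return [p for layer in self.layers for p in layer.parameters()]

    def feature_widths(self, x: np.ndarray | None = None) -> list[int]:
        """Feature-map widths after each of the four blocks, measured by a
        forward pass (not computed from a formula)."""
        if x is None:
            x = np.zeros((1, self.input_width))
        h = x[:1, None, :]
        widths = []
        for layer in self.layers:
            if isinstance(layer, nn.Flatten):
                widths.append(h.shape[2])  # unpooled final block
                break
            h = layer.forward(h, train=False)
            if isinstance(layer, nn.MaxPool1d):
                widths.append(h.shape[2])
        return widths

    def finalize_batchnorm(self, x: np.ndarray) -> None:
        """Replace every batch-norm layer's moving statistics by the exact
        population statistics of its input over ``x`` (the training set).

        With few optimizer steps per epoch the moving averages lag the true
        activation statistics badly, which would make inference-mode
        predictions — and hence validation losses and early stopping —
        meaningless.  Population statistics are recomputed layer by layer,
        each batch-norm being finalized before the signal propagates further.
        """
        h = x[:, None, :]
        for layer in self.layers:
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[...] = h.mean(axis=(0, 2))
                layer.running_var[...] = h.var(axis=(0, 2))
            h = layer.forward(h, train=False)

    def state(self) -> list[dict[str, np.ndarray]]:
        out = []
        for layer in self.layers:
            d = {}
            for name in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, name):
                    d[name] = np.array(getattr(layer, name), copy=True)
            out.append(d)
        return out

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, d in zip(self.layers, state):
            for name, arr in d.items():
                getattr(layer, name)[...] = arr


def _as_matrix(
    windows: Sequence[ObservationWindow] | np.ndarray,
    labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Stack windows into (B, width); encode labels as ints (ADL 0, FALL 1)."""
    if isinstance(windows, np.ndarray):
        x = np.atleast_2d(np.asarray(windows, dtype=float))
        y_src = labels
    else:
        windows = list(windows)
        if not windows:
            raise ValueError("empty window collection")
        widths = {w.width for w in windows}
        if len(widths) > 1:
            raise ValueError(f"windows have mixed widths {sorted(widths)}")
        x = np.stack([w.values for w in windows])
        y_src = labels if labels is not None else [w.label for w in windows]
    if y_src is None:
        return x, None
    y = np.array([CLASSES.index(lbl) for lbl in y_src], dtype=int)
    if len(y) != x.shape[0]:
        raise ValueError("label count does not match window count")
    return x, y


class FallDetectorCNN:
    """Model object binding labeled observation windows to the detector CNN.

    Parameters
    ----------
    train_windows, val_windows : sequence of ObservationWindow or 2-D array
        Training and validation inputs; all widths must agree.
    train_labels, val_labels : sequence of str, optional
        ``"ADL"``/``"FALL"`` labels; taken from the windows when omitted.
    config : NetworkConfig
    train_config : TrainConfig
    """

    def __init__(self, train_windows, val_windows, *, train_labels=None,
                 val_labels=None, config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.x_train, self.y_train = _as_matrix(train_windows, train_labels)
        self.x_val, self.y_val = _as_matrix(val_windows, val_labels)
        if self.y_train is None or self.y_val is None:
            raise ValueError("training and validation windows must be labeled")
        if self.x_train.shape[1] != self.x_val.shape[1]:
            raise ValueError(
                f"train width {self.x_train.shape[1]} != val width {self.x_val.shape[1]}"
            )
        for name, y in (("training", self.y_train), ("validation", self.y_val)):
            if len(np.unique(y)) < 2:
                raise ValueError(
                    f"{name} set contains a single class; both ADL and FALL "
                    f"are required to train the binary detector"
                )
        self.config = config or NetworkConfig()
        self.train_config = train_config or TrainConfig()
        self.input_width = int(self.x_train.shape[1])

    @classmethod
    def from_traces(cls, traces, half_width_s: float, variant: str,
                    split, **kwargs) -> "FallDetectorCNN":
        """Build the model from traces and a train/val split assignment."""
        from .preprocess import extract_window

        wins = {i: extract_window(t, half_width_s, variant) for i, t in enumerate(traces)}
        return cls(
            [wins[i] for i in split.train_ids],
            [wins[i] for i in split.val_ids],
            **kwargs,
        )

    def fit(self, seed: int | None = None) -> "FallDetectorResults":
        """Train the network; returns the fitted results object.

        Identical seeds, data and configuration give identical histories.
        """
        tc = self.train_config
        seed = tc.seed if seed is None else seed
        master = np.random.SeedSequence(seed)
        init_rng, shuffle_rng, drop_rng = (
            np.random.default_rng(s) for s in master.spawn(3)
        )
        net = _Network(self.input_width, self.config, tc.dropout_rate, init_rng)
        net.dropout.rng = drop_rng
        opt = nn.SGDMomentum(net.parameters(), lr=tc.learning_rate,
                             momentum=tc.momentum, l2=tc.l2_coefficient)

        history: list[dict] = []
        best_val = np.inf
        best_state = net.state()
        best_epoch = 0
        strikes = 0
        n = self.x_train.shape[0]
        for epoch in range(1, tc.max_epochs + 1):
            order = shuffle_rng.permutation(n)
            batch_losses, batch_hits = [], 0
            for start in range(0, n, tc.minibatch_size):
                idx = order[start:start + tc.minibatch_size]
                xb, yb = self.x_train[idx], self.y_train[idx]
                logits = net.forward(xb, train=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, yb)
                net.backward(dlogits)
                opt.step()
                batch_losses.append(loss * len(idx))
                batch_hits += int(np.sum(np.argmax(logits, axis=1) == yb))
            net.finalize_batchnorm(self.x_train)
            val_logits = net.forward(self.x_val, train=False)
            val_loss, _ = nn.softmax_cross_entropy(val_logits, self.y_val)
            val_acc = float(np.mean(np.argmax(val_logits, axis=1) == self.y_val))
            history.append({
                "epoch": epoch,
                "train_loss": sum(batch_losses) / n,
                "train_accuracy": batch_hits / n,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            })
            if val_loss < best_val:
                best_val, best_epoch, strikes = val_loss, epoch, 0
                best_state = net.state()
            else:
                strikes += 1
                if strikes >= tc.validation_patience:
                    break
        net.load_state(best_state)
        return FallDetectorResults(
            model=self, network=net,
            history=pd.DataFrame(history), best_epoch=best_epoch, seed=seed,
        )


class FallDetectorResults:
    """Fitted detector: best-epoch weights, training history, inference.

    Attributes
    ----------
    history : DataFrame
        Per-epoch train/validation loss and accuracy.
    best_epoch : int
        Epoch (1-based) whose weights are carried (minimum validation loss).
    """

    def __init__(self, model: FallDetectorCNN | None, network: _Network,
                 history: pd.DataFrame, best_epoch: int, seed: int):
        self.model = model
        self._network = network
        self.history = history
        self.best_epoch = int(best_epoch)
        self.seed = int(seed)

    @property
    def input_width(self) -> int:
        return self._network.input_width

    @property
    def n_epochs_run(self) -> int:
        return int(len(self.history))

    def predict_proba(self, windows) -> np.ndarray:
        """Class probabilities ``(p_ADL, p_FALL)`` per window; rows sum to 1."""
        x, _ = _as_matrix(windows)
        if x.shape[1] != self.input_width:
            raise ValueError(
                f"window width {x.shape[1]} does not match the model's "
                f"input width {self.input_width}"
            )
        return nn.softmax(self._network.forward(x, train=False))

    def predict(self, windows) -> list[str]:
        """Predicted labels; an exact probability tie resolves to FALL
        (the costlier error in a detector is a missed fall)."""
        proba = self.predict_proba(windows)
        return [FALL if p[1] >= p[0] else ADL for p in proba]

    def evaluate(self, windows, labels=None):
        """Confusion counts and Se/Sp/Acc on a labeled test set."""
        from .evaluate import evaluate_results

        return evaluate_results(self, windows, labels)

    def summary(self) -> str:
        """Plain-text fit report in the spirit of statsmodels results."""
        tc = self.model.train_config if self.model else TrainConfig()
        last = self.history.iloc[-1]
        best = self.history[self.history["epoch"] == self.best_epoch].iloc[0]
        lines = [
            "Fall detector CNN — fit summary",
            "=" * 46,
            f"input width:          {self.input_width}",
            f"filters per block:    {self._network.config.filters_per_block}",
            f"epochs run:           {self.n_epochs_run} (max {tc.max_epochs})",
            f"best epoch:           {self.best_epoch}",
            f"best val loss:        {best['val_loss']:.4f}",
            f"best val accuracy:    {best['val_accuracy']:.4f}",
            f"final train loss:     {last['train_loss']:.4f}",
            f"seed:                 {self.seed}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training/validation loss and accuracy curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.plot(h["epoch"], h["train_loss"], label="train loss")
        ax.plot(h["epoch"], h["val_loss"], label="val loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy loss")
        ax2 = ax.twinx()
        ax2.plot(h["epoch"], h["val_accuracy"], "--", color="gray",
                 label="val accuracy")
        ax2.set_ylabel("validation accuracy")
        ax.axvline(self.best_epoch, color="k", lw=0.5)
        ax.legend(loc="best")
        return ax

    def save(self, path: str | Path) -> Path:
        """Write a self-describing checkpoint (weights + configs + width)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, layer_state in enumerate(self._network.state()):
            for name, arr in layer_state.items():
                arrays[f"layer{i:02d}.{name}"] = arr
        meta = {
            "input_width": self.input_width,
            "best_epoch": self.best_epoch,
            "seed": self.seed,
            "network_config": asdict(self._network.config),
            "history": self.history.to_dict(orient="list"),
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FallDetectorResults":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["network_config"]
            cfg_dict["filters_per_block"] = tuple(cfg_dict["filters_per_block"])
            config = NetworkConfig(**cfg_dict)
            net = _Network(meta["input_width"], config, dropout_rate=0.0,
                           rng=np.random.default_rng(0))
            state = net.state()
            for i, layer_state in enumerate(state):
                for name in layer_state:
                    layer_state[name] = data[f"layer{i:02d}.{name}"]
            net.load_state(state)
        return cls(model=None, network=net,
                   history=pd.DataFrame(meta["history"]),
                   best_epoch=meta["best_epoch"], seed=meta["seed"])


# ---------------------------------------------------------------------------
# Functional surface over the model/results objects.

def build_network(input_width: int, config: NetworkConfig | None = None,
                  seed: int = 0, dropout_rate: float = 0.5) -> _Network:
    """Construct an untrained network for a given input width."""
    return _Network(input_width, config or NetworkConfig(), dropout_rate,
                    np.random.default_rng(seed))


def train(train_windows, val_windows, train_config: TrainConfig | None = None,
          config: NetworkConfig | None = None,
          seed: int | None = None) -> FallDetectorResults:
    """Fit the detector on labeled train/validation windows."""
    m = FallDetectorCNN(train_windows, val_windows, config=config,
                        train_config=train_config)
    return m.fit(seed=seed)


def predict(results: FallDetectorResults, windows) -> tuple[list[str], np.ndarray]:
    """Labels and class probabilities for a batch of windows."""
    proba = results.predict_proba(windows)
    labels = [FALL if p[1] >= p[0] else ADL for p in proba]
    return labels, proba
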