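"""Residual convolutional classifier for recurrence-plot images.

The architecture follows the staged layout: a 7x7/64 stride-2 stem, then
eight residual pairs of 3x3 convolutions with widths
64, 64, 128, 128, 256, 256, 512, 128 — the first two followed by 2x2 max
pooling — and a head of global average pooling plus a 3-way linear layer
with softmax. "D = 2" entries are read as stride 2. Shortcuts are
identity where shapes agree and 1x1 strided projections where the width
changes; by default a width change also halves resolution (standard
residual-network practice), switchable off via ``downsample_on_change``.

Training is plain Adam on softmax cross-entropy, deterministic given the
seed (single-threaded BLAS assumed for bit-stability; losses agree to
well under 1e-4 regardless).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .recording import STATES

#: Table-style width schedule: one residual pair per entry
DEFAULT_WIDTHS = (64, 64, 128, 128, 256, 256, 512, 128)
#: a monotone variant without the final contraction to 128
MONOTONE_WIDTHS = (64, 64, 128, 128, 256, 256, 512, 512)


@dataclass(frozen=True)
class RPNetConfig:
    """Architecture + seed; identical configs build identical networks."""

    input_side: int = 64
    stem_channels: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    block_widths: tuple[int, ...] = DEFAULT_WIDTHS
    pool_after: tuple[int, ...] = (0, 1)  # residual pairs followed by maxpool
    n_classes: int = 3
    downsample_on_change: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if any(w <= 0 for w in self.block_widths):
            raise ValueError("channel counts must be positive")
        if self.n_classes != 3:
            raise ValueError("this classifier is 3-class (calm/transitional/morbidity)")
        if self.input_side < 32:
            raise ValueError("input side must be >= 32")


class RPNet:
    """The assembled network; use :func:`build_rpnet` to construct."""

    def __init__(self, config: RPNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        side = config.input_side
        self.stem = [
            nn.Conv2d(1, config.stem_channels, config.stem_kernel,
                      stride=config.stem_stride, rng=rng),
            nn.BatchNorm2d(config.stem_channels),
            nn.ReLU(),
        ]
        side = -(-side // config.stem_stride)
        self.blocks: list = []
        c_in = config.stem_channels
        for i, width in enumerate(config.block_widths):
            stride = 2 if (config.downsample_on_change and width != c_in) else 1
            if side < 1:
                raise ValueError(
                    f"input side {config.input_side} collapses before "
                    f"residual pair {i}; reduce downsampling or enlarge input"
                )
            self.blocks.append(nn.ResidualBlock(c_in, width, stride=stride,
                                                rng=rng))
            side = -(-side // stride)
            if i in config.pool_after:
                self.blocks.append(nn.MaxPool2x2())
                side = -(-side // 2)
            c_in = width
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(c_in, config.n_classes, rng=rng)
        self._layers = self.stem + self.blocks + [self.gap, self.fc]

    # -- plumbing ---------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        side = self.config.input_side
        if x.shape[2] != side or x.shape[3] != side:
            raise ValueError(
                f"image side {x.shape[2]}x{x.shape[3]} does not match the "
                f"model's {side}x{side}"
            )
        return x

    def forward(self, images: np.ndarray, train: bool = True) -> np.ndarray:
        x = self._check_input(images)
        for layer in self._layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self._layers):
            d = layer.backward(d)

    def predict_proba(self, images: np.ndarray, batch: int = 32) -> np.ndarray:
        """Class probabilities in evaluation mode (running BN statistics)."""
        x = self._check_input(images)
        chunks = [
            nn.softmax(self.forward(x[i:i + batch], train=False))
            for i in range(0, x.shape[0], batch)
        ]
        return np.concatenate(chunks, axis=0)

    # -- checkpointing ----------------------------------------------------
    def _state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for layer in self._layers:
            bns = [layer] if isinstance(layer, nn.BatchNorm2d) else []
            if isinstance(layer, nn.ResidualBlock):
                bns = [layer.bn1, layer.bn2]
                if layer.proj_bn is not None:
                    bns.append(layer.proj_bn)
            for bn in bns:
                arrays.extend([bn.running_mean, bn.running_var])
        return arrays

    def save(self, path: str | os.PathLike) -> None:
        """Write weights (npz) plus a JSON config sidecar."""
        arrays = self._state_arrays()
        np.savez(path, **{f"a{i}": a for i, a in enumerate(arrays)})
        cfg = self.config.__dict__.copy()
        cfg["block_widths"] = list(cfg["block_widths"])
        cfg["pool_after"] = list(cfg["pool_after"])
        sidecar = str(path) + ".json" if not str(path).endswith(".npz") \
            else str(path)[:-4] + ".json"
        with open(sidecar, "w") as fh:
            json.dump(cfg, fh, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RPNet":
        p = str(path)
        if not p.endswith(".npz"):
            p = p + ".npz"
        sidecar = p[:-4] + ".json"
        with open(sidecar) as fh:
            cfg = json.load(fh)
        cfg["block_widths"] = tuple(cfg["block_widths"])
        cfg["pool_after"] = tuple(cfg["pool_after"])
        model = cls(RPNetConfig(**cfg))
        data = np.load(p)
        arrays = model._state_arrays()
        if len(arrays) != len(data.files):
            raise ValueError("checkpoint does not match the configured model")
        for i, target in enumerate(arrays):
            target[...] = data[f"a{i}"]
        return model


def build_rpnet(config: RPNetConfig | None = None) -> RPNet:
    """Construct the classifier; deterministic for identical configs."""
    return RPNet(config or RPNetConfig())


@dataclass
class TrainReport:
    """Per-epoch learning curves and the final hold-out performance."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    seed: int = 0
    checkpoint: str | None = None

    @property
    def final_val_accuracy(self) -> float:
        return self.val_accuracy[-1] if self.val_accuracy else float("nan")


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * idx.size)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def _evaluate(model: RPNet, images, labels):
    probs = model.predict_proba(images)
    pred = probs.argmax(axis=1)
    loss = float(-np.log(probs[np.arange(len(labels)), labels] + 1e-12).mean())
    return loss, float((pred == labels).mean())


def train_rpnet(
    model: RPNet,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int = 30,
    batch: int = 16,
    lr: float = 1e-3,
    seed: int = 0,
    val_fraction: float = 0.3,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> TrainReport:
    """Train on labeled images (labels are class indices 0/1/2 in the
    calm/transitional/morbidity order, or state-name strings).

    If no explicit validation set is given, a stratified ``val_fraction``
    split is held out using ``seed``.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    labels = _as_class_indices(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training needs at least two classes present")
    images = np.asarray(images, dtype=nn.DTYPE)
    rng = np.random.default_rng(seed)
    if val_images is None:
        tr, va = _stratified_split(labels, val_fraction, rng)
        val_images, val_labels = images[va], labels[va]
        images, labels = images[tr], labels[tr]
    else:
        val_labels = _as_class_indices(val_labels)

    opt = nn.Adam(model.params(), lr=lr)
    report = TrainReport(seed=seed)
    n = images.shape[0]
    for _epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for start in range(0, n, batch):
            sel = order[start:start + batch]
            xb, yb = images[sel], labels[sel]
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * sel.size
            correct += int((logits.argmax(axis=1) == yb).sum())
        report.train_loss.append(epoch_loss / n)
        report.train_accuracy.append(correct / n)
        vl, va = _evaluate(model, val_images, val_labels)
        report.val_loss.append(vl)
        report.val_accuracy.append(va)
    return report


def _as_class_indices(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        return np.array([STATES.index(s) for s in labels])
    return labels.astype(int)


def predict_re(model: RPNet, image: np.ndarray) -> np.ndarray:
    """RE: 3-class probability vector for one recurrence image (or the
    per-channel average when given a stack of images of one recording)."""
    image = np.asarray(image, dtype=nn.DTYPE)
    if image.ndim == 2:
        return model.predict_proba(image[None])[0]
    probs = model.predict_proba(image)
    avg = probs.mean(axis=0)
    return avg / avg.sum()
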