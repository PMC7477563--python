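"""Three-class spatiotemporal window classifier.

The pipeline is backend-agnostic: any object exposing
``predict_proba(window) -> length-3 probability vector`` can drive detection
(the :class:`WindowClassifier` protocol).  This module additionally provides a
desk-scale *reference* network trained here on the CPU -- three 3-D
convolution blocks (conv -> ReLU -> average pooling) behind an aggressive
spatial-pooling stem, an optional inception-style block, global average
pooling and a linear 3-way softmax head.  It exists so the whole framework is
exercisable end to end on synthetic data; it makes no claim of matching a
large pre-trained video network's capacity.

Classes follow the augmentation semantics: 0 = before, 1 = during,
2 = after the swallowing reflex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from . import nn

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "WindowClassifier",
    "build_inception_block",
    "build_reference_network",
    "train",
    "predict_proba",
    "save_model",
    "load_model",
    "DEFAULT_INCEPTION_SPEC",
]

#: Four parallel branches, two distinct filter sizes (1x1x1 and 3x3x3):
#: two pointwise branches and two reduce-then-3x3x3 branches.
DEFAULT_INCEPTION_SPEC: tuple[tuple[tuple[int, int], ...], ...] = (
    ((1, 8),),
    ((1, 4), (3, 8)),
    ((1, 4), (3, 8)),
    ((1, 8),),
)


@dataclass
class ClassifierConfig:
    """Hyperparameters of the reference backend.

    ``input_frames`` is the window length L (default 20 frames at 15 fps);
    ``input_size`` the per-frame geometry.  ``stem_pool`` spatially average-
    pools the input down before any convolution (``0`` = choose automatically
    so convolutions run at roughly 16x16), which is what makes CPU training
    practical.  All randomness (init, batch order) flows from ``seed``.
    """

    n_classes: int = 3
    input_frames: int = 20
    input_size: tuple[int, int] = (64, 64)
    channels: int = 3
    learning_rate: float = 1e-3
    epochs: int = 12
    batch_size: int = 16
    seed: int = 0
    backend: str = "reference"
    conv_channels: tuple[int, int, int] = (8, 16, 32)
    stem_pool: int = 0
    use_inception: bool = False

    def __post_init__(self) -> None:
        if self.n_classes != 3:
            raise ValueError("this classifier is a fixed three-class model")
        if self.input_frames < 1:
            raise ValueError("input_frames must be >= 1")
        if self.backend not in ("reference", "external"):
            raise ValueError(f"unknown backend {self.backend!r}")
        self.input_size = tuple(self.input_size)  # type: ignore[assignment]
        self.conv_channels = tuple(self.conv_channels)  # type: ignore[assignment]

    @property
    def effective_stem_pool(self) -> int:
        if self.stem_pool > 0:
            return self.stem_pool
        # convolutions run at roughly 16x16; scene features (bolus, hyoid
        # marker) are several pixels wide at 64x64 and survive this pooling
        return max(1, min(self.input_size) // 16)


@runtime_checkable
class WindowClassifier(Protocol):
    """Contract every detection backend must honor."""

    def predict_proba(self, window: np.ndarray) -> np.ndarray: ...


def build_inception_block(
    in_channels: int,
    branch_spec: Sequence[Sequence[tuple[int, int]]] = DEFAULT_INCEPTION_SPEC,
    rng: np.random.Generator | None = None,
) -> nn.ConcatBranches:
    """Inception-style block: parallel 3-D convolutions, two filter sizes.

    ``branch_spec`` lists branches; each branch is a sequence of
    ``(kernel_size, out_channels)`` convolutions applied back to back with a
    ReLU after each.  The default has four branches using only 1x1x1
    (pointwise) and 3x3x3 filters.  Outputs are concatenated on the channel
    axis, so the block's output channel count is the sum of the branches'
    final channels; unit stride and same-padding preserve T, H, W.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not branch_spec:
        raise ValueError("branch_spec must list at least one branch")
    branches = []
    for branch in branch_spec:
        if not branch:
            raise ValueError("each branch needs at least one convolution")
        layers: list[nn.Layer] = []
        c_in = in_channels
        for kernel, c_out in branch:
            if c_out < 1:
                raise ValueError(f"branch channel counts must be positive: {branch}")
            layers.append(nn.Conv3D(c_in, c_out, kernel, rng))
            layers.append(nn.ReLU())
            c_in = c_out
        branches.append(nn.Sequential(layers))
    return nn.ConcatBranches(branches)


def build_reference_network(
    config: ClassifierConfig, rng: np.random.Generator
) -> nn.Sequential:
    """Assemble the desk-scale reference network for the given config."""
    c1, c2, c3 = config.conv_channels
    sp = config.effective_stem_pool
    layers: list[nn.Layer] = []
    if sp > 1:
        layers.append(nn.AvgPool3D((1, sp, sp)))
    layers += [
        nn.Conv3D(config.channels, c1, 3, rng),
        nn.ReLU(),
        nn.AvgPool3D((1, 2, 2)),  # keep full temporal resolution early
        nn.Conv3D(c1, c2, 3, rng),
        nn.ReLU(),
        nn.AvgPool3D((2, 2, 2)),
    ]
    feat = c2
    if config.use_inception:
        block = build_inception_block(c2, rng=rng)
        layers.append(block)
        feat = sum(branch[-1][1] for branch in DEFAULT_INCEPTION_SPEC)
    layers += [
        nn.Conv3D(feat, c3, 3, rng),
        nn.ReLU(),
        nn.GlobalAvgPool(),
        nn.Linear(c3, config.n_classes, rng),
    ]
    return nn.Sequential(layers)


def _to_input(window: np.ndarray, config: ClassifierConfig) -> np.ndarray:
    """Validate an (L, H, W, 3) window and transpose to (3, L, H, W)."""
    window = np.asarray(window, dtype=np.float32)
    expected = (config.input_frames, *config.input_size, config.channels)
    if window.shape != expected:
        raise ValueError(
            f"window shape {window.shape} does not match the configured "
            f"(L, H, W, C) = {expected}"
        )
    return np.transpose(window, (3, 0, 1, 2))


@dataclass
class TrainedModel:
    """Reference-backend model: network parameters plus training history.

    ``predict_proba`` returns a 3-vector of non-negative reals summing to 1;
    argmax ties resolve toward the lowest class index.
    """

    network: nn.Sequential
    config: ClassifierConfig
    training_log: list[dict] = field(default_factory=list)

    def predict_proba(self, window: np.ndarray) -> np.ndarray:
        x = _to_input(window, self.config)[None]
        logits = self.network.forward(x)[0].astype(np.float64)
        p = nn.softmax(logits)
        return p / p.sum()

    def predict_proba_batch(self, windows: np.ndarray) -> np.ndarray:
        """(N, L, H, W, 3) -> (N, 3); batched forward for the sliding scan."""
        xs = np.stack([_to_input(w, self.config) for w in windows])
        logits = self.network.forward(xs).astype(np.float64)
        p = nn.softmax(logits, axis=1)
        return p / p.sum(axis=1, keepdims=True)


def train(
    samples: Sequence[tuple[np.ndarray, int]],
    config: ClassifierConfig,
) -> TrainedModel:
    """Train the reference network on (window, label) pairs.

    Cross-entropy loss, Adam, seeded shuffling each epoch; two runs with the
    same config and samples produce identical parameters and logs.  Shapes and
    labels are validated before any training step.
    """
    if config.backend != "reference":
        raise ValueError(
            "train() fits the reference backend only; external backends are "
            "trained elsewhere and plugged in via the WindowClassifier contract"
        )
    if not samples:
        raise ValueError("no training samples given")
    X = np.stack([_to_input(w, config) for w, _ in samples])
    y = np.asarray([label for _, label in samples], dtype=np.int64)
    if not np.isin(y, (0, 1, 2)).all():
        raise ValueError(f"labels must be in {{0, 1, 2}}; got {sorted(set(y))}")

    rng = np.random.default_rng(config.seed)
    net = build_reference_network(config, rng)
    opt = nn.Adam(net, lr=config.learning_rate)
    n = len(y)
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            logits = net.forward(X[idx])
            loss, dlogits = nn.cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        log.append(
            {
                "epoch": epoch,
                "loss": float(np.sum(losses) / n),
                "accuracy": correct / n,
            }
        )
    return TrainedModel(network=net, config=config, training_log=log)


def predict_proba(model: WindowClassifier, window: np.ndarray) -> np.ndarray:
    """Probability 3-vector for one window (validated, normalized)."""
    p = np.asarray(model.predict_proba(window), dtype=np.float64)
    if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"backend returned an invalid probability vector: {p}")
    return p


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize parameters, config and training log to an .npz archive."""
    arrays = {}
    for li, layer in enumerate(model.network.iter_layers()):
        for name, p in layer.params.items():
            arrays[f"{li}:{name}"] = p
    meta = {"config": asdict(model.config), "training_log": model.training_log}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
        cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        config = ClassifierConfig(**cfg_dict)
        net = build_reference_network(config, np.random.default_rng(config.seed))
        for li, layer in enumerate(net.iter_layers()):
            for name in layer.params:
                layer.params[name] = data[f"{li}:{name}"].copy()
    return TrainedModel(network=net, config=config,
                        training_log=meta["training_log"])
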