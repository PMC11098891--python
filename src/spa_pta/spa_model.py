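"""SPA-PTA: spatial-attention graph network with channel squeezing-fusion.

Architecture (applied per frame, weights shared across frames):

    input (x, y, c) per joint
      -> GNN block 1: locally connected attention layer (3 -> 64), batch
         norm, LeakyReLU(0.2), dropout(0.2)
      -> GNN block 2: same, 64 -> 128
      -> PCSF block: per-target-joint channel squeezing by hop distance
         (full width at hop 0, p*C at hops 1-2, q^d*C at hops >= 3) and
         concatenation-fusion back to 128 channels
      -> global average pooling over frames and joints
      -> fully connected classifier head

Binary tasks train with cross-entropy; multiclass tasks with focal loss to
counter class imbalance.  The attention layer's per-joint message norms,
aggregated over time, form the interpretability output: on tremor data the
wrist of the affected side should dominate.

Ablation variants: ``no_pcsf`` drops the PCSF block; ``no_attention``
additionally replaces the locally connected layers by weight-shared graph
convolutions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .skeleton_graph import SkeletonGraph

VARIANTS = ("full", "no_pcsf", "no_attention")


class ModelStateError(RuntimeError):
    """Raised when inference/interpretation is requested before training."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SqueezeSpec:
    """Per-hop output channel widths for the channel-squeezing block.

    The self node (hop 0) keeps all ``c_in`` channels; short-range nodes
    (hops 1-2) are squeezed to p * c_in; long-range nodes at hop d >= 3 get
    q^d * c_in, decaying with distance and floored at one channel.
    Requires p >> q (enforced as p > q): distant joints — in particular the
    opposite arm, where Parkinsonian tremor is typically absent — carry
    little relevant information.
    """

    c_in: int
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.c_in < 1:
            raise ValueError("c_in must be >= 1")
        for name, v in (("p", self.p), ("q", self.q)):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p <= self.q:
            raise ValueError(f"need p > q (got p={self.p}, q={self.q})")

    def width(self, hop: int) -> int:
        if hop < 0:
            raise ValueError("hop distance must be >= 0")
        if hop == 0:
            return self.c_in
        if hop <= 2:
            return max(1, _round_half_up(self.p * self.c_in))
        return max(1, _round_half_up(self.q ** hop * self.c_in))

    def widths_by_hop(self, max_hop: int) -> dict[int, int]:
        return {d: self.width(d) for d in range(max_hop + 1)}


def squeeze_channels(hop: int, spec: SqueezeSpec) -> int:
    """Output channel count for a relevant node at the given hop distance."""
    return spec.width(hop)


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the published training recipe."""

    block_channels: tuple[int, int] = (64, 128)
    leaky_relu_alpha: float = 0.2
    dropout: float = 0.2
    p: float = 0.5
    q: float = 0.25
    learning_rate: float = 0.01
    lr_decay: float = 0.1
    lr_decay_epoch: int | None = None  # default: halfway through training
    batch_size: int = 8
    epochs: int = 500
    loss: str = "auto"  # auto: cross-entropy if binary, focal otherwise
    focal_gamma: float = 2.0
    focal_alpha: str | None = "balanced"
    input_norm: bool = True  # standardize each joint-channel at the input
    augment_mirror: bool = False  # random left-right flips during training
    dtype: str = "float64"  # float32 roughly halves CPU training time
    seed: int = 0
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("learning_rate", "lr_decay"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")

    def resolve_loss(self, n_classes: int) -> str:
        if self.loss != "auto":
            return self.loss
        return "cross_entropy" if n_classes == 2 else "focal"


@dataclass
class AttentionMap:
    """Per-frame per-joint attention with its temporal aggregate.

    ``per_frame`` has shape (windows, frames, joints); ``aggregate`` is its
    mean over frames, shape (windows, joints).
    """

    per_frame: np.ndarray
    aggregate: np.ndarray
    joint_names: tuple[str, ...]

    def cohort_mean(self) -> np.ndarray:
        """Mean aggregate attention over windows — one value per joint."""
        return self.aggregate.mean(axis=0)


class SPAPTA:
    """The tremor classification network (see module docstring)."""

    IN_FEATURES = 3  # (x, y, confidence)

    def __init__(self, config: ModelConfig, graph: SkeletonGraph,
                 n_classes: int) -> None:
        if n_classes < 2:
            raise ValueError("need at least two classes")
        self.config = config
        self.graph = graph
        self.n_classes = n_classes
        self.rng = np.random.default_rng(config.seed)
        self.trained = False
        self.loss_history: list[float] = []
        c1, c2 = config.block_channels
        a = graph.adjacency
        mk_conv = (_nn.GCNConv if config.variant == "no_attention" else _nn.EdgeLCN)

        # per joint-channel standardization of the raw (x, y, c) input, the
        # usual data_bn of skeleton networks: puts every joint's coordinate
        # distribution on a comparable scale before the graph layers
        self.input_bn = (_nn.BatchNorm(graph.n_nodes * self.IN_FEATURES)
                         if config.input_norm else None)

        self.block1 = [
            mk_conv(a, self.IN_FEATURES, c1, self.rng),
            _nn.BatchNorm(c1),
            _nn.LeakyReLU(config.leaky_relu_alpha),
            _nn.Dropout(config.dropout, self.rng),
        ]
        self.block2 = [
            mk_conv(a, c1, c2, self.rng),
            _nn.BatchNorm(c2),
            _nn.LeakyReLU(config.leaky_relu_alpha),
            _nn.Dropout(config.dropout, self.rng),
        ]
        self.node_layers: list[_nn.Layer] = self.block1 + self.block2
        if config.variant == "full":
            self.squeeze = SqueezeSpec(c_in=c2, p=config.p, q=config.q)
            max_hop = int(graph.hops.max())
            self.pcsf: _nn.PCSF | None = _nn.PCSF(
                graph.hops, c2, c2, self.squeeze.widths_by_hop(max_hop), self.rng)
            self.node_layers.append(self.pcsf)
        else:
            self.squeeze = None
            self.pcsf = None
        self.head = _nn.Dense(c2, n_classes, self.rng)
        self.layers: list[_nn.Layer] = self.node_layers + [self.head]
        if self.input_bn is not None:
            self.layers.append(self.input_bn)

        # left-right mirror: swap paired joints and negate x (feature 0);
        # valid because tremor laterality is arbitrary and the graph is
        # symmetric under the joint swap
        self._mirror_perm = np.array([
            graph.index(n.replace("left_", "R_").replace("right_", "left_")
                        .replace("R_", "right_"))
            for n in graph.nodes
        ])

        self.dtype = np.dtype(config.dtype)
        if self.dtype != np.float64:
            for layer in self.layers:
                for k, v in layer.params.items():
                    layer.params[k] = v.astype(self.dtype)
                if isinstance(layer, _nn.BatchNorm):
                    layer.running_mean = layer.running_mean.astype(self.dtype)
                    layer.running_var = layer.running_var.astype(self.dtype)

    # ---------------------------------------------------------------- forward

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[2] != self.graph.n_nodes or x.shape[3] != self.IN_FEATURES:
            raise ValueError(
                f"expected windows shaped (B, T, {self.graph.n_nodes}, "
                f"{self.IN_FEATURES}); got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Window features (B, T, V, 3) -> class logits (B, n_classes)."""
        x = self._check_input(x)
        b, t, v, c = x.shape
        h = x.reshape(b * t, v, c)
        if self.input_bn is not None:
            h = self.input_bn.forward(h.reshape(b * t, v * c), training)
            h = h.reshape(b * t, v, c)
        for layer in self.node_layers:
            h = layer.forward(h, training)
        pooled = h.reshape(b, t, v, -1).mean(axis=(1, 2))
        self._pool_shape = (b, t, v, h.shape[-1])
        return self.head.forward(pooled, training)

    def _backward(self, dlogits: np.ndarray) -> None:
        dpooled = self.head.backward(dlogits)
        b, t, v, c = self._pool_shape
        dh = np.broadcast_to(dpooled[:, None, None, :] / (t * v), (b, t, v, c))
        dh = dh.reshape(b * t, v, c)
        for layer in reversed(self.node_layers):
            dh = layer.backward(dh)
        if self.input_bn is not None:
            n = dh.shape[0]
            self.input_bn.backward(dh.reshape(n, -1))

    # ---------------------------------------------------------------- training

    def _loss_fn(self, class_weights: np.ndarray | None):
        kind = self.config.resolve_loss(self.n_classes)
        if kind == "cross_entropy":
            return _nn.cross_entropy_loss
        if kind == "focal":
            gamma = self.config.focal_gamma
            return lambda z, y: _nn.focal_loss(z, y, gamma=gamma, alpha=class_weights)
        raise ValueError(f"unknown loss {kind!r}")

    def compute_loss(self, logits: np.ndarray, labels: np.ndarray,
                     class_weights: np.ndarray | None = None) -> float:
        labels = np.asarray(labels)
        if labels.min() < 0 or labels.max() >= self.n_classes:
            raise ValueError("label outside the configured label space")
        return self._loss_fn(class_weights)(logits, labels)[0]

    def fit(self, x: np.ndarray, y: np.ndarray, verbose: bool = False) -> "SPAPTA":
        """Train with Adam; lr decays by ``lr_decay`` at ``lr_decay_epoch``."""
        x = self._check_input(x)
        y = np.asarray(y, dtype=int)
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError("label outside the configured label space")
        cfg = self.config
        weights = None
        if cfg.resolve_loss(self.n_classes) == "focal" and cfg.focal_alpha == "balanced":
            counts = np.bincount(y, minlength=self.n_classes).astype(float)
            inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
            weights = inv * self.n_classes / inv.sum()
        loss_fn = self._loss_fn(weights)

        opt = _nn.Adam(self.layers, lr=cfg.learning_rate)
        decay_at = cfg.lr_decay_epoch if cfg.lr_decay_epoch is not None else cfg.epochs // 2
        n = x.shape[0]
        bs = min(cfg.batch_size, n)
        for epoch in range(cfg.epochs):
            if decay_at and epoch == decay_at:
                opt.lr = cfg.learning_rate * cfg.lr_decay
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb = x[idx]
                if cfg.augment_mirror:
                    flip = self.rng.random(len(idx)) < 0.5
                    if flip.any():
                        xb = xb.copy()
                        xb[flip] = xb[flip][:, :, self._mirror_perm, :]
                        xb[flip, :, :, 0] *= -1.0
                logits = self.forward(xb, training=True)
                loss, dlogits = loss_fn(logits, y[idx])
                for layer in self.layers:
                    layer.zero_grad()
                self._backward(dlogits)
                opt.step()
                epoch_loss += loss * len(idx)
            self.loss_history.append(epoch_loss / n)
            if verbose and (epoch % 10 == 0 or epoch == cfg.epochs - 1):
                print(f"epoch {epoch:4d}  loss {self.loss_history[-1]:.4f}")
        self.trained = True
        return self

    # ---------------------------------------------------------------- inference

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        """Class probabilities per window.

        When the model was trained with mirror augmentation, probabilities
        are averaged over both left-right orientations (the same symmetry
        assumption, applied at inference).
        """
        x = self._check_input(x)
        views = [x]
        if self.config.augment_mirror:
            xm = x[:, :, self._mirror_perm, :].copy()
            xm[:, :, :, 0] *= -1.0
            views.append(xm)
        probs = np.zeros((x.shape[0], self.n_classes))
        for view in views:
            out = [
                _nn.softmax(self.forward(view[s:s + batch], training=False))
                for s in range(0, view.shape[0], batch)
            ]
            probs += np.concatenate(out, axis=0)
        return probs / len(views)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def extract_attention(self, x: np.ndarray, batch: int = 64) -> AttentionMap:
        """Per-frame per-joint attention on ``x`` from the second GNN block.

        The attention value of joint j at a frame is the L2 norm of the
        messages joint j sends through the locally connected attention layer
        (its learned weights applied to its features, scaled by the
        adjacency).  The aggregate is the mean over the window's frames.
        """
        if not self.trained:
            raise ModelStateError("attention is only meaningful on a trained model")
        if self.config.variant == "no_attention":
            raise ModelStateError("the no-attention ablation has no attention layer")
        x = self._check_input(x)
        lcn = self.block2[0]
        assert isinstance(lcn, _nn.EdgeLCN)
        maps = []
        lcn.capture_attention = True
        try:
            for s in range(0, x.shape[0], batch):
                xb = x[s:s + batch]
                self.forward(xb, training=False)
                b, t = xb.shape[:2]
                maps.append(lcn.last_attention.reshape(b, t, -1))
        finally:
            lcn.capture_attention = False
        per_frame = np.concatenate(maps, axis=0)
        return AttentionMap(per_frame=per_frame,
                            aggregate=per_frame.mean(axis=1),
                            joint_names=self.graph.nodes)

    # ---------------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        """Write parameters (npz) plus an architecture JSON next to it."""
        path = Path(path)
        arrays = {}
        for li, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"{li}:{k}"] = v
            if isinstance(layer, _nn.BatchNorm):
                arrays[f"{li}:running_mean"] = layer.running_mean
                arrays[f"{li}:running_var"] = layer.running_var
        np.savez(path, **arrays)
        meta = {"config": asdict(self.config), "n_classes": self.n_classes,
                "joints": list(self.graph.nodes), "trained": self.trained}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path, graph: SkeletonGraph) -> "SPAPTA":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_d = meta["config"]
        cfg_d["block_channels"] = tuple(cfg_d["block_channels"])
        model = cls(ModelConfig(**cfg_d), graph, meta["n_classes"])
        with np.load(path) as data:
            for li, layer in enumerate(model.layers):
                for k in layer.params:
                    layer.params[k] = data[f"{li}:{k}"]
                if isinstance(layer, _nn.BatchNorm):
                    layer.running_mean = data[f"{li}:running_mean"]
                    layer.running_var = data[f"{li}:running_var"]
        model.trained = bool(meta["trained"])
        return model
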