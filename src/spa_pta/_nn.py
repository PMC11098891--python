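"""Minimal neural-network building blocks on numpy.

Each layer implements an explicit ``forward``/``backward`` pair; parameters
and their gradients live in per-layer dicts so a single Adam optimizer can
walk the whole stack.  The layers cover exactly what the tremor network
needs: locally connected graph layers (per-edge weights), a weight-shared
graph convolution, batch normalization, LeakyReLU, dropout, the
channel-squeezing/fusion block, pooling and a dense head.

All gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: parameter/grad dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class EdgeLCN(Layer):
    """Locally connected graph layer with spatial attention weights.

    Computes h_i = sum_{j in N(i)} W_ij x_j a_ij + b_i where every directed
    edge (including self-loops) carries its own weight matrix W_ij — unlike
    a GCN, no weight sharing across joints — and a_ij is the normalized
    adjacency.  Input/output shape: (rows, nodes, channels); rows are
    batch x frame, i.e. the same weights are applied to every frame.

    When ``capture_attention`` is set the forward pass records, per row and
    per source joint, the L2 norm of that joint's outgoing messages; this is
    the raw material for the interpretability maps.
    """

    def __init__(self, adjacency: np.ndarray, c_in: int, c_out: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.n_nodes = adjacency.shape[0]
        self.c_in = c_in
        self.c_out = c_out
        tgt, src = np.nonzero(adjacency)
        self.tgt = tgt
        self.src = src
        self.scale = adjacency[tgt, src]
        self.params["W"] = _he_init(rng, (len(tgt), c_in, c_out), c_in)
        self.params["b"] = np.zeros((self.n_nodes, c_out))
        self.capture_attention = False
        self.last_attention: np.ndarray | None = None

    def _assemble(self, dtype) -> np.ndarray:
        """Block matrix (V*Cin, V*Cout): W_ij a_ij at (source, target) block.

        Non-edge blocks stay zero, so one dense matmul applies the whole
        locally connected layer at BLAS speed.
        """
        big = np.zeros((self.n_nodes * self.c_in, self.n_nodes * self.c_out),
                       dtype=dtype)
        w = self.params["W"]
        for e, (i, j, a) in enumerate(zip(self.tgt, self.src, self.scale)):
            big[j * self.c_in:(j + 1) * self.c_in,
                i * self.c_out:(i + 1) * self.c_out] = w[e] * dtype.type(a)
        return big

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not np.isfinite(x).all():
            bad = np.argwhere(~np.isfinite(x))[0]
            raise FloatingPointError(f"non-finite feature at row {bad[0]}, joint {bad[1]}")
        n = x.shape[0]
        self._xflat = x.reshape(n, -1)
        self._big = self._assemble(x.dtype)
        h = (self._xflat @ self._big).reshape(n, self.n_nodes, self.c_out)
        if self.capture_attention:
            att = np.empty((n, self.n_nodes))
            for j in range(self.n_nodes):
                mj = self._xflat[:, j * self.c_in:(j + 1) * self.c_in] @ \
                    self._big[j * self.c_in:(j + 1) * self.c_in, :]
                att[:, j] = np.sqrt((mj ** 2).sum(axis=1))
            self.last_attention = att
        return h + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        dflat = dout.reshape(n, -1)
        dbig = self._xflat.T @ dflat
        dw = np.empty_like(self.params["W"])
        for e, (i, j, a) in enumerate(zip(self.tgt, self.src, self.scale)):
            dw[e] = a * dbig[j * self.c_in:(j + 1) * self.c_in,
                             i * self.c_out:(i + 1) * self.c_out]
        self.grads["W"] = dw
        self.grads["b"] = dout.sum(axis=0)
        return (dflat @ self._big.T).reshape(n, self.n_nodes, self.c_in)


class GCNConv(Layer):
    """Weight-shared graph convolution h = A x W + b (the no-attention ablation)."""

    def __init__(self, adjacency: np.ndarray, c_in: int, c_out: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.a = adjacency
        self.params["W"] = _he_init(rng, (c_in, c_out), c_in)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._ax = np.einsum("ij,njc->nic", self.a.astype(x.dtype), x)
        return self._ax @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = np.einsum("nic,nio->co", self._ax, dout)
        self.grads["b"] = dout.sum(axis=(0, 1))
        dax = dout @ self.params["W"].T
        return np.einsum("ij,nic->njc", self.a.T.astype(dout.dtype), dax)


class BatchNorm(Layer):
    """Per-channel batch normalization over (rows, nodes)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._ivar
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = tuple(range(dout.ndim - 1))
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        if not self._training:
            return dxhat * self._ivar
        m = self._m
        return (self._ivar / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._slope = np.where(x >= 0, x.dtype.type(1.0), x.dtype.type(self.alpha))
        return x * self._slope

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._slope


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        rand_dtype = x.dtype if x.dtype in (np.float32, np.float64) else np.float64
        u = self.rng.random(x.shape, dtype=rand_dtype)
        self._mask = (u < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class PCSF(Layer):
    """Pyramidal channel-squeezing-fusion block.

    For each target joint i, every joint j's features are squeezed by a
    learned map to a width set by the hop distance d(i, j) (full width for
    the self node, a fraction p for short-range hops 1-2, q^d for
    long-range hops >= 3).  The squeezed features are concatenated in node
    order — self, short and long-range contributions stacked — and fused by
    a per-target linear map to the block's output width.
    """

    def __init__(self, hops: np.ndarray, c_in: int, c_out: int,
                 widths_by_hop: dict[int, int], rng: np.random.Generator) -> None:
        super().__init__()
        self.n_nodes = hops.shape[0]
        self.widths = np.array([[widths_by_hop[int(hops[i, j])]
                                 for j in range(self.n_nodes)]
                                for i in range(self.n_nodes)])
        for i in range(self.n_nodes):
            for j in range(self.n_nodes):
                self.params[f"S_{i}_{j}"] = _he_init(
                    rng, (c_in, int(self.widths[i, j])), c_in)
        for i in range(self.n_nodes):
            fan = int(self.widths[i].sum())
            self.params[f"F_{i}"] = _he_init(rng, (fan, c_out), fan)
            self.params[f"b_{i}"] = np.zeros(c_out)

    def fused_width(self, i: int) -> int:
        """Total concatenated width feeding target ``i``'s fusion map."""
        return int(self.widths[i].sum())

    def _fusion_block(self, i: int, j: int) -> np.ndarray:
        """Rows of F_i that multiply the squeezed features of source j."""
        off = int(self.widths[i, :j].sum())
        return self.params[f"F_{i}"][off:off + int(self.widths[i, j])]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # concat_j(x_j S_ij) @ F_i == sum_j x_j (S_ij F_i^(j)); the composed
        # per-pair maps are assembled into one dense (V*Cin, V*Cout) matrix
        # so the block runs as a single matmul
        v = self.n_nodes
        n = x.shape[0]
        c_in = x.shape[2]
        c_out = self.params["F_0"].shape[1]
        big = np.empty((v * c_in, v * c_out), dtype=x.dtype)
        for i in range(v):
            for j in range(v):
                big[j * c_in:(j + 1) * c_in, i * c_out:(i + 1) * c_out] = \
                    self.params[f"S_{i}_{j}"] @ self._fusion_block(i, j)
        self._big = big
        self._xflat = x.reshape(n, -1)
        out = (self._xflat @ big).reshape(n, v, c_out)
        bias = np.stack([self.params[f"b_{i}"] for i in range(v)])
        return out + bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        v = self.n_nodes
        n = dout.shape[0]
        c_in = self._xflat.shape[1] // v
        c_out = dout.shape[2]
        dflat = dout.reshape(n, -1)
        dbig = self._xflat.T @ dflat
        for i in range(v):
            self.grads[f"b_{i}"] = dout[:, i, :].sum(axis=0)
            df = np.empty_like(self.params[f"F_{i}"])
            off = 0
            for j in range(v):
                w = int(self.widths[i, j])
                dm_ij = dbig[j * c_in:(j + 1) * c_in, i * c_out:(i + 1) * c_out]
                self.grads[f"S_{i}_{j}"] = dm_ij @ self._fusion_block(i, j).T
                df[off:off + w] = self.params[f"S_{i}_{j}"].T @ dm_ij
                off += w
            self.grads[f"F_{i}"] = df
        return (dflat @ self._big.T).reshape(n, v, c_in)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _he_init(rng, (c_in, c_out), c_in)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray,
                       ) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    pt = np.clip(p[np.arange(n), labels], 1e-12, None)
    loss = float(-np.log(pt).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def focal_loss(logits: np.ndarray, labels: np.ndarray, gamma: float = 2.0,
               alpha: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean focal loss alpha_t (1 - p_t)^gamma (-log p_t) and its gradient.

    ``alpha`` is an optional per-class weight vector (e.g. inverse class
    frequency).  gamma = 0 with uniform alpha reduces to cross-entropy.
    """
    n, k = logits.shape
    p = softmax(logits)
    idx = np.arange(n)
    pt = np.clip(p[idx, labels], 1e-12, 1.0 - 1e-12)
    at = np.ones(n) if alpha is None else np.asarray(alpha, dtype=float)[labels]
    one_minus = 1.0 - pt
    loss = float((at * one_minus ** gamma * (-np.log(pt))).mean())
    # dL/dp_t, then chain through softmax: dp_t/dz_k = p_t (delta_tk - p_k)
    dl_dpt = at * (gamma * one_minus ** (gamma - 1) * np.log(pt)
                   - one_minus ** gamma / pt)
    dlogits = -p * (dl_dpt * pt)[:, None]
    dlogits[idx, labels] += dl_dpt * pt
    return loss, dlogits / n


class Adam:
    """Adam optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = layers
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, g in ly.grads.items():
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                ly.params[k] -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
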