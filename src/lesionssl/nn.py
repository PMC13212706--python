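"""A small 3D U-Net in plain numpy, with hand-written backpropagation.

The semi-supervised mechanics this package implements (EMA teacher,
consistency under invertible transforms, pseudo-labeling, focal+Dice
supervision) are architecture-agnostic, so the backbone is deliberately
minimal: an encoder/decoder with 3x3x3 convolutions, optional instance
normalization, ReLU, 2x average pooling, nearest-neighbour upsampling and
skip connections, ending in a per-voxel 2-class softmax.  Convolutions are
realised as im2col + BLAS matmul; everything runs in float32 on one CPU.

Parameters live in a flat ``dict[str, ndarray]`` ("parameter tree"), which
makes the teacher/student EMA coupling a trivial element-wise operation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS_NORM = 1e-5


@dataclass(frozen=True)
class SegmentationNetworkSpec:
    """Configuration of the segmentation backbone.

    ``depth`` counts resolution levels (depth - 1 poolings); input grids must
    be divisible by ``2 ** (depth - 1)`` along every axis.  Output is a
    per-voxel softmax over ``n_classes`` on the input grid.
    """

    depth: int = 3
    base_width: int = 4
    convs_per_block: int = 2
    norm: str = "instance"  # "instance" or "none"
    in_channels: int = 3
    n_classes: int = 2
    kernel_size: int = 3

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.kernel_size != 3:
            raise ValueError("only 3x3x3 convolutions are supported")
        if self.norm not in ("instance", "none"):
            raise ValueError("norm must be 'instance' or 'none'")

    def validate_grid(self, grid_shape) -> None:
        f = 2 ** (self.depth - 1)
        if any(s % f for s in grid_shape):
            raise ValueError(
                f"grid {tuple(grid_shape)} must be divisible by {f} along every "
                f"axis for a depth-{self.depth} network"
            )
        if self.norm == "instance" and any(s // f < 2 for s in grid_shape):
            # a 1-voxel bottleneck makes per-instance statistics degenerate
            raise ValueError(
                f"grid {tuple(grid_shape)} leaves a single-voxel bottleneck at "
                f"depth {self.depth}; use a larger grid, smaller depth or norm='none'"
            )


# ---------------------------------------------------------------------------
# primitive layers (forward + backward)
# ---------------------------------------------------------------------------

def conv3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3x3 convolution, padding 1, as 27 shifted channel-mixing tensordots."""
    n, c, d, h, wd = x.shape
    o = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.zeros((o, n, d, h, wd), dtype=np.result_type(x, w))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                xs = xp[:, :, i:i + d, j:j + h, k:k + wd]
                out += np.tensordot(w[:, :, i, j, k], xs, axes=([1], [1]))
    y = np.ascontiguousarray(out.transpose(1, 0, 2, 3, 4))
    y += b.reshape(1, -1, 1, 1, 1)
    return y


def conv3_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray,
                   need_dx: bool = True):
    n, c, d, h, wd = x.shape
    o = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp) if need_dx else None
    dw = np.empty_like(w)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                xs = xp[:, :, i:i + d, j:j + h, k:k + wd]
                dw[:, :, i, j, k] = np.tensordot(dy, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
                if need_dx:
                    dxp[:, :, i:i + d, j:j + h, k:k + wd] += np.tensordot(
                        w[:, :, i, j, k], dy, axes=([0], [1])).transpose(1, 0, 2, 3, 4)
    db = dy.sum(axis=(0, 2, 3, 4))
    dx = np.ascontiguousarray(dxp[:, :, 1:-1, 1:-1, 1:-1]) if need_dx else None
    return dx, dw, db


def conv1_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    # w: (O, C)
    y = np.tensordot(w, x, axes=([1], [1]))  # (O, N, D, H, W)
    y = y.transpose(1, 0, 2, 3, 4) + b.reshape(1, -1, 1, 1, 1)
    return np.ascontiguousarray(y)


def conv1_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray):
    dw = np.tensordot(dy, x, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
    db = dy.sum(axis=(0, 2, 3, 4))
    dx = np.tensordot(w.T, dy, axes=([1], [1])).transpose(1, 0, 2, 3, 4)
    return np.ascontiguousarray(dx), dw, db


def instnorm_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray):
    mu = x.mean(axis=(2, 3, 4), keepdims=True)
    xc = x - mu
    var = np.mean(xc * xc, axis=(2, 3, 4), keepdims=True)
    inv = 1.0 / np.sqrt(var + EPS_NORM)
    xhat = xc * inv
    y = gamma.reshape(1, -1, 1, 1, 1) * xhat + beta.reshape(1, -1, 1, 1, 1)
    return y, (xhat, inv)


def instnorm_backward(cache, gamma: np.ndarray, dy: np.ndarray):
    xhat, inv = cache
    dxhat = dy * gamma.reshape(1, -1, 1, 1, 1)
    m1 = dxhat.mean(axis=(2, 3, 4), keepdims=True)
    m2 = (dxhat * xhat).mean(axis=(2, 3, 4), keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    dgamma = (dy * xhat).sum(axis=(0, 2, 3, 4))
    dbeta = dy.sum(axis=(0, 2, 3, 4))
    return dx, dgamma, dbeta


def avgpool2_forward(x: np.ndarray) -> np.ndarray:
    n, c, d, h, w = x.shape
    return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))


def avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    up = np.repeat(np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3), 2, axis=4)
    return up / 8.0


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(np.repeat(x, 2, axis=2), 2, axis=3), 2, axis=4)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, d, h, w = dy.shape
    return dy.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    inner = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - inner)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class UNet3D:
    """Functional 3D U-Net: parameters are passed explicitly to every call."""

    def __init__(self, spec: SegmentationNetworkSpec | None = None, **kwargs):
        self.spec = spec if spec is not None else SegmentationNetworkSpec(**kwargs)

    # widths per level: base, 2*base, 4*base, ...
    def _width(self, level: int) -> int:
        return self.spec.base_width * (2 ** level)

    def _layer_dims(self):
        """Yield (name, in_channels, out_channels) for every convolution."""
        s = self.spec
        dims = []
        for l in range(s.depth):
            cin = s.in_channels if l == 0 else self._width(l - 1)
            for i in range(s.convs_per_block):
                dims.append((f"enc{l}c{i}", cin, self._width(l)))
                cin = self._width(l)
        for l in range(s.depth - 2, -1, -1):
            cin = self._width(l) + self._width(l + 1)
            for i in range(s.convs_per_block):
                dims.append((f"dec{l}c{i}", cin, self._width(l)))
                cin = self._width(l)
        return dims

    def init_params(self, rng: np.random.Generator) -> dict:
        """He-normal initialisation; returns the flat parameter tree (float32)."""
        params = {}
        for name, cin, cout in self._layer_dims():
            std = np.sqrt(2.0 / (cin * 27))
            params[f"{name}_w"] = rng.normal(0, std, (cout, cin, 3, 3, 3)).astype(np.float32)
            params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)
            if self.spec.norm == "instance":
                params[f"{name}_gamma"] = np.ones(cout, dtype=np.float32)
                params[f"{name}_beta"] = np.zeros(cout, dtype=np.float32)
        head_in = self._width(0) if self.spec.depth > 1 else self._width(self.spec.depth - 1)
        params["head_w"] = rng.normal(
            0, np.sqrt(1.0 / head_in), (self.spec.n_classes, head_in)).astype(np.float32)
        params["head_b"] = np.zeros(self.spec.n_classes, dtype=np.float32)
        return params

    # -- blocks -----------------------------------------------------------

    def _block_forward(self, params, prefix, h, cache_list):
        for i in range(self.spec.convs_per_block):
            name = f"{prefix}c{i}"
            c = {"x": h}
            h = conv3_forward(h, params[f"{name}_w"], params[f"{name}_b"])
            if self.spec.norm == "instance":
                h, c["norm"] = instnorm_forward(
                    h, params[f"{name}_gamma"], params[f"{name}_beta"])
            c["relu_mask"] = h > 0
            h = h * c["relu_mask"]
            if cache_list is not None:
                cache_list.append((name, c))
        return h

    def _block_backward(self, params, block_cache, dh, grads, need_input_grad=True):
        for idx, (name, c) in reversed(list(enumerate(block_cache))):
            dh = dh * c["relu_mask"]
            if self.spec.norm == "instance":
                dh, dg, dbt = instnorm_backward(c["norm"], params[f"{name}_gamma"], dh)
                grads[f"{name}_gamma"] = grads.get(f"{name}_gamma", 0) + dg
                grads[f"{name}_beta"] = grads.get(f"{name}_beta", 0) + dbt
            need_dx = need_input_grad or idx > 0
            dh, dw, db = conv3_backward(c["x"], params[f"{name}_w"], dh,
                                        need_dx=need_dx)
            grads[f"{name}_w"] = grads.get(f"{name}_w", 0) + dw
            grads[f"{name}_b"] = grads.get(f"{name}_b", 0) + db
        return dh

    # -- full passes ------------------------------------------------------

    def forward(self, params: dict, x: np.ndarray, want_cache: bool = False):
        """Run the network; returns per-voxel class probabilities (N, K, D, H, W).

        With ``want_cache=True`` also returns the cache needed by
        :meth:`backward`.
        """
        self.spec.validate_grid(x.shape[2:])
        x = np.ascontiguousarray(x, dtype=np.float32)
        s = self.spec
        cache = {"enc": [], "dec": [], "skip_ch": []} if want_cache else None
        skips = []
        h = x
        for l in range(s.depth):
            bc = [] if want_cache else None
            h = self._block_forward(params, f"enc{l}", h, bc)
            if want_cache:
                cache["enc"].append(bc)
            if l < s.depth - 1:
                skips.append(h)
                h = avgpool2_forward(h)
        for l in range(s.depth - 2, -1, -1):
            h = upsample2_forward(h)
            skip = skips[l]
            h = np.concatenate([skip, h], axis=1)
            bc = [] if want_cache else None
            h = self._block_forward(params, f"dec{l}", h, bc)
            if want_cache:
                cache["dec"].append((l, bc))
                cache["skip_ch"].append(skip.shape[1])
        logits = conv1_forward(h, params["head_w"], params["head_b"])
        probs = softmax(logits)
        if want_cache:
            cache["head_x"] = h
            cache["probs"] = probs
            return probs, cache
        return probs

    def backward(self, params: dict, cache: dict, dprobs: np.ndarray) -> dict:
        """Backpropagate a gradient w.r.t. the probabilities; returns grads tree."""
        s = self.spec
        grads = {}
        dlogits = softmax_backward(cache["probs"], dprobs)
        dh, dw, db = conv1_backward(cache["head_x"], params["head_w"], dlogits)
        grads["head_w"], grads["head_b"] = dw, db
        d_skip = {}
        for (l, bc), skip_ch in zip(reversed(cache["dec"]), reversed(cache["skip_ch"])):
            dh = self._block_backward(params, bc, dh, grads)
            d_skip[l] = dh[:, :skip_ch]
            dh = upsample2_backward(np.ascontiguousarray(dh[:, skip_ch:]))
        dh = self._block_backward(params, cache["enc"][s.depth - 1], dh, grads,
                                  need_input_grad=s.depth > 1)
        for l in range(s.depth - 2, -1, -1):
            dh = avgpool2_backward(dh)
            dh = dh + d_skip[l]
            dh = self._block_backward(params, cache["enc"][l], dh, grads,
                                      need_input_grad=l > 0)
        return grads


class Adam:
    """Adam optimizer over a flat parameter tree."""

    def __init__(self, params: dict, lr: float = 3e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for k in params:
            g = grads.get(k)
            if g is None or np.isscalar(g):
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            params[k] = (params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32)
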