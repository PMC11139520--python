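"""3D encoder-decoder regression network for displacement vector fields.

A U-Net-style fully convolutional network maps a one-channel intensity
cube to a three-channel displacement field of identical spatial shape.
Large stacks are partitioned into cubes before inference and the per-cube
predictions are re-assembled (overlaps averaged).

The network is implemented directly on numpy with a small reverse-mode
tape: 3x3x3 convolutions via im2col GEMM, 2x max pooling, nearest
upsampling, skip concatenation, ReLU, and an Adam optimizer.  The
published configuration (5 levels, 32..512 channels, 80x128x128 cubes) is
expressible; the defaults here are a desk-scale 3-level variant suited to
CPU training on phantoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dvf import LossWeights, compute_dvf, direction_loss, displacement_loss, total_loss, total_loss_grad

__all__ = [
    "CubeSpec",
    "ModelConfig",
    "UNet3D",
    "build_model",
    "partition_volume",
    "assemble_cubes",
    "train",
    "predict_dvf",
    "normalize_volume",
]


@dataclass(frozen=True)
class CubeSpec:
    """Cube partitioning convention: cube shape and stride, both (z, y, x)."""

    shape: tuple[int, int, int] = (16, 32, 32)
    stride: tuple[int, int, int] | None = None  # None -> stride == shape

    def __post_init__(self) -> None:
        stride = self.stride if self.stride is not None else self.shape
        if any(s <= 0 for s in self.shape) or any(s <= 0 for s in stride):
            raise ValueError("cube shape and stride must be positive")
        if any(st > sh for st, sh in zip(stride, self.shape)):
            raise ValueError("stride must not exceed cube shape")

    @property
    def eff_stride(self) -> tuple[int, int, int]:
        return self.stride if self.stride is not None else self.shape


@dataclass
class ModelConfig:
    levels: int = 3
    channels: tuple[int, ...] = (16, 32, 64)
    in_channels: int = 1
    out_channels: int = 3
    decoder_convs: int = 1
    norm: bool = True  # instance normalization after every hidden conv
    lr: float = 1e-3
    epochs: int = 5
    cubes_per_epoch: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != self.levels:
            raise ValueError("channels length must equal levels")


def published_config() -> ModelConfig:
    """The full-scale configuration (5 levels, 32..512 channels)."""
    return ModelConfig(levels=5, channels=(32, 64, 128, 256, 512))


# ---------------------------------------------------------------------------
# minimal reverse-mode tape


class _Node:
    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data: np.ndarray, parents=(), backward=None):
        self.data = data
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    def backward(self, seed: np.ndarray) -> None:
        order: list[_Node] = []
        seen: set[int] = set()

        def visit(node: _Node) -> None:
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            order.append(node)

        visit(self)
        for node in order:
            node.grad = np.zeros_like(node.data)
        self.grad = seed.astype(self.data.dtype, copy=True)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)


DTYPE = np.float32


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C, D, H, W) -> (C*k^3, D*H*W) patch matrix for stride-1 same-pad conv.

    Built offset-by-offset with contiguous slice copies, which is far
    cheaper than gathering a 7D strided view.
    """
    c, d, h, wd = x.shape
    if k == 1:
        return x.reshape(c, d * h * wd)
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    cols = np.empty((k**3, c, d, h, wd), dtype=x.dtype)
    o = 0
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                np.copyto(cols[o], xp[:, dz : dz + d, dy : dy + h, dx : dx + wd])
                o += 1
    return cols.reshape(k**3 * c, d * h * wd)


def _w_flat(w: np.ndarray) -> np.ndarray:
    """(Cout, C, k, k, k) -> (Cout, k^3*C) in the offset-major layout of _im2col."""
    cout, c, k = w.shape[0], w.shape[1], w.shape[2]
    if k == 1:
        return w.reshape(cout, c)
    return np.ascontiguousarray(w.transpose(0, 2, 3, 4, 1)).reshape(cout, -1)


def _conv3d_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, pad: int) -> np.ndarray:
    """x: (C, D, H, W); w: (Cout, C, k, k, k) -> (Cout, D, H, W) for stride 1, same pad."""
    c, d, h, wd = x.shape
    cout = w.shape[0]
    cols = _im2col(x, w.shape[2], pad)
    out = _w_flat(w) @ cols
    if b is not None:
        out = out + b[:, None]
    return out.reshape(cout, d, h, wd)


class _Layer:
    def params(self):
        return []


class Conv3d(_Layer):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k, k)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.k = k
        self.pad = k // 2
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def __call__(self, x: _Node) -> _Node:
        c, d, h, wd = x.data.shape
        cout = self.w.shape[0]
        cols = _im2col(x.data, self.k, self.pad)  # cached for backward
        y = (_w_flat(self.w) @ cols + self.b[:, None]).reshape(cout, d, h, wd)

        def backward(gy: np.ndarray) -> None:
            k = self.k
            gy2 = gy.reshape(cout, -1)  # (Cout, DHW)
            gwf = gy2 @ cols.T  # (Cout, k^3*C) offset-major
            if k == 1:
                self.gw += gwf.reshape(self.w.shape)
            else:
                cin = self.w.shape[1]
                self.gw += gwf.reshape(cout, k, k, k, cin).transpose(0, 4, 1, 2, 3)
            self.gb += gy2.sum(axis=1)
            # dX = conv(gY, W flipped, in/out channels swapped)
            w_flip = self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            x.grad += _conv3d_raw(gy, np.ascontiguousarray(w_flip), None, self.pad)

        return _Node(y, (x,), backward)


class InstanceNorm(_Layer):
    """Per-channel spatial normalization with learnable gain and bias."""

    def __init__(self, channels: int):
        self.g = np.ones(channels, dtype=DTYPE)
        self.b = np.zeros(channels, dtype=DTYPE)
        self.gg = np.zeros_like(self.g)
        self.gb = np.zeros_like(self.b)
        self.eps = 1e-5

    def params(self):
        return [(self.g, self.gg), (self.b, self.gb)]

    def __call__(self, x: _Node) -> _Node:
        c = x.data.shape[0]
        flat = x.data.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mu) * inv
        y = (xhat * self.g[:, None] + self.b[:, None]).reshape(x.data.shape)

        def backward(gy: np.ndarray) -> None:
            gyf = gy.reshape(c, -1)
            self.gg += (gyf * xhat).sum(axis=1)
            self.gb += gyf.sum(axis=1)
            gxhat = gyf * self.g[:, None]
            m1 = gxhat.mean(axis=1, keepdims=True)
            m2 = (gxhat * xhat).mean(axis=1, keepdims=True)
            x.grad += ((gxhat - m1 - xhat * m2) * inv).reshape(x.data.shape)

        return _Node(y, (x,), backward)


class ReLU(_Layer):
    def __call__(self, x: _Node) -> _Node:
        mask = x.data > 0
        y = x.data * mask

        def backward(gy: np.ndarray) -> None:
            x.grad += gy * mask

        return _Node(y, (x,), backward)


class MaxPool2(_Layer):
    def __call__(self, x: _Node) -> _Node:
        c, d, h, w = x.data.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x pooling")
        blocks = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        flat = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def backward(gy: np.ndarray) -> None:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, arg[..., None], gy[..., None], axis=-1)
            gx = gflat.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(
                0, 1, 4, 2, 5, 3, 6
            ).reshape(c, d, h, w)
            x.grad += gx

        return _Node(y, (x,), backward)


class Upsample2(_Layer):
    def __call__(self, x: _Node) -> _Node:
        y = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

        def backward(gy: np.ndarray) -> None:
            c, d, h, w = x.data.shape
            x.grad += gy.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))

        return _Node(y, (x,), backward)


def _concat(a: _Node, b: _Node) -> _Node:
    y = np.concatenate([a.data, b.data], axis=0)
    ca = a.data.shape[0]

    def backward(gy: np.ndarray) -> None:
        a.grad += gy[:ca]
        b.grad += gy[ca:]

    return _Node(y, (a, b), backward)


class UNet3D:
    """Encoder-decoder with skip connections; two convs per encoder block,
    one per decoder block, linear 1x1x1 output head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels

        def unit(cin: int, cout: int) -> list[_Layer]:
            ops: list[_Layer] = [Conv3d(cin, cout, 3, rng)]
            if cfg.norm:
                ops.append(InstanceNorm(cout))
            return ops

        self.enc: list[list[list[_Layer]]] = []
        cin = cfg.in_channels
        for c in ch:
            self.enc.append([unit(cin, c), unit(c, c)])
            cin = c
        self.dec: list[list[list[_Layer]]] = []
        for lvl in range(cfg.levels - 2, -1, -1):
            block = [unit(ch[lvl + 1] + ch[lvl], ch[lvl])]
            for _ in range(cfg.decoder_convs - 1):
                block.append(unit(ch[lvl], ch[lvl]))
            self.dec.append(block)
        self.head = Conv3d(ch[0], cfg.out_channels, 1, rng)
        self.relu = ReLU()
        self.pool = MaxPool2()
        self.up = Upsample2()

    def layers(self) -> list[_Layer]:
        out: list[_Layer] = []
        for block in self.enc:
            for u in block:
                out += u
        for block in self.dec:
            for u in block:
                out += u
        out.append(self.head)
        return out

    def params(self):
        for layer in self.layers():
            yield from layer.params()

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def check_shape(self, shape: tuple[int, int, int]) -> None:
        div = 2 ** (self.cfg.levels - 1)
        if any(s % div for s in shape):
            raise ValueError(
                f"spatial shape {shape} must be divisible by 2^(levels-1)={div}"
            )

    def forward_node(self, cube: np.ndarray) -> _Node:
        """cube: (D, H, W) float -> node with data (3, D, H, W)."""
        cube = np.asarray(cube, dtype=DTYPE)
        self.check_shape(cube.shape)
        x = _Node(cube[None])

        def apply_unit(x: _Node, ops: list[_Layer]) -> _Node:
            for op in ops:
                x = op(x)
            return self.relu(x)

        skips: list[_Node] = []
        for lvl, block in enumerate(self.enc):
            for u in block:
                x = apply_unit(x, u)
            if lvl < self.cfg.levels - 1:
                skips.append(x)
                x = self.pool(x)
        for block, skip in zip(self.dec, reversed(skips)):
            x = self.up(x)
            x = apply_unit(_concat(x, skip), block[0])
            for u in block[1:]:
                x = apply_unit(x, u)
        return self.head(x)

    def predict(self, cube: np.ndarray) -> np.ndarray:
        return self.forward_node(cube).data


class Adam:
    def __init__(self, model: UNet3D, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state = [
            (np.zeros_like(p), np.zeros_like(p)) for p, _ in model.params()
        ]

    def step(self) -> None:
        self.t += 1
        for (p, g), (m, v) in zip(self.model.params(), self.state):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_model(cfg: ModelConfig = ModelConfig()) -> UNet3D:
    """Construct the regression network from a config."""
    return UNet3D(cfg)


def normalize_volume(vol: np.ndarray) -> np.ndarray:
    """Per-volume min-max normalization to [0, 1]."""
    vol = np.asarray(vol, dtype=np.float64)
    lo, hi = vol.min(), vol.max()
    return (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)


def partition_volume(
    vol: np.ndarray, spec: CubeSpec = CubeSpec()
) -> list[tuple[np.ndarray, tuple[int, int, int]]]:
    """Tile a volume into cubes on a regular grid; edge cubes zero-padded.

    Returns (cube, origin) pairs; origins are (z, y, x) voxel coordinates
    of each cube's corner in the source volume.
    """
    vol = np.asarray(vol)
    if vol.ndim != 3 or vol.size == 0:
        raise ValueError("volume must be non-empty 3D")
    cz, cy, cx = spec.shape
    sz, sy, sx = spec.eff_stride
    starts = []
    for dim, c, s in zip(vol.shape, spec.shape, spec.eff_stride):
        pos = list(range(0, max(dim - c, 0) + 1, s))
        if pos[-1] + c < dim:
            pos.append(dim - c if dim >= c else 0)
        if dim < c:
            pos = [0]
        starts.append(pos)
    pieces = []
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                cube = np.zeros(spec.shape, dtype=vol.dtype)
                sl = vol[z0 : z0 + cz, y0 : y0 + cy, x0 : x0 + cx]
                cube[: sl.shape[0], : sl.shape[1], : sl.shape[2]] = sl
                pieces.append((cube, (z0, y0, x0)))
    return pieces


def assemble_cubes(
    pieces: list[tuple[np.ndarray, tuple[int, int, int]]],
    out_shape: tuple[int, ...],
) -> np.ndarray:
    """Re-assemble (possibly multi-channel) cubes; overlaps are averaged.

    Cubes may carry a leading channel axis; padding beyond ``out_shape``
    is cropped.  Raises if any voxel of ``out_shape`` is left uncovered.
    """
    if not pieces:
        raise ValueError("no pieces to assemble")
    has_channels = pieces[0][0].ndim == 4
    spatial = out_shape[-3:]
    nch = pieces[0][0].shape[0] if has_channels else 1
    acc = np.zeros((nch,) + tuple(spatial), dtype=np.float64)
    cnt = np.zeros(spatial, dtype=np.int32)
    for cube, (z0, y0, x0) in pieces:
        c = cube if has_channels else cube[None]
        cz, cy, cx = c.shape[1:]
        ez, ey, ex = min(z0 + cz, spatial[0]), min(y0 + cy, spatial[1]), min(x0 + cx, spatial[2])
        acc[:, z0:ez, y0:ey, x0:ex] += c[:, : ez - z0, : ey - y0, : ex - x0]
        cnt[z0:ez, y0:ey, x0:ex] += 1
    if (cnt == 0).any():
        raise ValueError("pieces do not cover the output volume")
    out = acc / cnt
    return out if has_channels else out[0]


def _sample_cube_pair(
    vol: np.ndarray,
    mask: np.ndarray,
    spec: CubeSpec,
    rng: np.random.Generator,
    max_retry: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-origin training cube; resamples if the crop has no background."""
    cz, cy, cx = spec.shape
    nz, ny, nx = vol.shape
    for attempt in range(max_retry):
        z0 = rng.integers(0, max(nz - cz, 0) + 1)
        y0 = rng.integers(0, max(ny - cy, 0) + 1)
        x0 = rng.integers(0, max(nx - cx, 0) + 1)
        v = vol[z0 : z0 + cz, y0 : y0 + cy, x0 : x0 + cx]
        m = mask[z0 : z0 + cz, y0 : y0 + cy, x0 : x0 + cx]
        if v.shape != spec.shape:
            vv = np.zeros(spec.shape, dtype=vol.dtype)
            mm = np.zeros(spec.shape, dtype=mask.dtype)
            vv[: v.shape[0], : v.shape[1], : v.shape[2]] = v
            mm[: m.shape[0], : m.shape[1], : m.shape[2]] = m
            v, m = vv, mm
        if (m == 0).any():
            return v, m
    warnings.warn("sampled cube without background after retries; using last crop")
    return v, m


def train(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    cfg: ModelConfig = ModelConfig(),
    cube: CubeSpec = CubeSpec(),
    w: LossWeights = LossWeights(),
) -> tuple[UNet3D, dict]:
    """Train the DVF regressor on (volume, instance-mask) pairs.

    Each epoch samples ``cubes_per_epoch`` random cubes across the
    training volumes, derives the ground-truth DVF of each crop, and takes
    one Adam step on the combined displacement + direction loss.  Fully
    deterministic under the config seed (single-threaded).

    Returns the trained model and a history dict with per-epoch mean
    losses.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    model = build_model(cfg)
    model.check_shape(cube.shape)
    opt = Adam(model, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    vols = [normalize_volume(v) for v, _ in pairs]
    masks = [np.asarray(m) for _, m in pairs]
    history: dict = {"total": [], "displacement": [], "direction": []}
    for _epoch in range(cfg.epochs):
        tot = ld = lr_ = 0.0
        for _ in range(cfg.cubes_per_epoch):
            i = int(rng.integers(0, len(pairs)))
            v, m = _sample_cube_pair(vols[i], masks[i], cube, rng)
            gt = compute_dvf(m)
            node = model.forward_node(v)
            pred = node.data
            loss = total_loss(pred, gt, w)
            grad = total_loss_grad(pred, gt, w)
            model.zero_grad()
            node.backward(grad)
            opt.step()
            tot += loss
            ld += displacement_loss(pred, gt)
            lr_ += direction_loss(pred, gt)
        n = cfg.cubes_per_epoch
        history["total"].append(tot / n)
        history["displacement"].append(ld / n)
        history["direction"].append(lr_ / n)
    return model, history


def overfit_single_cube(
    vol_cube: np.ndarray,
    mask_cube: np.ndarray,
    cfg: ModelConfig = ModelConfig(),
    steps: int = 200,
    w: LossWeights = LossWeights(),
) -> tuple[UNet3D, list[float]]:
    """Repeatedly fit one cube; returns the per-step displacement-loss trace.

    A sanity harness: on a single training example the displacement loss
    must collapse well below its initial value.
    """
    model = build_model(cfg)
    gt = compute_dvf(mask_cube)
    v = normalize_volume(vol_cube)
    opt = Adam(model, lr=cfg.lr)
    trace: list[float] = []
    for _ in range(steps):
        node = model.forward_node(v)
        trace.append(displacement_loss(node.data, gt))
        grad = total_loss_grad(node.data, gt, w)
        model.zero_grad()
        node.backward(grad)
        opt.step()
    return model, trace


def predict_dvf(vol: np.ndarray, model: UNet3D, spec: CubeSpec = CubeSpec()) -> np.ndarray:
    """Predict the full-volume DVF: partition, per-cube inference, assemble."""
    vol = normalize_volume(vol)
    pieces = partition_volume(vol, spec)
    preds = [(model.predict(c), org) for c, org in pieces]
    return assemble_cubes(preds, (3,) + vol.shape)
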