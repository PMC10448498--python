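"""Trainable U-net backend for double-spot segmentation and counting.

A compact encoder-decoder ("U") convolutional network, implemented directly
on numpy (im2col 3x3 convolutions, explicit backpropagation, Adam), sized so
that training on a few hundred 64 px patches completes in minutes on one CPU
core.  Training labels are derived from simulator ground truth: the union of
small disks at both spot centers of each true double spot — single spots are
excluded — so that connected components of the predicted binary mask equal
the double-spot count (mask-then-count).

Training is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "UNetSpec",
    "UNetWeights",
    "train_unet",
    "predict_mask",
    "mask_to_count",
    "make_training_data",
    "normalize_frame",
    "truth_pair_mask",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity for component counting


@dataclass(frozen=True)
class UNetSpec:
    """U-net architecture and training hyper-parameters.

    ``patch_size_px`` must be divisible by 2**depth.  Defaults are sized for
    CPU training: depth 3, 8 base channels, 64 px patches, 8 epochs.
    """

    depth: int = 3
    base_channels: int = 8
    patch_size_px: int = 64
    epochs: int = 8
    learning_rate: float = 2e-3
    batch_size: int = 8
    pos_weight: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size_px % (2**self.depth) != 0:
            raise ValueError("patch_size_px must be divisible by 2**depth")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")


class UNetWeights:
    """Trained parameters plus the spec they belong to."""

    def __init__(self, params: dict[str, np.ndarray], spec: UNetSpec):
        self.params = params
        self.spec = spec


# ---------------------------------------------------------------- primitives

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C, 9, H, W) patches of the 3x3 neighbourhood."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, 9, h, w), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di:di + h, dj:dj + w]
            k += 1
    return cols


def _col2im(dcols: np.ndarray, h: int, w: int) -> np.ndarray:
    n, c = dcols.shape[:2]
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, k]
            k += 1
    return dxp[:, :, 1:h + 1, 1:w + 1]


def _conv_fwd(x, W, b):
    cols = _im2col(x)
    y = np.tensordot(W, cols, axes=([1, 2], [1, 2]))  # (O, N, H, W)
    y = np.moveaxis(y, 0, 1) + b[None, :, None, None]
    return y, cols


def _conv_bwd(dy, cols, W, h, w):
    dW = np.tensordot(dy, cols, axes=([0, 2, 3], [0, 3, 4]))
    db = dy.sum(axis=(0, 2, 3))
    dcols = np.tensordot(dy, W, axes=([1], [0]))      # (N, H, W, C, 9)
    dcols = np.moveaxis(dcols, (3, 4), (1, 2))
    return _col2im(dcols, h, w), dW, db


def _pool_fwd(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]
    # split gradient evenly among ties for determinism
    mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
    return y, mask


def _pool_bwd(dy, mask):
    n, c, h2, _, w2, _ = mask.shape
    d = mask * dy[:, :, :, None, :, None]
    return d.reshape(n, c, h2 * 2, w2 * 2)


def _up_fwd(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up_bwd(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ----------------------------------------------------------------- the U-net

def _channels(spec: UNetSpec) -> list[int]:
    return [spec.base_channels * 2**lvl for lvl in range(spec.depth + 1)]


def _init_params(spec: UNetSpec) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    ch = _channels(spec)
    params: dict[str, np.ndarray] = {}

    def conv(name: str, cin: int, cout: int) -> None:
        scale = math.sqrt(2.0 / (cin * 9))
        params[f"{name}_W"] = rng.normal(0, scale, (cout, cin, 9))
        params[f"{name}_b"] = np.zeros(cout)

    cin = 1
    for lvl in range(spec.depth):
        conv(f"enc{lvl}a", cin, ch[lvl])
        conv(f"enc{lvl}b", ch[lvl], ch[lvl])
        cin = ch[lvl]
    conv("botta", ch[spec.depth - 1], ch[spec.depth])
    conv("bottb", ch[spec.depth], ch[spec.depth])
    for lvl in reversed(range(spec.depth)):
        above = ch[lvl + 1]
        conv(f"dec{lvl}u", above, ch[lvl])          # after nearest upsample
        conv(f"dec{lvl}a", 2 * ch[lvl], ch[lvl])    # after skip concat
        conv(f"dec{lvl}b", ch[lvl], ch[lvl])
    params["out_W"] = rng.normal(0, math.sqrt(2.0 / ch[0]), (1, ch[0]))
    params["out_b"] = np.zeros(1)
    return params


def _forward(x: np.ndarray, params: dict, spec: UNetSpec):
    """Forward pass; returns logits and the cache for backprop."""
    cache: dict = {"x": x}
    h = x
    skips = []
    for lvl in range(spec.depth):
        for tag in "ab":
            name = f"enc{lvl}{tag}"
            z, cols = _conv_fwd(h, params[f"{name}_W"], params[f"{name}_b"])
            h = np.maximum(z, 0)
            cache[name] = (cols, z, h.shape[2:])
        skips.append(h)
        h, mask = _pool_fwd(h)
        cache[f"pool{lvl}"] = mask
    for name in ("botta", "bottb"):
        z, cols = _conv_fwd(h, params[f"{name}_W"], params[f"{name}_b"])
        h = np.maximum(z, 0)
        cache[name] = (cols, z, h.shape[2:])
    for lvl in reversed(range(spec.depth)):
        h = _up_fwd(h)
        name = f"dec{lvl}u"
        z, cols = _conv_fwd(h, params[f"{name}_W"], params[f"{name}_b"])
        h = np.maximum(z, 0)
        cache[name] = (cols, z, h.shape[2:])
        h = np.concatenate([skips[lvl], h], axis=1)
        for tag in "ab":
            name = f"dec{lvl}{tag}"
            z, cols = _conv_fwd(h, params[f"{name}_W"], params[f"{name}_b"])
            h = np.maximum(z, 0)
            cache[name] = (cols, z, h.shape[2:])
    logits = np.einsum("oc,nchw->nohw", params["out_W"], h) + params["out_b"][None, :, None, None]
    cache["final_h"] = h
    return logits, cache


def _backward(dlogits: np.ndarray, cache: dict, params: dict, spec: UNetSpec
              ) -> dict[str, np.ndarray]:
    grads: dict[str, np.ndarray] = {}
    h = cache["final_h"]
    grads["out_W"] = np.einsum("nohw,nchw->oc", dlogits, h)
    grads["out_b"] = dlogits.sum(axis=(0, 2, 3))
    dh = np.einsum("oc,nohw->nchw", params["out_W"], dlogits)

    def conv_back(name: str, dh: np.ndarray) -> np.ndarray:
        cols, z, (hh, ww) = cache[name]
        dz = dh * (z > 0)
        dx, dW, db = _conv_bwd(dz, cols, params[f"{name}_W"], hh, ww)
        grads[f"{name}_W"] = dW
        grads[f"{name}_b"] = db
        return dx

    ch = _channels(spec)
    dskips = [None] * spec.depth
    for lvl in range(spec.depth):
        for tag in "ba":
            dh = conv_back(f"dec{lvl}{tag}", dh)
        dskips[lvl] = dh[:, :ch[lvl]]
        dh = dh[:, ch[lvl]:]
        dh = conv_back(f"dec{lvl}u", dh)
        dh = _up_bwd(dh)
    for name in ("bottb", "botta"):
        dh = conv_back(name, dh)
    for lvl in reversed(range(spec.depth)):
        dh = _pool_bwd(dh, cache[f"pool{lvl}"])
        dh = dh + dskips[lvl]
        for tag in "ba":
            dh = conv_back(f"enc{lvl}{tag}", dh)
    return grads


def _bce_with_logits(logits: np.ndarray, y: np.ndarray, pos_weight: float
                     ) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy; returns (loss, dloss/dlogits)."""
    z = logits
    sig = 1.0 / (1.0 + np.exp(-z))
    softplus_negz = np.logaddexp(0.0, -z)
    softplus_z = np.logaddexp(0.0, z)
    loss = pos_weight * y * softplus_negz + (1.0 - y) * softplus_z
    dz = (pos_weight * y * (sig - 1.0) + (1.0 - y) * sig) / z.size
    return float(loss.mean()), dz


# ------------------------------------------------------------------ training

def normalize_frame(frame: np.ndarray) -> np.ndarray:
    """Robust per-frame normalization: (x - median) / (1.4826 * MAD)."""
    x = np.asarray(frame, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return (x - med) / max(1.4826 * mad, 1e-6)


def truth_pair_mask(truth: pd.DataFrame, frame_index: int,
                    shape: tuple[int, int], radius: float = 3.0) -> np.ndarray:
    """Label mask from simulator ground truth: a radius-``radius`` capsule
    (two spot disks joined along the pair axis) over every two-spot emitter;
    single spots are left unlabeled, so connected components of the mask
    correspond to double spots only."""
    from .detect import add_capsule

    mask = np.zeros(shape, dtype=bool)
    sub = truth[truth.frame == frame_index]
    if len(sub) == 0:
        return mask
    for _, grp in sub.groupby("emitter_id"):
        if len(grp) != 2:
            continue
        pts = list(zip(grp.row + grp.d_row, grp.col + grp.d_col))
        add_capsule(mask, pts[0], pts[1], radius)
    return mask


def make_training_data(stacks_with_truth, spec: UNetSpec, n_patches: int,
                       rng: np.random.Generator | int | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Sample training patches and truth masks from simulated stacks.

    Half the patches are centered near a random emitter — double spots (so
    the positive class is represented) and single spots alike (hard
    negatives the network must learn to suppress) — and half are uniform
    random crops.  Returns (X, Y) with shapes (n, 1, p, p): normalized
    patches and binary masks.
    """
    rng = np.random.default_rng(rng)
    p = spec.patch_size_px
    X = np.empty((n_patches, 1, p, p))
    Y = np.empty((n_patches, 1, p, p))
    frames_pool = []
    for stack, truth in stacks_with_truth:
        for k in range(stack.n_frames):
            frames_pool.append((stack.frames[k], truth, k))
    if not frames_pool:
        raise ValueError("no frames to sample from")
    for i in range(n_patches):
        frame, truth, k = frames_pool[rng.integers(len(frames_pool))]
        h, w = frame.shape
        norm = normalize_frame(frame)
        mask = truth_pair_mask(truth, k, frame.shape)
        sub = truth[(truth.frame == k)]
        emitter_ids = sub.emitter_id.unique()
        if i % 2 == 0 and len(emitter_ids):
            eid = emitter_ids[rng.integers(len(emitter_ids))]
            e = sub[sub.emitter_id == eid].iloc[0]
            r0 = int(e.row) - p // 2 + rng.integers(-8, 9)
            c0 = int(e.col) - p // 2 + rng.integers(-8, 9)
        else:
            r0 = rng.integers(0, max(h - p, 1))
            c0 = rng.integers(0, max(w - p, 1))
        r0 = int(np.clip(r0, 0, h - p))
        c0 = int(np.clip(c0, 0, w - p))
        X[i, 0] = norm[r0:r0 + p, c0:c0 + p]
        Y[i, 0] = mask[r0:r0 + p, c0:c0 + p]
    return X, Y


def train_unet(X: np.ndarray, Y: np.ndarray, spec: UNetSpec = UNetSpec(),
               verbose: bool = False) -> UNetWeights:
    """Train the U-net with Adam on weighted BCE; deterministic per seed.

    ``X``: (n, 1, p, p) normalized patches; ``Y``: matching binary masks.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 4:
        raise ValueError("X and Y must be matching (n, 1, p, p) arrays")
    params = _init_params(spec)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    rng = np.random.default_rng(spec.seed + 1)
    lr, b1, b2, eps = spec.learning_rate, 0.9, 0.999, 1e-8
    t = 0
    n = len(X)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            logits, cache = _forward(X[idx], params, spec)
            loss, dlogits = _bce_with_logits(logits, Y[idx], spec.pos_weight)
            grads = _backward(dlogits, cache, params, spec)
            t += 1
            for k in params:
                g = grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mh = m[k] / (1 - b1**t)
                vh = v[k] / (1 - b2**t)
                params[k] -= lr * mh / (np.sqrt(vh) + eps)
            losses.append(loss)
        if verbose:  # pragma: no cover - logging only
            print(f"epoch {epoch + 1}/{spec.epochs}  loss {np.mean(losses):.4f}")
    return UNetWeights(params, spec)


def predict_mask(frame: np.ndarray, weights: UNetWeights,
                 threshold: float = 0.5) -> np.ndarray:
    """Predict the binary double-spot mask for a full frame.

    The frame is normalized as in training, tiled into overlapping patches,
    logits are averaged in overlaps, and the sigmoid output is thresholded.
    """
    if not isinstance(weights, UNetWeights) or not weights.params:
        raise ValueError("predict_mask requires trained UNetWeights")
    spec = weights.spec
    p = spec.patch_size_px
    x = normalize_frame(frame)
    h, w = x.shape
    if h < p or w < p:
        raise ValueError(f"frame smaller than patch size {p}")
    stride = max(p - 16, p // 2)
    starts_r = sorted({min(r, h - p) for r in range(0, h, stride)})
    starts_c = sorted({min(c, w - p) for c in range(0, w, stride)})
    logit_sum = np.zeros((h, w))
    hits = np.zeros((h, w))
    tiles = [(r, c) for r in starts_r for c in starts_c]
    batch = 16
    for start in range(0, len(tiles), batch):
        chunk = tiles[start:start + batch]
        xb = np.stack([x[r:r + p, c:c + p] for r, c in chunk])[:, None]
        logits, _ = _forward(xb, weights.params, spec)
        for i, (r, c) in enumerate(chunk):
            logit_sum[r:r + p, c:c + p] += logits[i, 0]
            hits[r:r + p, c:c + p] += 1
    prob = 1.0 / (1.0 + np.exp(-logit_sum / np.maximum(hits, 1)))
    return prob >= threshold


def mask_to_count(mask: np.ndarray, min_area_px: int = 25) -> int:
    """Double-spot count from a binary mask: 8-connected components whose
    area survives the minimum-area filter.

    The default threshold is ~40% of the nominal pair-capsule label area
    (2 * radius * separation + pi * radius^2 ~ 67 px for radius 3 and
    separation 6.5), rejecting fragments and partially activated singles.
    """
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_EIGHT)
    if n == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int((areas >= min_area_px).sum())
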