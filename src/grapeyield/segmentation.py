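"""Stage 1: encoder-decoder (U-Net) grape-cluster segmentation.

The network is the canonical small U-Net: ``depth`` encoder levels of two
3x3 convolutions + ReLU with 2x2 max pooling, channel count doubling per
level from ``base_channels``; a two-conv bottleneck; a decoder of
2x2-stride-2 transpose convolutions with skip connections by channel
concatenation; and a 1x1 convolution onto two output channels
(grape vs background).  Training follows the recipe used throughout this
package: Adam, learning rate 0.001, per-pixel cross-entropy, batch size 8.

Inputs are reflect-padded to the nearest multiple of 2**depth and the
logits cropped back, so all resolution tiers pass through unchanged.
Prediction resolves the two-channel argmax with ties going to background.

Train/test splitting is group-aware: all view-angle renderings of one bunch
arrangement share a ``group_id`` and are kept entirely on one side of the
split, eliminating leakage between multiple views of the same bunch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._nn import Adam, Conv2d, ConvTranspose2x2, MaxPool2x2, ReLU, softmax_cross_entropy

__all__ = [
    "UNetSegmenter",
    "SplitError",
    "NonConvergenceWarning",
    "split_by_group",
    "train_segmenter",
    "segment",
    "load_training_arrays",
]


class SplitError(ValueError):
    """Cannot build a group-aware split (fewer than two groups)."""


class NonConvergenceWarning(UserWarning):
    """Final-epoch training loss did not improve on the first epoch."""


def split_by_group(manifest: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0):
    """Partition manifest records into train/test at the group level.

    Whole groups are assigned to one side; the number of test groups is the
    prefix of a seeded group shuffle whose record fraction is closest to
    ``test_fraction``.  No ``group_id`` ever appears on both sides.
    """
    if manifest.empty:
        raise SplitError("manifest is empty")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    groups = manifest["group_id"].unique()
    if len(groups) < 2:
        raise SplitError("need at least 2 distinct group_ids to split")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(len(groups))
    shuffled = groups[order]
    sizes = manifest["group_id"].value_counts()
    counts = np.array([sizes[g] for g in shuffled], dtype=float)
    cum = np.cumsum(counts)
    frac = cum / cum[-1]
    # at least one group on each side
    candidates = np.arange(1, len(groups))
    k = candidates[np.argmin(np.abs(frac[candidates - 1] - test_fraction))]
    test_groups = set(shuffled[:k])
    is_test = manifest["group_id"].isin(test_groups)
    return manifest[~is_test].reset_index(drop=True), manifest[is_test].reset_index(drop=True)


class _UNetNet:
    """Explicit forward/backward U-Net graph on the numpy layer core."""

    def __init__(self, depth: int, base: int, rng: np.random.Generator,
                 in_channels: int = 3, out_channels: int = 2):
        self.depth, self.base = depth, base
        self.in_channels, self.out_channels = in_channels, out_channels
        self.enc, self.pools = [], []
        ch = in_channels
        c = base
        for _ in range(depth):
            self.enc.append([Conv2d(ch, c, 3, rng), ReLU(), Conv2d(c, c, 3, rng), ReLU()])
            self.pools.append(MaxPool2x2())
            ch, c = c, c * 2
        self.bottleneck = [Conv2d(ch, c, 3, rng), ReLU(), Conv2d(c, c, 3, rng), ReLU()]
        self.ups, self.dec = [], []
        for _ in range(depth):
            self.ups.append(ConvTranspose2x2(c, c // 2, rng))
            self.dec.append(
                [Conv2d(c, c // 2, 3, rng), ReLU(), Conv2d(c // 2, c // 2, 3, rng), ReLU()]
            )
            c //= 2
        self.head = Conv2d(c, out_channels, 1, rng)

    def params(self):
        out = []
        for block in self.enc + [self.bottleneck] + self.dec:
            for layer in block:
                out.extend(layer.params())
        for up in self.ups:
            out.extend(up.params())
        out.extend(self.head.params())
        return out

    @staticmethod
    def _run_block(block, x):
        for layer in block:
            x = layer.forward(x)
        return x

    @staticmethod
    def _back_block(block, dy):
        for layer in reversed(block):
            dy = layer.backward(dy)
        return dy

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = self._run_block(block, x)
            skips.append(x)
            x = pool.forward(x)
        x = self._run_block(self.bottleneck, x)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=1)
            x = self._run_block(block, x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = []
        for up, block in zip(reversed(self.ups), reversed(self.dec)):
            dy = self._back_block(block, dy)
            c_skip = dy.shape[1] // 2
            dskips.append(dy[:, :c_skip])
            dy = up.backward(np.ascontiguousarray(dy[:, c_skip:]))
        dy = self._back_block(self.bottleneck, dy)
        # dskips were collected shallowest-first, matching enc order
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            dy = pool.backward(dy)
            dy = self._back_block(block, dy + dskip)


def _pad_to_multiple(x: np.ndarray, mult: int):
    """Reflect-pad NCHW spatial dims up to a multiple of ``mult``."""
    h, w = x.shape[2], x.shape[3]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph == 0 and pw == 0:
        return x, (h, w)
    return np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect"), (h, w)


def _to_nchw(images) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError("expected images of shape (n, rows, cols, 3)")
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("images must be normalized to [0, 1]")
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


class UNetSegmenter(BaseEstimator):
    """U-Net grape-cluster segmenter with a scikit-learn estimator surface.

    Parameters
    ----------
    depth : encoder levels (input padded to a multiple of ``2**depth``).
    base_channels : channels at the first level, doubling per level.
    epochs, learning_rate, batch_size : Adam / cross-entropy training recipe.
    seed : master seed for weight init and batch shuffling.

    Fitted attributes: ``net_`` (parameter state), ``loss_curve_``
    (per-epoch mean training loss).
    """

    def __init__(self, depth: int = 4, base_channels: int = 16, epochs: int = 10,
                 learning_rate: float = 1e-3, batch_size: int = 8, seed: int = 0):
        self.depth = depth
        self.base_channels = base_channels
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    def _init_net(self):
        rng = np.random.Generator(np.random.PCG64(self.seed))
        self.net_ = _UNetNet(self.depth, self.base_channels, rng)
        self.loss_curve_ = []
        return self

    def fit(self, X, y):
        """Train on images ``X`` (n, rows, cols, 3) and masks ``y`` (n, rows, cols)."""
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        x = _to_nchw(X)
        t = np.asarray(y)
        if t.shape != (x.shape[0],) + x.shape[2:]:
            raise ValueError("mask shapes must match image spatial shapes")
        if x.shape[0] == 0:
            raise ValueError("training set is empty")
        t = (t > 0).astype(np.int64)
        self._init_net()
        opt = Adam(self.net_.params(), lr=self.learning_rate)
        rng = np.random.Generator(np.random.PCG64(self.seed + 1))
        mult = 2**self.depth
        for _epoch in range(self.epochs):
            order = rng.permutation(x.shape[0])
            losses = []
            for s in range(0, len(order), self.batch_size):
                idx = order[s : s + self.batch_size]
                xb, (h, w) = _pad_to_multiple(x[idx], mult)
                tb = t[idx]
                logits = self.net_.forward(xb)[:, :, :h, :w]
                loss, dl = softmax_cross_entropy(logits, tb)
                dl_full = np.zeros(
                    (xb.shape[0], 2, xb.shape[2], xb.shape[3]), dtype=np.float32
                )
                dl_full[:, :, :h, :w] = dl
                opt.zero_grad()
                self.net_.backward(dl_full)
                opt.step()
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)))
        if self.loss_curve_ and self.loss_curve_[-1] > self.loss_curve_[0]:
            warnings.warn(
                "final-epoch loss exceeds first-epoch loss; the segmenter may not "
                "have converged", NonConvergenceWarning,
            )
        return self

    def predict(self, X) -> np.ndarray:
        """Binary masks (n, rows, cols); two-channel argmax, ties -> background."""
        if not hasattr(self, "net_"):
            self._init_net()  # untrained predictions still honour the shape contract
        x = _to_nchw(X)
        mult = 2**self.depth
        out = np.empty((x.shape[0],) + x.shape[2:], dtype=np.uint8)
        step = max(1, self.batch_size)
        for s in range(0, x.shape[0], step):
            xb, (h, w) = _pad_to_multiple(x[s : s + step], mult)
            logits = self.net_.forward(xb)[:, :, :h, :w]
            out[s : s + step] = (logits[:, 1] > logits[:, 0]).astype(np.uint8)
        return out

    # -- checkpointing ------------------------------------------------------

    _CKPT_VERSION = 1

    def save(self, path) -> None:
        if not hasattr(self, "net_"):
            raise ValueError("nothing to save: estimator has no network state")
        header = dict(
            format="grapeyield-unet", version=self._CKPT_VERSION,
            params=self.get_params(), loss_curve=list(self.loss_curve_),
        )
        arrays = {f"p{i:04d}": p.value for i, p in enumerate(self.net_.params())}
        np.savez(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["header"]))
            if header.get("format") != "grapeyield-unet":
                raise ValueError(f"{path} is not a U-Net checkpoint")
            est = cls(**header["params"])
            est._init_net()
            est.loss_curve_ = list(header.get("loss_curve", []))
            for i, p in enumerate(est.net_.params()):
                p.value[...] = data[f"p{i:04d}"]
        return est


# ---------------------------------------------------------------------------
# manifest-level wrappers


def load_training_arrays(manifest: pd.DataFrame, data_dir, shape=None):
    """Load images and ground-truth masks for the manifest records.

    ``shape=(rows, cols)`` resizes everything to one training size.
    """
    from . import io as gio
    from pathlib import Path

    root = Path(data_dir)
    images, masks = [], []
    for rec in manifest.itertuples():
        img = gio.load_image(root / rec.image_path)
        msk = gio.load_mask(root / rec.mask_path)
        if img.shape[:2] != msk.shape[:2]:
            raise ValueError(f"{rec.image_path}: image and mask shapes differ")
        if shape is not None:
            img = gio.resize_image(img, shape)
            msk = gio.resize_mask(msk, shape)
        images.append(img)
        masks.append(msk)
    return np.stack(images), np.stack(masks)


def train_segmenter(train_set: pd.DataFrame, data_dir, shape=None,
                    **params) -> UNetSegmenter:
    """Fit a :class:`UNetSegmenter` on manifest records (see the class for params)."""
    X, y = load_training_arrays(train_set, data_dir, shape=shape)
    return UNetSegmenter(**params).fit(X, y)


def segment(model: UNetSegmenter, image: np.ndarray) -> np.ndarray:
    """Predict a binary mask for one normalized RGB image."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected one image of shape (rows, cols, 3)")
    return model.predict(img[None])[0]
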