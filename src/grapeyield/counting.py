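"""Stage 3: occlusion-corrected berry count and weight estimation.

Two complementary realisations of the occlusion correction live here.

*Implicit (learned)*: :class:`CNNYieldRegressor`, a small convolutional
regression network trained with mean-squared-error on two scalar heads whose
supervision targets are the TOTAL berry count (visible + occluded) and the
measured bunch weight.  Because the targets include berries the image does
not show, the network learns the occlusion offset directly from data.

*Explicit (closed form)*: :class:`OcclusionRatioCorrector`, a stratified
total-to-visible count ratio.  For each stratum (by default grape colour x
foliage level) the ratio is the training mean of ``total_count /
visible_count``; strata with too few records fall back to the global ratio.
A visible-count estimate (e.g. from :func:`count_visible_blobs`) multiplied
by the ratio and rounded gives the corrected count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from sklearn.base import BaseEstimator, RegressorMixin

from ._nn import Adam, AvgPool2x2, Conv2d, Linear, MaxPool2x2, ReLU, mse_loss
from .segmentation import NonConvergenceWarning, _to_nchw

__all__ = [
    "CNNYieldRegressor",
    "OcclusionRatioCorrector",
    "YieldPrediction",
    "predict_yield",
    "count_visible_blobs",
]


@dataclass
class YieldPrediction:
    """Count (raw and rounded) and weight for one image."""

    count_raw: float
    count_int: int
    weight_g: float


class _CounterNet:
    """Conv/pool feature stack, flattened into dense layers, two linear heads."""

    def __init__(self, in_shape, conv_channels, dense_widths, rng, pool="avg",
                 global_pool=True):
        c, h, w = in_shape
        pool_cls = AvgPool2x2 if pool == "avg" else MaxPool2x2
        self.global_pool = global_pool
        self.convs = []
        for ch in conv_channels:
            self.convs.append([Conv2d(c, ch, 3, rng), ReLU(), pool_cls()])
            c = ch
            h //= 2
            w //= 2
            if h < 1 or w < 1:
                raise ValueError("too many pooling stages for the input size")
        self.flat_dim = c if global_pool else c * h * w
        self.dense = []
        n = self.flat_dim
        for width in dense_widths:
            self.dense.append([Linear(n, width, rng), ReLU()])
            n = width
        self.head_count = Linear(n, 1, rng)
        self.head_weight = Linear(n, 1, rng)
        self._conv_out_shape = None

    def params(self):
        out = []
        for block in self.convs:
            for layer in block:
                out.extend(layer.params())
        for block in self.dense:
            for layer in block:
                out.extend(layer.params())
        out.extend(self.head_count.params())
        out.extend(self.head_weight.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for block in self.convs:
            for layer in block:
                x = layer.forward(x)
        self._conv_out_shape = x.shape
        if self.global_pool:
            x = x.mean(axis=(2, 3))  # spatial average: one evidence sum per channel
        else:
            x = x.reshape(x.shape[0], -1)
        for block in self.dense:
            for layer in block:
                x = layer.forward(x)
        return np.concatenate(
            [self.head_count.forward(x), self.head_weight.forward(x)], axis=1
        )

    def backward(self, dy: np.ndarray) -> None:
        dx = self.head_count.backward(np.ascontiguousarray(dy[:, :1]))
        dx = dx + self.head_weight.backward(np.ascontiguousarray(dy[:, 1:]))
        for block in reversed(self.dense):
            for layer in reversed(block):
                dx = layer.backward(dx)
        n, c, h, w = self._conv_out_shape
        if self.global_pool:
            dx = np.broadcast_to(
                dx[:, :, None, None] / np.float32(h * w), (n, c, h, w)
            ).astype(np.float32)
        else:
            dx = dx.reshape(self._conv_out_shape)
        for block in reversed(self.convs):
            for layer in reversed(block):
                dx = layer.backward(dx)


class CNNYieldRegressor(BaseEstimator, RegressorMixin):
    """Convolutional count/weight regressor with two scalar output heads.

    Trained with the summed mean-squared error of both heads (Adam,
    learning rate 0.001, batch size 8).  Targets are standardised
    internally per head and de-standardised at prediction time; raw-scale
    MSE at typical count/weight magnitudes is otherwise poorly conditioned
    for a fixed learning rate.  Pooling defaults to 2x2 averaging, which
    preserves the summed-evidence signal a counting readout integrates
    (max pooling is available via ``pool="max"``).

    Fitted attributes: ``net_``, ``loss_curve_``, ``input_shape_``,
    ``y_mean_`` / ``y_std_`` (target standardisation).
    """

    def __init__(self, conv_channels=(16, 32, 64), dense_widths=(64, 32),
                 epochs: int = 15, learning_rate: float = 1e-3,
                 batch_size: int = 8, pool: str = "avg",
                 global_pool: bool = True, seed: int = 0):
        self.conv_channels = conv_channels
        self.dense_widths = dense_widths
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.pool = pool
        self.global_pool = global_pool
        self.seed = seed

    def fit(self, X, y):
        """Fit on images (n, rows, cols, 3) and targets (n, 2) = [count, weight]."""
        x = _to_nchw(X)
        t = np.asarray(y, dtype=np.float64)
        if t.ndim != 2 or t.shape[1] != 2:
            raise ValueError("targets must have shape (n, 2): total count and weight")
        if np.isnan(t).any():
            raise ValueError("targets contain missing values")
        if x.shape[0] == 0:
            raise ValueError("training set is empty")
        if x.shape[0] != t.shape[0]:
            raise ValueError("images and targets disagree in length")
        self.input_shape_ = x.shape[1:]
        self.y_mean_ = t.mean(axis=0)
        self.y_std_ = np.maximum(t.std(axis=0), 1e-6)
        tz = ((t - self.y_mean_) / self.y_std_).astype(np.float32)

        rng = np.random.Generator(np.random.PCG64(self.seed))
        self.net_ = _CounterNet(self.input_shape_, tuple(self.conv_channels),
                                tuple(self.dense_widths), rng, pool=self.pool,
                                global_pool=self.global_pool)
        opt = Adam(self.net_.params(), lr=self.learning_rate)
        shuffle_rng = np.random.Generator(np.random.PCG64(self.seed + 1))
        self.loss_curve_ = []
        for _epoch in range(self.epochs):
            order = shuffle_rng.permutation(x.shape[0])
            losses = []
            for s in range(0, len(order), self.batch_size):
                idx = order[s : s + self.batch_size]
                pred = self.net_.forward(x[idx])
                loss, grad = mse_loss(pred, tz[idx])
                opt.zero_grad()
                self.net_.backward(grad.astype(np.float32))
                opt.step()
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)))
        if self.loss_curve_ and self.loss_curve_[-1] > self.loss_curve_[0]:
            warnings.warn(
                "final-epoch loss exceeds first-epoch loss; the counter may not "
                "have converged", NonConvergenceWarning,
            )
        return self

    def _require_net(self):
        if not hasattr(self, "net_"):
            raise ValueError("model is not fitted; call fit() or load()")

    def predict(self, X) -> np.ndarray:
        """Predict (n, 2) = [count, weight_g] on the training scale.

        Inputs whose spatial size differs from the training size are resized.
        """
        self._require_net()
        from . import io as gio

        x = np.asarray(X, dtype=np.float32)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError("expected images of shape (n, rows, cols, 3)")
        want = (self.input_shape_[1], self.input_shape_[2])
        if x.shape[1:3] != want:
            x = np.stack([gio.resize_image(im, want) for im in x])
        xn = _to_nchw(x)
        preds = []
        step = max(1, self.batch_size)
        for s in range(0, xn.shape[0], step):
            preds.append(self.net_.forward(xn[s : s + step]))
        z = np.concatenate(preds, axis=0).astype(np.float64)
        return z * self.y_std_ + self.y_mean_

    # -- checkpointing ------------------------------------------------------

    _CKPT_VERSION = 1

    def save(self, path) -> None:
        self._require_net()
        header = dict(
            format="grapeyield-counter", version=self._CKPT_VERSION,
            params={**self.get_params(),
                    "conv_channels": list(self.conv_channels),
                    "dense_widths": list(self.dense_widths)},
            input_shape=list(self.input_shape_),
            y_mean=list(self.y_mean_), y_std=list(self.y_std_),
            loss_curve=list(self.loss_curve_),
        )
        arrays = {f"p{i:04d}": p.value for i, p in enumerate(self.net_.params())}
        np.savez(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path) -> "CNNYieldRegressor":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["header"]))
            if header.get("format") != "grapeyield-counter":
                raise ValueError(f"{path} is not a counter checkpoint")
            params = dict(header["params"])
            params["conv_channels"] = tuple(params["conv_channels"])
            params["dense_widths"] = tuple(params["dense_widths"])
            est = cls(**params)
            est.input_shape_ = tuple(header["input_shape"])
            est.y_mean_ = np.asarray(header["y_mean"])
            est.y_std_ = np.asarray(header["y_std"])
            est.loss_curve_ = list(header.get("loss_curve", []))
            rng = np.random.Generator(np.random.PCG64(est.seed))
            est.net_ = _CounterNet(est.input_shape_, tuple(est.conv_channels),
                                   tuple(est.dense_widths), rng, pool=est.pool,
                                   global_pool=est.global_pool)
            for i, p in enumerate(est.net_.params()):
                p.value[...] = data[f"p{i:04d}"]
        return est


def predict_yield(model: CNNYieldRegressor, masked_image: np.ndarray) -> YieldPrediction:
    """Count and weight for one masked (background-suppressed) image."""
    from .overlay import MaskedImage

    img = masked_image.image if isinstance(masked_image, MaskedImage) else masked_image
    pred = model.predict(np.asarray(img, dtype=np.float32)[None])[0]
    return YieldPrediction(
        count_raw=float(pred[0]),
        count_int=int(round(float(pred[0]))),
        weight_g=float(pred[1]),
    )


# ---------------------------------------------------------------------------
# classical visible-count baseline


def count_visible_blobs(mask, min_blob_area: int = 8, min_peak_distance: int = 3) -> int:
    """Count approximately-circular blobs in a binary mask.

    Connected components smaller than ``min_blob_area`` are discarded; the
    remaining foreground's Euclidean distance transform is searched for
    local maxima at least ``min_peak_distance`` apart, one per blob.  Exact
    for non-touching disks; merged disks are separated by their distance
    peaks.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        return 0
    labels, n = ndimage.label(m)
    if min_blob_area > 1:
        sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_blob_area) + 1
        if keep.size == 0:
            return 0
        m = np.isin(labels, keep)
        labels, n = ndimage.label(m)
    edt = ndimage.distance_transform_edt(m)
    peaks = peak_local_max(
        edt, min_distance=min_peak_distance, labels=labels, exclude_border=False
    )
    if len(peaks) == 0:
        return int(n)
    # every surviving component contributes at least one blob
    peak_labels = labels[tuple(peaks.T)]
    per_comp = np.bincount(peak_labels, minlength=n + 1)[1:]
    return int(np.maximum(per_comp, 1).sum())


# ---------------------------------------------------------------------------
# explicit stratified correction factor


class OcclusionRatioCorrector(BaseEstimator):
    """Stratified total-to-visible count ratio estimator.

    ``fit`` consumes a dataset manifest carrying ``visible_count`` and
    ``total_count`` columns.  Per-stratum ratios are training means of
    ``total/visible``; strata with fewer than ``n_min`` records use the
    global ratio, as do unseen strata at correction time.

    Fitted attributes: ``global_ratio_``, ``per_stratum_ratios_``,
    ``n_per_stratum_``.
    """

    def __init__(self, stratify=("color_variety", "foliage_level"), n_min: int = 5):
        self.stratify = stratify
        self.n_min = n_min

    def fit(self, manifest: pd.DataFrame, y=None):
        df = manifest
        zero_vis = df["visible_count"] == 0
        if zero_vis.any():
            warnings.warn(
                f"excluding {int(zero_vis.sum())} records with visible_count == 0 "
                "from ratio estimation"
            )
            df = df[~zero_vis]
        if df.empty:
            raise ValueError("no records with visible_count >= 1; cannot estimate ratios")
        ratios = df["total_count"] / df["visible_count"]
        self.global_ratio_ = float(ratios.mean())
        self.per_stratum_ratios_ = {}
        self.n_per_stratum_ = {}
        cols = list(self.stratify)
        if cols:
            for key, grp in df.groupby(cols):
                key = key if isinstance(key, tuple) else (key,)
                n = len(grp)
                self.n_per_stratum_[key] = n
                r = float((grp["total_count"] / grp["visible_count"]).mean())
                self.per_stratum_ratios_[key] = r if n >= self.n_min else self.global_ratio_
        return self

    def ratio(self, stratum=None) -> float:
        if not hasattr(self, "global_ratio_"):
            raise ValueError("corrector is not fitted")
        if stratum is None:
            return self.global_ratio_
        key = stratum if isinstance(stratum, tuple) else (stratum,)
        if key not in self.per_stratum_ratios_:
            warnings.warn(f"unknown stratum {key!r}; using the global ratio")
            return self.global_ratio_
        return self.per_stratum_ratios_[key]

    def correct(self, visible_estimate: float, stratum=None) -> int:
        """Inflate a visible-count estimate to a total-count estimate."""
        if visible_estimate < 0:
            raise ValueError("visible_estimate must be >= 0")
        return int(round(visible_estimate * self.ratio(stratum)))

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            dict(
                stratify=list(self.stratify),
                n_min=self.n_min,
                global_ratio=self.global_ratio_,
                per_stratum={
                    "|".join(map(str, k)): v for k, v in self.per_stratum_ratios_.items()
                },
                n_per_stratum={
                    "|".join(map(str, k)): v for k, v in self.n_per_stratum_.items()
                },
            ),
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "OcclusionRatioCorrector":
        d = json.loads(text)
        est = cls(stratify=tuple(d["stratify"]), n_min=d["n_min"])
        est.global_ratio_ = d["global_ratio"]
        est.per_stratum_ratios_ = {
            tuple(k.split("|")): v for k, v in d["per_stratum"].items()
        }
        est.n_per_stratum_ = {
            tuple(k.split("|")): v for k, v in d["n_per_stratum"].items()
        }
        return est


def estimate_correction_factor(train_set: pd.DataFrame,
                               stratify=("color_variety", "foliage_level"),
                               n_min: int = 5) -> OcclusionRatioCorrector:
    """Functional wrapper over :class:`OcclusionRatioCorrector`."""
    return OcclusionRatioCorrector(stratify=stratify, n_min=n_min).fit(train_set)


def apply_correction(visible_estimate: float, corrector: OcclusionRatioCorrector,
                     stratum=None) -> int:
    """Functional wrapper over :meth:`OcclusionRatioCorrector.correct`."""
    return corrector.correct(visible_estimate, stratum)
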