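"""Image and mask I/O, tier resizing and the end-to-end pipeline runner.

Conventions: images are float arrays in [0, 1] with 3 channels (row-major,
origin top-left); masks are {0, 1} arrays stored on disk as 8-bit PNG with
0 = background and 255 = grape.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from PIL import Image
from skimage.transform import resize as _sk_resize

from .simulate import RESOLUTION_TIERS_DESK, RESOLUTION_TIERS_PAPER

__all__ = [
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "resize_to_tier",
    "resize_image",
    "resize_mask",
    "normalize_image",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("grapeyield")


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG as float RGB in [0, 1]."""
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B", "F"):
            raise ValueError(
                f"{path}: unsupported bit depth {im.mode!r}; only 8-bit images are supported"
            )
        im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.float32) / 255.0
    return arr


def save_image(path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path, format="PNG")


def load_mask(path) -> np.ndarray:
    """Read a mask PNG, thresholding grey values at 128 to {0, 1}."""
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B", "F"):
            raise ValueError(
                f"{path}: unsupported bit depth {im.mode!r}; only 8-bit masks are supported"
            )
        arr = np.asarray(im.convert("L"))
    return (arr >= 128).astype(np.uint8)


def save_mask(path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path, format="PNG")


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Scale an arbitrary-range image to [0, 1] float32."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def resize_image(image: np.ndarray, shape) -> np.ndarray:
    """Bilinear resize of an intensity image to (rows, cols)."""
    if image.shape[:2] == tuple(shape):
        return image
    out = _sk_resize(image, shape, order=1, anti_aliasing=True, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def resize_mask(mask: np.ndarray, shape) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask (values stay in {0, 1})."""
    if mask.shape[:2] == tuple(shape):
        return mask
    out = _sk_resize(mask.astype(np.uint8), shape, order=0, anti_aliasing=False,
                     preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def resize_to_tier(array: np.ndarray, tier: str, tier_table=None, is_mask: bool = False):
    """Resize to a named resolution tier (3:4 aspect preserved by the tables)."""
    if tier_table is None:
        tier_table = RESOLUTION_TIERS_DESK
    elif tier_table == "paper":
        tier_table = RESOLUTION_TIERS_PAPER
    elif tier_table == "desk":
        tier_table = RESOLUTION_TIERS_DESK
    if tier not in tier_table:
        raise KeyError(f"unknown resolution tier {tier!r}; known: {sorted(tier_table)}")
    shape = tier_table[tier]
    return resize_mask(array, shape) if is_mask else resize_image(array, shape)


@dataclass
class PipelineConfig:
    """Wiring for the three-stage pipeline (segment -> overlay -> count).

    ``use_segmentation=False`` is the ablation switch: stage 3 then runs on
    the raw resized image.
    """

    seg_checkpoint: Optional[str] = None
    counter_checkpoint: Optional[str] = None
    output_dir: str = "out"
    target_rows: int = 96
    target_cols: int = 128
    normalize: bool = True
    use_segmentation: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.target_rows <= 0 or self.target_cols <= 0:
            raise ValueError("target size must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, image_paths: Sequence, truth_masks=None):
    """Run the staged pipeline over images, returning per-image JSON records.

    Stages: (1) segment, (2) overlay mask on image, (3) regress count and
    weight from the masked image.  With ``use_segmentation=False`` stage 3
    consumes the raw image directly.  If ``truth_masks`` paths are supplied,
    each record also carries the IoU of the predicted mask.
    """
    from .counting import CNNYieldRegressor
    from .metrics import iou
    from .overlay import overlay
    from .segmentation import UNetSegmenter

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.counter_checkpoint is None:
        raise FileNotFoundError("counter checkpoint is required to run the pipeline")
    counter = CNNYieldRegressor.load(config.counter_checkpoint)
    segmenter = None
    if config.use_segmentation:
        if config.seg_checkpoint is None:
            raise FileNotFoundError(
                "segmentation checkpoint required when use_segmentation is true"
            )
        segmenter = UNetSegmenter.load(config.seg_checkpoint)

    shape = (config.target_rows, config.target_cols)
    records = []
    for i, path in enumerate(image_paths):
        try:
            img = load_image(path)
            if config.normalize:
                img = normalize_image(img)
            img = resize_image(img, shape)
            rec = {"image": str(path), "config_hash": config.config_hash()}
            if segmenter is not None:
                mask = segmenter.predict(img[None])[0]
                stage3_input = overlay(img, mask).image
                if truth_masks is not None:
                    truth = resize_mask(load_mask(truth_masks[i]), shape)
                    rec["iou"] = iou(mask, truth)
            else:
                stage3_input = img
            pred = counter.predict(stage3_input[None])[0]
            rec.update(
                count_raw=float(pred[0]),
                count_int=int(round(float(pred[0]))),
                weight_g=float(pred[1]),
            )
            records.append(rec)
            log.info("pipeline image=%s count=%.2f weight=%.1f", path, pred[0], pred[1])
        except (OSError, ValueError) as exc:
            log.error("pipeline failed on %s: %s", path, exc)
            records.append({"image": str(path), "error": str(exc)})
    return records
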