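"""Stage 2: mask overlay.

Combines the stage-1 mask with the original image so that only grape-cluster
pixels remain; everything outside the mask is set to a constant fill
(black by default), which is what the stage-3 counting network consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaskedImage", "overlay"]


@dataclass
class MaskedImage:
    """An image with background suppressed: pixels where ``source_mask == 0``
    equal the fill value exactly."""

    image: np.ndarray
    source_mask: np.ndarray


def overlay(image: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> MaskedImage:
    """Keep image pixels under the mask, replace the rest with ``fill``.

    Idempotent: re-applying the same mask leaves the result unchanged.
    """
    img = np.asarray(image, dtype=np.float32)
    m = np.asarray(mask)
    if img.shape[:2] != m.shape[:2]:
        raise ValueError(f"image {img.shape[:2]} and mask {m.shape[:2]} shapes differ")
    mb = m.astype(bool)
    if mb.ndim == 2 and img.ndim == 3:
        mb = mb[..., None]
    out = np.where(mb, img, np.float32(fill))
    return MaskedImage(image=out, source_mask=np.asarray(m).astype(np.uint8))
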