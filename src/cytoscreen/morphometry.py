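"""Nucleus gray-value and size morphometry.

Nuclear enlargement and hyperchromasia are the core cytologic markers of
cervical intraepithelial lesions.  For targets whose refined class is SC,
ASC_L_S, or ASC_H_S a segmentation mask (produced upstream) is paired with
the image crop; this module reduces the pair to :class:`NucleusStats`:
mean gray value under the mask, pixel area, physical area at the scan
resolution of 0.25 um/pixel, and the number of connected mask components.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import label as _cc_label

from .records import NucleusStats

__all__ = ["MICRONS_PER_PIXEL", "UM2_PER_PIXEL", "to_grayscale",
           "nucleus_stats", "EmptyMaskError"]

#: Scanner resolution assumed throughout the pipeline.
MICRONS_PER_PIXEL = 0.25
#: Physical area of one pixel: 0.25 um * 0.25 um.
UM2_PER_PIXEL = MICRONS_PER_PIXEL ** 2

# ITU-R BT.601 luminance weights (the stated grayscale convention).
_LUMA = np.array([0.299, 0.587, 0.114])


class EmptyMaskError(ValueError):
    """Mask with no foreground pixel — upstream segmentation failed."""


def to_grayscale(rgb_image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB crop to single-channel gray (BT.601 weights).

    Output is uint8, rounded half-away-from-zero via ``np.rint`` banker's
    rounding on the weighted sum.
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {img.shape}")
    gray = img.astype(np.float64) @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def nucleus_stats(gray_image: np.ndarray, mask: np.ndarray) -> NucleusStats:
    """Morphometry of the masked nucleus region.

    ``mask`` may be boolean or 0/255; it must match the image shape and
    contain at least one foreground pixel.  Multiple connected components
    are summarized jointly, with their count recorded.
    """
    gray = np.asarray(gray_image)
    m = np.asarray(mask)
    if m.shape != gray.shape:
        raise ValueError(
            f"mask shape {m.shape} does not match image shape {gray.shape}")
    m = m.astype(bool)
    area_px = int(m.sum())
    if area_px == 0:
        raise EmptyMaskError("segmentation mask has no foreground pixel")
    mean_gray = float(gray[m].mean())
    n_components = int(_cc_label(m, connectivity=2).max())
    return NucleusStats(
        mean_gray=mean_gray,
        area_px=area_px,
        area_um2=area_px * UM2_PER_PIXEL,
        n_components=n_components,
    )
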