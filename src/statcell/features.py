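"""Segmentation and the 14-feature morphology extractor.

For each of the two reference channels (cell, nucleus) of a 2D image we
compute three shape features — area, circumference, circularity
(4*pi*A/P^2, the 2D reading of sphericity) — and four intensity features —
median, mean, standard deviation, and Shannon entropy (bits, 256-bin 8-bit
histogram) — over the segmented mask.  Segmentation is adaptive
thresholding with an arithmetic mean filter (block size 199 by default)
on the image rescaled to 8-bit, keeping the largest connected component.

These features quantify real-versus-generated similarity: distributions of
features measured on model samples are compared against those of the input
population, per beta.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.measure import label as cc_label, perimeter_crofton

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("area", "circumference", "circularity", "median", "mean", "std", "entropy")


def _to_8bit(channel: np.ndarray) -> np.ndarray:
    lo, hi = float(channel.min()), float(channel.max())
    if hi == lo:
        return np.zeros(channel.shape, dtype=np.uint8)
    return np.clip((channel - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)


def segment_channel(channel: np.ndarray, block_size: int = 199) -> np.ndarray:
    """Foreground mask by local arithmetic-mean thresholding on 8-bit data.

    The block size must be odd (it defines a centered window).  The largest
    connected component is kept; an empty result is returned (with a
    warning) rather than raised, and downstream features report zeros.
    """
    if channel.ndim != 2:
        raise ValueError("segmentation operates on single 2D channels")
    if block_size % 2 == 0:
        raise ValueError(f"block size must be odd, got {block_size}")
    img = _to_8bit(channel).astype(np.float64)
    if img.max() == 0:
        logger.warning("constant channel: empty mask")
        return np.zeros(channel.shape, dtype=bool)
    bs = min(block_size, (min(channel.shape) // 2) * 2 + 1)
    thresh = threshold_local(img, block_size=bs, method="mean")
    mask = img > thresh
    if not mask.any():
        logger.warning("adaptive threshold produced an empty mask")
        return mask
    lab, n = cc_label(mask, return_num=True)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = lab == np.argmax(sizes)
    return mask


def shape_features(mask: np.ndarray) -> tuple[float, float, float]:
    """(area, circumference, circularity) of a binary mask.

    The circumference is the Crofton perimeter (4-direction), which
    corrects the staircase bias of naive boundary counting; circularity is
    4*pi*area/circumference^2, 1 for an ideal disk.
    """
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        return 0.0, 0.0, 0.0
    circ = float(perimeter_crofton(mask, directions=4))
    if circ == 0:  # single pixel or degenerate line
        return area, 0.0, 0.0
    return area, circ, min(4.0 * np.pi * area / circ**2, 1.0)


def intensity_features(
    channel: np.ndarray, mask: np.ndarray
) -> tuple[float, float, float, float]:
    """(median, mean, std, entropy-bits) of the channel inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0, 0.0, 0.0, 0.0
    vals = channel[mask]
    v8 = _to_8bit(channel)[mask]
    hist = np.bincount(v8, minlength=256).astype(np.float64)
    p = hist / hist.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    return float(np.median(vals)), float(vals.mean()), float(vals.std()), entropy


def channel_features(channel: np.ndarray, block_size: int = 199) -> dict[str, float]:
    mask = segment_channel(channel, block_size)
    area, circ, circularity = shape_features(mask)
    med, mean, std, ent = intensity_features(channel, mask)
    return {
        "area": area,
        "circumference": circ,
        "circularity": circularity,
        "median": med,
        "mean": mean,
        "std": std,
        "entropy": ent,
    }


def feature_table(images, block_size: int = 199) -> pd.DataFrame:
    """One 14-feature row per image: 7 features x {cell, nucleus} channels.

    ``images`` is an iterable of (2+)-channel 2D arrays or
    :class:`~statcell.image.CellImage` objects; channel 0 is the membrane
    (cell) channel and channel 1 the nucleus.  Column order is fixed:
    cell_* then nucleus_*, each in (area, circumference, circularity,
    median, mean, std, entropy) order.
    """
    from .image import CellImage

    rows = []
    for im in images:
        arr = im.data if isinstance(im, CellImage) else np.asarray(im)
        if arr.ndim != 3 or arr.shape[0] < 2:
            raise ValueError("each image needs >= 2 channels and 2D spatial axes")
        row = {}
        for prefix, ch in (("cell", arr[0]), ("nucleus", arr[1])):
            for k, v in channel_features(ch, block_size).items():
                row[f"{prefix}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
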