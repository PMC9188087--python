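"""Deterministic histology-image editing operators.

Histology edits — contrast stretching, histogram equalization, light
denoising, color-keyed transparency, brightness — are often what makes
faint tissue structure visible under a spot overlay. Every operator here
takes and returns an :class:`~visiumview.core_model.RGBAImage`, preserves
the image dimensions, never touches the alpha channel except
:func:`transparent`, and is bit-deterministic.

All semantics are defined precisely in this module (clip percentages, CDF
remap, neighborhood weights, fuzz as a percentage of the maximum Euclidean
RGB distance) so that results are reproducible across environments.
"""

from __future__ import annotations

import numpy as np

from .core_model import RGBAImage

MAX_RGB_DISTANCE = float(np.sqrt(3.0) * 255.0)

# CSS basic colors plus pink, for color-key transparency
NAMED_COLORS = {
    "black": (0, 0, 0), "white": (255, 255, 255), "red": (255, 0, 0),
    "lime": (0, 255, 0), "green": (0, 128, 0), "blue": (0, 0, 255),
    "yellow": (255, 255, 0), "cyan": (0, 255, 255), "aqua": (0, 255, 255),
    "magenta": (255, 0, 255), "fuchsia": (255, 0, 255),
    "silver": (192, 192, 192), "gray": (128, 128, 128),
    "grey": (128, 128, 128), "maroon": (128, 0, 0), "olive": (128, 128, 0),
    "purple": (128, 0, 128), "teal": (0, 128, 128), "navy": (0, 0, 128),
    "pink": (255, 192, 203),
}


def resolve_color(color) -> tuple[int, int, int]:
    """Resolve a named color or RGB triple to an (r, g, b) tuple."""
    if isinstance(color, str):
        key = color.lower()
        if key not in NAMED_COLORS:
            raise ValueError(f"unknown color name {color!r}; known names: "
                             f"{', '.join(sorted(NAMED_COLORS))}")
        return NAMED_COLORS[key]
    rgb = tuple(int(c) for c in color)
    if len(rgb) != 3 or any(c < 0 or c > 255 for c in rgb):
        raise ValueError(f"invalid RGB triple: {color!r}")
    return rgb


def normalize(img: RGBAImage, low_clip_percent: float = 2.0,
              high_clip_percent: float = 1.0) -> RGBAImage:
    """Per-channel linear contrast stretch with percentile clipping.

    The darkest ``low_clip_percent`` and brightest ``high_clip_percent`` of
    pixels are clipped per channel, then the remaining range is stretched
    to [0, 255]. A constant channel is left unchanged.
    """
    px = img.pixels.copy()
    for ch in range(3):
        chan = px[:, :, ch].astype(float)
        lo = np.percentile(chan, low_clip_percent)
        hi = np.percentile(chan, 100.0 - high_clip_percent)
        if hi <= lo:
            continue
        stretched = (np.clip(chan, lo, hi) - lo) * (255.0 / (hi - lo))
        px[:, :, ch] = np.round(stretched).astype(np.uint8)
    return RGBAImage(px, img.resolution_tag)


def equalize(img: RGBAImage) -> RGBAImage:
    """Per-channel histogram equalization.

    Standard CDF remap: ``v' = round(255 * (cdf(v) - cdf_min) / (1 - cdf_min))``
    where ``cdf`` is the cumulative pixel fraction and ``cdf_min`` the CDF at
    the lowest occupied level. A constant channel is unchanged.
    """
    px = img.pixels.copy()
    n = px.shape[0] * px.shape[1]
    for ch in range(3):
        chan = px[:, :, ch]
        hist = np.bincount(chan.ravel(), minlength=256)
        cdf = np.cumsum(hist) / n
        occupied = np.flatnonzero(hist)
        cdf_min = cdf[occupied[0]]
        if cdf_min >= 1.0:  # constant channel
            continue
        lut = np.round(255.0 * (cdf - cdf_min) / (1.0 - cdf_min))
        px[:, :, ch] = np.clip(lut, 0, 255).astype(np.uint8)[chan]
    return RGBAImage(px, img.resolution_tag)


def enhance(img: RGBAImage, distance_threshold_percent: float = 15.0,
            center_weight: float = 2.0) -> RGBAImage:
    """Edge-preserving 3×3 noise reduction.

    Each pixel is replaced by the weighted mean of itself (weight
    ``center_weight``) and its 3×3 neighbors whose Euclidean RGB distance to
    it is at most ``distance_threshold_percent`` of the maximum RGB distance
    (weight 1 each). Neighbors across an edge in color space are thus
    excluded, smoothing noise without blurring tissue boundaries. Image
    borders use the neighbors that exist.
    """
    rgb = img.pixels[:, :, :3].astype(float)
    h, w, _ = rgb.shape
    threshold = (distance_threshold_percent / 100.0) * MAX_RGB_DISTANCE
    acc = rgb * center_weight
    wsum = np.full((h, w), center_weight)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(rgb, np.nan)
            src_r = slice(max(0, -dr), h - max(0, dr))
            dst_r = slice(max(0, dr), h - max(0, -dr))
            src_c = slice(max(0, -dc), w - max(0, dc))
            dst_c = slice(max(0, dc), w - max(0, -dc))
            shifted[dst_r, dst_c] = rgb[src_r, src_c]
            valid = np.isfinite(shifted[:, :, 0])
            dist = np.sqrt(np.nansum((shifted - rgb) ** 2, axis=2))
            use = valid & (dist <= threshold)
            acc[use] += shifted[use]
            wsum[use] += 1.0
    out = img.pixels.copy()
    out[:, :, :3] = np.round(acc / wsum[:, :, None]).astype(np.uint8)
    return RGBAImage(out, img.resolution_tag)


def transparent(img: RGBAImage, key_color, fuzz_percent: float) -> RGBAImage:
    """Make pixels matching a key color transparent.

    Pixels whose Euclidean RGB distance to ``key_color`` is at most
    ``fuzz_percent`` percent of the maximum distance (√3 × 255) get alpha 0;
    all other pixels are unchanged. ``key_color`` may be an RGB triple or a
    named color (e.g. ``"pink"`` → (255, 192, 203)).
    """
    if not (0.0 <= fuzz_percent <= 100.0):
        raise ValueError(f"fuzz_percent must be in [0, 100], got {fuzz_percent}")
    key = np.array(resolve_color(key_color), dtype=float)
    px = img.pixels.copy()
    dist = np.sqrt(((px[:, :, :3].astype(float) - key) ** 2).sum(axis=2))
    px[:, :, 3] = np.where(dist <= (fuzz_percent / 100.0) * MAX_RGB_DISTANCE,
                           0, px[:, :, 3])
    return RGBAImage(px, img.resolution_tag)


def brightness(img: RGBAImage, percent: float) -> RGBAImage:
    """Scale RGB channels by ``percent``/100 (100 = identity), clipped."""
    if percent < 0:
        raise ValueError(f"brightness percent must be >= 0, got {percent}")
    px = img.pixels.copy()
    scaled = px[:, :, :3].astype(float) * (percent / 100.0)
    px[:, :, :3] = np.clip(np.round(scaled), 0, 255).astype(np.uint8)
    return RGBAImage(px, img.resolution_tag)


OPS = {"normalize": normalize, "equalize": equalize, "enhance": enhance}


def apply_ops(img: RGBAImage, op_names) -> RGBAImage:
    """Apply a left-to-right chain of parameter-free operators by name."""
    for name in op_names:
        if name not in OPS:
            raise ValueError(f"unknown image operation {name!r}; "
                             f"valid: {', '.join(sorted(OPS))}")
        img = OPS[name](img)
    return img
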