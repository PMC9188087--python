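"""Color scales and categorical palettes.

A fixed registry of nine named continuous scales, each reversible, covers
the continuous-variable plots; most are perceptually-uniform
colorblind-friendly scales (the viridis family plus seaborn's rocket and
mako), rounded out by turbo and greys. Categorical variables draw from a
deterministic 36-color cycle assigned in sorted-label order, so the same
cluster label gets the same color in every sample and every plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import matplotlib
import numpy as np
import seaborn as sns

logger = logging.getLogger(__name__)

_N_SAMPLES = 256
NA_COLOR = (128, 128, 128)  # mid-grey for missing values


def _sample_cmap(cmap) -> list[tuple[int, int, int]]:
    xs = np.linspace(0.0, 1.0, _N_SAMPLES)
    rgba = cmap(xs)
    return [tuple(int(round(c * 255)) for c in row[:3]) for row in rgba]


def _build_registry() -> dict[str, list[tuple[int, int, int]]]:
    reg = {}
    for name, mpl_name in [("viridis", "viridis"), ("magma", "magma"),
                           ("inferno", "inferno"), ("plasma", "plasma"),
                           ("cividis", "cividis"), ("turbo", "turbo"),
                           ("greys", "Greys")]:
        reg[name] = _sample_cmap(matplotlib.colormaps[mpl_name])
    for name in ("rocket", "mako"):
        reg[name] = _sample_cmap(sns.color_palette(name, as_cmap=True))
    return reg


_REGISTRY = _build_registry()

SCALE_NAMES = tuple(sorted(_REGISTRY))  # exactly nine


@dataclass(frozen=True)
class ColorScale:
    """A named ordered list of RGB triples, optionally reversed."""

    name: str
    colors: tuple
    reversed: bool = False

    def reverse(self) -> "ColorScale":
        return ColorScale(self.name, tuple(self.colors[::-1]),
                          not self.reversed)


def get_scale(name: str, reversed: bool = False) -> ColorScale:
    """Look up one of the nine registered continuous scales.

    With ``reversed=True`` the gradient order is flipped, so the minimum
    value maps to what is normally the scale's high end (e.g. reversed
    magma renders low values in near-white).
    """
    if name not in _REGISTRY:
        raise ValueError(f"unknown color scale {name!r}; valid scales: "
                         f"{', '.join(SCALE_NAMES)}")
    colors = tuple(_REGISTRY[name])
    if reversed:
        colors = colors[::-1]
    return ColorScale(name=name, colors=colors, reversed=reversed)


def map_continuous(values, scale: ColorScale,
                   na_color=NA_COLOR,
                   vmin: float | None = None,
                   vmax: float | None = None) -> np.ndarray:
    """Map numeric values to RGB via linear min–max interpolation.

    The finite range (or an explicit ``vmin``/``vmax``, used for shared
    scales across panels) maps linearly onto the color list; an all-equal
    vector maps to the scale midpoint; non-finite values get ``na_color``.
    Returns an ``(n, 3)`` uint8 array.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot color an empty value vector")
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("need at least one finite value")
    lo = np.nanmin(vals[finite]) if vmin is None else vmin
    hi = np.nanmax(vals[finite]) if vmax is None else vmax
    colors = np.asarray(scale.colors, dtype=float)  # (m, 3)
    m = len(colors)
    out = np.empty((vals.size, 3), dtype=np.uint8)
    out[:] = na_color
    if hi > lo:
        t = np.clip((vals[finite] - lo) / (hi - lo), 0.0, 1.0)
    else:
        t = np.full(finite.sum(), 0.5)
    pos = t * (m - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, m - 1)
    frac = (pos - i0)[:, None]
    rgb = colors[i0] * (1 - frac) + colors[i1] * frac
    out[finite] = np.round(rgb).astype(np.uint8)
    return out


# 36-color categorical cycle: tab20 + tab20b's first 16, frozen at import.
def _build_cycle() -> list[tuple[int, int, int]]:
    cyc = []
    for name, take in [("tab20", 20), ("tab20b", 16)]:
        cmap = matplotlib.colormaps[name]
        for i in range(take):
            r, g, b, _ = cmap(i / (cmap.N - 1) if cmap.N > 1 else 0.0)
            cyc.append((int(round(r * 255)), int(round(g * 255)),
                        int(round(b * 255))))
    return cyc


_CATEGORICAL_CYCLE = _build_cycle()


def categorical_palette(labels) -> dict[str, tuple[int, int, int]]:
    """Deterministic label → RGB mapping from a fixed 36-color cycle.

    Colors are assigned in sorted-label order, so the palette is a pure
    function of the label *set* — two samples sharing labels get identical
    colors regardless of input order. Beyond 36 labels the cycle repeats
    with darkened shades (and a warning), keeping the mapping injective.
    """
    labels = sorted({str(l) for l in labels})
    if not labels:
        raise ValueError("label set is empty")
    n_cycle = len(_CATEGORICAL_CYCLE)
    if len(labels) > n_cycle:
        logger.warning("more than %d labels (%d); repeating the color cycle "
                       "with shade perturbation", n_cycle, len(labels))
    palette = {}
    for i, label in enumerate(labels):
        base = _CATEGORICAL_CYCLE[i % n_cycle]
        shade = 0.7 ** (i // n_cycle)
        palette[label] = tuple(int(round(c * shade)) for c in base)
    return palette
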