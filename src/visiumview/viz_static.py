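"""Static spot-map rendering over histology.

Spots are drawn as filled circles at their image-frame centers (radius =
the physical spot footprint scaled into the target frame, times a point
size multiplier), over the histology raster when requested. Figures carry
a ``_visiumview`` metadata dict (centers, colors, radius, value range,
legend) so tests and downstream code can probe the plotted data structures
instead of rasterized pixels.

Orientation: images are drawn with row 0 at the top (raster convention),
and spot centers are (row_px, col_px) in the same frame, so the overlay
needs no y-flip — the y-axis is simply inverted to point downward.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")  # noqa: E402 — headless rendering
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PatchCollection
from matplotlib.lines import Line2D
from matplotlib.patches import Circle

from . import qc_norm
from .core_model import (SpatialDataset, SpatialSample, spot_radius_px,
                         to_image_coords)
from .palettes import (NA_COLOR, ColorScale, categorical_palette, get_scale,
                       map_continuous)

EXPORT_FORMATS = ("pdf", "png")


@dataclass
class PlotSpec:
    """What to plot and how."""

    variable: str
    kind: str = "continuous"  # or "categorical"
    resolution_tag: str = "lowres"
    point_size_multiplier: float = 1.0
    spot_alpha: float = 1.0
    scale: ColorScale | None = None  # continuous
    palette: dict | None = None      # categorical
    show_image: bool = True
    include_out_of_tissue: bool = False
    title: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.spot_alpha <= 1.0):
            raise ValueError(f"spot_alpha must be in [0, 1], "
                             f"got {self.spot_alpha}")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"kind must be continuous or categorical, "
                             f"got {self.kind!r}")


def resolve_continuous(sample: SpatialSample, variable: str) -> np.ndarray:
    """A continuous per-spot vector: a covariate by name, else a gene."""
    if variable in sample.spot_covariates:
        vec = np.asarray(sample.spot_covariates[variable])
        if not np.issubdtype(vec.dtype, np.number):
            raise ValueError(f"covariate {variable!r} is categorical, not "
                             "continuous")
        return vec.astype(float)
    return qc_norm.log_norm_expression(sample, variable)


def resolve_categorical(sample: SpatialSample, variable: str) -> np.ndarray:
    if variable not in sample.spot_covariates:
        raise KeyError(f"unknown categorical variable {variable!r} on sample "
                       f"{sample.sample_id!r}; have "
                       f"{sorted(sample.spot_covariates)}")
    vec = np.asarray(sample.spot_covariates[variable], dtype=object)
    return vec


def _plot_mask(sample: SpatialSample, spec: PlotSpec) -> np.ndarray:
    spots = sample.counted_spots()
    if spec.include_out_of_tissue:
        return np.ones(len(spots), dtype=bool)
    return spots.in_tissue.copy()


def _draw_spots(ax, sample, spec, rgb, mask):
    spots = sample.counted_spots()
    centers = to_image_coords(spots, sample.scalefactors, spec.resolution_tag)
    radius = spot_radius_px(sample.scalefactors, spec.resolution_tag,
                            spec.point_size_multiplier)
    patches = [Circle((c, r), radius)
               for (r, c), m in zip(centers, mask) if m]
    colors = rgb[mask] / 255.0
    coll = PatchCollection(patches, facecolors=colors, edgecolors="none",
                           alpha=spec.spot_alpha)
    ax.add_collection(coll)
    if spec.show_image and spec.resolution_tag in sample.images:
        img = sample.images[spec.resolution_tag]
        ax.imshow(img.pixels, zorder=coll.get_zorder() - 1)
        ax.set_xlim(-0.5, img.pixels.shape[1] - 0.5)
        ax.set_ylim(img.pixels.shape[0] - 0.5, -0.5)
    else:
        pad = 2 * radius
        ax.set_xlim(centers[mask][:, 1].min() - pad,
                    centers[mask][:, 1].max() + pad)
        ax.set_ylim(centers[mask][:, 0].max() + pad,
                    centers[mask][:, 0].min() - pad)  # row axis downward
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    return centers[mask], radius


def _continuous_panel(ax, sample, spec, vmin=None, vmax=None):
    values = resolve_continuous(sample, spec.variable)
    mask = _plot_mask(sample, spec)
    scale = spec.scale or get_scale("viridis")
    finite = values[mask][np.isfinite(values[mask])]
    lo = float(finite.min()) if vmin is None and finite.size else vmin
    hi = float(finite.max()) if vmax is None and finite.size else vmax
    rgb = map_continuous(values, scale, vmin=lo, vmax=hi)
    centers, radius = _draw_spots(ax, sample, spec, rgb, mask)
    cmap = matplotlib.colors.ListedColormap(np.asarray(scale.colors) / 255.0)
    norm = matplotlib.colors.Normalize(vmin=lo, vmax=hi)
    sm = matplotlib.cm.ScalarMappable(norm=norm, cmap=cmap)
    label = spec.variable
    if spec.variable not in sample.spot_covariates:
        label = f"{spec.variable} (log2 CP10K + 1)"
    ax.figure.colorbar(sm, ax=ax, label=label, fraction=0.046)
    return {"centers": centers, "colors": rgb[mask], "radius": radius,
            "vmin": lo, "vmax": hi, "values": values[mask],
            "sample_id": sample.sample_id}


def _categorical_panel(ax, sample, spec, palette=None):
    labels = resolve_categorical(sample, spec.variable)
    mask = _plot_mask(sample, spec)
    present = [l for l in labels[mask] if l is not None]
    if palette is None:
        palette = (spec.palette if spec.palette is not None
                   else (categorical_palette(present) if present else {}))
    rgb = np.array([palette.get(str(l), NA_COLOR) if l is not None
                    else NA_COLOR for l in labels], dtype=np.uint8)
    centers, radius = _draw_spots(ax, sample, spec, rgb, mask)
    handles = [Line2D([], [], marker="o", linestyle="",
                      markerfacecolor=np.array(c) / 255.0,
                      markeredgecolor="none", label=lab)
               for lab, c in sorted(palette.items())]
    if any(l is None for l in labels[mask]):
        handles.append(Line2D([], [], marker="o", linestyle="",
                              markerfacecolor=np.array(NA_COLOR) / 255.0,
                              markeredgecolor="none", label="NA"))
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.0, 0.5),
              frameon=False, fontsize="small")
    return {"centers": centers, "colors": rgb[mask], "radius": radius,
            "palette": dict(palette), "legend": [h.get_label()
                                                 for h in handles],
            "sample_id": sample.sample_id}


def plot_continuous(sample: SpatialSample, spec: PlotSpec):
    """Render one continuous variable as a spot map over histology."""
    fig, ax = plt.subplots(figsize=(5, 5))
    meta = _continuous_panel(ax, sample, spec)
    ax.set_title(spec.title or f"{sample.sample_id}: {spec.variable}")
    fig._visiumview = {"kind": "continuous", "panels": [meta]}
    return fig


def plot_categorical(sample: SpatialSample, spec: PlotSpec):
    """Render one categorical variable (clusters, annotations) as a spot map."""
    fig, ax = plt.subplots(figsize=(6, 5))
    meta = _categorical_panel(ax, sample, spec)
    ax.set_title(spec.title or f"{sample.sample_id}: {spec.variable}")
    fig._visiumview = {"kind": "categorical", "panels": [meta]}
    return fig


def plot_grid(dataset: SpatialDataset, spec: PlotSpec):
    """One panel per sample, sharing a single color scale or palette.

    Continuous variables share the global min–max across all samples;
    categorical variables share one palette built from the union of labels,
    so a given cluster keeps its color in every panel. Layout is ⌈√n⌉
    columns.
    """
    n = len(dataset.samples)
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(nrows, ncols,
                             figsize=(4.5 * ncols, 4.0 * nrows),
                             squeeze=False)
    panels = []
    if spec.kind == "continuous":
        lo, hi = np.inf, -np.inf
        for sample in dataset.samples:
            try:
                vals = resolve_continuous(sample, spec.variable)
            except (KeyError, ValueError) as exc:
                raise type(exc)(f"variable {spec.variable!r} not resolvable "
                                f"on sample {sample.sample_id!r}: {exc}")
            m = _plot_mask(sample, spec)
            finite = vals[m][np.isfinite(vals[m])]
            if finite.size:
                lo = min(lo, float(finite.min()))
                hi = max(hi, float(finite.max()))
        for i, sample in enumerate(dataset.samples):
            ax = axes[i // ncols][i % ncols]
            panels.append(_continuous_panel(ax, sample, spec,
                                            vmin=lo, vmax=hi))
            ax.set_title(sample.sample_id)
    else:
        all_labels = set()
        for sample in dataset.samples:
            try:
                labels = resolve_categorical(sample, spec.variable)
            except KeyError as exc:
                raise KeyError(f"variable {spec.variable!r} missing on "
                               f"sample {sample.sample_id!r}") from exc
            all_labels.update(str(l) for l in labels if l is not None)
        palette = (spec.palette if spec.palette is not None
                   else categorical_palette(all_labels))
        for i, sample in enumerate(dataset.samples):
            ax = axes[i // ncols][i % ncols]
            panels.append(_categorical_panel(ax, sample, spec,
                                             palette=palette))
            ax.set_title(sample.sample_id)
    for j in range(n, nrows * ncols):
        axes[j // ncols][j % ncols].set_visible(False)
    fig.suptitle(spec.title or spec.variable)
    fig._visiumview = {"kind": spec.kind, "panels": panels,
                       "ncols": ncols, "nrows": nrows}
    return fig


def plot_side_by_side(sample: SpatialSample, spec: PlotSpec,
                      left_image=None):
    """Histology alone (left) next to the spot map (right), axes aligned.

    ``left_image`` overrides the sample's stored image — pass an edited
    raster (equalized, color-keyed, ...) to recreate the classic
    histology-vs-clusters composition.
    """
    fig, (ax_l, ax_r) = plt.subplots(1, 2, figsize=(11, 5))
    img = left_image if left_image is not None \
        else sample.images.get(spec.resolution_tag)
    if img is None:
        raise ValueError(f"sample {sample.sample_id!r} has no "
                         f"{spec.resolution_tag} image")
    ax_l.imshow(img.pixels)
    ax_l.set_xticks([])
    ax_l.set_yticks([])
    ax_l.set_title("histology")
    if spec.kind == "continuous":
        meta = _continuous_panel(ax_r, sample, spec)
    else:
        meta = _categorical_panel(ax_r, sample, spec)
    ax_r.set_title(spec.variable)
    h, w = img.pixels.shape[:2]
    for ax in (ax_l, ax_r):
        ax.set_xlim(-0.5, w - 0.5)
        ax.set_ylim(h - 0.5, -0.5)
        ax.set_aspect("equal")
    fig._visiumview = {"kind": f"side_by_side:{spec.kind}", "panels": [meta],
                       "axis_limits": (ax_l.get_xlim(), ax_l.get_ylim())}
    return fig


def export_figure(fig, path: str, format: str | None = None,
                  dpi: int = 150) -> str:
    """Write a rendered figure as PDF or PNG."""
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    if format not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {format!r}; "
                         f"valid: {', '.join(EXPORT_FORMATS)}")
    fig.savefig(path, format=format, dpi=dpi, bbox_inches="tight")
    return path


def export_figures(figures: dict, out_dir: str, basename: str,
                   format: str = "pdf", dpi: int = 150) -> list[str]:
    """Batch export: one file per figure, suffixed with its sample id."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for suffix, fig in figures.items():
        path = os.path.join(out_dir, f"{basename}_{suffix}.{format}")
        paths.append(export_figure(fig, path, format=format, dpi=dpi))
    return paths
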