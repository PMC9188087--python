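"""Manual spot annotation: geometric selection, labeling, covariate export.

Annotating spots — e.g. assigning cortical layers from known marker genes —
is done by selecting spots (by polygon in image coordinates, or by barcode
list) and attaching a label. Annotations live in a flat
(sample_id, barcode, label) table that round-trips to CSV and can be
injected back into a dataset as a categorical covariate for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import SpatialDataset, SpatialSample, to_image_coords

ANNOTATION_COLUMNS = ["sample_id", "barcode", "label"]


@dataclass
class AnnotationTable:
    """Rows of (sample_id, barcode, label); one label per spot."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ANNOTATION_COLUMNS))

    def __post_init__(self) -> None:
        if list(self.df.columns) != ANNOTATION_COLUMNS:
            raise ValueError(f"annotation table columns must be "
                             f"{ANNOTATION_COLUMNS}, got {list(self.df.columns)}")
        if self.df.duplicated(["sample_id", "barcode"]).any():
            raise ValueError("(sample_id, barcode) pairs must be unique")
        self.df = self.df.reset_index(drop=True).astype(str)
        if len(self.df) and (self.df["label"] == "").any():
            raise ValueError("empty labels are not stored; use label_spots "
                             "with an empty label to delete rows")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        a = self.df.sort_values(["sample_id", "barcode"]).reset_index(drop=True)
        b = other.df.sort_values(["sample_id", "barcode"]).reset_index(drop=True)
        return a.equals(b)

    def labels_for(self, sample_id: str) -> dict[str, str]:
        sub = self.df[self.df["sample_id"] == sample_id]
        return dict(zip(sub["barcode"], sub["label"]))


def _on_segment(px, py, ax, ay, bx, by, eps=1e-9) -> bool:
    """True if point p lies on segment a-b (within eps)."""
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    seg_len = np.hypot(bx - ax, by - ay)
    if seg_len == 0:
        return np.hypot(px - ax, py - ay) <= eps
    if abs(cross) / seg_len > eps:
        return False
    dot = (px - ax) * (bx - ax) + (py - ay) * (by - ay)
    return -eps * seg_len <= dot <= seg_len * seg_len + eps * seg_len


def point_in_polygon(point, vertices) -> bool:
    """Even-odd rule point-in-polygon test; boundary counts as inside."""
    px, py = float(point[0]), float(point[1])
    verts = [(float(x), float(y)) for x, y in vertices]
    n = len(verts)
    inside = False
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        if _on_segment(px, py, ax, ay, bx, by):
            return True
        # even-odd ray cast along +x
        if (ay > py) != (by > py):
            x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_cross:
                inside = not inside
    return inside


def select_in_polygon(sample: SpatialSample, polygon, resolution_tag: str,
                      in_tissue_only: bool = True) -> list[str]:
    """Barcodes of spots whose centers fall inside a polygon.

    The polygon is an ordered vertex list of ``(row_px, col_px)`` pairs in
    the pixel frame named by ``resolution_tag``; containment uses the
    even-odd rule, with centers on the boundary counted as inside.
    """
    polygon = list(polygon)
    if len(polygon) < 3:
        raise ValueError(f"polygon needs at least 3 vertices, got {len(polygon)}")
    spots = sample.counted_spots()
    centers = to_image_coords(spots, sample.scalefactors, resolution_tag)
    selected = []
    for i, bc in enumerate(spots.barcode):
        if in_tissue_only and not spots.in_tissue[i]:
            continue
        if point_in_polygon(centers[i], polygon):
            selected.append(str(bc))
    return selected


def label_spots(ann: AnnotationTable, sample: SpatialSample,
                barcodes, label: str) -> AnnotationTable:
    """Upsert labels for barcodes of one sample; empty label deletes.

    Returns a new table; relabeling overwrites the previous label.
    Unknown barcodes raise, listing the offenders.
    """
    barcodes = [str(b) for b in barcodes]
    known = set(sample.counts.barcodes)
    bad = [b for b in barcodes if b not in known]
    if bad:
        raise ValueError(f"barcodes not in sample {sample.sample_id!r}: {bad}")
    df = ann.df.copy()
    drop = (df["sample_id"] == sample.sample_id) & df["barcode"].isin(barcodes)
    df = df[~drop]
    if label != "":
        new = pd.DataFrame({"sample_id": sample.sample_id,
                            "barcode": barcodes, "label": label})
        df = pd.concat([df, new], ignore_index=True)
    return AnnotationTable(df.reset_index(drop=True))


def annotations_to_covariate(ann: AnnotationTable, dataset: SpatialDataset,
                             name: str, overwrite: bool = False
                             ) -> SpatialDataset:
    """Materialize annotations as a categorical covariate on every sample.

    Unannotated spots get a missing label (None). The covariate is then
    plottable like any imported clustering.
    """
    ds_ids = {s.sample_id for s in dataset.samples}
    extra = set(ann.df["sample_id"]) - ds_ids
    if extra:
        raise ValueError(f"annotations reference unknown samples: {sorted(extra)}")
    for sample in dataset.samples:
        if name in sample.spot_covariates and not overwrite:
            raise ValueError(f"covariate {name!r} already exists on sample "
                             f"{sample.sample_id!r} (pass overwrite=True)")
        labels = ann.labels_for(sample.sample_id)
        vec = np.array([labels.get(b) for b in sample.counts.barcodes],
                       dtype=object)
        sample.spot_covariates[name] = vec
    return dataset
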