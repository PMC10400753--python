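"""Quantitative histomorphometry of coronary capillaries and fibrosis.

Works on segmentation masks (not raw stains): a binary or labelled mask of
capillary walls, an optional lumen mask, and collagen/myocardium masks from
a Picro-Sirius-Red-type stain.  Capillary cross-sections are extracted as
8-connected components; their ellipse-equivalent axes (from second moments)
give an aspect ratio that classifies the cutting plane as transverse
(AR < 1.5), oblique (1.5 <= AR < 3) or longitudinal (AR >= 3) -- threshold
values are an operational choice and are exposed as parameters.  Lumina are
enclosed background holes (or a provided lumen mask) fully inside a
component.  Summaries follow the study conventions: total wall area as % of
tissue area, per-class percentages of total wall area, mean lumen area of
lumen-bearing oblique/transverse capillaries, and the smallest averaged
edge-to-edge distance between oblique/transverse capillaries.  Fibrosis is
% collagen of the whole section, collagen / (collagen + myocardium).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "CapillaryComponentTable",
    "MorphometrySummary",
    "FibrosisResult",
    "ORIENTATION_THRESHOLDS",
    "extract_components",
    "summarize_architecture",
    "collagen_fraction",
]

#: Aspect-ratio cut points (transverse | oblique | longitudinal).
ORIENTATION_THRESHOLDS = (1.5, 3.0)

IN_PLANE_CLASSES = ("oblique", "transverse")


@dataclass(frozen=True)
class CapillaryComponentTable:
    """Per-capillary-component measurements plus boundary pixel lists."""

    table: pd.DataFrame             # indexed by component id
    boundaries: dict                # id -> (n, 2) array of boundary pixels
    pixel_size: float               # um per pixel

    def __len__(self):
        return len(self.table)


@dataclass(frozen=True)
class MorphometrySummary:
    wall_area_fraction: float       # % of tissue area
    class_percent: dict             # class -> % of total wall area
    mean_lumen_area: float          # um^2, lumen-bearing oblique+transverse
    mean_nearest_distance: float    # um, oblique+transverse only (NaN if <2)
    n_components: int
    flags: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class FibrosisResult:
    collagen_percent: float
    collagen_area: int              # px^2
    myocardium_area: int            # px^2
    flags: tuple = field(default_factory=tuple)


def _orientation_class(aspect_ratio: float, thresholds) -> str:
    lo, hi = thresholds
    if aspect_ratio < lo:
        return "transverse"
    if aspect_ratio < hi:
        return "oblique"
    return "longitudinal"


def _as_labeled(mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return measure.label(mask, connectivity=2)
    if np.issubdtype(mask.dtype, np.integer):
        vals = np.unique(mask)
        if vals.size <= 2 and set(vals.tolist()) <= {0, 1}:
            return measure.label(mask.astype(bool), connectivity=2)
        return mask.astype(np.int64)
    raise TypeError("capillary mask must be boolean/binary or integer-labelled")


def extract_components(capillary_mask, lumen_mask=None, pixel_size: float = 1.0,
                       thresholds=ORIENTATION_THRESHOLDS) -> CapillaryComponentTable:
    """Extract capillary cross-sections from a wall mask.

    8-connected components; ellipse-equivalent major/minor axes from second
    moments; orientation class from the aspect ratio; lumen = enclosed
    background hole (or the part of ``lumen_mask`` fully inside the filled
    component).  An empty mask yields an empty table.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    labeled = _as_labeled(capillary_mask)
    if lumen_mask is not None:
        lumen_mask = np.asarray(lumen_mask).astype(bool)
        if lumen_mask.shape != labeled.shape:
            raise ValueError("lumen mask shape must match the capillary mask")

    rows = []
    boundaries = {}
    for rp in measure.regionprops(labeled):
        comp = labeled == rp.label
        filled = ndi.binary_fill_holes(comp)
        if lumen_mask is None:
            lum = filled & ~comp
        else:
            lum = lumen_mask & filled
        lumen_px = int(lum.sum())
        minor = rp.axis_minor_length
        ar = rp.axis_major_length / minor if minor > 0 else np.inf
        border = comp & ~ndi.binary_erosion(comp)
        boundaries[rp.label] = np.argwhere(border)
        rows.append({
            "id": rp.label,
            "area_px": int(rp.area),
            "area_um2": rp.area * pixel_size ** 2,
            "centroid_row": rp.centroid[0],
            "centroid_col": rp.centroid[1],
            "major_axis_px": rp.axis_major_length,
            "minor_axis_px": minor,
            "aspect_ratio": float(ar),
            "orientation_class": _orientation_class(ar, thresholds),
            "lumen_present": lumen_px > 0,
            "lumen_area_um2": lumen_px * pixel_size ** 2,
        })
    cols = ["id", "area_px", "area_um2", "centroid_row", "centroid_col",
            "major_axis_px", "minor_axis_px", "aspect_ratio",
            "orientation_class", "lumen_present", "lumen_area_um2"]
    table = pd.DataFrame(rows, columns=cols).set_index("id")
    return CapillaryComponentTable(table=table, boundaries=boundaries,
                                   pixel_size=float(pixel_size))


def nearest_edge_distances(components: CapillaryComponentTable,
                           classes=IN_PLANE_CLASSES) -> pd.Series:
    """Per component (restricted to ``classes``): the minimum edge-to-edge
    boundary-pixel distance to any other component of those classes, in um."""
    tab = components.table
    ids = list(tab.index[tab["orientation_class"].isin(classes)])
    out = pd.Series(np.nan, index=ids, dtype=float)
    if len(ids) < 2:
        return out
    trees = {i: cKDTree(components.boundaries[i]) for i in ids}
    for i in ids:
        pts = components.boundaries[i]
        best = np.inf
        for j in ids:
            if j == i:
                continue
            d = trees[j].query(pts, k=1)[0].min()
            best = min(best, d)
        out[i] = best * components.pixel_size
    return out


def summarize_architecture(components: CapillaryComponentTable,
                           tissue_area: float) -> MorphometrySummary:
    """Study-style capillary architecture summary.

    ``tissue_area`` is in um^2.  Wall area fraction is 100 * total wall
    area / tissue area; class percentages are of total wall area; the mean
    lumen area is over lumen-bearing oblique/transverse components; the
    nearest-neighbour distance averages each oblique/transverse component's
    minimal edge-to-edge distance to any other such component.
    """
    if tissue_area <= 0:
        raise ValueError("tissue_area must be positive")
    tab = components.table
    flags = []
    n = len(tab)
    total_wall = float(tab["area_um2"].sum()) if n else 0.0
    wall_frac = 100.0 * total_wall / tissue_area

    class_percent = {c: 0.0 for c in ("longitudinal", "oblique", "transverse")}
    if n and total_wall > 0:
        by = tab.groupby("orientation_class")["area_um2"].sum()
        for c in class_percent:
            class_percent[c] = 100.0 * float(by.get(c, 0.0)) / total_wall

    inplane = tab[tab["orientation_class"].isin(IN_PLANE_CLASSES)]
    with_lumen = inplane[inplane["lumen_present"]]
    mean_lumen = float(with_lumen["lumen_area_um2"].mean()) if len(with_lumen) \
        else float("nan")
    if not len(with_lumen):
        flags.append("no lumen-bearing oblique/transverse capillaries")

    dists = nearest_edge_distances(components)
    if dists.notna().any():
        mean_dist = float(dists.mean())
    else:
        mean_dist = float("nan")
        flags.append("fewer than 2 oblique/transverse components: "
                     "nearest distance undefined")

    return MorphometrySummary(wall_area_fraction=wall_frac,
                              class_percent=class_percent,
                              mean_lumen_area=mean_lumen,
                              mean_nearest_distance=mean_dist,
                              n_components=n, flags=tuple(flags))


def collagen_fraction(collagen_mask, myocardium_mask) -> FibrosisResult:
    """Fibrosis degree: % collagen of the section, collagen/(collagen+myocardium)."""
    col = np.asarray(collagen_mask).astype(bool)
    myo = np.asarray(myocardium_mask).astype(bool)
    if col.shape != myo.shape:
        raise ValueError("masks must have the same shape")
    if (col & myo).any():
        raise ValueError("collagen and myocardium masks overlap")
    c, m = int(col.sum()), int(myo.sum())
    if c + m == 0:
        warnings.warn("both masks empty: collagen fraction undefined", RuntimeWarning)
        return FibrosisResult(collagen_percent=float("nan"), collagen_area=0,
                              myocardium_area=0, flags=("empty masks",))
    return FibrosisResult(collagen_percent=100.0 * c / (c + m),
                          collagen_area=c, myocardium_area=m)
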