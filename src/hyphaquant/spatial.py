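"""Tip intensity profiles, septal Woronin-body scoring, and leakage measurement.

Tip line scans average a 20-px-wide band along a tip-first trace of a max-Z
projection, subtract each cell's own background, and bin by distance from the
tip.  Septal crops are classified by which side(s) of the septal plane carry
488-channel puncta within 1 um.  Septal intensity uses a 0.5 x 1 um rectangle
centered on the septum with an adjacent same-size background rectangle.
Cytoplasmic leakage is the background-corrected integrated density of a
puddle ROI on a sum-Z projection, normalized to the wild-type group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from hyphaquant.errors import (
    InvalidGeometryError,
    MissingSeptumError,
    UndefinedStatisticError,
)
from hyphaquant.segcoloc import SegmentationParams, segment_puncta

SEPTAL_RECT_UM = (0.5, 1.0)  # along-axis width x across-axis length
LINESCAN_WIDTH_PX = 20
LINESCAN_BIN_UM = 0.5


@dataclass
class LineScanProfile:
    """Binned, background-corrected intensity versus distance from the tip."""

    bin_centers_um: np.ndarray
    mean_intensity: np.ndarray
    n_cells: np.ndarray

    def __post_init__(self):
        self.bin_centers_um = np.asarray(self.bin_centers_um, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.n_cells = np.asarray(self.n_cells, dtype=int)
        if np.any(np.diff(self.bin_centers_um) <= 0) or (
            self.bin_centers_um.size and self.bin_centers_um[0] < 0
        ):
            raise ValueError("bin centers must increase from 0")

    def to_frame(self):
        return pd.DataFrame(
            {
                "distance_um": self.bin_centers_um,
                "mean_intensity": self.mean_intensity,
                "n_cells": self.n_cells,
            }
        )


@dataclass
class SeptumRecord:
    septum_id: int
    klass: str  # both / one / none
    mean_intensity: float = float("nan")  # background-corrected
    normalized_intensity: float = float("nan")
    n_left: int = 0
    n_right: int = 0

    def __post_init__(self):
        if self.klass not in ("both", "one", "none"):
            raise ValueError("class must be 'both', 'one' or 'none'")


@dataclass
class PuddleRecord:
    integrated_density: float
    background_mean: float
    area_px: int
    normalized: float = float("nan")

    @property
    def corrected(self):
        """Background-corrected integrated density (exact identity)."""
        return self.integrated_density - self.background_mean * self.area_px


# ---------------------------------------------------------------------------
# Tip line scans
# ---------------------------------------------------------------------------


def _band_samples(image, path_um, width_px, pixel_size_um):
    """Per-arclength mean across a width_px-wide band along the path."""
    from hyphaquant.motility import _resample_path

    pts = _resample_path(path_um, pixel_size_um)
    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    tangents /= np.where(norms == 0, 1.0, norms)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2
    ys = pts[:, 0][None, :] + offsets[:, None] * normals[:, 0][None, :]
    xs = pts[:, 1][None, :] + offsets[:, None] * normals[:, 1][None, :]
    vals = ndimage.map_coordinates(np.asarray(image, dtype=float), [ys, xs], order=1,
                                   mode="nearest")
    s_um = np.arange(len(pts)) * pixel_size_um
    return s_um, vals.mean(axis=0), (ys, xs)


def tip_linescan(image, path_um, pixel_size_um, width_px=LINESCAN_WIDTH_PX,
                 bin_um=LINESCAN_BIN_UM):
    """Background-corrected, binned tip line scan of one cell.

    The cell's background is the median of pixels outside the hyphal band
    (the path dilated to ``width_px``) and is subtracted before binning.
    """
    img = np.asarray(image, dtype=float)
    s_um, band_mean, (ys, xs) = _band_samples(img, path_um, width_px, pixel_size_um)
    # hypha mask: pixels hit by the band samples
    mask = np.zeros(img.shape, dtype=bool)
    yi = np.clip(np.round(ys).astype(int), 0, img.shape[0] - 1)
    xi = np.clip(np.round(xs).astype(int), 0, img.shape[1] - 1)
    mask[yi, xi] = True
    mask = ndimage.binary_dilation(mask, iterations=2)
    outside = img[~mask]
    background = float(np.median(outside)) if outside.size else float(np.median(img))
    corrected = band_mean - background

    edges = np.arange(0.0, s_um[-1] + bin_um, bin_um)
    idx = np.clip(np.digitize(s_um, edges) - 1, 0, len(edges) - 2)
    centers, means = [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            centers.append((edges[b] + edges[b + 1]) / 2)
            means.append(corrected[sel].mean())
    return LineScanProfile(np.array(centers), np.array(means), np.ones(len(centers), int))


def average_profiles(profiles):
    """Average line-scan profiles across cells, weighting cells equally."""
    if not profiles:
        raise ValueError("no profiles to average")
    table = {}
    for prof in profiles:
        for c, v in zip(prof.bin_centers_um, prof.mean_intensity):
            table.setdefault(round(float(c), 6), []).append(float(v))
    centers = sorted(table)
    means = [np.mean(table[c]) for c in centers]
    ns = [len(table[c]) for c in centers]
    return LineScanProfile(np.array(centers), np.array(means), np.array(ns))


# ---------------------------------------------------------------------------
# Septa
# ---------------------------------------------------------------------------


def classify_septum(crop, pixel_size_um, seg=None, max_dist_um=1.0,
                    septum_image=None, septum_id=0):
    """Score Woronin-body localization around a septal plane.

    ``crop`` is a 488-channel image centered on the (vertical) septal plane
    with the tip to the left.  Puncta with centroids within ``max_dist_um``
    of the plane are assigned to a side by the sign of their offset (a
    centroid exactly on the plane counts toward the tipward side).  Returns a
    :class:`SeptumRecord` with class both/one/none and per-side counts.
    """
    crop = np.asarray(crop, dtype=float)
    if septum_image is not None:
        simg = np.asarray(septum_image, dtype=float)
        if np.ptp(simg) == 0 or simg.max() < 1.1 * np.median(simg):
            raise MissingSeptumError("no septum marker signal in the crop")
    # full recipe incl. background subtraction: a blank crop must stay blank
    seg = seg or SegmentationParams()
    puncta, _ = segment_puncta(crop, seg, channel="488")
    plane_x = (crop.shape[1] - 1) / 2
    n_left = n_right = 0
    for p in puncta:
        dx_um = (p.centroid_px[1] - plane_x) * pixel_size_um
        if abs(dx_um) > max_dist_um:
            continue
        if dx_um <= 0:  # tie-break: on-plane centroid counts as the tipward side
            n_left += 1
        else:
            n_right += 1
    if n_left and n_right:
        klass = "both"
    elif n_left or n_right:
        klass = "one"
    else:
        klass = "none"
    return SeptumRecord(septum_id, klass, n_left=n_left, n_right=n_right)


def _rect_mean(image, center_yx_px, axis_extent_px, cross_extent_px, step=1.0):
    """Mean of a bilinearly sampled axis-aligned rectangle (axis = x)."""
    cy, cx = center_yx_px
    nx = max(int(round(axis_extent_px / step)), 1)
    ny = max(int(round(cross_extent_px / step)), 1)
    xs = cx + (np.arange(nx) - (nx - 1) / 2) * step
    ys = cy + (np.arange(ny) - (ny - 1) / 2) * step
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    vals = ndimage.map_coordinates(np.asarray(image, dtype=float), [gy, gx], order=1,
                                   mode="nearest")
    return float(vals.mean())


def septal_intensity(image, septum_center_yx_um, pixel_size_um, wildtype_mean,
                     rect_um=SEPTAL_RECT_UM, background_offset_um=1.0,
                     away_from_tip=(0.0, 1.0)):
    """Normalized septal signal from a 0.5 x 1 um rectangle at the septum.

    The adjacent background is a same-size rectangle displaced
    ``background_offset_um`` along the hypha away from the tip; the
    background-corrected mean is divided by the wild-type mean.
    """
    if wildtype_mean <= 0:
        raise UndefinedStatisticError("wild-type mean must be positive to normalize")
    img = np.asarray(image, dtype=float)
    cy, cx = (c / pixel_size_um for c in septum_center_yx_um)
    w_px = rect_um[0] / pixel_size_um  # along the hyphal axis
    l_px = rect_um[1] / pixel_size_um  # across the hypha
    if not (0 <= cy < img.shape[0] and 0 <= cx < img.shape[1]):
        raise InvalidGeometryError("septal rectangle center outside the field")
    mean_rect = _rect_mean(img, (cy, cx), w_px, l_px)
    dyx = np.asarray(away_from_tip, dtype=float) * background_offset_um / pixel_size_um
    mean_bg = _rect_mean(img, (cy + dyx[0], cx + dyx[1]), w_px, l_px)
    return (mean_rect - mean_bg) / wildtype_mean


# ---------------------------------------------------------------------------
# Leakage
# ---------------------------------------------------------------------------


def measure_puddle(image, puddle_mask, background_mask):
    """Background-corrected integrated density of a cytoplasmic puddle.

    ``corrected = sum(puddle) - mean(background) * area`` exactly; adding any
    constant offset to the whole image leaves the corrected value unchanged.
    """
    img = np.asarray(image, dtype=float)
    pm = np.asarray(puddle_mask, dtype=bool)
    bm = np.asarray(background_mask, dtype=bool)
    if not pm.any() or not bm.any():
        raise UndefinedStatisticError("puddle and background ROIs must be nonempty")
    if (pm & bm).any():
        raise ValueError("puddle and background ROIs must be disjoint")
    return PuddleRecord(
        integrated_density=float(img[pm].sum()),
        background_mean=float(img[bm].mean()),
        area_px=int(pm.sum()),
    )


def normalize_to_wildtype(values, wildtype_values):
    """Divide measurements by the wild-type group mean (WT mean becomes 1)."""
    wt = np.asarray(wildtype_values, dtype=float)
    if wt.size == 0 or wt.mean() == 0:
        raise UndefinedStatisticError("cannot normalize to an empty/zero wild-type group")
    return np.asarray(values, dtype=float) / wt.mean()


def summarize_groups(values, labels):
    """Descriptive per-group statistics (n, mean, SD, SEM); no inference."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(labels)})
    if df.empty:
        raise ValueError("no values to summarize")
    rows = []
    for g, sub in df.groupby("group", sort=True):
        v = sub["value"].to_numpy()
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        rows.append(
            {
                "group": g,
                "n": len(v),
                "mean": float(v.mean()),
                "sd": sd,
                "sem": sd / np.sqrt(len(v)) if len(v) else 0.0,
            }
        )
    return pd.DataFrame(rows)
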