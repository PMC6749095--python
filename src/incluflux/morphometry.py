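"""Inclusion segmentation and shape statistics.

Inclusions are segmented from calibrated z-stacks by thresholding at a
multiple (default 1.2×) of the mean cytoplasmic intensity, measured on the
z-slice where each object is brightest.  Objects are classified as ovoid
inclusion bodies (IBs), small particles, or cluster-like inclusions (CLIs)
following area/visibility rules; shape is summarised by the circularity
ratio CR = 4π·area/perimeter² (1 for a perfect circle) and the major/minor
aspect ratio of the best-fit ellipse.  Also provided: apparent 3D volumes
from supra-threshold voxels, the chance-overlap probability between an IB
and another body given the available cytoplasmic area, and population
prevalence summaries.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, segmentation, feature

from .types import CellMeasurement, ImageStack, ObjectClass, SegmentedObject

__all__ = [
    "segment_objects",
    "classify_object",
    "circularity",
    "aspect_ratio",
    "apparent_volume",
    "count_lobes",
    "chance_overlap_probability",
    "prevalence_summary",
]

SMALL_PARTICLE_AREA_UM2 = 0.01  # supra-threshold objects below this are small particles
_STRUCT8 = np.ones((3, 3), dtype=int)


# ---------------------------------------------------------------------------
# shape statistics
# ---------------------------------------------------------------------------

def circularity(shape, perimeter: Optional[float] = None,
                pixel_size_um: float = 1.0) -> float:
    """Circularity ratio CR = 4π·area/perimeter².

    Called either with an analytic ``(area, perimeter)`` pair, or with a
    boolean mask, in which case the area is the pixel count and the
    perimeter the multi-directional Crofton estimate (naive pixel-edge
    counting overestimates the perimeter and depresses CR).
    """
    if isinstance(shape, np.ndarray):
        mask = shape.astype(bool)
        area = float(mask.sum()) * pixel_size_um**2
        perim = float(measure.perimeter_crofton(mask, directions=4)) * pixel_size_um
    else:
        area = float(shape)
        if perimeter is None:
            raise ValueError("analytic form needs both area and perimeter")
        perim = float(perimeter)
    if perim <= 0:
        raise ValueError("degenerate region: zero perimeter")
    return 4.0 * np.pi * area / perim**2


def aspect_ratio(mask: np.ndarray, intensity: Optional[np.ndarray] = None) -> float:
    """Major/minor axis ratio of the (intensity-weighted) best-fit ellipse.

    Computed from the eigenvalues of the weighted central second moments;
    uniform weights are used when no intensity image is given.
    """
    mask = mask.astype(bool)
    if mask.sum() < 5:
        raise ValueError("need >= 5 pixels for an ellipse fit")
    yy, xx = np.nonzero(mask)
    w = intensity[yy, xx].astype(float) if intensity is not None else np.ones(len(yy))
    wsum = w.sum()
    cy, cx = (w * yy).sum() / wsum, (w * xx).sum() / wsum
    dy, dx = yy - cy, xx - cx
    myy = (w * dy * dy).sum() / wsum
    mxx = (w * dx * dx).sum() / wsum
    mxy = (w * dx * dy).sum() / wsum
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals = np.linalg.eigvalsh(cov)
    lo, hi = float(evals[0]), float(evals[1])
    if lo <= 1e-12:
        raise ValueError("collinear pixels: aspect ratio not estimable")
    return float(np.sqrt(hi / lo))


def apparent_volume(label_stack: np.ndarray, label: int,
                    pixel_size_um: float, z_spacing_um: float) -> float:
    """Apparent 3D volume: supra-threshold voxel count × pixel² × z-spacing."""
    n_vox = int((label_stack == label).sum())
    return n_vox * pixel_size_um**2 * z_spacing_um


def count_lobes(mask: np.ndarray, min_distance: int = 3) -> int:
    """Number of watershed lobes of a binary object (for the CLI rule)."""
    mask = mask.astype(bool)
    if not mask.any():
        return 0
    dist = ndimage.distance_transform_edt(mask)
    peaks = feature.peak_local_max(dist, min_distance=min_distance, labels=mask,
                                   exclude_border=False)
    if len(peaks) <= 1:
        return 1 if mask.any() else 0
    markers = np.zeros_like(mask, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    ws = segmentation.watershed(-dist, markers, mask=mask)
    return int(len(np.unique(ws[ws > 0])))


def chance_overlap_probability(d_ib_um: float, d_ap_um: float,
                               available_area_um2: float) -> float:
    """Probability that two bodies appear to touch or overlap by chance.

    They appear to overlap when the second body's centre falls inside a
    circle of diameter d_ib + 2·d_ap; the probability is that circle's area
    over the available cytoplasmic cross-sectional area.
    """
    if d_ib_um <= 0 or d_ap_um < 0 or available_area_um2 <= 0:
        raise ValueError("diameters and area must be positive")
    r = (d_ib_um + 2.0 * d_ap_um) / 2.0
    circle = np.pi * r**2
    if circle >= available_area_um2:
        warnings.warn("overlap circle exceeds the available area; returning 1",
                      stacklevel=2)
        return 1.0
    return float(circle / available_area_um2)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _link_slices(per_slice_labels: list[np.ndarray]) -> list[dict]:
    """Group per-slice 2D regions into 3D objects by centroid overlap.

    A region in slice z joins the object of a region in slice z−1 when
    either centroid falls inside the other's mask.
    """
    objects: list[dict] = []  # each: {"slices": {z: mask}, "open": region of last slice}
    prev_regions: list[tuple[int, np.ndarray, tuple[float, float]]] = []  # (obj_idx, mask, centroid)
    for z, labels in enumerate(per_slice_labels):
        cur_regions = []
        for lab in range(1, labels.max() + 1):
            m = labels == lab
            if not m.any():
                continue
            yy, xx = np.nonzero(m)
            cen = (yy.mean(), xx.mean())
            target = None
            for obj_idx, pmask, pcen in prev_regions:
                ci, cj = int(round(cen[0])), int(round(cen[1]))
                pi, pj = int(round(pcen[0])), int(round(pcen[1]))
                if pmask[ci, cj] or m[pi, pj]:
                    target = obj_idx
                    break
            if target is None:
                objects.append({"slices": {}})
                target = len(objects) - 1
            objects[target]["slices"][z] = (
                objects[target]["slices"].get(z, np.zeros_like(m)) | m
            )
            cur_regions.append((target, m, cen))
        prev_regions = cur_regions
    return objects


def segment_objects(
    zstack: ImageStack,
    cell: CellMeasurement,
    k_threshold: float = 1.2,
    t: int = 0,
    channel: int = 0,
    k_detect: Optional[float] = None,
    min_pixels: int = 1,
) -> list[SegmentedObject]:
    """Segment fluorescent bodies from a calibrated z-stack.

    Voxels above ``k_threshold × cytoplasm_mean`` (after background
    subtraction on both sides) form supra-threshold objects; if
    ``k_detect`` (< k_threshold) is given, dimmer bodies above that level
    are additionally detected and flagged sub-threshold.  Per object, the
    z-slice with the highest mean intensity is selected and area, Crofton
    perimeter, CR and aspect ratio are measured on that slice; the apparent
    volume sums that object's voxels across slices.  In-plane adjacency is
    8-connected; slices are linked by centroid overlap.
    """
    if cell.cytoplasm_mean <= 0:
        raise ValueError("cytoplasm_mean must be positive")
    vol = zstack.data[t, :, channel].astype(float) - cell.background
    cyto = cell.cytoplasm_mean - cell.background
    level_main = k_threshold * cyto
    level_detect = k_detect * cyto if k_detect is not None else level_main

    per_slice = []
    for z in range(vol.shape[0]):
        labels, _ = ndimage.label(vol[z] > level_detect, structure=_STRUCT8)
        per_slice.append(labels)
    groups = _link_slices(per_slice)

    px = zstack.pixel_size_um
    dz = zstack.z_spacing_um or px
    out: list[SegmentedObject] = []
    next_label = 1
    for g in groups:
        slices = g["slices"]
        n_planes = len(slices)
        # brightest slice: maximal integrated object intensity
        best_z, best_sum = None, -np.inf
        for z, m in slices.items():
            s = vol[z][m].sum()
            if s > best_sum:
                best_z, best_sum = z, s
        m = slices[best_z]
        supra = m & (vol[best_z] > level_main)
        is_supra = supra.sum() >= min_pixels
        meas_mask = supra if is_supra else m
        if meas_mask.sum() < min_pixels:
            continue
        area = float(meas_mask.sum()) * px**2
        perim = float(measure.perimeter_crofton(meas_mask, directions=4)) * px
        cr = 4 * np.pi * area / perim**2 if perim > 0 else np.nan
        try:
            ar = aspect_ratio(meas_mask, vol[best_z])
        except ValueError:
            ar = np.nan
        n_vox = sum(int(((mm & (vol[z] > level_main)) if is_supra else mm).sum())
                    for z, mm in slices.items())
        yy, xx = np.nonzero(meas_mask)
        obj = SegmentedObject(
            label=next_label,
            z_slice=int(best_z),
            area_um2=area,
            perimeter_um=perim,
            circularity=cr,
            aspect_ratio=ar,
            mean_intensity=float(vol[best_z][meas_mask].mean() + cell.background),
            centroid_yx_px=(float(yy.mean()), float(xx.mean())),
            apparent_volume_um3=n_vox * px**2 * dz,
            n_visible_planes=n_planes,
        )
        obj.object_class = classify_object(obj, n_planes, is_supra)
        out.append(obj)
        next_label += 1
    return out


def classify_object(
    obj: SegmentedObject,
    visible_planes: int,
    supra_threshold: bool,
    n_lobes: int = 1,
    n_peripheral_objects: int = 0,
) -> Optional[ObjectClass]:
    """Classify a segmented body as IB, small particle, or CLI.

    Rules: a supra-threshold object with area < 0.01 μm², or a
    sub-threshold body visible in more than one focal plane, is a small
    particle; a supra-threshold object of at least 0.01 μm² is an IB —
    unless it is cluster-like: ≥ 3 watershed lobes, or CR < 0.8 with ≥ 5
    accompanying peripheral objects.
    """
    if supra_threshold:
        if obj.area_um2 < SMALL_PARTICLE_AREA_UM2:
            return ObjectClass.SMALL_PARTICLE
        if n_lobes >= 3 or (obj.circularity < 0.8 and n_peripheral_objects >= 5):
            return ObjectClass.CLI
        return ObjectClass.IB
    if visible_planes > 1:
        return ObjectClass.SMALL_PARTICLE
    return None  # single-plane sub-threshold body: unclassified


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

def prevalence_summary(
    cells: Sequence[Sequence[SegmentedObject]],
    replicate_ids: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per-category prevalence fractions over a cell population.

    Categories: cells with a single IB, multiple IBs, any CLI, and with
    0 / 1–2 / ≥3 small particles.  When ``replicate_ids`` groups the cells
    into independent replicates, the SEM of each fraction across replicates
    is reported; otherwise SEM is NaN.
    """
    if len(cells) == 0:
        raise ValueError("need at least one cell")

    def cell_flags(objs) -> dict:
        n_ib = sum(1 for o in objs if o.object_class is ObjectClass.IB)
        n_cli = sum(1 for o in objs if o.object_class is ObjectClass.CLI)
        n_sp = sum(1 for o in objs if o.object_class is ObjectClass.SMALL_PARTICLE)
        return {
            "single_IB": n_ib == 1,
            "multiple_IB": n_ib > 1,
            "CLI": n_cli > 0,
            "particles_0": n_sp == 0,
            "particles_1_2": 1 <= n_sp <= 2,
            "particles_3plus": n_sp >= 3,
        }

    flags = pd.DataFrame([cell_flags(c) for c in cells])
    overall = flags.mean(axis=0)
    if replicate_ids is not None:
        flags["_rep"] = list(replicate_ids)
        per_rep = flags.groupby("_rep").mean()
        sem = per_rep.std(ddof=1) / np.sqrt(len(per_rep)) if len(per_rep) > 1 else per_rep.iloc[0] * np.nan
    else:
        sem = overall * np.nan
    return pd.DataFrame({"fraction": overall, "sem": sem})
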