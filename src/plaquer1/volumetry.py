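"""Plaque ROI handling: volumes, threshold segmentation, grid transfer.

Total plaque volume (TPV) is the sum of per-slice ROI areas times the slice
thickness, reported in mm^3.  Because voxels are boxes, this equals the ROI
voxel count times the voxel volume.  ROI masks live on a :class:`Grid`, so
they can be moved between acquisitions with different resolution or a
shifted field of view by exact world-space box overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.base import BaseEstimator

from .grid import Grid
from . import stats as _stats

__all__ = [
    "ROISet",
    "VolumeResult",
    "total_plaque_volume",
    "ThresholdSegmenter",
    "threshold_segment",
    "transfer_rois",
    "perturb_rois",
    "interobserver_agreement",
]


@dataclass
class ROISet:
    """A binary plaque mask on a named grid, attributed to one reader."""

    mask: np.ndarray
    grid: Grid
    reader_id: str = "reader"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("ROI mask does not conform to its grid")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def slice_mask(self, k: int) -> np.ndarray:
        """The in-plane ROI of slice ``k`` (slices along the last axis)."""
        return self.mask[:, :, k]


@dataclass(frozen=True)
class VolumeResult:
    tpv_mm3: float
    per_slice_mm2: tuple[float, ...]
    n_voxels: int


def total_plaque_volume(rois: ROISet) -> VolumeResult:
    """Sum per-slice ROI areas (mm^2) times slice thickness into TPV (mm^3)."""
    grid = rois.grid
    per_slice_counts = rois.mask.sum(axis=(0, 1))
    per_slice_mm2 = tuple(float(c) * grid.pixel_area_mm2 for c in per_slice_counts)
    slice_thickness = grid.voxel_size[2]
    tpv = float(sum(per_slice_mm2)) * slice_thickness
    return VolumeResult(tpv_mm3=tpv, per_slice_mm2=per_slice_mm2, n_voxels=rois.n_voxels)


# ---------------------------------------------------------------------------
# threshold segmentation
# ---------------------------------------------------------------------------


class ThresholdSegmenter(BaseEstimator):
    """Semi-automatic intensity segmentation: global threshold + size filter.

    Voxels at or above ``threshold`` are kept; connected components (26-
    connectivity in 3D, 8 in 2D) smaller than ``min_component`` voxels are
    discarded as noise specks.

    Attributes (after :meth:`fit`)
    ------------------------------
    mask_ : ndarray of bool
    n_components_ : int
        Connected components surviving the size filter.
    """

    def __init__(self, threshold: float = 0.5, min_component: int = 0):
        self.threshold = threshold
        self.min_component = min_component

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.size and not (X.min() <= self.threshold <= X.max()):
            warnings.warn(
                f"threshold {self.threshold} outside intensity range "
                f"[{X.min():.4g}, {X.max():.4g}]",
                stacklevel=2,
            )
        mask = X >= self.threshold
        n_kept = 0
        if self.min_component > 0 and mask.any():
            lab, n = measure.label(mask, connectivity=mask.ndim, return_num=True)
            sizes = np.bincount(lab.ravel())
            keep = np.flatnonzero(sizes >= self.min_component)
            keep = keep[keep != 0]
            mask = np.isin(lab, keep)
            n_kept = len(keep)
        elif mask.any():
            _, n_kept = measure.label(mask, connectivity=mask.ndim, return_num=True)
        self.mask_ = mask
        self.n_components_ = int(n_kept)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).mask_


def threshold_segment(
    volume: np.ndarray,
    grid: Grid,
    threshold: float,
    min_component: int = 0,
    reader_id: str = "semiauto",
) -> ROISet:
    """Functional wrapper over :class:`ThresholdSegmenter` returning a ROISet."""
    seg = ThresholdSegmenter(threshold=threshold, min_component=min_component).fit(volume)
    return ROISet(mask=seg.mask_, grid=grid, reader_id=reader_id)


# ---------------------------------------------------------------------------
# cross-grid ROI transfer
# ---------------------------------------------------------------------------


def _axis_overlap(src: Grid, dst: Grid, axis: int) -> np.ndarray:
    """Matrix O[i, a] of 1D interval overlap (mm) between target voxel i and
    source voxel a along one axis."""
    sv, dv = src.voxel_size[axis], dst.voxel_size[axis]
    s_lo = src.fov_origin[axis] + (np.arange(src.shape[axis]) - 0.5) * sv
    d_lo = dst.fov_origin[axis] + (np.arange(dst.shape[axis]) - 0.5) * dv
    lo = np.maximum(d_lo[:, None], s_lo[None, :])
    hi = np.minimum(d_lo[:, None] + dv, s_lo[None, :] + sv)
    return np.clip(hi - lo, 0.0, None)


def transfer_rois(
    rois: ROISet,
    target_grid: Grid,
    mode: str = "coverage",
    min_coverage: float = 0.5,
) -> ROISet:
    """Resample a ROI mask onto another grid via their shared world frame.

    In ``coverage`` mode the exact fraction of each target voxel's volume
    covered by the source mask is computed (axis-aligned box overlap) and
    voxels with coverage >= ``min_coverage`` are included.  ``nearest`` maps
    each target voxel centre to its nearest source voxel.
    """
    src, dst = rois.grid, target_grid
    for axis in range(3):
        s_lo, s_hi = src.axis_extent(axis)
        d_lo, d_hi = dst.axis_extent(axis)
        if s_hi <= d_lo or d_hi <= s_lo:
            raise ValueError("source and target fields of view do not overlap")

    if mode == "nearest":
        out = np.zeros(dst.shape, dtype=bool)
        idx = []
        inside = np.ones(dst.shape, dtype=bool)
        for axis in range(3):
            centers = dst.axis_centers(axis)
            i_src = np.rint((centers - src.fov_origin[axis]) / src.voxel_size[axis]).astype(int)
            ok = (i_src >= 0) & (i_src < src.shape[axis])
            shape = [1, 1, 1]
            shape[axis] = -1
            inside &= ok.reshape(shape)
            idx.append(np.clip(i_src, 0, src.shape[axis] - 1))
        gathered = rois.mask[np.ix_(idx[0], idx[1], idx[2])]
        out = gathered & inside
        return ROISet(mask=out, grid=dst, reader_id=rois.reader_id)

    if mode != "coverage":
        raise ValueError(f"unknown transfer mode {mode!r}")

    o0 = _axis_overlap(src, dst, 0)
    o1 = _axis_overlap(src, dst, 1)
    o2 = _axis_overlap(src, dst, 2)
    m = rois.mask.astype(float)
    cov = np.tensordot(o0, m, axes=(1, 0))          # (i, b, c)
    cov = np.tensordot(o1, cov, axes=(1, 1))        # (j, i, c)
    cov = np.tensordot(o2, cov, axes=(1, 2))        # (k, j, i)
    cov = cov.transpose(2, 1, 0) / dst.voxel_volume_mm3
    return ROISet(mask=cov >= min_coverage, grid=dst, reader_id=rois.reader_id)


# ---------------------------------------------------------------------------
# synthetic readers and interobserver agreement
# ---------------------------------------------------------------------------

_DISK = ndimage.generate_binary_structure(2, 1)


def perturb_rois(
    rois: ROISet,
    seed: int,
    reader_id: str = "readerB",
    p_change: float = 0.7,
) -> ROISet:
    """Emulate manual-delineation variability: per slice, the ROI boundary is
    randomly dilated or eroded by one voxel (or left unchanged)."""
    rng = np.random.default_rng(seed)
    out = rois.mask.copy()
    for k in range(rois.grid.shape[2]):
        sl = out[:, :, k]
        if not sl.any():
            continue
        u = rng.uniform()
        if u < p_change / 2:
            out[:, :, k] = ndimage.binary_erosion(sl, structure=_DISK)
        elif u < p_change:
            out[:, :, k] = ndimage.binary_dilation(sl, structure=_DISK)
    return ROISet(mask=out, grid=rois.grid, reader_id=reader_id)


def interobserver_agreement(readers_a: list[ROISet], readers_b: list[ROISet]):
    """Pearson correlation between two readers' per-case TPV measurements."""
    if len(readers_a) != len(readers_b):
        raise ValueError("readers must rate the same cases")
    if len(readers_a) < 3:
        raise ValueError("need at least 3 cases for a correlation")
    tpv_a = [total_plaque_volume(r).tpv_mm3 for r in readers_a]
    tpv_b = [total_plaque_volume(r).tpv_mm3 for r in readers_b]
    return _stats.pearson(tpv_a, tpv_b)
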