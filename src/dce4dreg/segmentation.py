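"""Semiautomatic lesion ROI extraction on subtraction images.

A spheroid brush (radius in mm, anisotropy-aware) localizes the lesion; all
voxels above a fraction (default 0.1) of the maximum subtraction intensity
under the brush join the ROI, restricted to the seed's 26-connected
component so a bright vessel at the brush edge cannot merge in.  Standard
3D morphological dilation/erosion provides manual-style adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .core import SubtractionSeries

__all__ = ["LesionRoi", "select_timepoint", "threshold_segment",
           "morph_adjust"]

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class LesionRoi:
    """Binary tumor mask in series voxel space."""

    mask: np.ndarray
    source_timepoint: int = 0
    threshold_fraction: float = 0.1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def select_timepoint(sub: SubtractionSeries, seed_point,
                     neighborhood_vox: int = 1) -> int:
    """Pick the subtraction timepoint with earliest adequate enhancement.

    Returns 0 (first postcontrast) unless local mean enhancement around the
    seed at timepoint 0 is below 50% of its value at timepoint 1 (markedly
    delayed enhancement), in which case 1.  Never returns beyond 1.
    """
    seed = tuple(int(s) for s in seed_point)
    shape = sub.voxels.shape[:3]
    if any(s < 0 or s >= d for s, d in zip(seed, shape)):
        raise ValueError(f"seed {seed} outside image domain {shape}")
    sl = tuple(slice(max(0, s - neighborhood_vox),
                     min(d, s + neighborhood_vox + 1))
               for s, d in zip(seed, shape))
    local0 = float(np.mean(sub.volume(0)[sl]))
    if sub.n_timepoints < 2:
        return 0
    local1 = float(np.mean(sub.volume(1)[sl]))
    if local1 <= 0:
        if local0 <= 0:
            warnings.warn("no local enhancement around seed; defaulting to "
                          "first postcontrast timepoint", RuntimeWarning,
                          stacklevel=2)
        return 0
    return 1 if local0 < 0.5 * local1 else 0


def threshold_segment(sub_volume: np.ndarray, seed_point, brush_radius_mm,
                      threshold_fraction: float = 0.1,
                      spacing=(1.0, 1.0, 1.0),
                      source_timepoint: int = 0) -> LesionRoi:
    """Fractional-threshold segmentation inside a spheroid brush.

    The maximum intensity M under the brush sets the threshold; voxels with
    intensity strictly above ``threshold_fraction * M`` within the brush
    are kept, then restricted to the 26-connected component containing (or
    nearest to) the seed.
    """
    vol = np.asarray(sub_volume, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    seed = tuple(int(s) for s in seed_point)
    if any(s < 0 or s >= d for s, d in zip(seed, vol.shape)):
        raise ValueError(f"seed {seed} outside image domain {vol.shape}")
    idx = np.indices(vol.shape, dtype=float)
    r2 = sum((((idx[a] - seed[a]) * spacing[a]) / brush_radius_mm) ** 2
             for a in range(3))
    brush = r2 <= 1.0
    if not brush.any():
        raise ValueError("brush does not intersect the image domain")
    m = float(vol[brush].max())
    if m <= 0:
        raise ValueError("no enhancing lesion under brush")
    mask = brush & (vol > threshold_fraction * m)
    labels, _ = ndimage.label(mask, structure=_CONNECTIVITY_26)
    if mask[seed]:
        lab = labels[seed]
    else:  # nearest selected voxel to the seed (world distance)
        sel = np.argwhere(mask)
        d2 = np.sum(((sel - np.array(seed)) * spacing) ** 2, axis=1)
        lab = labels[tuple(sel[np.argmin(d2)])]
    mask = labels == lab
    return LesionRoi(mask=mask, source_timepoint=source_timepoint,
                     threshold_fraction=threshold_fraction)


def morph_adjust(roi: LesionRoi, operation: str, radius_vox: int) -> LesionRoi:
    """3D morphological dilation or erosion with a ball structuring element."""
    if radius_vox < 1:
        raise ValueError("radius must be >= 1")
    selem = ball(radius_vox)
    if operation == "dilate":
        mask = ndimage.binary_dilation(roi.mask, structure=selem)
    elif operation == "erode":
        mask = ndimage.binary_erosion(roi.mask, structure=selem)
        if not mask.any():
            raise ValueError("ROI vanished")
    else:
        raise ValueError(f"unknown operation: {operation}")
    return LesionRoi(mask=mask, source_timepoint=roi.source_timepoint,
                     threshold_fraction=roi.threshold_fraction)
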