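"""4D DCE-MRI data model, NIfTI I/O and subtraction images.

A dynamic contrast-enhanced (DCE) series is a stack of T1-weighted volumes
acquired before and repeatedly after contrast-agent injection.  The series
is represented as a single 4D array with the time axis last, together with
voxel spacing, per-volume acquisition times (seconds relative to injection)
and a voxel-to-world affine.  Subtraction images — postcontrast minus the
unenhanced volume — are the clinical reading format in which both enhancing
lesions and motion artifacts appear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["DceSeries", "SubtractionSeries", "read_series", "write_series",
           "compute_subtractions"]


@dataclass
class DceSeries:
    """A 4D DCE-MRI series: 3 spatial dimensions plus time (last axis).

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz, nt)
        Signal intensities, arbitrary units.
    spacing : sequence of 3 floats
        Voxel size in mm per spatial axis.
    times : sequence of floats
        Acquisition time of each volume in seconds relative to contrast
        injection; the unenhanced volume is at or before 0.  Strictly
        increasing, one entry per volume.
    affine : ndarray (4, 4), optional
        Voxel-to-world map.  Defaults to a diagonal scaling by ``spacing``.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    times: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("series must be 4D (x, y, z, t)")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 strictly positive values in mm")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.voxels.shape[3]:
            raise ValueError(
                f"number of times ({self.times.size}) must equal temporal "
                f"extent of voxels ({self.voxels.shape[3]})")
        if self.times.size < 2:
            raise ValueError("series needs at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.voxels.shape

    @property
    def n_timepoints(self) -> int:
        return self.voxels.shape[3]

    def volume(self, t: int) -> np.ndarray:
        """The 3D volume at timepoint index ``t``."""
        return self.voxels[..., t]

    def with_voxels(self, voxels: np.ndarray) -> "DceSeries":
        """A copy of this series carrying new voxel data, same metadata."""
        return DceSeries(voxels=np.asarray(voxels), spacing=self.spacing.copy(),
                         times=self.times.copy(), affine=self.affine.copy())


@dataclass
class SubtractionSeries:
    """Postcontrast-minus-unenhanced volumes (one fewer than the source)."""

    voxels: np.ndarray
    times: np.ndarray
    spacing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("subtraction series must be 4D")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size != self.voxels.shape[3]:
            raise ValueError("one time per subtraction volume required")
        if self.spacing is not None:
            self.spacing = np.asarray(self.spacing, dtype=float)

    @property
    def n_timepoints(self) -> int:
        return self.voxels.shape[3]

    def volume(self, t: int) -> np.ndarray:
        return self.voxels[..., t]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_series(path, times=None) -> DceSeries:
    """Read a 4D NIfTI volume (plus JSON times sidecar) as a :class:`DceSeries`.

    ``times`` overrides the sidecar when given (seconds).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such series file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("series must be 4D")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    if "spacing_mm" in meta:  # full-precision spacing (header pixdim is f32)
        spacing = np.asarray(meta["spacing_mm"], dtype=float)
    if times is None:
        if "times_s" not in meta:
            raise FileNotFoundError(
                f"acquisition times not given and sidecar {sidecar} missing")
        times = meta["times_s"]
    times = np.asarray(times, dtype=float)
    if times.size != data.shape[3]:
        raise ValueError(
            f"time count ({times.size}) does not match volumes ({data.shape[3]})")
    return DceSeries(voxels=data, spacing=spacing, times=times,
                     affine=np.asarray(img.affine))


def write_series(series: DceSeries, path) -> Path:
    """Write a series as 4D NIfTI plus a ``{"times_s": [...]}`` JSON sidecar."""
    if not np.all(np.isfinite(series.voxels)):
        raise ValueError("non-finite voxel values")
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(series.voxels, dtype=np.float64),
                          series.affine)
    img.header.set_zooms((*series.spacing, 1.0))
    nib.save(img, str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"times_s": [float(t) for t in series.times],
                   "spacing_mm": [float(s) for s in series.spacing]}, fh)
    return path


def compute_subtractions(series: DceSeries) -> SubtractionSeries:
    """Subtraction images: volume ``i`` is postcontrast ``i+1`` minus volume 0.

    Negative values are retained — downstream residual and metric
    computations need signed differences.
    """
    if series.n_timepoints < 2:
        raise ValueError("need at least 2 time points to subtract")
    sub = series.voxels[..., 1:] - series.voxels[..., :1]
    return SubtractionSeries(voxels=sub, times=series.times[1:],
                             spacing=series.spacing.copy())
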