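"""Cubic B-spline free-form deformation (FFD) motion model.

Each timepoint of a DCE series carries its own smooth displacement field,
interpolated from a coarse regular grid of control-point displacement
vectors (mm) by the cubic B-spline tensor basis.  The same parameterization
serves both as the injected ground-truth motion of synthetic phantoms and
as the transform recovered by groupwise registration; no timepoint is a
designated reference (the groupwise gauge is a zero temporal-mean
displacement at every control point).

Coordinates: the field lives in "grid-world" mm, i.e. world = index *
spacing along each axis.  Displacements map sampling points of the output
volume to source locations in the input volume (backward warping).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["BSplineMotionModel", "bspline_weights"]

TRANSFORM_SCHEMA_VERSION = 1


def bspline_derivative_weights(t: np.ndarray) -> np.ndarray:
    """First-derivative cubic B-spline basis values (per grid unit)."""
    t = np.asarray(t, dtype=float)
    t2 = t * t
    w = np.empty(t.shape + (4,))
    w[..., 0] = -(1 - t) ** 2 / 2.0
    w[..., 1] = (3 * t2 - 4 * t) / 2.0
    w[..., 2] = (-3 * t2 + 2 * t + 1) / 2.0
    w[..., 3] = t2 / 2.0
    return w


def bspline_weights(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis values for fractional offsets ``t`` in [0, 1).

    Returns an array (..., 4): weights of control points i-1, i, i+1, i+2
    where i = floor(u) and t = u - i in grid units.
    """
    t = np.asarray(t, dtype=float)
    t2 = t * t
    t3 = t2 * t
    w = np.empty(t.shape + (4,))
    w[..., 0] = (1 - 3 * t + 3 * t2 - t3) / 6.0
    w[..., 1] = (3 * t3 - 6 * t2 + 4) / 6.0
    w[..., 2] = (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0
    w[..., 3] = t3 / 6.0
    return w


@dataclass
class BSplineMotionModel:
    """Per-timepoint cubic B-spline displacement fields on a shared grid.

    Parameters
    ----------
    control_spacing : (3,) float
        Control-point spacing in mm per axis.
    origin : (3,) float
        World position (mm) of control-point index (0, 0, 0); includes the
        cubic support margin, so it lies outside the image domain.
    coefficients : ndarray (T, nx, ny, nz, 3)
        Control-point displacement vectors in mm, one grid per timepoint.
    """

    control_spacing: np.ndarray
    origin: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.control_spacing = np.asarray(self.control_spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 5 or self.coefficients.shape[-1] != 3:
            raise ValueError("coefficients must have shape (T, nx, ny, nz, 3)")

    # ------------------------------------------------------------------ setup
    @classmethod
    def for_domain(cls, shape, spacing, control_spacing_mm, n_timepoints,
                   coefficients=None) -> "BSplineMotionModel":
        """Grid covering the image domain plus the cubic-support margin."""
        shape = np.asarray(shape[:3], dtype=int)
        spacing = np.asarray(spacing, dtype=float)
        cs = np.broadcast_to(np.asarray(control_spacing_mm, dtype=float),
                             (3,)).astype(float)
        extent = (shape - 1) * spacing
        n_ctrl = np.floor(extent / cs).astype(int) + 4
        origin = -cs
        if coefficients is None:
            coefficients = np.zeros((n_timepoints, *n_ctrl, 3))
        return cls(control_spacing=cs, origin=origin, coefficients=coefficients)

    @property
    def n_timepoints(self) -> int:
        return self.coefficients.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape[1:4]

    # ------------------------------------------------------------- evaluation
    def support(self, points_mm: np.ndarray):
        """Base control indices and per-axis basis weights for sample points.

        Returns ``(base, weights)``: ``base`` (N, 3) int index of the i-1
        corner of each point's 4x4x4 support cube, ``weights`` a list of
        three (N, 4) arrays.  Indices are clamped to the grid.
        """
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        u = (pts - self.origin) / self.control_spacing
        i = np.floor(u).astype(int)
        t = u - i
        grid = np.asarray(self.grid_shape)
        i = np.clip(i, 1, grid - 3)  # keep the 4-point stencil inside the grid
        weights = [bspline_weights(t[:, a]) for a in range(3)]
        return i - 1, weights

    def displacement(self, points_mm: np.ndarray, timepoint: int) -> np.ndarray:
        """Displacement vectors (mm) at arbitrary world points, one timepoint."""
        base, (wx, wy, wz) = self.support(points_mm)
        coef = self.coefficients[timepoint]
        out = np.zeros((base.shape[0], 3))
        for a in range(4):
            ix = base[:, 0] + a
            for b in range(4):
                iy = base[:, 1] + b
                wab = wx[:, a] * wy[:, b]
                for c in range(4):
                    iz = base[:, 2] + c
                    out += (wab * wz[:, c])[:, None] * coef[ix, iy, iz]
        return out

    def dense_displacement(self, shape, spacing, timepoint: int) -> np.ndarray:
        """Displacement field (mm) sampled at every voxel center: (nx,ny,nz,3)."""
        shape = tuple(int(s) for s in shape[:3])
        spacing = np.asarray(spacing, dtype=float)
        idx = np.indices(shape).reshape(3, -1).T * spacing
        return self.displacement(idx, timepoint).reshape(*shape, 3)

    def warp_volume(self, volume: np.ndarray, spacing, timepoint: int,
                    order: int = 1, cval: float | None = None) -> np.ndarray:
        """Backward-warp one volume through this timepoint's deformation.

        ``out(x) = volume(x + u_t(x))`` with spline interpolation of the
        given order; out-of-domain samples take ``cval`` (default: the
        volume minimum, a background value).
        """
        spacing = np.asarray(spacing, dtype=float)
        disp = self.dense_displacement(volume.shape, spacing, timepoint)
        coords = (np.indices(volume.shape).transpose(1, 2, 3, 0)
                  + disp / spacing)
        if cval is None:
            cval = float(volume.min())
        # mirror boundaries keep the cubic stencil accurate up to the edge;
        # truly out-of-domain voxels get the background value explicitly
        out = ndimage.map_coordinates(volume, coords.transpose(3, 0, 1, 2),
                                      order=order, mode="mirror")
        dims = np.asarray(volume.shape, dtype=float)
        outside = np.any((coords < 0) | (coords > dims - 1), axis=-1)
        out[outside] = cval
        return out

    # --------------------------------------------------------------- algebra
    def project_zero_mean(self) -> None:
        """Remove the temporal-mean displacement at every control point.

        This is the groupwise gauge: with no reference image the problem is
        underdetermined up to a common deformation; the zero-mean constraint
        pins it down and prevents drift.
        """
        self.coefficients -= self.coefficients.mean(axis=0, keepdims=True)

    def refined(self) -> "BSplineMotionModel":
        """Halve the control spacing by exact cubic B-spline subdivision.

        Even/odd insertion rules reproduce the displacement field exactly in
        the grid interior; edge stencils are clamped (margin only).
        """
        T = self.n_timepoints
        old = self.coefficients
        cs_new = self.control_spacing / 2.0
        origin_new = -cs_new
        grid = np.asarray(self.grid_shape)
        # world position of new index k along axis a: origin_new[a] + k*cs_new[a]
        # in old grid units u = (k + 1) / 2 - hence odd k hit old knots.
        n_new = 2 * (grid - 2) + 1  # covers the same world extent
        coef = old
        for axis in range(3):
            coef = np.moveaxis(coef, 1 + axis, 1)
            n = coef.shape[1]
            k = np.arange(n_new[axis])
            u2 = k + 1  # = 2u, integer
            even = u2 % 2 == 0
            i = u2 // 2
            im1 = np.clip(i - 1, 0, n - 1)
            i0 = np.clip(i, 0, n - 1)
            ip1 = np.clip(i + 1, 0, n - 1)
            new = np.where(
                even[(slice(None),) + (None,) * (coef.ndim - 2)],
                (coef[:, im1] + 6.0 * coef[:, i0] + coef[:, ip1]) / 8.0,
                (coef[:, i0] + coef[:, ip1]) / 2.0,
            )
            coef = np.moveaxis(new, 1, 1 + axis)
        return BSplineMotionModel(control_spacing=cs_new, origin=origin_new,
                                  coefficients=coef)

    def inverted(self, shape, spacing, n_iter: int = 30) -> "BSplineMotionModel":
        """Numerically exact inverse deformation on the given grid.

        Solves v(y) = -u(y + v(y)) per timepoint by fixed-point iteration
        at every control location of a voxel-spaced grid, then prefilters
        the sampled inverse into B-spline coefficients so the returned
        model interpolates it exactly at those locations.
        """
        from scipy import ndimage
        shape = tuple(int(s) for s in shape[:3])
        spacing = np.asarray(spacing, dtype=float)
        inv = BSplineMotionModel.for_domain(shape, spacing, spacing,
                                            self.n_timepoints)
        grid = np.asarray(inv.grid_shape)
        # control j sits at world (j - 1) * spacing, including the margin
        # ring outside the domain (the forward field extends smoothly there)
        coords = [np.arange(g) - 1.0 for g in grid]
        pts = np.stack(np.meshgrid(*coords, indexing="ij"),
                       axis=-1).reshape(-1, 3) * spacing
        for t in range(self.n_timepoints):
            if not np.any(self.coefficients[t]):
                continue
            v = np.zeros_like(pts)
            for _ in range(n_iter):
                v = -self.displacement(pts + v, t)
            vals = v.reshape(*grid, 3)
            coef = np.stack([ndimage.spline_filter(vals[..., a], order=3,
                                                   mode="mirror")
                             for a in range(3)], axis=-1)
            inv.coefficients[t] = coef
        return inv

    def copy(self) -> "BSplineMotionModel":
        return BSplineMotionModel(self.control_spacing.copy(),
                                  self.origin.copy(), self.coefficients.copy())

    # ------------------------------------------------------------------- I/O
    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "schema_version": TRANSFORM_SCHEMA_VERSION,
            "control_spacing_mm": self.control_spacing.tolist(),
            "origin_mm": self.origin.tolist(),
            "grid_shape": list(self.grid_shape),
            "n_timepoints": self.n_timepoints,
            "coefficients_mm": self.coefficients.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def from_json(cls, path) -> "BSplineMotionModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema_version") != TRANSFORM_SCHEMA_VERSION:
            raise ValueError("unsupported transform schema version")
        return cls(control_spacing=np.array(payload["control_spacing_mm"]),
                   origin=np.array(payload["origin_mm"]),
                   coefficients=np.array(payload["coefficients_mm"]))


class CubicVolumeInterpolator:
    """Cubic B-spline interpolation of a 3D volume with analytic gradient.

    The interpolant is C2-smooth everywhere, so finite differences of any
    functional built on it agree with the chain-rule gradient through
    :meth:`value_and_gradient` — the property the registration metric's
    analytic gradient relies on.  Boundary handling mirrors about the edge
    samples (consistent with the prefilter).
    """

    def __init__(self, volume: np.ndarray, spacing):
        from scipy import ndimage
        vol = np.ascontiguousarray(volume, dtype=float)
        self.coef = ndimage.spline_filter(vol, order=3, mode="mirror")
        self.shape = vol.shape
        self.spacing = np.asarray(spacing, dtype=float)

    @staticmethod
    def _mirror(idx: np.ndarray, n: int) -> np.ndarray:
        if n == 1:
            return np.zeros_like(idx)
        idx = np.abs(idx)
        period = 2 * n - 2
        idx = idx % period
        return np.where(idx >= n, period - idx, idx)

    def value_and_gradient(self, coords_vox: np.ndarray, need_gradient=True):
        """Interpolated values (N,) and gradients per mm (N, 3)."""
        pts = np.atleast_2d(np.asarray(coords_vox, dtype=float))
        i = np.floor(pts).astype(int)
        dims = np.asarray(self.shape)
        i = np.minimum(i, dims - 2)  # keep t in [0,1] at the top edge
        i = np.maximum(i, 0)
        t = pts - i
        w = [bspline_weights(t[:, a]) for a in range(3)]
        dw = [bspline_derivative_weights(t[:, a]) for a in range(3)]
        idx = [np.stack([self._mirror(i[:, a] + o - 1, dims[a])
                         for o in range(4)], axis=1) for a in range(3)]
        vals = np.zeros(pts.shape[0])
        grads = np.zeros((pts.shape[0], 3)) if need_gradient else None
        for a in range(4):
            ix = idx[0][:, a]
            for b in range(4):
                iy = idx[1][:, b]
                for c in range(4):
                    cz = self.coef[ix, iy, idx[2][:, c]]
                    vals += w[0][:, a] * w[1][:, b] * w[2][:, c] * cz
                    if need_gradient:
                        grads[:, 0] += dw[0][:, a] * w[1][:, b] * w[2][:, c] * cz
                        grads[:, 1] += w[0][:, a] * dw[1][:, b] * w[2][:, c] * cz
                        grads[:, 2] += w[0][:, a] * w[1][:, b] * dw[2][:, c] * cz
        if need_gradient:
            grads /= self.spacing
        return vals, grads
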