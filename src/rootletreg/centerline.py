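"""Spinal cord centerline extraction and straightening.

The centerline is fit as a pair of cubic smoothing splines x(z), y(z)
through the per-slice centers of mass of the binary cord mask.  The
straightened image resamples the input on planes orthogonal to the
centerline tangent, with the vertical axis parameterized by arc length so
distances along the cord are preserved by construction; in-plane frames
are parallel-transported along the curve to avoid spinning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline, interp1d

from .imgio import DisplacementField, LabelVolume, Volume, sample_at_world
from . import warps


class CenterlineError(ValueError):
    pass


@dataclass
class Centerline:
    """Smoothed cord centerline as a graph over the world z axis."""

    z_slices: np.ndarray        # world z of the fitted slices (ascending)
    raw_centers: np.ndarray     # (n, 2) pre-smoothing per-slice (x, y) mm
    _sx: UnivariateSpline
    _sy: UnivariateSpline
    _z_dense: np.ndarray
    _arc_dense: np.ndarray      # cumulative arc length (mm) at _z_dense

    @property
    def z_range(self):
        return float(self.z_slices[0]), float(self.z_slices[-1])

    @property
    def total_arc_length(self) -> float:
        return float(self._arc_dense[-1])

    def center_xy(self, z):
        """Smoothed (x, y) at world z; linear end-tangent extrapolation outside."""
        z = np.atleast_1d(np.asarray(z, float))
        lo, hi = self.z_range
        zc = np.clip(z, lo, hi)
        x = self._sx(zc)
        y = self._sy(zc)
        below, above = z < lo, z > hi
        if below.any():
            x[below] += self._sx.derivative()(lo) * (z[below] - lo)
            y[below] += self._sy.derivative()(lo) * (z[below] - lo)
        if above.any():
            x[above] += self._sx.derivative()(hi) * (z[above] - hi)
            y[above] += self._sy.derivative()(hi) * (z[above] - hi)
        return np.stack([x, y], axis=-1)

    def point(self, z):
        """3D point on the curve at world z."""
        z = np.atleast_1d(np.asarray(z, float))
        xy = self.center_xy(z)
        return np.concatenate([xy, z[:, None]], axis=1)

    def tangent(self, z):
        """Unit tangent (dx/dz, dy/dz, 1)/norm at world z (end values clamped)."""
        z = np.clip(np.atleast_1d(np.asarray(z, float)), *self.z_range)
        t = np.stack(
            [self._sx.derivative()(z), self._sy.derivative()(z), np.ones_like(z)],
            axis=-1,
        )
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def arc_length_at(self, z):
        """Cumulative arc length (mm) from the bottom of the fit range."""
        z = np.atleast_1d(np.asarray(z, float))
        lo, hi = self.z_range
        s = np.interp(np.clip(z, lo, hi), self._z_dense, self._arc_dense)
        s = s + np.where(z < lo, z - lo, 0.0) + np.where(z > hi, z - hi, 0.0)
        return s

    def z_at_arc_length(self, s):
        """Inverse of arc_length_at (linear extension beyond the ends)."""
        s = np.atleast_1d(np.asarray(s, float))
        S = self.total_arc_length
        z = np.interp(np.clip(s, 0.0, S), self._arc_dense, self._z_dense)
        lo, hi = self.z_range
        z = z + np.where(s < 0, s, 0.0) + np.where(s > S, s - S, 0.0)
        return z


def extract_centerline(cord: LabelVolume, smoothing: float = 1.0) -> Centerline:
    """Per-slice centers of mass, spline-smoothed along z.

    ``smoothing`` is the target mean squared residual (mm^2) per slice of
    the smoothing spline.  Empty slices inside the segmented z range are
    filled by linear interpolation of neighbouring centers.
    """
    mask = cord.labels > 0
    if not mask.any():
        raise CenterlineError("empty cord mask")
    counts = mask.sum(axis=(0, 1))
    filled = np.flatnonzero(counts > 0)
    if filled.size < 5:
        raise CenterlineError(f"need >= 5 non-empty axial slices, got {filled.size}")

    k_lo, k_hi = filled[0], filled[-1]
    ks = np.arange(k_lo, k_hi + 1)
    # voxel-space centers of mass per slice, vectorized
    ii, jj = np.meshgrid(np.arange(mask.shape[0]), np.arange(mask.shape[1]),
                         indexing="ij")
    ci = np.full(ks.size, np.nan)
    cj = np.full(ks.size, np.nan)
    for n, k in enumerate(ks):
        m = mask[:, :, k]
        c = m.sum()
        if c:
            ci[n] = (ii * m).sum() / c
            cj[n] = (jj * m).sum() / c
    good = ~np.isnan(ci)
    ci = np.interp(ks, ks[good], ci[good])
    cj = np.interp(ks, ks[good], cj[good])

    world = cord.index_to_world(np.stack([ci, cj, ks.astype(float)], axis=1))
    z = world[:, 2]
    order = np.argsort(z)
    z, wx, wy = z[order], world[order, 0], world[order, 1]

    s_factor = smoothing * z.size
    sx = UnivariateSpline(z, wx, k=3, s=s_factor)
    sy = UnivariateSpline(z, wy, k=3, s=s_factor)

    z_dense = np.linspace(z[0], z[-1], max(4 * z.size, 64))
    dxdz = sx.derivative()(z_dense)
    dydz = sy.derivative()(z_dense)
    speed = np.sqrt(dxdz**2 + dydz**2 + 1.0)
    arc = np.concatenate(
        [[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(z_dense))]
    )
    return Centerline(z, np.stack([wx, wy], axis=1), sx, sy, z_dense, arc)


def _transport_frames(centerline: Centerline, z_dense: np.ndarray):
    """Parallel-transported orthonormal in-plane frames (u, v) along the curve."""
    t = centerline.tangent(z_dense)
    u = np.empty_like(t)
    v = np.empty_like(t)
    u0 = np.array([1.0, 0.0, 0.0])
    u0 = u0 - t[0] * (u0 @ t[0])
    u0 /= np.linalg.norm(u0)
    u[0] = u0
    v[0] = np.cross(t[0], u0)
    for n in range(1, len(z_dense)):
        un = u[n - 1] - t[n] * (u[n - 1] @ t[n])
        norm = np.linalg.norm(un)
        if norm < 1e-9:  # degenerate tangent flip
            raise CenterlineError("centerline tangent undefined (degenerate spline)")
        u[n] = un / norm
        v[n] = np.cross(t[n], u[n])
    return u, v


def straighten(image: Volume, centerline: Centerline, like=None,
               pad_mm: float = 10.0, center_xy=None, s_anchor: float | None = None,
               order: int = 1, compute_inverse: bool = True):
    """Resample ``image`` so the centerline becomes the vertical axis.

    Output vertical coordinate = arc length along the centerline (distances
    along the cord are preserved).  If ``like`` is given its grid is used
    for the output (the template grid in the registration pipeline);
    otherwise a grid matching the input in-plane with the cord z range plus
    ``pad_mm`` is built.  ``center_xy`` fixes the world (x, y) where the
    straightened centerline sits (default: mean raw center).  ``s_anchor``
    maps arc length s to output z via z = s + s_anchor (default aligns the
    arc-length midpoint with the output grid's z midpoint).

    Returns (straightened Volume, straightening field on the output grid,
    inverse field on the input grid or None).
    """
    vx = image.voxel_size
    if like is not None:
        out_shape, out_affine = tuple(like.shape), np.asarray(like.affine, float)
    else:
        lo, hi = centerline.z_range
        nz = int(np.ceil((centerline.total_arc_length + 2 * pad_mm) / vx[2]))
        out_affine = image.affine.copy()
        out_shape = (image.shape[0], image.shape[1], nz)

    probe = Volume(np.zeros(out_shape), out_affine)
    if center_xy is None:
        center_xy = centerline.raw_centers.mean(axis=0)
    cx, cy = float(center_xy[0]), float(center_xy[1])

    # output z values and the arc length each one represents
    kz = np.arange(out_shape[2], dtype=float)
    z_out = out_affine[2, 2] * kz + out_affine[2, 3] \
        if _is_z_separable(out_affine) else None
    if z_out is None:
        raise CenterlineError("output grid must have a z-separable affine")
    if s_anchor is None:
        s_anchor = 0.5 * (z_out[0] + z_out[-1]) - 0.5 * centerline.total_arc_length
    s_out = z_out - s_anchor

    z_curve = centerline.z_at_arc_length(s_out)
    lo, hi = centerline.z_range
    inside = (z_curve >= lo) & (z_curve <= hi)
    c = centerline.point(z_curve)
    t = centerline.tangent(z_curve)
    # beyond the fit range extend linearly along the end tangents
    for side, zend in ((z_curve < lo, lo), (z_curve > hi, hi)):
        if side.any():
            pe = centerline.point(np.array([zend]))[0]
            te = centerline.tangent(np.array([zend]))[0]
            s_end = centerline.arc_length_at(np.array([zend]))[0]
            c[side] = pe + (s_out[side] - s_end)[:, None] * te

    zf = np.linspace(z_curve[inside].min() if inside.any() else lo,
                     z_curve[inside].max() if inside.any() else hi,
                     max(2 * out_shape[2], 64))
    uf, vf = _transport_frames(centerline, zf)
    u = np.stack([np.interp(np.clip(z_curve, zf[0], zf[-1]), zf, uf[:, c_]) for c_ in range(3)], axis=1)
    v = np.stack([np.interp(np.clip(z_curve, zf[0], zf[-1]), zf, vf[:, c_]) for c_ in range(3)], axis=1)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v -= u * (v * u).sum(axis=1, keepdims=True)
    v /= np.linalg.norm(v, axis=1, keepdims=True)

    # world coordinates of the output grid
    w_out = probe.world_coords()
    dx = w_out[..., 0] - cx
    dy = w_out[..., 1] - cy
    # sampling points: curve point + in-plane offsets along transported frame
    pts = (c[None, None, :, :]
           + dx[..., None] * u[None, None, :, :]
           + dy[..., None] * v[None, None, :, :])
    data = sample_at_world(image.data, image.affine, pts, order=order)
    straightened = Volume(data, out_affine)

    fwd = DisplacementField(pts - w_out, out_affine, "forward", "template")
    inv = None
    if compute_inverse:
        inv = warps.invert(fwd, target_shape=image.shape, target_affine=image.affine,
                           max_iter=100, tol_mm=0.05)
    return straightened, fwd, inv


def _is_z_separable(affine, tol=1e-9) -> bool:
    a = np.asarray(affine, float)
    return (abs(a[2, 0]) < tol and abs(a[2, 1]) < tol and a[2, 2] > 0
            and abs(a[0, 2]) < tol and abs(a[1, 2]) < tol)
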