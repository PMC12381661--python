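"""Displacement-field post-processing and application.

All fields use pull-back semantics: a field on grid G maps a point p on G
to the sampling location ``p + field(p)`` in the source space.  Composition
therefore chains as ``result(p) = outer(p) + inner(p + outer(p))`` — the
outer field is traversed first when pulling an image back through both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import medfilt

from .imgio import (
    DisplacementField,
    LabelVolume,
    Volume,
    check_same_grid,
    sample_at_world,
)

#: |dz| at or below this (mm) counts as "zero" when slice-averaging.
ZERO_TOL = 1e-9


class WarpError(ValueError):
    pass


@dataclass
class ScaleProfile:
    """Per-slice isotropic in-plane scale factors about per-slice centers."""

    scales: np.ndarray          # (nz,), unitless
    centers: np.ndarray         # (nz, 2) world mm (x, y)

    def __post_init__(self):
        self.scales = np.asarray(self.scales, float)
        self.centers = np.asarray(self.centers, float)
        if np.any(~np.isfinite(self.scales)) or np.any(~np.isfinite(self.centers)):
            raise WarpError("scale profile must be finite")
        if np.any(self.scales <= 0.2) or np.any(self.scales >= 5.0):
            raise WarpError("scale factors must lie in (0.2, 5)")


def symmetrize_slicewise(fld: DisplacementField, zero_tol: float = ZERO_TOL) -> DisplacementField:
    """Replace each axial slice's dz by the mean of its non-zero values.

    The mean is broadcast across the whole slice, which makes the result
    exactly left-right symmetric; slices with no non-zero dz stay zero.
    Requires a z-only field (x and y components all zero).
    """
    v = fld.vectors
    if np.any(v[..., 0] != 0) or np.any(v[..., 1] != 0):
        raise WarpError("symmetrize_slicewise requires zero x/y components")
    dz = v[..., 2]
    out = np.zeros_like(v)
    for k in range(dz.shape[2]):
        vals = dz[:, :, k][np.abs(dz[:, :, k]) > zero_tol]
        if vals.size == 0:
            continue
        if vals.min() == vals.max():      # constant slice: idempotent path
            m = vals.flat[0]
        else:
            # sorted summation: bit-identical under any grid permutation
            m = np.sort(vals).sum() / vals.size
        out[:, :, k, 2] = 0.0 if abs(m) <= zero_tol else m
    return DisplacementField(out, fld.affine, fld.direction, fld.reference)


def xy_scaling(subject_cord_warped: LabelVolume, template_cord: LabelVolume,
               median_window: int = 5, clamp=(0.25, 4.0)):
    """In-plane isotropic scaling matching the subject cord size to the template.

    Per template slice z the scale is s(z) = sqrt(area_template / area_subject)
    about the template cord center of that slice, median-filtered along z;
    slices where either mask is empty get s = 1.  Returned as a pull-back
    field with zero z component (at template point p the subject is sampled
    at ``center + (p - center)/s``), plus the ScaleProfile.
    """
    if not check_same_grid(subject_cord_warped, template_cord):
        raise WarpError("cord masks must share the template grid")
    sub = subject_cord_warped.labels > 0
    tpl = template_cord.labels > 0
    nz = tpl.shape[2]
    area_sub = sub.sum(axis=(0, 1)).astype(float)
    area_tpl = tpl.sum(axis=(0, 1)).astype(float)
    tpl_slices = area_tpl > 0
    if tpl_slices.sum() and (area_sub[tpl_slices] == 0).mean() > 0.5:
        raise WarpError("subject cord empty on >50% of template cord slices")

    both = (area_sub > 0) & (area_tpl > 0)
    scales = np.ones(nz)
    scales[both] = np.sqrt(area_tpl[both] / area_sub[both])
    if median_window > 1:
        scales = medfilt(scales, kernel_size=median_window)
    scales = np.clip(scales, clamp[0], clamp[1])

    # per-slice template cord center (world mm); overall centroid as fallback
    world = template_cord.world_coords()
    if tpl.any():
        cx_all, cy_all = world[tpl][:, 0].mean(), world[tpl][:, 1].mean()
    else:
        cx_all = cy_all = 0.0
    centers = np.tile([cx_all, cy_all], (nz, 1))
    for k in np.flatnonzero(tpl_slices):
        m = tpl[:, :, k]
        centers[k, 0] = world[:, :, k, 0][m].mean()
        centers[k, 1] = world[:, :, k, 1][m].mean()

    vec = np.zeros(tuple(tpl.shape) + (3,))
    factor = (1.0 / scales - 1.0)[None, None, :]
    vec[..., 0] = (world[..., 0] - centers[None, None, :, 0]) * factor
    vec[..., 1] = (world[..., 1] - centers[None, None, :, 1]) * factor
    fld = DisplacementField(vec, template_cord.affine, "forward", "template")
    return fld, ScaleProfile(scales, centers)


def sample_field(fld: DisplacementField, pts_xyz: np.ndarray) -> np.ndarray:
    """Linearly interpolate a field at world points; edge-clamped outside.

    Clamping (rather than zero) keeps the field continuous across the grid
    boundary, which composition and fixed-point inversion rely on.
    """
    pts = np.asarray(pts_xyz, float)
    out = np.empty(pts.shape)
    for c in range(3):
        out[..., c] = sample_at_world(fld.vectors[..., c], fld.affine, pts,
                                      order=1, mode="nearest")
    return out


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Single field equivalent to pulling back through ``outer`` then ``inner``.

    result(p) = outer(p) + inner(p + outer(p)), with linear interpolation of
    ``inner`` off its grid.  Lives on the grid of ``outer``.  The chaining
    rule is purely positional: the caller must ensure ``inner`` is defined
    on the space that ``outer`` points into (direction flags are
    descriptive, which is what lets a field be composed with its inverse).
    """
    pts = outer.world_coords()
    inner_at = sample_field(inner, pts + outer.vectors)
    return DisplacementField(
        outer.vectors + inner_at, outer.affine, outer.direction, outer.reference
    )


def invert(fld: DisplacementField, target_shape=None, target_affine=None,
           max_iter: int = 50, tol_mm: float = 0.05, damping: float = 0.5) -> DisplacementField:
    """Damped fixed-point inverse: g with g(q) = -f(q + g(q)).

    The update is relaxed by ``damping`` which keeps the iteration
    contractive for displacement gradients well beyond the undamped limit.
    Optionally evaluated on a different target grid (e.g. the subject grid
    for a field defined on the template grid).  Raises on non-convergence,
    which signals a folded field.
    """
    if target_affine is None:
        target_affine = fld.affine
        target_shape = fld.shape
    probe = Volume(np.zeros(tuple(target_shape)), target_affine)
    pts = probe.world_coords()
    g = None
    # steeper displacement gradients need a smaller relaxation factor
    for alpha in (damping, damping / 2, damping / 4):
        g = np.zeros(pts.shape)
        converged = False
        for _ in range(max_iter):
            proposal = -sample_field(fld, pts + g)
            delta = np.max(np.abs(proposal - g))   # fixed-point residual
            g = (1.0 - alpha) * g + alpha * proposal
            if delta < tol_mm:
                converged = True
                break
        if converged:
            break
    else:
        raise WarpError(
            f"displacement inversion did not converge (last update {delta:.3f} mm); "
            "field may be folded"
        )
    direction = "backward" if fld.direction == "forward" else "forward"
    reference = "subject" if fld.reference == "template" else "template"
    return DisplacementField(g, target_affine, direction, reference)


def apply_warp(image, fld: DisplacementField, interpolation: str | None = None):
    """Pull-back resampling of a Volume or LabelVolume onto the field's grid.

    Volumes default to linear interpolation, label volumes to nearest
    neighbour; linear on labels is refused.  Out-of-field samples are 0.
    """
    is_labels = isinstance(image, LabelVolume)
    if interpolation is None:
        interpolation = "nearest" if is_labels else "linear"
    if interpolation not in ("linear", "nearest"):
        raise WarpError(f"unknown interpolation {interpolation!r}")
    if is_labels and interpolation == "linear":
        raise WarpError("linear interpolation on a label volume is refused")
    order = 0 if interpolation == "nearest" else 1
    pts = fld.vectors + _grid_world(fld)
    if is_labels:
        out = sample_at_world(image.labels, image.affine, pts, order=order)
        return LabelVolume(np.rint(out).astype(image.labels.dtype), fld.affine,
                           kind=image.kind)
    out = sample_at_world(image.data, image.affine, pts, order=order)
    return Volume(out, fld.affine)


def _grid_world(fld: DisplacementField) -> np.ndarray:
    return fld.world_coords()
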