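"""Masked non-linear refinement of the rostro-caudal alignment.

After straightening and landmark alignment, the subject and template
images — each masked by its (dilated) rootlet segmentation — are brought
into register by a deformation restricted to the z axis: a single cubic
B-spline displacement profile dz(z), shared in-plane, optimized greedily
over a shrink-factor pyramid with a monotone (accept-only-improvement)
line search on the similarity metric.  Because the next pipeline stage
averages the field slice-wise anyway, the in-plane constancy loses
nothing; the field it emits is non-zero only inside the mask so the
slice-wise averaging step has a well-defined non-zero support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline
from scipy.ndimage import binary_dilation, gaussian_filter1d, generate_binary_structure

from .imgio import DisplacementField, LabelVolume, Volume, check_same_grid


class ZRegError(ValueError):
    pass


@dataclass
class ZRegParams:
    """Configuration of the rostro-caudal B-spline refinement.

    spacing_mm: control-point spacing of the z displacement profile.
    pyramid: shrink factors, coarse to fine; each level smooths along z
        with sigma = 0.5 * factor voxels (factor 1 = no smoothing).
    metric: 'ncc' (normalized cross-correlation) or 'ssd' (mean squares).
    iters: optimizer iterations per pyramid level.
    step_mm: initial gradient-ascent step length.
    tol: stop when the metric improves by less than this.
    dilation: mask dilation radius in voxels.
    cap_mm: bound on |dz|.
    """

    spacing_mm: float = 10.0
    pyramid: tuple = (4, 2, 1)
    metric: str = "ncc"
    iters: int = 50
    step_mm: float = 1.0
    tol: float = 1e-6
    dilation: int = 3
    cap_mm: float = 10.0

    def __post_init__(self):
        if self.iters < 1:
            raise ZRegError("iters must be >= 1")
        if self.dilation < 0:
            raise ZRegError("dilation radius must be >= 0")
        if self.metric not in ("ncc", "ssd"):
            raise ZRegError(f"unknown metric {self.metric!r}")

    @classmethod
    def from_param_string(cls, text: str, base: "ZRegParams | None" = None) -> "ZRegParams":
        """Parse 'key=value,key=value' overrides (CLI parity)."""
        params = base or cls()
        if not text:
            return params
        updates = {}
        casts = {
            "spacing_mm": float, "metric": str, "iters": int, "step_mm": float,
            "tol": float, "dilation": int, "cap_mm": float,
            "pyramid": lambda s: tuple(int(x) for x in s.split("x")),
        }
        for item in text.split(","):
            if "=" not in item:
                raise ZRegError(f"malformed param {item!r}; expected key=value")
            key, value = item.split("=", 1)
            key = key.strip()
            if key not in casts:
                raise ZRegError(f"unknown zreg parameter {key!r}")
            updates[key] = casts[key](value.strip())
        return replace(params, **updates)


def dilate_labels(labels: LabelVolume, radius: int) -> LabelVolume:
    """Binary union of all non-zero labels, dilated with a 6-connected element.

    ``radius`` iterations of the 3D city-block structuring element, i.e. the
    L1 ball of the given radius on the lattice; radius 0 just binarizes.
    """
    if radius < 0:
        raise ZRegError("dilation radius must be >= 0")
    mask = labels.labels > 0
    if radius > 0:
        struct = generate_binary_structure(3, 1)
        mask = binary_dilation(mask, structure=struct, iterations=radius)
    return LabelVolume(mask.astype(np.int16), labels.affine, kind="cord")


def _bspline_design(z: np.ndarray, spacing: float):
    """Cubic B-spline design matrix over the span of z (+ margin knots)."""
    lo, hi = float(z.min()) - spacing, float(z.max()) + spacing
    n_int = max(int(np.ceil((hi - lo) / spacing)), 1)
    knots = lo + spacing * np.arange(-3, n_int + 4)
    n_coef = len(knots) - 4
    design = np.empty((z.size, n_coef))
    for j in range(n_coef):
        c = np.zeros(n_coef)
        c[j] = 1.0
        design[:, j] = BSpline(knots, c, 3, extrapolate=False)(z)
    design[~np.isfinite(design)] = 0.0
    return design


def _metric(name, tpl, warped):
    if name == "ssd":
        return -float(np.mean((tpl - warped) ** 2))
    t = tpl - tpl.mean()
    w = warped - warped.mean()
    denom = np.sqrt((t * t).sum() * (w * w).sum())
    if denom < 1e-12:
        return -1.0
    return float((t * w).sum() / denom)


def _warp_z(sub: np.ndarray, dz_vox: np.ndarray) -> np.ndarray:
    """Resample ``sub`` along z at slice positions k + dz_vox[k] (linear)."""
    nz = sub.shape[2]
    zq = np.arange(nz) + dz_vox
    i0 = np.floor(zq).astype(int)
    w = zq - i0
    i1 = i0 + 1
    valid0 = (i0 >= 0) & (i0 < nz)
    valid1 = (i1 >= 0) & (i1 < nz)
    a = sub[:, :, np.clip(i0, 0, nz - 1)] * valid0[None, None, :]
    b = sub[:, :, np.clip(i1, 0, nz - 1)] * valid1[None, None, :]
    return a * (1.0 - w)[None, None, :] + b * w[None, None, :]


def register_z(subject_masked: Volume, template_masked: Volume,
               params: ZRegParams | None = None):
    """Estimate the z-only displacement profile aligning the masked images.

    Returns (DisplacementField, diagnostics).  The field is a pull-back
    field on the template grid: its z component at slice z is the offset at
    which the subject image should be sampled; it is non-zero only within
    the template mask support.  Diagnostics carry the per-level metric
    traces (non-decreasing across accepted steps) and the fitted profile.
    """
    params = params or ZRegParams()
    if not check_same_grid(subject_masked, template_masked):
        raise ZRegError("subject and template must be on the same grid")
    dz_vox_size = float(template_masked.voxel_size[2])
    if params.spacing_mm <= dz_vox_size:
        raise ZRegError("control-point spacing must exceed the voxel size")

    tpl = np.asarray(template_masked.data, float)
    sub = np.asarray(subject_masked.data, float)
    mask = tpl != 0
    if not mask.any() or not (sub != 0).any():
        raise ZRegError("empty mask overlap")

    # crop in-plane to the mask bounding box (cheap cost evaluations)
    ij = np.argwhere(mask.any(axis=2))
    i0, j0 = ij.min(axis=0)
    i1, j1 = ij.max(axis=0) + 1
    tpl_c = tpl[i0:i1, j0:j1, :]
    sub_c = sub[i0:i1, j0:j1, :]
    mask_c = mask[i0:i1, j0:j1, :]

    zk = np.flatnonzero(mask_c.any(axis=(0, 1)))
    affine = template_masked.affine
    z_world = affine[2, 2] * np.arange(tpl.shape[2]) + affine[2, 3]
    design = _bspline_design(z_world, params.spacing_mm)
    coef = np.zeros(design.shape[1])
    active = np.flatnonzero(np.abs(design[zk, :]).sum(axis=0) > 1e-9)

    traces = []
    for factor in params.pyramid:
        sigma = 0.5 * factor if factor > 1 else 0.0
        if sigma > 0:
            tpl_l = gaussian_filter1d(tpl_c, sigma, axis=2)
            sub_l = gaussian_filter1d(sub_c, sigma, axis=2)
        else:
            tpl_l, sub_l = tpl_c, sub_c
        t_mask = tpl_l[mask_c]

        def cost(c):
            dz = np.clip(design @ c, -params.cap_mm, params.cap_mm)
            warped = _warp_z(sub_l, dz / dz_vox_size)
            m = _metric(params.metric, t_mask, warped[mask_c])
            if not np.isfinite(m):
                raise ZRegError("non-finite similarity metric")
            return m

        current = cost(coef)
        trace = [current]
        step = params.step_mm * factor
        eps = 0.05
        for _ in range(params.iters):
            grad = np.zeros_like(coef)
            for j in active:
                cp = coef.copy(); cp[j] += eps
                cm = coef.copy(); cm[j] -= eps
                grad[j] = (cost(cp) - cost(cm)) / (2 * eps)
            gnorm = np.linalg.norm(grad)
            if gnorm < 1e-12:
                break
            direction = grad / gnorm
            improved = False
            s = step
            for _try in range(8):
                cand = np.clip(coef + s * direction, -params.cap_mm, params.cap_mm)
                val = cost(cand)
                if val > current:   # accept only improvements: monotone trace
                    coef, current = cand, val
                    improved = True
                    break
                s *= 0.5
            trace.append(current)
            if not improved or (len(trace) > 1 and trace[-1] - trace[-2] < params.tol):
                break
        traces.append(trace)

    dz = np.clip(design @ coef, -params.cap_mm, params.cap_mm)
    vec = np.zeros(tuple(tpl.shape) + (3,))
    vec[..., 2] = np.where(mask, dz[None, None, :], 0.0)
    fld = DisplacementField(vec, affine, "forward", "template")
    diagnostics = {"metric_traces": traces, "dz_profile_mm": dz,
                   "final_metric": traces[-1][-1]}
    return fld, diagnostics
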