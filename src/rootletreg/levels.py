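"""Per-level landmark centers and 1D rostro-caudal landmark alignment.

Rootlet levels are coded 2..8 for C2..C8 (disc labels use the same kind of
integer codes).  The alignment between subject and template landmarks is a
monotone 1D mapping along z: exact at the landmark z positions, monotone
piecewise-cubic (PCHIP, shape-preserving) between them, and extended with a
constant shift beyond the outermost landmarks so the deformation does not
run away above C2 or below C8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .imgio import DisplacementField, LabelVolume


class LevelError(ValueError):
    pass


@dataclass
class LevelCenters:
    """Map level code -> world (x, y, z) center of mass, plus voxel counts."""

    centers: dict = field(default_factory=dict)   # code -> np.ndarray (3,)
    counts: dict = field(default_factory=dict)    # code -> int

    @property
    def codes(self):
        return sorted(self.centers)

    def z_of(self, code: int) -> float:
        return float(self.centers[code][2])

    @property
    def z_values(self) -> np.ndarray:
        return np.array([self.z_of(c) for c in self.codes])


def level_centers(labels: LabelVolume) -> LevelCenters:
    """Unweighted world-mm center of mass of each non-zero label code.

    Requires >= 2 distinct levels and strictly decreasing z with increasing
    code (more caudal levels are more inferior); violation signals a
    corrupt segmentation.
    """
    codes = np.unique(labels.labels)
    codes = codes[codes != 0]
    if codes.size < 2:
        raise LevelError(f"need >= 2 labelled levels for alignment, got {codes.size}")
    out = LevelCenters()
    for code in codes:
        idx = np.argwhere(labels.labels == code).astype(float)
        world = labels.index_to_world(idx)
        out.centers[int(code)] = world.mean(axis=0)
        out.counts[int(code)] = idx.shape[0]
    zs = out.z_values
    if not np.all(np.diff(zs) < 0):
        raise LevelError(
            "level z centers are not strictly decreasing with level code "
            f"(z = {np.round(zs, 2).tolist()} for codes {out.codes})"
        )
    return out


def _common_knots(subject: LevelCenters, template: LevelCenters):
    common = sorted(set(subject.codes) & set(template.codes))
    if len(common) < 2:
        raise LevelError(f"need >= 2 common levels, got {len(common)}")
    full = list(range(common[0], common[-1] + 1))
    gaps = [c for c in full if c not in common]
    if gaps:
        warnings.warn(
            f"missing intermediate level(s) {gaps}; interpolating across the gap",
            stacklevel=3,
        )
    sub_z = np.array([subject.z_of(c) for c in common])
    tpl_z = np.array([template.z_of(c) for c in common])
    return common, sub_z, tpl_z


def level_mapping(subject: LevelCenters, template: LevelCenters):
    """Monotone mappings (subject z -> template z, template z -> subject z).

    Both interpolate the landmark pairs exactly with PCHIP and continue
    with a constant shift beyond the outermost landmarks.
    """
    _, sub_z, tpl_z = _common_knots(subject, template)
    # knots ascending in z (C8 ... C2)
    order = np.argsort(sub_z)
    sub_z, tpl_z = sub_z[order], tpl_z[order]
    if not (np.all(np.diff(sub_z) > 0) and np.all(np.diff(tpl_z) > 0)):
        raise LevelError("crossing landmarks: level mapping would be non-monotone")

    def _make(src, dst):
        interp = PchipInterpolator(src, dst, extrapolate=False)
        lo_shift = dst[0] - src[0]
        hi_shift = dst[-1] - src[-1]

        def f(z):
            z = np.asarray(z, float)
            out = interp(np.clip(z, src[0], src[-1]))
            out = np.where(z < src[0], z + lo_shift, out)
            out = np.where(z > src[-1], z + hi_shift, out)
            return out

        return f

    return _make(sub_z, tpl_z), _make(tpl_z, sub_z)


def build_level_alignment(subject: LevelCenters, template: LevelCenters,
                          reference_grid) -> DisplacementField:
    """z-only pull-back field on the reference grid aligning subject levels.

    At a template-grid point with coordinate z the field's z component is
    ``m(z) - z`` where m maps template z to the matching subject z, so
    pulling the subject image back through the field lands each subject
    level at its template position.  x and y components are zero.
    """
    _, m_t2s = level_mapping(subject, template)
    shape = tuple(reference_grid.shape)[:3]
    affine = np.asarray(reference_grid.affine, float)
    # z of each output slice (z-separable canonical affine)
    kz = np.arange(shape[2], dtype=float)
    z = affine[2, 2] * kz + affine[2, 3]
    dz = m_t2s(z) - z
    # no-fold check on the sampled mapping
    if np.any(np.diff(z + dz) <= 0):
        raise LevelError("level mapping folds over along z")
    vec = np.zeros(shape + (3,))
    vec[..., 2] = dz[None, None, :]
    return DisplacementField(vec, affine, "forward", "template")


def disc_baseline_alignment(subject_discs: LevelCenters, template_discs: LevelCenters,
                            reference_grid) -> DisplacementField:
    """Disc-landmark baseline: identical machinery, disc codes as landmarks."""
    return build_level_alignment(subject_discs, template_discs, reference_grid)
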