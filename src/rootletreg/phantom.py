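"""Synthetic cervical spinal cord phantoms with known ground truth.

The generator emulates the inputs of the registration pipeline at the
resolution of the validation images (0.8 mm isotropic): a T2-like
intensity volume, a binary cord mask, level-labelled dorsal rootlet blobs
(codes 2..8 = C2..C8), and single-voxel intervertebral disc labels.  The
cord is a tube along a (possibly curved) centerline with a Gaussian radius
bulge at the cervical enlargement; neck position is modelled as a smooth
sagittal bend (flexion/extension of opposite sign) combined with a small
slide of the cord — and everything attached to it: rootlets, enlargement —
along the canal relative to the vertebral discs, which is what decouples
spinal from vertebral levels across positions.

``generate_cohort`` adds inter-subject variability: per-level rootlet
jitter that grows linearly toward caudal levels, and a per-subject
rootlet-vs-disc offset that decouples the two landmark systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .imgio import LabelVolume, Volume


class PhantomError(ValueError):
    pass


def _default_rootlets():
    # world z (mm) of rootlet level centers C2..C8, ~13 mm apart
    return {2: 118.0, 3: 105.0, 4: 92.0, 5: 79.0, 6: 66.0, 7: 53.0, 8: 40.0}


def _default_discs():
    # disc labels follow the host convention: 3 = C2-C3 disc, ... 8 = C7-T1
    return {3: 111.0, 4: 98.0, 5: 85.0, 6: 72.0, 7: 59.0, 8: 46.0}


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic cervical cord."""

    shape: tuple = (48, 48, 176)
    resolution: float = 0.8                  # mm, isotropic
    cord_radius: float = 4.0                 # mm baseline
    enlargement_z: float = 72.0              # mm, between C5 and C6
    enlargement_amp: float = 1.3             # mm added radius at the bulge
    enlargement_width: float = 12.0          # mm Gaussian sigma
    rootlet_z: dict = field(default_factory=_default_rootlets)
    rootlet_radius: float = 1.6              # mm, blob in-plane radius
    rootlet_halflength: float = 3.5          # mm, blob half-extent along z
    disc_z: dict = field(default_factory=_default_discs)
    cord_z_range: tuple = (20.0, 130.0)      # mm
    curvature: str = "neutral"               # neutral | flexion | extension
    curvature_amp: float = 6.0               # mm peak sagittal bow
    cord_slide_mm: float = 3.0               # cord slide along canal per position
    intensity: dict = field(default_factory=lambda: {
        "background": 60.0, "csf": 255.0, "cord": 130.0, "rootlet": 95.0})
    csf_margin: float = 2.5                  # mm CSF ring around the cord
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise PhantomError("resolution must be positive")
        if self.cord_radius <= 0 or self.rootlet_radius <= 0 or self.enlargement_width <= 0:
            raise PhantomError("radii and widths must be positive")
        for name, zz in (("rootlet", self.rootlet_z), ("disc", self.disc_z)):
            z = [zz[k] for k in sorted(zz)]
            if not all(b < a for a, b in zip(z, z[1:])):
                raise PhantomError(f"{name} z positions must strictly decrease with level code")
        if self.curvature not in ("neutral", "flexion", "extension"):
            raise PhantomError(f"unknown curvature mode {self.curvature!r}")


@dataclass
class PhantomSet:
    """One generated phantom and its ground-truth record."""

    image: Volume
    cord: LabelVolume
    rootlets: LabelVolume
    discs: LabelVolume
    truth: dict


def _slide_sign(mode: str) -> float:
    return {"neutral": 0.0, "flexion": 1.0, "extension": -1.0}[mode]


def generate_phantom(spec: PhantomSpec) -> PhantomSet:
    """Build the image + label volumes of one phantom (deterministic per seed)."""
    nx, ny, nz = spec.shape
    res = spec.resolution
    affine = np.diag([res, res, res, 1.0])
    x = res * np.arange(nx)
    y = res * np.arange(ny)
    z = res * np.arange(nz)
    cx, cy = res * (nx - 1) / 2.0, res * (ny - 1) / 2.0

    zlo, zhi = spec.cord_z_range
    sign = _slide_sign(spec.curvature)
    amp = 0.0 if spec.curvature == "neutral" else sign * spec.curvature_amp
    slide = sign * spec.cord_slide_mm

    # sagittal (y) bow of the canal over the cord range, zero at the ends
    def y_offset(zv):
        u = np.clip((zv - zlo) / (zhi - zlo), 0.0, 1.0)
        return amp * np.sin(np.pi * u)

    rootlet_z = {k: v + slide for k, v in spec.rootlet_z.items()}
    enlargement_z = spec.enlargement_z + slide

    yoff = y_offset(z)                                     # (nz,)
    radius = spec.cord_radius + spec.enlargement_amp * np.exp(
        -((z - enlargement_z) ** 2) / (2 * spec.enlargement_width ** 2))
    in_range = (z >= zlo) & (z <= zhi)

    dx2 = (x[:, None, None] - cx) ** 2                      # (nx,1,1)
    dy = y[None, :, None] - (cy + yoff[None, None, :])      # (nx? broadcast)
    r2 = dx2 + dy ** 2                                      # (nx,ny,nz)
    cord = (r2 <= (radius[None, None, :] ** 2)) & in_range[None, None, :]
    csf = (r2 <= ((radius + spec.csf_margin)[None, None, :] ** 2)) & in_range[None, None, :]

    # dorsal rootlet blobs: left/right pairs posterior to the cord surface.
    # Adjacent levels interleave in z (as real rootlet levels do), so the
    # pairs of odd and even levels sit at different lateral offsets: only a
    # genuinely too-dense spec makes two blobs claim the same voxel.
    rootlets = np.zeros(spec.shape, dtype=np.int16)
    a2 = spec.rootlet_radius ** 2
    b2 = spec.rootlet_halflength ** 2
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]
    for code in sorted(rootlet_z):
        zl = rootlet_z[code]
        rl = spec.cord_radius + spec.enlargement_amp * np.exp(
            -((zl - enlargement_z) ** 2) / (2 * spec.enlargement_width ** 2))
        yl = cy + y_offset(np.array([zl]))[0] - (rl + 0.5)
        lateral = 2.2 if code % 2 == 0 else 5.6
        blob = np.zeros(spec.shape, dtype=bool)
        for sx in (-1.0, 1.0):
            xl = cx + sx * lateral
            e = ((X - xl) ** 2 / a2 + (Y - yl) ** 2 / a2 + (Z - zl) ** 2 / b2)
            blob |= e <= 1.0
        if (rootlets[blob] != 0).any():
            raise PhantomError(
                f"rootlet blobs of level {code} overlap a neighbouring level; spec too dense")
        rootlets[blob] = code

    # single-voxel disc labels on the anterior (vertebral body) side
    discs = np.zeros(spec.shape, dtype=np.int16)
    for code in sorted(spec.disc_z):
        zd = spec.disc_z[code]
        yd = cy + y_offset(np.array([zd]))[0] + spec.cord_radius + spec.csf_margin + 2.0
        i = int(round(cx / res))
        j = int(round(yd / res))
        k = int(round(zd / res))
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            raise PhantomError(f"disc {code} falls outside the grid")
        discs[i, j, k] = code

    inten = spec.intensity
    img = np.full(spec.shape, inten["background"], dtype=float)
    img[csf] = inten["csf"]
    img[cord] = inten["cord"]
    img[rootlets > 0] = inten["rootlet"]
    img = gaussian_filter(img, sigma=0.6)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    truth = {
        "rootlet_z_mm": dict(rootlet_z),
        "disc_z_mm": dict(spec.disc_z),
        "enlargement_z_mm": float(enlargement_z),
        "enlargement_slice": int(round(enlargement_z / res)),
        "curvature": spec.curvature,
        "curvature_amp_mm": float(amp),
        "cord_slide_mm": float(slide),
        "centerline_y_offset_mm": yoff.copy(),
        "center_xy_mm": (float(cx), float(cy)),
    }
    return PhantomSet(
        image=Volume(img, affine),
        cord=LabelVolume(cord.astype(np.int16), affine, kind="cord"),
        rootlets=LabelVolume(rootlets, affine, kind="rootlets"),
        discs=LabelVolume(discs, affine, kind="discs"),
        truth=truth,
    )


def neck_position_series(spec: PhantomSpec, modes=("flexion", "neutral", "extension")) -> dict:
    """The same synthetic subject scanned in several neck positions."""
    return {mode: generate_phantom(replace(spec, curvature=mode)) for mode in modes}


def generate_cohort(n: int, template_spec: PhantomSpec | None = None,
                    level_jitter_sd: float = 2.0,
                    rootlet_disc_offset_sd: float = 0.0,
                    seed: int = 0):
    """One clean template phantom plus ``n`` jittered subject phantoms.

    Subject rootlet levels are the template levels plus seeded Gaussian
    jitter whose SD grows linearly from 1x at C2 to 2x at C8 (caudal levels
    vary more across individuals); the cervical enlargement follows the
    mean C5/C6 jitter.  Disc positions additionally carry a per-subject
    offset (SD ``rootlet_disc_offset_sd``), decoupling vertebral from
    spinal levels.  Non-monotone jitter draws are resampled up to 10 times.
    """
    if n < 1:
        raise PhantomError("n must be >= 1")
    template_spec = template_spec or PhantomSpec(noise_sd=0.0, seed=0)
    template = generate_phantom(template_spec)
    rng = np.random.default_rng(seed)
    codes = sorted(template_spec.rootlet_z)
    scale = {c: 1.0 + (c - codes[0]) / max(codes[-1] - codes[0], 1) for c in codes}

    blob_sep = 2 * template_spec.rootlet_halflength + template_spec.resolution
    subjects = []
    for s in range(n):
        for attempt in range(10):
            jitter = {c: rng.normal(0.0, level_jitter_sd * scale[c]) for c in codes}
            new_rz = {c: template_spec.rootlet_z[c] + jitter[c] for c in codes}
            zs = [new_rz[c] for c in codes]
            monotone = all(a - b > template_spec.resolution
                           for a, b in zip(zs, zs[1:]))
            # same-lateral-offset levels (codes two apart) must not collide
            clear = all(a - b > blob_sep for a, b in zip(zs, zs[2:]))
            if monotone and clear:
                break
        else:
            raise PhantomError("could not draw monotone rootlet levels in 10 attempts")
        disc_offset = rng.normal(0.0, rootlet_disc_offset_sd) if rootlet_disc_offset_sd > 0 else 0.0
        new_dz = {c: v + disc_offset for c, v in template_spec.disc_z.items()}
        enl = template_spec.enlargement_z + 0.5 * (jitter.get(5, 0.0) + jitter.get(6, 0.0))
        sub_spec = replace(
            template_spec,
            rootlet_z=new_rz,
            disc_z=new_dz,
            enlargement_z=enl,
            noise_sd=template_spec.noise_sd if template_spec.noise_sd > 0 else 5.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(generate_phantom(sub_spec))
    return template, subjects
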