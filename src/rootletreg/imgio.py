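"""Volumes, label volumes and displacement fields, with NIfTI I/O.

All in-memory grids follow a single canonical orientation after loading:
array axis 0 increases left->right (x), axis 1 posterior->anterior (y) and
axis 2 inferior->superior (z, the rostro-caudal axis).  World coordinates
are millimetres, obtained from the voxel-index -> world affine.

Displacement fields are stored as 4D NIfTI volumes (last axis = the three
world-mm components) together with a small JSON sidecar recording the
field's direction and reference grid.  A ``forward`` field lives on the
template grid and its value at a template point is the offset to the
corresponding subject-space point (pull-back convention); ``backward`` is
the converse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

CANONICAL_AXCODES = ("R", "A", "S")

LABEL_KINDS = ("cord", "rootlets", "discs")

#: rootlet level codes: 2 -> C2 ... 8 -> C8
ROOTLET_CODES = tuple(range(2, 9))


class GridError(ValueError):
    """Raised for invalid grids, affines or shapes."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GridError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise GridError("affine contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GridError("affine is not invertible")
    return affine


def voxel_size_from_affine(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel size in mm (column norms of the linear part)."""
    return np.sqrt((np.asarray(affine, float)[:3, :3] ** 2).sum(axis=0))


@dataclass
class Volume:
    """A 3D scalar image on a world-mm grid."""

    data: np.ndarray
    affine: np.ndarray
    orig_axcodes: tuple = CANONICAL_AXCODES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GridError(f"expected 3D volume, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)
        if np.any(voxel_size_from_affine(self.affine) <= 0):
            raise GridError("voxel sizes must be strictly positive")
        if not np.all(np.isfinite(self.data)):
            raise GridError("volume intensities must be finite")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return voxel_size_from_affine(self.affine)

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        ijk = np.asarray(ijk, float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_coords(self) -> np.ndarray:
        """World coordinates of every voxel, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"),
            axis=-1,
        )
        return self.index_to_world(idx)


@dataclass
class LabelVolume:
    """An integer-labelled grid sharing the Volume affine contract.

    kind 'cord': binary mask {0, 1}.
    kind 'rootlets': levels {0, 2..8}, 2=C2 ... 8=C8.
    kind 'discs': sparse point labels with level codes.
    """

    labels: np.ndarray
    affine: np.ndarray
    kind: str = "cord"
    orig_axcodes: tuple = CANONICAL_AXCODES

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GridError(f"expected 3D label volume, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels, float)
            if not np.allclose(lab, np.round(lab)):
                raise GridError("label volume has non-integer values")
            self.labels = np.round(lab).astype(np.int16)
        self.affine = _check_affine(self.affine)
        if self.kind not in LABEL_KINDS:
            raise GridError(f"unknown label kind {self.kind!r}")
        present = np.unique(self.labels)
        if self.kind == "cord" and not np.all(np.isin(present, [0, 1])):
            raise GridError("cord mask labels must be in {0, 1}")
        if self.kind == "rootlets" and not np.all(
            np.isin(present, [0, *ROOTLET_CODES])
        ):
            raise GridError("rootlet labels must be in {0, 2..8}")

    @property
    def shape(self):
        return self.labels.shape

    voxel_size = Volume.voxel_size
    index_to_world = Volume.index_to_world
    world_to_index = Volume.world_to_index

    def world_coords(self) -> np.ndarray:
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"),
            axis=-1,
        )
        return self.index_to_world(idx)


@dataclass
class DisplacementField:
    """Per-voxel world-mm offsets on a reference grid.

    ``vectors`` has shape ``grid_shape + (3,)``; components are world-mm
    offsets along (x, y, z).  A zero field is the identity.
    """

    vectors: np.ndarray
    affine: np.ndarray
    direction: str = "forward"
    reference: str = "template"

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise GridError(
                f"displacement vectors must have shape (nx,ny,nz,3), got {self.vectors.shape}"
            )
        self.affine = _check_affine(self.affine)
        if self.direction not in ("forward", "backward"):
            raise GridError(f"direction must be forward|backward, got {self.direction!r}")
        if self.reference not in ("subject", "template"):
            raise GridError(f"reference must be subject|template, got {self.reference!r}")
        if not np.all(np.isfinite(self.vectors)):
            raise GridError("displacement components must be finite")

    @property
    def shape(self):
        return self.vectors.shape[:3]

    voxel_size = Volume.voxel_size
    index_to_world = Volume.index_to_world
    world_to_index = Volume.world_to_index

    def world_coords(self) -> np.ndarray:
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"),
            axis=-1,
        )
        return Volume.index_to_world(self, idx)


def zero_field_like(vol, direction: str = "forward", reference: str = "template") -> DisplacementField:
    """Identity displacement field on the grid of ``vol``."""
    return DisplacementField(
        np.zeros(tuple(vol.shape) + (3,)), vol.affine, direction, reference
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_canonical(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise GridError(f"expected 3D volume, got {len(img.shape)}D in {path}")
    orig_axcodes = nib.aff2axcodes(img.affine)
    img = nib.as_closest_canonical(img)
    return img, orig_axcodes


def read_volume(path) -> Volume:
    """Read a NIfTI scalar volume, reoriented to the canonical RAS axes."""
    img, orig = _load_canonical(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    return Volume(data, img.affine, orig_axcodes=orig)


def read_label_volume(path, kind: str) -> LabelVolume:
    img, orig = _load_canonical(path)
    data = np.asarray(img.dataobj)
    return LabelVolume(np.rint(data).astype(np.int16), img.affine, kind=kind, orig_axcodes=orig)


def write_volume(vol, path) -> Path:
    """Write a Volume or LabelVolume as NIfTI-1."""
    path = Path(path)
    data = vol.labels if isinstance(vol, LabelVolume) else vol.data
    img = nib.Nifti1Image(np.asarray(data), vol.affine)
    img.set_qform(vol.affine, code=1)
    img.set_sform(vol.affine, code=1)
    nib.save(img, str(path))
    return path


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_displacement_field(fld: DisplacementField, path) -> Path:
    """Write a field as 4D NIfTI (+ JSON sidecar: direction, reference, units)."""
    path = Path(path)
    img = nib.Nifti1Image(fld.vectors, fld.affine)
    img.set_qform(fld.affine, code=1)
    img.set_sform(fld.affine, code=1)
    nib.save(img, str(path))
    meta = {"direction": fld.direction, "reference": fld.reference, "units": "mm"}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_displacement_field(path) -> DisplacementField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if len(img.shape) != 4 or img.shape[-1] != 3:
        raise GridError(f"displacement field must be 4D with 3 components, got {img.shape}")
    meta = {"direction": "forward", "reference": "template"}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    vectors = np.asarray(img.dataobj, dtype=np.float64)
    return DisplacementField(vectors, img.affine, meta["direction"], meta["reference"])


def check_same_grid(a, b, tol_mm: float = 1e-5) -> bool:
    """True iff shapes are equal and affines agree within ``tol_mm``."""
    if tuple(a.shape)[:3] != tuple(b.shape)[:3]:
        return False
    return bool(np.allclose(a.affine, b.affine, atol=tol_mm))


def sample_at_world(data: np.ndarray, affine: np.ndarray, pts_xyz: np.ndarray,
                    order: int = 1, cval: float = 0.0, mode: str = "constant") -> np.ndarray:
    """Sample a 3D array at world-mm points (pull-back).

    mode 'constant': out-of-field -> cval (images); mode 'nearest': clamp to
    the edge (displacement-field components, which must stay continuous).
    """
    from scipy.ndimage import map_coordinates

    pts = np.asarray(pts_xyz, float)
    flat = pts.reshape(-1, 3)
    inv = np.linalg.inv(np.asarray(affine, float))
    idx = flat @ inv[:3, :3].T + inv[:3, 3]
    out = map_coordinates(np.asarray(data, float), idx.T, order=order,
                          mode=mode, cval=cval, prefilter=False)
    return out.reshape(pts.shape[:-1])
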