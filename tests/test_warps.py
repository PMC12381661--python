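import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rootletreg import LabelVolume, Volume
from rootletreg.imgio import DisplacementField
from rootletreg.warps import (
    WarpError,
    apply_warp,
    compose,
    invert,
    symmetrize_slicewise,
    xy_scaling,
)


def _zfield(dz, affine=None):
    """z-only field from a (nx,ny,nz) dz array."""
    vec = np.zeros(tuple(dz.shape) + (3,))
    vec[..., 2] = dz
    return DisplacementField(vec, affine if affine is not None else np.eye(4),
                             "forward", "template")


def _const_field(shape, t, affine=None):
    vec = np.zeros(tuple(shape) + (3,))
    vec[...] = np.asarray(t, float)
    return DisplacementField(vec, affine if affine is not None else np.eye(4),
                             "forward", "template")


# -- symmetrize ------------------------------------------------------------

def test_symmetrize_mean_of_nonzeros():
    dz = np.zeros((3, 1, 2))
    dz[:, 0, 0] = [2.0, 0.0, 4.0]
    out = symmetrize_slicewise(_zfield(dz))
    np.testing.assert_allclose(out.vectors[:, 0, 0, 2], 3.0)
    np.testing.assert_allclose(out.vectors[:, 0, 1, 2], 0.0)   # all-zero slice


def test_symmetrize_rejects_xy_components():
    vec = np.zeros((2, 2, 2, 3))
    vec[..., 0] = 1.0
    with pytest.raises(WarpError):
        symmetrize_slicewise(DisplacementField(vec, np.eye(4)))


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_symmetrize_idempotent_and_flip_invariant(seed):
    rng = np.random.default_rng(seed)
    dz = rng.normal(size=(6, 5, 8)) * (rng.random((6, 5, 8)) < 0.5)
    once = symmetrize_slicewise(_zfield(dz))
    twice = symmetrize_slicewise(once)
    np.testing.assert_array_equal(once.vectors, twice.vectors)
    flipped = symmetrize_slicewise(_zfield(dz[::-1]))
    np.testing.assert_array_equal(once.vectors, flipped.vectors[::-1])


# -- compose / invert ------------------------------------------------------

def test_compose_identity_element(rng):
    w = _zfield(rng.normal(size=(6, 6, 6)))
    zero = _const_field((6, 6, 6), (0, 0, 0))
    np.testing.assert_allclose(compose(zero, w).vectors, w.vectors, atol=1e-9)
    np.testing.assert_allclose(compose(w, zero).vectors, w.vectors, atol=1e-9)


def test_compose_translation_group():
    a = _const_field((5, 5, 5), (1.0, 0.0, 2.0))
    b = _const_field((5, 5, 5), (0.0, 1.0, 1.0))
    out = compose(a, b)
    np.testing.assert_allclose(out.vectors,
                               np.broadcast_to([1.0, 1.0, 3.0], out.vectors.shape),
                               atol=1e-9)


def test_invert_trivial_cases():
    zero = _const_field((5, 5, 5), (0, 0, 0))
    assert np.all(invert(zero).vectors == 0)
    t = _const_field((8, 8, 8), (0.5, -0.25, 1.0))
    inv_vec = invert(t).vectors
    np.testing.assert_allclose(
        inv_vec, np.broadcast_to([-0.5, 0.25, -1.0], inv_vec.shape), atol=0.05)
    assert invert(t).direction == "backward"


def test_compose_with_inverse_is_near_identity(rng):
    """Smooth random field of amplitude <= 5 mm: compose(w, invert(w))
    residual < 0.5 mm."""
    from scipy.ndimage import gaussian_filter

    shape = (16, 16, 24)
    vec = np.stack([gaussian_filter(rng.normal(size=shape), 4.0) for _ in range(3)],
                   axis=-1)
    vec *= 5.0 / np.abs(vec).max()
    w = DisplacementField(vec, np.eye(4), "forward", "template")
    winv = invert(w)
    resid = compose(w, winv)
    mag = np.linalg.norm(resid.vectors, axis=-1)
    interior = mag[3:-3, 3:-3, 3:-3]
    assert interior.mean() < 0.5


# -- apply_warp ------------------------------------------------------------

def test_apply_zero_field_is_identity(rng):
    data = rng.normal(size=(7, 7, 7))
    vol = Volume(data, np.eye(4))
    zero = _const_field((7, 7, 7), (0, 0, 0))
    np.testing.assert_array_equal(apply_warp(vol, zero, "nearest").data, data)
    np.testing.assert_allclose(apply_warp(vol, zero, "linear").data, data, atol=1e-9)


def test_integer_translation_moves_labels_exactly(rng):
    labels = np.zeros((10, 10, 10), np.int16)
    labels[2:5, 3:6, 4:7] = 2
    lab = LabelVolume(labels, np.eye(4), kind="rootlets")
    fld = _const_field((10, 10, 10), (1.0, 0.0, -2.0))   # pull from (+1, 0, -2)
    out = apply_warp(lab, fld)
    np.testing.assert_array_equal(out.labels[1:4, 3:6, 6:9], 2)
    assert out.labels.sum() == labels.sum()   # voxel count conserved


def test_linear_on_labels_refused():
    lab = LabelVolume(np.zeros((4, 4, 4), np.int16), np.eye(4), kind="cord")
    with pytest.raises(WarpError):
        apply_warp(lab, _const_field((4, 4, 4), (0, 0, 0)), "linear")


def test_warped_centers_match_analytic_transport():
    """A known smooth z-warp moves rootlet blob centers by the analytic
    displacement within half a voxel."""
    from rootletreg import PhantomSpec, generate_phantom, level_centers

    tpl = generate_phantom(PhantomSpec(noise_sd=0.0, seed=0))
    aff = tpl.rootlets.affine
    nz = tpl.rootlets.shape[2]
    z = aff[2, 2] * np.arange(nz)
    dz = 2.0 * np.sin(2 * np.pi * z / 80.0)
    vec = np.zeros(tuple(tpl.rootlets.shape) + (3,))
    vec[..., 2] = dz[None, None, :]
    fld = DisplacementField(vec, aff, "forward", "template")
    warped = apply_warp(tpl.rootlets, fld)
    before = level_centers(tpl.rootlets)
    after = level_centers(warped)
    for code in before.codes:
        z0 = before.z_of(code)
        # analytic transport: find z with z + dz(z) = z0 (pull-back inverse)
        zq = np.linspace(z0 - 4, z0 + 4, 4001)
        z_target = zq[np.argmin(np.abs(zq + 2.0 * np.sin(2 * np.pi * zq / 80.0) - z0))]
        assert abs(after.z_of(code) - z_target) < 0.5 * aff[2, 2]


# -- xy scaling ------------------------------------------------------------

def _disc_mask(shape, res, radius, z_range):
    nx, ny, nz = shape
    x = res * (np.arange(nx) - (nx - 1) / 2)
    y = res * (np.arange(ny) - (ny - 1) / 2)
    mask = np.zeros(shape, np.int16)
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    for k in range(*z_range):
        mask[:, :, k] = r2 <= radius ** 2
    aff = np.diag([res, res, res, 1.0])
    aff[0, 3] = -res * (nx - 1) / 2
    aff[1, 3] = -res * (ny - 1) / 2
    return LabelVolume(mask, aff, kind="cord")


def test_xy_scaling_identity_for_identical_masks():
    m = _disc_mask((40, 40, 20), 0.5, 4.0, (2, 18))
    fld, prof = xy_scaling(m, m)
    np.testing.assert_allclose(fld.vectors, 0.0, atol=1e-12)
    np.testing.assert_allclose(prof.scales, 1.0)


def test_xy_scaling_area_ratio():
    """Subject radius 4 mm vs template radius 5 mm: s = 1.25 and a point
    2 mm right of center maps 2.5 mm right (forward), i.e. the pull-back
    field at 2.5 mm samples the subject at 2 mm."""
    sub = _disc_mask((48, 48, 20), 0.5, 4.0, (2, 18))
    tpl = _disc_mask((48, 48, 20), 0.5, 5.0, (2, 18))
    # brute-force voxel-count area ratio oracle
    a_sub = (sub.labels[:, :, 10] > 0).sum() * 0.25
    a_tpl = (tpl.labels[:, :, 10] > 0).sum() * 0.25
    s_expect = np.sqrt(a_tpl / a_sub)
    fld, prof = xy_scaling(sub, tpl)
    assert prof.scales[10] == pytest.approx(s_expect, abs=1e-9)
    assert s_expect == pytest.approx(1.25, abs=0.02)   # voxelized pi r^2
    # pull-back sample position at a template point 2.5 mm right of center
    probe = Volume(np.zeros(tpl.shape), tpl.affine)
    from rootletreg.warps import sample_field

    p = np.array([2.5, 0.0, 10 * 0.5])
    shift = sample_field(fld, p[None])[0]
    assert p[0] + shift[0] == pytest.approx(2.5 / prof.scales[10], abs=0.05)


def test_xy_scaling_matches_template_csa():
    from rootletreg import csa_profile

    sub = _disc_mask((48, 48, 20), 0.5, 4.0, (2, 18))
    tpl = _disc_mask((48, 48, 20), 0.5, 5.0, (2, 18))
    fld, _ = xy_scaling(sub, tpl)
    warped = apply_warp(sub, fld)
    csa_w = csa_profile(warped).csa_mm2
    csa_t = csa_profile(tpl).csa_mm2
    ratio = csa_w[3:-3] / csa_t[3:-3]
    assert np.all(np.abs(ratio - 1.0) < 0.03)


def test_xy_scaling_empty_subject_rejected():
    sub = _disc_mask((40, 40, 20), 0.5, 4.0, (14, 16))   # almost empty
    tpl = _disc_mask((40, 40, 20), 0.5, 5.0, (2, 18))
    with pytest.raises(WarpError, match="50%"):
        xy_scaling(sub, tpl)
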