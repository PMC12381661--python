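import numpy as np
import pandas as pd
import pytest

from rootletreg import LabelVolume
from rootletreg.metrics import (
    CSAProfile,
    MetricError,
    csa_profile,
    group_aggregate,
    normalize_csa,
    rootlet_overlap,
    smooth_and_localize,
)


def _rootlets_with_extents(extents, shape=(10, 10, 40)):
    """Label volume where level code -> slice range [start, stop)."""
    arr = np.zeros(shape, np.int16)
    for code, (start, stop) in extents.items():
        arr[4, 4, start:stop] = code
    return LabelVolume(arr, np.eye(4), kind="rootlets")


def test_self_overlap_is_100_percent(template_set):
    result = rootlet_overlap(template_set.rootlets, template_set.rootlets)
    assert np.all(result.table["percent"] == 100.0)
    assert result.mean == 100.0
    assert result.sd == 0.0


def test_disjoint_extents_give_zero():
    sub = _rootlets_with_extents({2: (30, 35), 3: (5, 10)})
    tpl = _rootlets_with_extents({2: (20, 25), 3: (12, 17)})
    result = rootlet_overlap(sub, tpl)
    assert np.all(result.table["percent"] == 0.0)


def test_partial_overlap_brute_force():
    """Subject spans [10, 20), template [15, 25): overlap 5 slices, 50%."""
    sub = _rootlets_with_extents({2: (30, 36), 4: (10, 20)})
    tpl = _rootlets_with_extents({2: (30, 36), 4: (15, 25)})
    result = rootlet_overlap(sub, tpl)
    row = result.table[result.table["level"] == 4].iloc[0]
    assert row["length_overlap"] == 5
    assert row["length_pam50"] == 10
    assert row["length_sub"] == 10
    assert row["percent"] == 50.0
    assert row["dice1d"] == pytest.approx(200 * 5 / 20)


def test_missing_level_flagged_not_error():
    sub = _rootlets_with_extents({2: (30, 35), 3: (20, 25)})
    tpl = _rootlets_with_extents({2: (30, 35), 3: (20, 25), 4: (10, 15)})
    result = rootlet_overlap(sub, tpl)
    row = result.table[result.table["level"] == 4].iloc[0]
    assert row["percent"] == 0.0
    assert bool(row["missing"])


def test_overlap_invariant_to_inplane_relabeling(rng):
    """Only z extents matter: scattering rootlet voxels in-plane changes nothing."""
    sub = _rootlets_with_extents({2: (28, 34), 3: (18, 24)})
    tpl = _rootlets_with_extents({2: (30, 36), 3: (20, 26)})
    base = rootlet_overlap(sub, tpl)
    scattered = np.zeros_like(sub.labels)
    for k in range(40):
        codes = np.unique(sub.labels[:, :, k])
        for code in codes[codes != 0]:
            n = rng.integers(1, 20)
            ii = rng.integers(0, 10, n)
            jj = rng.integers(0, 10, n)
            scattered[ii, jj, k] = code
    moved = rootlet_overlap(LabelVolume(scattered, np.eye(4), kind="rootlets"), tpl)
    pd.testing.assert_frame_equal(base.table, moved.table)


def _cylinder(radius_mm, res=0.5, shape=(48, 48, 30), z_range=(2, 28)):
    nx, ny, nz = shape
    x = res * (np.arange(nx) - (nx - 1) / 2)
    y = res * (np.arange(ny) - (ny - 1) / 2)
    mask = np.zeros(shape, np.int16)
    disc = (x[:, None] ** 2 + y[None, :] ** 2) <= radius_mm ** 2
    mask[:, :, z_range[0]:z_range[1]] = disc[:, :, None]
    return LabelVolume(mask, np.diag([res, res, res, 1.0]), kind="cord")


def test_cylinder_csa_matches_pi_r_squared():
    cord = _cylinder(5.0)
    prof = csa_profile(cord)
    interior = prof.csa_mm2[2:-2]
    assert np.all(np.abs(interior - np.pi * 25.0) / (np.pi * 25.0) < 0.02)


def test_single_voxel_slice_csa():
    arr = np.zeros((8, 8, 10), np.int16)
    arr[4, 4, 3:7] = 1
    cord = LabelVolume(arr, np.diag([0.5, 0.5, 0.5, 1.0]), kind="cord")
    prof = csa_profile(cord)
    assert np.all(prof.csa_mm2 == 0.25)


def test_empty_cord_rejected():
    with pytest.raises(MetricError):
        csa_profile(LabelVolume(np.zeros((4, 4, 4), np.int16), np.eye(4), kind="cord"))


def _profile(values, z0=0, dz=0.5):
    values = np.asarray(values, float)
    return CSAProfile(np.arange(z0, z0 + values.size), values, dz)


def test_normalize_constant_profile():
    prof = normalize_csa(_profile(np.full(60, 80.0)), reference_z=30)
    np.testing.assert_allclose(prof.csa_norm, 1.0)


def test_normalize_scale_invariant():
    base = np.linspace(50, 90, 60)
    a = normalize_csa(_profile(base), reference_z=30)
    b = normalize_csa(_profile(2 * base), reference_z=30)
    np.testing.assert_allclose(a.csa_norm, b.csa_norm)


def test_normalize_window_mean_is_one():
    prof = normalize_csa(_profile(np.linspace(50, 90, 60)), reference_z=30)
    sel = (prof.z_index >= 20) & (prof.z_index < 40)
    assert prof.csa_norm[sel].mean() == pytest.approx(1.0, abs=1e-9)


def test_normalize_idempotent():
    once = normalize_csa(_profile(np.linspace(40, 100, 60)), reference_z=30)
    twice = normalize_csa(once, reference_z=30)
    np.testing.assert_allclose(once.csa_norm, twice.csa_norm)


def test_normalize_window_out_of_support_rejected():
    with pytest.raises(MetricError, match="window"):
        normalize_csa(_profile(np.full(60, 80.0)), reference_z=3)


def test_smooth_constant_profile_and_rostral_tie():
    prof = smooth_and_localize(_profile(np.full(80, 70.0)))
    np.testing.assert_allclose(prof.csa_smooth, 70.0, atol=1e-6)
    assert prof.enlargement_z == 79   # most rostral slice wins ties


def test_smooth_two_equal_maxima_rostral_wins():
    values = np.full(80, 50.0)
    values[20] = values[60] = 90.0
    prof = smooth_and_localize(_profile(values), window_mm=2.5)
    # both spikes smooth to equal 5-slice plateaus; the most rostral tied
    # slice of the rostral plateau wins
    assert prof.enlargement_z == 62


def test_smooth_gaussian_bump_localized():
    z = np.arange(120)
    values = 60 + 25 * np.exp(-((z - 70) ** 2) / (2 * 15.0 ** 2))
    prof = smooth_and_localize(_profile(values))
    # brute-force argmax of the analytically smoothed curve
    w = int(round(22.5 / 0.5)) | 1
    padded = np.pad(values, w // 2, mode="reflect")
    expect = int(np.argmax(np.convolve(padded, np.ones(w) / w, "valid")))
    assert abs(prof.enlargement_z - expect) <= 1


def test_smooth_window_longer_than_profile_rejected():
    with pytest.raises(MetricError, match="window"):
        smooth_and_localize(_profile(np.full(10, 70.0)))


def test_group_aggregate_overlap():
    sub1 = _rootlets_with_extents({2: (30, 35), 3: (20, 25)})
    tpl = _rootlets_with_extents({2: (30, 35), 3: (20, 25)})
    sub2 = _rootlets_with_extents({2: (31, 36), 3: (20, 25)})
    r1 = rootlet_overlap(sub1, tpl)   # 100, 100
    r2 = rootlet_overlap(sub2, tpl)   # 80, 100
    agg = group_aggregate([r1])
    overall = agg[agg["level"] == -1].iloc[0]
    assert overall["mean"] == 100.0 and overall["sd"] == 0.0
    agg2 = group_aggregate([r1, r2])
    lvl2 = agg2[agg2["level"] == 2].iloc[0]
    assert lvl2["mean"] == pytest.approx(90.0)
    assert lvl2["sd"] == pytest.approx(10.0)   # population SD


def test_group_aggregate_enlargement():
    profs = []
    for peak in (60, 70):
        z = np.arange(120)
        values = 60 + 20 * np.exp(-((z - peak) ** 2) / (2 * 12.0 ** 2))
        profs.append(smooth_and_localize(_profile(values)))
    agg = group_aggregate(profs)
    assert agg.iloc[0]["mean"] == pytest.approx(65.0, abs=1.5)
    assert agg.iloc[0]["sd"] == pytest.approx(5.0, abs=1.5)
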