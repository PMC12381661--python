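"""Validation metrics: rostro-caudal rootlet overlap and CSA morphometry.

The overlap metric counts, per spinal level, the axial slices where the
warped subject rootlet segmentation and the template rootlet segmentation
both contain that level, normalized by the template level's slice count
(100% = the subject exactly covers the template extent).  A 1D Dice
variant, 200*overlap/(len_template + len_subject), is reported alongside.

CSA morphometry computes the slice-wise cord cross-sectional area,
normalizes it over a 20-slice (10 mm at 0.5 mm slices) window centered at
the C2-C3 disc, smooths with a 22.5 mm moving average and localizes the
cervical enlargement as the maximum of the smoothed profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imgio import LabelVolume, check_same_grid


class MetricError(ValueError):
    pass


@dataclass
class OverlapResult:
    """Per-level rostro-caudal overlap between subject and template rootlets."""

    table: pd.DataFrame   # level, length_overlap, length_pam50, length_sub, percent, dice1d, missing
    mean: float           # mean percent across template levels
    sd: float             # population SD of percent

    def percent_of(self, level: int) -> float:
        row = self.table[self.table["level"] == level]
        if row.empty:
            raise KeyError(level)
        return float(row["percent"].iloc[0])


def _slice_set(labels: np.ndarray, code: int) -> np.ndarray:
    return np.flatnonzero((labels == code).any(axis=(0, 1)))


def rootlet_overlap(subject_warped: LabelVolume, template_rootlets: LabelVolume) -> OverlapResult:
    """Slice-extent overlap of each level, subject (in template space) vs template.

    Levels present in the template but absent from the subject get percent 0
    and a ``missing`` flag rather than an error.
    """
    if not check_same_grid(subject_warped, template_rootlets):
        raise MetricError("both volumes must be on the template grid")
    rows = []
    tpl_codes = np.unique(template_rootlets.labels)
    tpl_codes = tpl_codes[tpl_codes != 0]
    for code in tpl_codes:
        tpl_slices = _slice_set(template_rootlets.labels, code)
        sub_slices = _slice_set(subject_warped.labels, code)
        overlap = np.intersect1d(tpl_slices, sub_slices).size
        len_tpl, len_sub = tpl_slices.size, sub_slices.size
        percent = 100.0 * overlap / len_tpl if len_tpl else 0.0
        dice1d = 200.0 * overlap / (len_tpl + len_sub) if (len_tpl + len_sub) else 0.0
        rows.append({
            "level": int(code), "length_overlap": int(overlap),
            "length_pam50": int(len_tpl), "length_sub": int(len_sub),
            "percent": percent, "dice1d": dice1d, "missing": len_sub == 0,
        })
    if not rows:
        raise MetricError("template rootlet volume has no labels")
    table = pd.DataFrame(rows)
    percents = table["percent"].to_numpy()
    return OverlapResult(table, float(percents.mean()), float(percents.std()))


@dataclass
class CSAProfile:
    """Slice-wise cord cross-sectional area along the rostro-caudal axis."""

    z_index: np.ndarray                 # axial slice indices within support
    csa_mm2: np.ndarray                 # raw CSA per slice
    slice_thickness_mm: float
    csa_norm: np.ndarray | None = None
    csa_smooth: np.ndarray | None = None
    enlargement_z: int | None = None    # slice index of the smoothed maximum

    def to_frame(self) -> pd.DataFrame:
        out = {"z": self.z_index, "csa_mm2": self.csa_mm2}
        if self.csa_norm is not None:
            out["csa_norm"] = self.csa_norm
        if self.csa_smooth is not None:
            out["csa_smooth"] = self.csa_smooth
        return pd.DataFrame(out)


def csa_profile(cord: LabelVolume) -> CSAProfile:
    """Per-slice CSA = voxel count x in-plane voxel area, within mask support."""
    mask = cord.labels > 0
    if not mask.any():
        raise MetricError("empty cord mask")
    vx = cord.voxel_size
    counts = mask.sum(axis=(0, 1))
    filled = np.flatnonzero(counts)
    z = np.arange(filled[0], filled[-1] + 1)
    return CSAProfile(z, counts[z] * float(vx[0] * vx[1]), float(vx[2]))


def normalize_csa(profile: CSAProfile, reference_z: int, window_slices: int = 20) -> CSAProfile:
    """Divide the profile by its mean over ``window_slices`` centered at reference_z."""
    start = int(reference_z) - window_slices // 2
    stop = start + window_slices
    z0, z1 = int(profile.z_index[0]), int(profile.z_index[-1])
    if start < z0 or stop - 1 > z1:
        raise MetricError(
            f"normalization window [{start}, {stop}) exceeds profile support [{z0}, {z1}]"
        )
    base = profile.csa_norm if profile.csa_norm is not None else profile.csa_mm2
    sel = (profile.z_index >= start) & (profile.z_index < stop)
    ref = float(np.asarray(base)[sel].mean())
    if ref <= 0:
        raise MetricError("normalization window has zero mean CSA")
    return CSAProfile(profile.z_index, profile.csa_mm2, profile.slice_thickness_mm,
                      csa_norm=np.asarray(base) / ref)


def smooth_and_localize(profile: CSAProfile, window_mm: float = 22.5) -> CSAProfile:
    """Moving-average smoothing and localization of the cervical enlargement.

    The window is round(window_mm / slice thickness) slices, forced odd,
    with reflected boundaries; the enlargement is the argmax of the
    smoothed curve, ties broken toward the more rostral (superior) slice.
    Smoothing applies to the normalized profile when present, else raw CSA.
    """
    base = profile.csa_norm if profile.csa_norm is not None else profile.csa_mm2
    base = np.asarray(base, float)
    w = int(round(window_mm / profile.slice_thickness_mm))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    if base.size < w:
        raise MetricError(f"profile length {base.size} shorter than window {w}")
    if w > 1:
        padded = np.pad(base, w // 2, mode="reflect")
        smooth = np.convolve(padded, np.ones(w) / w, mode="valid")
    else:
        smooth = base.copy()
    peak = int(np.flatnonzero(smooth == smooth.max()).max())  # rostral tie-break
    return CSAProfile(profile.z_index, profile.csa_mm2, profile.slice_thickness_mm,
                      csa_norm=profile.csa_norm, csa_smooth=smooth,
                      enlargement_z=int(profile.z_index[peak]))


def group_aggregate(results) -> pd.DataFrame:
    """Mean and population SD across subjects.

    For OverlapResults: per-level and overall percent.  For CSAProfiles:
    enlargement slice position (requires smooth_and_localize first).
    """
    results = list(results)
    if not results:
        raise MetricError("need >= 1 result")
    if isinstance(results[0], OverlapResult):
        frames = []
        for i, r in enumerate(results):
            t = r.table[["level", "percent"]].copy()
            t["subject"] = i
            frames.append(t)
        allt = pd.concat(frames, ignore_index=True)
        per_level = allt.groupby("level")["percent"].agg(
            mean="mean", sd=lambda x: float(np.asarray(x).std())
        ).reset_index()
        overall_mean = [r.mean for r in results]
        per_level.loc[len(per_level)] = {
            "level": -1,
            "mean": float(np.mean(overall_mean)),
            "sd": float(np.std(overall_mean)),
        }
        return per_level
    zs = np.array([r.enlargement_z for r in results], float)
    if np.any(np.isnan(zs)):
        raise MetricError("run smooth_and_localize before aggregating CSA profiles")
    return pd.DataFrame(
        [{"quantity": "enlargement_z", "mean": float(zs.mean()), "sd": float(zs.std())}]
    )
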