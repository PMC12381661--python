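"""End-to-end rootlet-based registration to the straightened template.

Orchestrates the seven stages: per-level landmark centers; cord
straightening; monotone 1D landmark alignment; masked rostro-caudal
B-spline refinement; slice-wise symmetrization of the refinement field;
in-plane cord-size scaling; and concatenation of all fields into the
forward (template-grid) and backward (subject-grid) warps.  The landmark
mode switches between rootlet levels (the method) and intervertebral
discs (the traditional baseline); the image-based rostro-caudal
refinement is a rootlet-masked step, so the disc baseline — which has no
rootlet information by construction — skips it by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import levels, warps, zreg
from .centerline import extract_centerline, straighten
from .imgio import (
    LabelVolume,
    Volume,
    check_same_grid,
    read_label_volume,
    read_volume,
    write_volume,
)
from .zreg import ZRegParams


class PipelineError(RuntimeError):
    pass


@dataclass
class TemplateBundle:
    """Template image plus cord, rootlet and disc annotations on one grid."""

    image: Volume
    cord: LabelVolume
    rootlets: LabelVolume
    discs: LabelVolume | None = None

    def __post_init__(self):
        for name, vol in (("cord", self.cord), ("rootlets", self.rootlets),
                          ("discs", self.discs)):
            if vol is not None and not check_same_grid(self.image, vol):
                raise PipelineError(f"template {name} is not on the template grid")


BUNDLE_FILES = {
    "image": ("template.nii.gz", None),
    "cord": ("cord.nii.gz", "cord"),
    "rootlets": ("rootlets.nii.gz", "rootlets"),
    "discs": ("discs.nii.gz", "discs"),
}


def save_template_bundle(bundle: TemplateBundle, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for attr, (fname, _) in BUNDLE_FILES.items():
        vol = getattr(bundle, attr)
        if vol is None:
            continue
        write_volume(vol, directory / fname)
        manifest[attr] = fname
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_template_bundle(directory) -> TemplateBundle:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    kwargs = {}
    for attr, (default_name, kind) in BUNDLE_FILES.items():
        fname = manifest.get(attr)
        if fname is None:
            continue
        path = directory / fname
        kwargs[attr] = read_volume(path) if kind is None else read_label_volume(path, kind)
    return TemplateBundle(**kwargs)


@dataclass
class RegistrationOptions:
    landmarks: str = "rootlets"          # 'rootlets' | 'discs'
    no_xy_scaling: bool = False
    refine: bool | None = None           # default: landmarks == 'rootlets'
    zreg_params: ZRegParams = field(default_factory=ZRegParams)
    centerline_smoothing: float = 1.0

    def __post_init__(self):
        if self.landmarks not in ("rootlets", "discs"):
            raise PipelineError(f"landmarks must be rootlets|discs, got {self.landmarks!r}")
        if self.refine is None:
            self.refine = self.landmarks == "rootlets"


@dataclass
class RegistrationResult:
    warp_forward: "warps.DisplacementField"     # template grid -> subject space
    warp_backward: "warps.DisplacementField"    # subject grid -> template space
    straightened: Volume
    warped_image: Volume
    warped_cord: LabelVolume
    warped_rootlets: LabelVolume
    scale_profile: "warps.ScaleProfile | None"
    diagnostics: dict


def _stage(name):
    """Context tagging stage errors with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def _cord_center_xy(cord: LabelVolume):
    world = cord.world_coords()
    m = cord.labels > 0
    return float(world[m][:, 0].mean()), float(world[m][:, 1].mean())


def _cord_z_mid(cord: LabelVolume) -> float:
    world_z = cord.affine[2, 2] * np.arange(cord.shape[2]) + cord.affine[2, 3]
    filled = np.flatnonzero((cord.labels > 0).any(axis=(0, 1)))
    return float(0.5 * (world_z[filled[0]] + world_z[filled[-1]]))


def register_to_template(image: Volume, cord: LabelVolume, rootlets: LabelVolume,
                         template: TemplateBundle, discs: LabelVolume | None = None,
                         options: RegistrationOptions | None = None) -> RegistrationResult:
    """Run the full registration and return warps, warped volumes and diagnostics."""
    options = options or RegistrationOptions()
    for name, vol in (("cord", cord), ("rootlets", rootlets), ("discs", discs)):
        if vol is not None and not check_same_grid(image, vol):
            raise PipelineError(f"subject {name} is not on the subject image grid")

    diagnostics = {}

    with _stage("level landmarks"):
        if options.landmarks == "discs":
            if discs is None or template.discs is None:
                raise PipelineError("disc landmark mode requires subject and template disc labels")
            subject_lm_vol = discs
            template_lm = levels.level_centers(template.discs)
        else:
            subject_lm_vol = rootlets
            template_lm = levels.level_centers(template.rootlets)
        subject_lm_native = levels.level_centers(subject_lm_vol)

    with _stage("straightening"):
        cl = extract_centerline(cord, smoothing=options.centerline_smoothing)
        center_xy = _cord_center_xy(template.cord)
        s_anchor = _cord_z_mid(template.cord) - 0.5 * cl.total_arc_length
        straightened, w_str, w_unstr = straighten(
            image, cl, like=template.image, center_xy=center_xy, s_anchor=s_anchor)

    with _stage("level alignment"):
        lm_straight = levels.LevelCenters()
        for code, p in subject_lm_native.centers.items():
            shift = warps.sample_field(w_unstr, p[None, :])[0]
            lm_straight.centers[code] = p + shift
            lm_straight.counts[code] = subject_lm_native.counts[code]
        w_lvl = levels.build_level_alignment(lm_straight, template_lm, template.image)
        m_s2t, _ = levels.level_mapping(lm_straight, template_lm)
        common = sorted(set(lm_straight.codes) & set(template_lm.codes))
        diagnostics["level_residuals_mm"] = {
            c: float(m_s2t(lm_straight.z_of(c)) - template_lm.z_of(c)) for c in common
        }

    w23 = warps.compose(w_lvl, w_str)

    with _stage("rostro-caudal refinement"):
        if options.refine:
            params = options.zreg_params
            rootlets_tpl = warps.apply_warp(rootlets, w23)
            mask_sub = zreg.dilate_labels(rootlets_tpl, params.dilation)
            mask_tpl = zreg.dilate_labels(template.rootlets, params.dilation)
            img_tpl = warps.apply_warp(image, w23)
            sub_masked = Volume(img_tpl.data * mask_sub.labels, template.image.affine)
            tpl_masked = Volume(template.image.data * mask_tpl.labels, template.image.affine)
            w_z, zdiag = zreg.register_z(sub_masked, tpl_masked, params)
            w_sym = warps.symmetrize_slicewise(w_z)
            diagnostics["zreg"] = zdiag
            full = warps.compose(w_sym, w23)
        else:
            full = w23

    scale_profile = None
    with _stage("xy scaling"):
        if not options.no_xy_scaling:
            cord_tpl = warps.apply_warp(cord, full)
            w_xy, scale_profile = warps.xy_scaling(cord_tpl, template.cord)
            diagnostics["scale_profile"] = scale_profile
            full = warps.compose(w_xy, full)

    with _stage("warp concatenation"):
        w_fwd = full
        w_bwd = warps.invert(full, target_shape=image.shape, target_affine=image.affine,
                             max_iter=100)

    with _stage("resampling outputs"):
        warped_image = warps.apply_warp(image, w_fwd)
        warped_cord = warps.apply_warp(cord, w_fwd)
        warped_rootlets = warps.apply_warp(rootlets, w_fwd)

    return RegistrationResult(
        warp_forward=w_fwd, warp_backward=w_bwd, straightened=straightened,
        warped_image=warped_image, warped_cord=warped_cord,
        warped_rootlets=warped_rootlets, scale_profile=scale_profile,
        diagnostics=diagnostics,
    )
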