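# rootletreg

Rootlet-landmark registration of cervical spinal cord MRI to a straightened
template, for researchers doing group-level spinal cord analyses (fMRI,
morphometry, atlas-based quantification) who need spinal levels — not just
vertebral levels — aligned across subjects.

## Why rootlets?

Template registration of the spinal cord traditionally aligns intervertebral
discs. But spinal levels are defined by where the nerve rootlets enter the
cord, and the rootlet-to-disc correspondence varies substantially across
individuals and with neck position, increasingly so toward caudal levels.
`rootletreg` aligns a level-labelled dorsal rootlet segmentation (labels
2–8 = C2–C8) directly to the template's rootlets:

1. per-level center-of-mass landmarks, subject and template;
2. cord straightening along the centerline (arc-length parameterized,
   parallel-transported in-plane frames);
3. monotone 1D alignment of landmark z positions (PCHIP between landmarks,
   constant shift beyond);
4. rostro-caudal B-spline refinement on rootlet-masked images
   (z-only displacement profile, normalized cross-correlation);
5. slice-wise averaging of the refinement field for left–right symmetry
   (mean over non-zero values, broadcast per slice);
6. per-slice isotropic in-plane scaling, s(z) = √(A_template / A_subject),
   to match cord size (optional);
7. concatenation of all displacement fields into forward and backward warps.

A disc-landmark baseline (same machinery, disc labels, no rootlet-masked
refinement) is included for head-to-head comparisons, and a synthetic
phantom generator provides subject/template pairs with known ground truth
so the whole pipeline is testable without any imaging data.

## Worked example

```python
import numpy as np
from rootletreg import (PhantomSpec, generate_phantom, generate_cohort,
                        register_to_template, rootlet_overlap)
from rootletreg.pipeline import TemplateBundle, RegistrationOptions

# synthetic template and a jittered subject with a 4 mm rootlet-disc offset
template, subjects = generate_cohort(1, level_jitter_sd=2.0,
                                     rootlet_disc_offset_sd=4.0, seed=42)
bundle = TemplateBundle(image=template.image, cord=template.cord,
                        rootlets=template.rootlets, discs=template.discs)
sub = subjects[0]

res = register_to_template(sub.image, sub.cord, sub.rootlets, bundle,
                           discs=sub.discs)
ov = rootlet_overlap(res.warped_rootlets, bundle.rootlets)
print(f"rootlet-based: mean overlap {ov.mean:.1f} %")

baseline = register_to_template(sub.image, sub.cord, sub.rootlets, bundle,
                                discs=sub.discs,
                                options=RegistrationOptions(landmarks="discs"))
ovd = rootlet_overlap(baseline.warped_rootlets, bundle.rootlets)
print(f"disc-based:    mean overlap {ovd.mean:.1f} %")
```

prints

```
rootlet-based: mean overlap 96.4 %
disc-based:    mean overlap 56.7 %
```

The overlap is, per level, the percentage of the template level's axial
slices that the warped subject rootlets also occupy — 100% means the
subject's spinal levels land exactly on the template's. The disc baseline
is blind to the simulated rootlet-vs-disc offset and misplaces the levels.

The same pipeline is available from the shell:

```bash
rootletreg phantom cohort --out-dir data --n 3 --seed 1 --disc-offset-sd 4
rootletreg register --image data/sub-00/image.nii.gz \
    --cord data/sub-00/cord.nii.gz --rootlets data/sub-00/rootlets.nii.gz \
    --template-dir data/template --out-dir out
rootletreg metrics overlap --subject out/rootlets_in_template.nii.gz \
    --template data/template/rootlets.nii.gz --out out/overlap.csv
```

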