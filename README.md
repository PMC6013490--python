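# bbsynth

Vessel-suppressed "black-blood" (BB) brain MRI without the extra scan, at
desk scale.

## The problem

Contrast-enhanced 3D gradient-echo (CE 3D-GRE) imaging is the workhorse
sequence for detecting brain metastases, but enhancing blood vessels are
bright on it too, and tiny cortical metastases are easily lost among small
vessels. Black-blood imaging suppresses flowing-blood signal so that only
lesions stay bright — at the cost of an additional 5–7 minute acquisition.
A 3D convolutional network can learn to transform a GRE volume directly
into a vessel-suppressed volume, but raw BB images make poor training
labels (different tissue contrast, blur), so the pipeline first builds
*synthetic BB* label volumes from registered GRE/BB pairs by an automatic
two-pass vessel extraction-and-replacement, then trains a residual 3D CNN
on GRE → synthetic-BB patch pairs. This package implements that full
pipeline and replaces patient data with 3D digital phantoms carrying exact
vessel/lesion/tissue ground truth, so every stage is testable on a laptop.

## What is in the box

| module | role |
| --- | --- |
| `bbsynth.phantom` | paired GRE-like/BB-like phantoms: three vessel caliber classes, blob metastases, WM/GM tissue contrast, noise, BB blur, optional unsuppressed vessel segments |
| `bbsynth.preprocess` | NIfTI I/O, intensity normalization (divide by volume max), rigid registration (SimpleITK), brain extraction (Otsu + closing + largest component) |
| `bbsynth.autolabel` | fuzzy c-means tissue clustering, region-grown pass-1 vessel mask, BB fill with blended dilation ring, difference-image thresholding for the pass-2 residual-vessel mask |
| `bbsynth.bbnet` | residual 3D CNN (NumPy, manual backprop): 3×3×3 convs, batch norm + ReLU, input-to-output skip, MSRA init, Adam with global-norm gradient clipping and step lr decay, 31³ co-located patch sampling, whole-volume/tiled inference |
| `bbsynth.evalmetrics` | nine-ROI vessel suppression ratio `R_s`, per-lesion detection scoring with false-positive counts, weighted-kappa rater agreement |

The key evaluation statistic is the vessel suppression ratio

```
R_s = SI_WM / (0.5 * (SI_WM + SI_vessel))
```

with `SI_WM` the mean white-matter ROI signal and `SI_vessel` the mean of
three vessel-ROI means of one caliber class. `R_s` ranges over (0, 2]:
2 means vessel signal fully suppressed to background, 1 means vessels
isointense to WM, and values below 1 mean vessels brighter than WM (the
GRE situation).

## Worked example

```python
import numpy as np
from bbsynth import PhantomSpec, generate_pair, synthesize_bb, StudyPair
from bbsynth.preprocess import extract_brain
from bbsynth.evalmetrics import place_phantom_rois, suppression_report

spec = PhantomSpec(seed=1)                     # 96³, 1 mm isotropic
truth, gre, bb = generate_pair(spec)
pair = StudyPair(gre=gre, bb=bb, brain_mask=extract_brain(gre), registered=True)
synth, mask1, mask2 = synthesize_bb(pair)

vess = truth.vessel_mask()
print("vessel voxels covered:", (mask1.core | mask2.core)[vess].mean())
print("lesion voxels covered:", (mask1.core | mask2.core)[truth.lesion_mask()].mean())

rois = place_phantom_rois(truth, spec)
rep = suppression_report([gre, bb, synth], rois)
print(rep.to_frame()[["modality", "vessel_type", "r_s"]])
```

prints

```
vessel voxels covered: 1.0
lesion voxels covered: 0.0
   modality  vessel_type       r_s
0       GRE            1  0.687478
1       GRE            2  0.688614
2       GRE            3  0.689999
3        BB            1  1.741504
4        BB            2  1.713809
5        BB            3  1.578396
6  SYNTH_BB            1  1.740412
7  SYNTH_BB            2  1.712620
8  SYNTH_BB            3  1.576783
```

— the two-pass extraction found every true vessel voxel and no lesion
voxels; on the GRE volume vessels are brighter than WM (`R_s < 1`), while
the synthetic BB volume matches the original BB suppression to three
decimals (its vessel voxels are copied from BB) with lesions untouched.

The same pipeline continues into network training (see
`bbsynth.bbnet.TrainConfig.desk_scale()` for the CPU-sized configuration
used by the test suite) and produces deep-learned BB volumes from GRE
input alone via `bbsynth.bbnet.infer`.

A CLI mirrors the library: `bbsynth phantom | preprocess | autolabel |
train | infer | evaluate` (see `--help` on each).

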