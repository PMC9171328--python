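"""Partial-volume interface correction and intensity normalization.

Simulates an over-segmented cortical GM / WM interface on a phantom,
rebuilds the tissue boundary from partial-volume coefficients, and shows
the piecewise-linear tissue-median intensity normalizer mapping anchors
exactly.
"""

import numpy as np

from densefuse import dice
from densefuse.curation import correct_interface, normalize_intensity, partial_volume_map, regularize_pv
from densefuse.synthdata import PhantomSpec, corrupt_segmentation, make_phantom

spec = PhantomSpec(shape=(40, 40, 40), seed=9)
img, truth, scheme = make_phantom(spec)

# a biased labeling: cortical GM dilated one voxel into WM
biased = corrupt_segmentation(truth, scheme, "dilate_cGM_into_cWM", 0.8, seed=4)
cgm, cwm = scheme.ids_of_tissue("cGM"), scheme.ids_of_tissue("cWM")

# partial-volume coefficients from the tissue medians, then regularized
med_gm = float(np.median(img.voxels[np.isin(truth.labels, cgm)]))
med_wm = float(np.median(img.voxels[np.isin(truth.labels, cwm)]))
pv = regularize_pv(partial_volume_map(img, med_gm, med_wm))

fixed = correct_interface(biased, pv, cgm, cwm)
before = dice(biased, truth, cgm + cwm).mean()
after = dice(fixed, truth, cgm + cwm).mean()
print(f"GM/WM medians: {med_gm:.1f} / {med_wm:.1f}")
print(f"mean GM+WM Dice: biased {before:.4f} -> PV-corrected {after:.4f}")

out = normalize_intensity(img, [20.0, med_gm, med_wm], [20.0, 70.0, 120.0])
print(
    f"normalizer maps the measured GM median {med_gm:.2f} to "
    f"{np.interp(med_gm, [20.0, med_gm, med_wm], [20.0, 70.0, 120.0]):.1f} exactly"
)
print(
    "\nInterface voxels whose partial-volume content favours the opposing"
    "\ntissue are relabeled; the normalizer pins tissue medians to targets."
)
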