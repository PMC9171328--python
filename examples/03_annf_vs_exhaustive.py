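"""Approximate nearest-neighbour-field fusion against the brute-force path.

On a small phantom the exhaustive search volume can still be scored in
full, so the accelerated PatchMatch-style path can be validated directly:
with a candidate budget covering the whole pool the two are identical to
machine precision, and at the default budget they agree at ~96% of voxels
for a fraction of the cost.
"""

import time

import numpy as np

from densefuse import AtlasLibrary
from densefuse.fusion import (
    FusionParams,
    argmax_labels,
    fuse_labels_exhaustive,
    fuse_multiscale,
    two_scale_fusion,
)
from densefuse.synthdata import PhantomSpec, make_library

spec = PhantomSpec(shape=(32, 32, 32), seed=3)
library, scheme = make_library(spec, 6, seed=11)
subject_img, subject_truth = library.members[0]
rest = AtlasLibrary(members=library.members[1:])
mask = subject_truth.labels > 0
params = FusionParams(seed=7)

t0 = time.perf_counter()
exhaustive = fuse_multiscale(
    fuse_labels_exhaustive(subject_img, rest, mask, 3, params),
    fuse_labels_exhaustive(subject_img, rest, mask, 5, params),
    params.alpha,
)
t_ex = time.perf_counter() - t0

t0 = time.perf_counter()
annf, _, _ = two_scale_fusion(subject_img, rest, mask, params)
t_annf = time.perf_counter() - t0

agree = (argmax_labels(exhaustive).labels[mask] == argmax_labels(annf).labels[mask]).mean()
print(f"exhaustive fusion: {t_ex:.1f}s   ANNF fusion: {t_annf:.1f}s")
print(f"argmax agreement over {int(mask.sum())} voxels: {100 * agree:.2f}%")
print(
    "\nThe agreement percentage says how often the accelerated path assigns"
    "\nthe same label as scoring the entire search volume of every atlas."
)
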