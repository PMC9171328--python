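# densefuse

Multiscale non-local patch-based multi-atlas segmentation of T1-weighted
brain MRI, with approximate-nearest-neighbour-field (ANNF) acceleration, a
boosted patch-based ensemble error corrector, library-curation operators,
and multiscale volumetric reporting. A synthetic labeled-phantom generator
provides a fully reproducible test bed.

## Who this is for

Researchers who need a dense anatomical labeling of an affinely
template-registered brain volume from a library of co-registered expert
label maps, plus per-structure volumetry (template and native space),
left-right asymmetry ratios, and tissue/lobe-scale summaries — and who
want every stage of that computation testable against brute-force oracles
on synthetic data.

Inputs are assumed preprocessed: denoised, inhomogeneity-corrected, and
affinely registered to a common template grid (e.g. MNI152 at 1 mm³).
Denoising, bias correction, and registration are out of scope; a
piecewise-linear tissue-median intensity normalizer is included.

## The method

**Non-local label fusion.** Each target voxel `x_i` collects weighted votes
from every voxel `x_{s,j}` in a search volume `V_i` across all `N` library
members:

```
v(x_i) = Σ_s Σ_{j ∈ V_i} w(x_i, x_{s,j}) · y_{s,j}  /  Σ_s Σ_j w(x_i, x_{s,j})
w(x_i, x_{s,j}) = exp(−D_{i,j,s} / h²),   D = ‖P(x_i) − P(x_{s,j})‖² / |P|
```

where `P(·)` is the intensity patch, `D` the element-normalized squared L2
patch distance, and `h²` is estimated per voxel as the minimum patch
distance within the search volume (plus a small ε): a perfect match gets
weight 1 and collapses all competing votes.

**ANNF acceleration.** Instead of scoring the whole search volume, a
PatchMatch-style randomized field keeps the best k candidate patches per
voxel (random initialisation, scan-order propagation, decaying random
search). Each matched patch votes its whole label patch into the
corresponding subject neighbourhood ("patchwise late aggregation"). When
the search window is small enough the field falls back to exact
enumeration, which makes the accelerated path testable against the
brute-force one to machine precision.

**Two scales.** Fusion runs at two patch sizes (default 3³ and 5³) and the
per-label probability maps are mixed convexly: `p(l) = α·p₁(l) + (1−α)·p₂(l)`.

**ICC restriction.** The intracranial cavity is extracted first by the same
two-scale fusion run with binary (brain / background) labels; structure
fusion only processes ICC voxels.

**Error correction (PEC).** A per-structure corrector learns the
segmenter's systematic errors: 112 features per voxel (3³ fully sampled +
7³ skip-two-subsampled patches of both intensity and segmentation, one
contour-distance value, three template-space coordinates) mapped by an
ensemble of ten 112×83×55×27 networks, boosted so each new network focuses
on samples the running ensemble got wrong, onto the 3³ manual membership
patch. Averaged overlapping predictions toggle voxels in or out of the
structure near its contour.

**Reporting.** The corrected labeling is regrouped into eight tissue
classes (CSF, cGM, cWM, sGM, ceGM, ceWM, BS, WML) and cerebrum lobes, and
summarised as a CSV report: volumes (template and native space), percent of
ICC, right−left asymmetry `100·(R−L)/((R+L)/2)`, and cortical thickness
mean/SD per region when a thickness map is supplied.

## Worked example

```python
import numpy as np
from densefuse import (AtlasLibrary, FusionParams, PhantomSpec, dice,
                       make_library, segment_volume)

spec = PhantomSpec(shape=(48, 48, 48), seed=3)       # noisy, lesioned brain phantom
library, scheme = make_library(spec, 10, seed=11)    # 10 deformed copies
subject_img, subject_truth = library.members[0]      # leave-one-out subject
rest = AtlasLibrary(members=library.members[1:])

result = segment_volume(subject_img, rest, scheme, params=FusionParams(seed=7))
table = dice(result.structures, subject_truth)
print(f"mean structure Dice: {table.mean():.4f}")
print(result.report.table.head(9).to_string(index=False))
```

prints (abridged):

```
mean structure Dice: 0.9666
region  scale  volume_mm3_template  volume_mm3_native    pct_icc ...
   ICC    ICC              42225.0            42225.0 100.000000
    BS tissue                596.0              596.0   1.411486
   CSF tissue              21079.0            21079.0  49.920663
   WML tissue                142.0              142.0   0.336294
   cGM tissue               9718.0             9718.0  23.014802
   cWM tissue               7674.0             7674.0  18.174067
```

The mean Dice of 0.97 is the overlap between the automatic segmentation of
the held-out phantom and its ground-truth labels, averaged over the 19
structures present; the report rows give each region's volume and its share
of the intracranial cavity (tissue rows partition the ICC exactly).

The `examples/` directory holds short narrative scripts, one per
capability; the `densefuse` command exposes the same pipeline from the
shell (`densefuse phantom`, `densefuse run`, `densefuse pec-train`,
`densefuse dice`, `densefuse report`).

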