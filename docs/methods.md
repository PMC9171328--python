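# Methods

This note documents the models, parameter choices, and numerical decisions
behind densefuse, and what the synthetic test bed does and does not show.

## Label fusion

The segmentation engine is weighted non-local label voting: for each target
voxel, intensity patches from every library member within a cubic search
volume vote for their central (or covered) labels with weight
`exp(−D/h²)`, `D` being the mean squared intensity difference between the
subject patch and the candidate patch.

**h estimation.** `h² = D_min + ε` per target voxel, where `D_min` is the
minimum patch distance within that voxel's search volume and `ε = 1e−6`.
Consequences: a zero-distance (self) match gets weight exactly 1 and, since
`h² → ε`, suppresses every other candidate; when `D_min ≫ ε` the best match
gets weight ≈ `e^{−1}`. `h` is recomputed per voxel and per patch scale;
sharing it across scales would couple the two probability maps before the
explicit mixing step, which is the one place scale interaction is intended.

**Search volume.** Default half-width 4 voxels (9³ window). The library is
affinely pre-aligned to the template grid, so residual anatomical
displacement is a few voxels; the window must cover it and little more
(larger windows admit more false matches and cost cubically).

**Patch scales and mixing.** Two patch sizes, 3³ and 5³. The small scale
resolves thin structures (cortical ribbon), the large one is more robust in
homogeneous regions. The per-label maps are mixed convexly with
`α = 0.5` by default — an uninformative midpoint, exposed as a parameter.
Mixing endpoints are handled specially (`α ∈ {0, 1}` copies the input map
bit-exactly) so that endpoint identities hold exactly, not to floating
tolerance.

**ANNF.** The accelerated path keeps `k = 8` candidates per voxel per
scale, refined over 4 iterations of scan-order propagation (forward and
backward alternating) plus random search with radius halving per probe.
Candidate lists only improve, so the mean best distance is non-increasing
across iterations — a property the tests assert. When the search window
holds at most `k` positions per member the field is computed by exact
enumeration instead; with `k` equal to the whole candidate pool this makes
the ANNF path bit-compatible with exhaustive fusion, which is how the
equivalence tests work.

**Vote aggregation.** The exhaustive path votes per central voxel (the
literal reading of the voting equation). The ANNF path defaults to
patchwise late aggregation — each matched patch votes its whole label patch
into the covered subject neighbourhood with the weight computed at the
centre — which extracts more evidence per patch comparison, the standard
trade in the PatchMatch segmentation lineage. A central-voxel mode is also
provided and is what the oracle-equivalence tests use, since the two
aggregation rules are only comparable candidate-by-candidate in that mode.

**Borders and ties.** Patches are filled by edge replication at grid
borders; search windows are clamped to the grid. Probability argmax ties
break to the lowest label id — reproducible and independent of the label
scheme.

**ICC restriction.** The intracranial cavity is segmented first by the same
two-scale machinery with binary labels over the whole grid; structure
fusion then processes only ICC voxels. The reported ICC is the final
nonzero-labeled region (voxels inside the fusion mask that argmax assigns
to background are dropped), which is what makes the tissue-scale volumes
partition the ICC volume exactly.

**Lesion robustness** comes purely from library content: members carrying
WML labels let lesioned patches vote lesion, with no lesion-specific code
path.

## Error corrector (PEC)

One corrector per structure, applied one-vs-rest. The 27 network outputs
are sigmoid memberships of the structure in the 3³ patch of the reference
labels around the sample voxel; this is the only output-head reading
consistent with a fixed 112×83×55×27 topology when the scheme has
hundreds of structures. Features (length 112 = 27+27+27+27+1+3): 3³ fully
sampled and 7³ skip-two-subsampled patches of the intensity image and of
the binary automatic membership of the structure, the Euclidean distance to
the structure's automatic contour (contour = structure voxels with a
six-connected outside neighbour; unsigned), and the voxel's world
coordinates from the affine. Features are z-scored with statistics stored
in the model archive.

Training samples come from the band within 2 voxels of the automatic
contour — the corrector's contract is local, and the band bounds both the
sample pool and the set of voxels `pec_apply` may change. Ten networks
(ReLU hidden layers 83 and 55, trained as multilabel classifiers) are fit
sequentially on resamples of the pool; after each, samples the running
ensemble misclassifies (any of the 27 thresholded outputs wrong) have their
selection weight multiplied by `1 + β`, `β = 2`, then renormalized. At
apply time the overlapping 3³ predictions are averaged per voxel; band
voxels whose mean membership crosses 0.5 toggle in or out. Voxels displaced
out of the structure take the runner-up fusion label when probability maps
are available, else the label of the nearest non-structure voxel.

Unstated training details (activations, epochs, loss, overlap
reconciliation) are package decisions: ReLU/logistic heads, log-loss with
a fixed iteration budget, plain averaging of overlapping predictions.

## Curation operators

Relabel tables apply all rules simultaneously in one step (cycles are
rejected; chains move one step per application). Partial-volume
coefficients come from the two-median linear mixing model, clipped to
[0, 1]; regularization is a non-local-means filter whose weights reuse the
fusion module's min-distance-normalized rule, with the centre voxel fixed
at weight 1 (otherwise the self-distance of 0 would drive `h² → ε` and
freeze the filter). Interface correction relabels only voxels with a
six-connected neighbour in the opposing tissue set, switching when the
opposing coefficient exceeds their own, and assigns the nearest structure
id of the target set (per-id distance transforms, ties to the lowest id).
Regularization precedes relabeling. Intensity normalization is a continuous
piecewise-linear map through strictly increasing tissue-median anchors,
extrapolated with the adjacent segment's slope; anchors map bit-exactly.
Tissue medians are estimated globally, not per hemisphere.

## Reporting

Asymmetry is `100·(R−L)/((R+L)/2)` (positive = right larger) — the
conventional normalized difference; the choice of formula and sign is a
package convention. Native-space volumes are template volumes scaled by
|det| of the native-to-template affine inverse, avoiding a second
interpolation. Dice for labels absent from both volumes is reported as
missing, not zero, so averages run over present labels. Thickness is
consumed, never computed: without a supplied thickness map the columns stay
absent. Report CSV rows are ordered ICC, tissues, lobes, structures, with
fixed columns and formatting, so identical runs produce byte-identical
files.

## Synthetic test bed

The phantom nests an ICC ellipsoid, an outer CSF shell, a cortical GM
ribbon over a cerebral WM core with subcortical GM blobs, a cerebellum
with its own GM shell and WM core, and a brainstem cylinder; everything is
split at the midplane into hemisphere-specific structures with flip pairs,
and the cortical ribbon is further split into anterior/posterior lobes.
Intensities are per-tissue constants (CSF 20, cGM 70, cWM 120, sGM 85,
ceGM 75, ceWM 110, BS 95, WML 72, arbitrary units) plus Gaussian noise,
default σ = 2.5 — 5% of the 50-unit cGM–cWM contrast. WM lesions (default
one per hemisphere, radius 5–7% of the grid edge ≈ 2.4–3.4 voxels at 48³)
are carved strictly inside cerebral WM with near-cGM intensity, the failure
mode a lesion-bearing library absorbs. Libraries warp a noiseless base
phantom with smooth random displacement fields (Gaussian-correlated,
default peak amplitude 2 voxels, correlation length 6 voxels), nearest-
neighbour for labels and trilinear for intensities, then add per-member
intensity jitter (2%) and fresh noise. Every generator is a pure function
of its spec and seed.

What this does not emulate: cortical folding, MR physics (Gaussian, not
Rician, noise — adequate at phantom SNR), partial-volume intensity
gradients, periventricular lesion priors, and inter-protocol label
variability. Passing the synthetic benchmarks therefore demonstrates the
correctness and internal consistency of the machinery — oracle agreement,
determinism, conservation properties, the direction of the corrector's
effect — not clinical-grade accuracy on real scans, whose Dice levels
depend on a real expert-labeled library.

## Problem sizes and benchmarks

The benchmark battery uses grids of 8³–48³ with libraries of up to 10
members: 48³ with N = 10 for leave-one-out segmentation and scan-rescan
reproducibility, 40³ with 5 train / 5 test phantoms for the corrector, 32³
for accelerated-vs-exhaustive agreement, and 8³ for exact oracle identity.
These sizes keep brute-force oracles computable while leaving every
structure several hundred voxels, large enough for Dice to be a stable
statistic. Determinism is end-to-end: identical inputs, parameters, and
seed give bit-identical label volumes and byte-identical reports.

## Known limitations

- The exhaustive fusion path is cubic in the search radius and only
  practical on small grids; at full template resolution (181×217×181) only
  the ANNF path is realistic.
- Correctors are per-structure; correcting many structures trains and
  applies many ensembles (no joint multi-structure head).
- PatchMatch candidate quality (and hence the ≈95–97% agreement with
  exhaustive fusion) depends on the budget `k × iterations`; pathological
  images with no spatial label coherence would degrade propagation.
- `normalize_intensity` assumes strictly increasing tissue medians and a
  global (not per-hemisphere) estimate.
- The pipeline accepts preprocessing as a met precondition and performs no
  registration or resampling; volumes in native space are obtained by
  determinant scaling, not inverse warping.
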