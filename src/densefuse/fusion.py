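"""Non-local patch-based multi-atlas label fusion.

The segmentation engine: each target voxel collects weighted label votes
from similar intensity patches found across a co-registered template
library, either exhaustively within a search volume or through a
PatchMatch-style approximate nearest-neighbour field (ANNF). Two patch
scales are fused by a convex mixing of their probability maps, and the
intracranial cavity (ICC) is extracted with the same machinery run on
binary masks.

Vote weight for a candidate patch at distance D is ``exp(-D / h^2)`` with
``h^2`` estimated per target voxel from the minimum patch distance within
its search volume (plus a small epsilon so a perfect self-match yields
weight exactly 1 and collapses all competing votes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core_io import AtlasLibrary, ImageVolume, LabelVolume


@dataclass
class FusionParams:
    """Tunable parameters of the fusion engine.

    patch_sizes
        Two odd cube edge lengths in voxels; the small scale is sharper,
        the large scale more contextual.
    search_radius
        Half-width of the cubic search volume around each voxel.
    alpha
        Mixing coefficient of the two scale probability maps
        (``p = alpha * p_small + (1 - alpha) * p_large``).
    annf_iterations, annf_k
        PatchMatch budget: propagation/random-search rounds and candidates
        kept per voxel per scale.
    h_epsilon
        Additive floor of the per-voxel weight normaliser ``h^2``.
    """

    patch_sizes: tuple[int, int] = (3, 5)
    search_radius: int = 4
    alpha: float = 0.5
    annf_iterations: int = 4
    annf_k: int = 8
    seed: int = 0
    h_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        for p in self.patch_sizes:
            if p < 1 or p % 2 == 0:
                raise ValueError(f"patch sizes must be odd and >= 1, got {p}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.search_radius < max(self.patch_sizes) // 2:
            raise ValueError("search_radius must be >= the largest patch half-width")
        if self.annf_iterations < 1:
            raise ValueError("annf_iterations must be positive")
        if self.annf_k < 1:
            raise ValueError("annf_k must be positive")
        if self.h_epsilon <= 0:
            raise ValueError("h_epsilon must be positive")


@dataclass
class ProbabilityMaps:
    """Per-label probability grids over a processed-voxel mask.

    At every masked voxel the values are non-negative and sum to one
    (within 1e-6); outside the mask all maps are zero.
    """

    labels: np.ndarray  # ordered label ids, ascending
    maps: np.ndarray  # (n_labels, nx, ny, nz)
    mask: np.ndarray  # bool (nx, ny, nz)

    def check_normalized(self, tol: float = 1e-6) -> None:
        sums = self.maps.sum(axis=0)
        if not np.all(np.abs(sums[self.mask] - 1.0) < tol):
            raise AssertionError("masked probabilities do not sum to 1")
        if self.mask.size and np.any(sums[~self.mask] != 0.0):
            raise AssertionError("probabilities nonzero outside the mask")


@dataclass
class PatchMatchField:
    """Per-voxel best-k patch correspondences into the library."""

    positions: np.ndarray  # (M, 3) masked voxel indices, scan order
    subject_index: np.ndarray  # (M, k)
    cand_x: np.ndarray
    cand_y: np.ndarray
    cand_z: np.ndarray
    distance: np.ndarray  # (M, k), ascending
    count: np.ndarray  # (M,) valid candidates
    patch_size: int
    mask: np.ndarray
    mean_best_per_iteration: np.ndarray = field(default_factory=lambda: np.zeros(0))


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def patch_distance(patch_a: np.ndarray, patch_b: np.ndarray) -> float:
    """Normalised squared L2 distance: mean of squared element differences."""
    a = np.asarray(patch_a, dtype=float)
    b = np.asarray(patch_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"patch shapes differ: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def patch_weights(distances, h_epsilon: float = 1e-6) -> np.ndarray:
    """Exponential patch weights with the minimum-distance h estimate.

    ``h^2 = min(distances) + h_epsilon`` so the closest candidate always
    receives the largest weight, equal to 1 when its distance is zero.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("distances must be nonempty")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    h2 = d.min() + h_epsilon
    return np.exp(-d / h2)


# ---------------------------------------------------------------------------
# Shared preparation helpers
# ---------------------------------------------------------------------------

def _check_grids(subject: ImageVolume, library: AtlasLibrary) -> None:
    if library.N < 1:
        raise ValueError("empty library")
    if subject.shape != library.shape:
        raise ValueError(
            f"subject grid {subject.shape} does not match library grid {library.shape}"
        )


def _padded_stacks(subject: ImageVolume, library: AtlasLibrary, patch_size: int):
    hw = patch_size // 2
    pad = ((hw, hw),) * 3
    subpad = np.pad(subject.voxels.astype(np.float64), pad, mode="edge")
    libpad = np.stack(
        [np.pad(img.astype(np.float64), pad, mode="edge") for img in library.images()]
    )
    return subpad, libpad, hw


def _label_universe(library: AtlasLibrary):
    ids = np.unique(np.concatenate([np.unique(g) for g in library.label_grids()]))
    lut = np.zeros(int(ids.max()) + 1, dtype=np.int64)
    for i, lab in enumerate(ids):
        lut[lab] = i
    return ids.astype(np.int64), lut


def _mask_positions(mask: np.ndarray) -> np.ndarray:
    positions = np.argwhere(mask).astype(np.int64)
    if positions.shape[0] == 0:
        raise ValueError("mask is empty")
    return positions


def _scatter_rows(
    row_probs: np.ndarray, positions: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> ProbabilityMaps:
    maps = np.zeros((len(labels),) + mask.shape, dtype=np.float64)
    maps[:, positions[:, 0], positions[:, 1], positions[:, 2]] = row_probs.T
    return ProbabilityMaps(labels=labels, maps=maps, mask=mask.astype(bool))


# ---------------------------------------------------------------------------
# Fusion paths
# ---------------------------------------------------------------------------

def fuse_labels_exhaustive(
    subject: ImageVolume,
    library: AtlasLibrary,
    mask: np.ndarray,
    patch_size: int,
    params: FusionParams,
) -> ProbabilityMaps:
    """Brute-force non-local label fusion over the full search volume.

    Every position of every library member within the search window votes
    for its central label. This is the reference path the ANNF acceleration
    is checked against; cost grows with the cube of the search radius.
    """
    _check_grids(subject, library)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != subject.shape:
        raise ValueError("mask grid mismatch")
    positions = _mask_positions(mask)
    subpad, libpad, _ = _padded_stacks(subject, library, patch_size)
    labstack = np.stack([g.astype(np.int64) for g in library.label_grids()])
    labels, lut = _label_universe(library)
    rows = _kernels.exhaustive_fuse_kernel(
        subpad,
        libpad,
        labstack,
        positions,
        lut,
        len(labels),
        np.asarray(subject.shape, dtype=np.int64),
        patch_size,
        params.search_radius,
        params.h_epsilon,
    )
    return _scatter_rows(rows, positions, labels, mask)


def build_annf(
    subject: ImageVolume,
    library: AtlasLibrary,
    mask: np.ndarray,
    patch_size: int,
    params: FusionParams,
    seed: int | None = None,
) -> PatchMatchField:
    """Build the approximate nearest-neighbour field for one patch scale.

    When the search window is small enough that it holds at most ``annf_k``
    positions per member, the field is computed by exact enumeration (the
    randomised search could add nothing); otherwise the PatchMatch loop of
    random initialisation, scan-order propagation, and decaying random
    search is run for ``annf_iterations`` rounds.
    """
    _check_grids(subject, library)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != subject.shape:
        raise ValueError("mask grid mismatch")
    window = (2 * params.search_radius + 1) ** 3
    if params.annf_k > window * library.N:
        raise ValueError(
            f"annf_k={params.annf_k} exceeds the candidate pool "
            f"({window} window positions x {library.N} members)"
        )
    positions = _mask_positions(mask)
    subpad, libpad, _ = _padded_stacks(subject, library, patch_size)
    shape = np.asarray(subject.shape, dtype=np.int64)
    if window <= params.annf_k:
        cs, cx, cy, cz, cd, cn = _kernels.enumerate_field_kernel(
            subpad, libpad, positions, shape, patch_size,
            params.search_radius, params.annf_k,
        )
        mean_best = np.full(params.annf_iterations + 1, cd[:, 0].mean())
    else:
        idx_map = np.full(subject.shape, -1, dtype=np.int64)
        idx_map[positions[:, 0], positions[:, 1], positions[:, 2]] = np.arange(
            positions.shape[0]
        )
        kernel_seed = int((params.seed if seed is None else seed) + 7919 * patch_size) % (
            2**31 - 1
        )
        cs, cx, cy, cz, cd, cn, mean_best = _kernels.patchmatch_kernel(
            subpad, libpad, positions, idx_map, shape, patch_size,
            params.search_radius, params.annf_k, params.annf_iterations, kernel_seed,
        )
    return PatchMatchField(
        positions=positions,
        subject_index=cs,
        cand_x=cx,
        cand_y=cy,
        cand_z=cz,
        distance=cd,
        count=cn,
        patch_size=patch_size,
        mask=mask,
        mean_best_per_iteration=mean_best,
    )


def fuse_labels_annf(
    subject: ImageVolume,
    library: AtlasLibrary,
    annf_field: PatchMatchField,
    patch_size: int,
    params: FusionParams,
    aggregation: str = "patch",
) -> ProbabilityMaps:
    """Label fusion over ANNF candidates.

    ``aggregation="patch"`` (default) performs patchwise late aggregation:
    each matched patch votes its whole label patch into the corresponding
    subject neighbourhood with the weight computed at the patch centre.
    ``aggregation="center"`` restricts voting to the central voxel, which
    makes the output comparable term-by-term with the exhaustive path
    restricted to the same candidates.
    """
    _check_grids(subject, library)
    if annf_field.patch_size != patch_size:
        raise ValueError("field was built for a different patch size")
    if annf_field.mask.shape != subject.shape:
        raise ValueError("field mask grid mismatch")
    labels, lut = _label_universe(library)
    positions = annf_field.positions
    mask = annf_field.mask
    if aggregation == "center":
        labstack = np.stack([g.astype(np.int64) for g in library.label_grids()])
        rows = _kernels.vote_center_kernel(
            labstack,
            positions,
            annf_field.subject_index,
            annf_field.cand_x,
            annf_field.cand_y,
            annf_field.cand_z,
            annf_field.distance,
            annf_field.count,
            lut,
            len(labels),
            params.h_epsilon,
        )
        return _scatter_rows(rows, positions, labels, mask)
    if aggregation != "patch":
        raise ValueError(f"unknown aggregation mode {aggregation!r}")
    hw = patch_size // 2
    pad = ((hw, hw),) * 3
    labpad = np.stack(
        [np.pad(g.astype(np.int64), pad, mode="edge") for g in library.label_grids()]
    )
    acc, wsum = _kernels.vote_patchwise_kernel(
        labpad,
        positions,
        annf_field.subject_index,
        annf_field.cand_x,
        annf_field.cand_y,
        annf_field.cand_z,
        annf_field.distance,
        annf_field.count,
        lut,
        len(labels),
        np.asarray(subject.shape, dtype=np.int64),
        patch_size,
        hw,
        params.h_epsilon,
    )
    maps = np.zeros_like(acc)
    valid = mask & (wsum > 0)
    maps[:, valid] = acc[:, valid] / wsum[valid]
    return ProbabilityMaps(labels=labels, maps=maps, mask=mask.astype(bool))


def fuse_multiscale(
    p1: ProbabilityMaps, p2: ProbabilityMaps, alpha: float
) -> ProbabilityMaps:
    """Convex per-voxel mixing of two scale probability maps:
    ``p(l) = alpha * p1(l) + (1 - alpha) * p2(l)``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not np.array_equal(p1.labels, p2.labels):
        raise ValueError("probability maps carry different label sets")
    if not np.array_equal(p1.mask, p2.mask):
        raise ValueError("probability maps carry different masks")
    if alpha == 1.0:
        maps = p1.maps.copy()
    elif alpha == 0.0:
        maps = p2.maps.copy()
    else:
        maps = alpha * p1.maps + (1.0 - alpha) * p2.maps
    return ProbabilityMaps(labels=p1.labels.copy(), maps=maps, mask=p1.mask.copy())


def argmax_labels(p: ProbabilityMaps, affine: np.ndarray | None = None) -> LabelVolume:
    """Most probable label per masked voxel; ties go to the lowest label id,
    unmasked voxels get background (0)."""
    order = np.argsort(p.labels, kind="stable")
    # labels are kept ascending so np.argmax's first-hit rule is the tie rule
    best = np.argmax(p.maps[order], axis=0)
    out = p.labels[order][best]
    out = np.where(p.mask, out, 0).astype(np.int32)
    if affine is None:
        affine = np.eye(4)
    return LabelVolume(labels=out, affine=affine)


def write_probability_maps(p: ProbabilityMaps, path, affine=None) -> None:
    """Write probability maps as a 4-D NIfTI stack (one volume per label).

    The label order is documented in a sidecar CSV next to the stack
    (``<stem>_labels.csv`` with columns ``index,label_id``).
    """
    import nibabel as nib
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    stack = np.moveaxis(p.maps, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(stack, np.asarray(affine, dtype=float)), str(path))
    stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    sidecar = path.parent / f"{stem}_labels.csv"
    pd.DataFrame(
        {"index": np.arange(len(p.labels)), "label_id": p.labels}
    ).to_csv(sidecar, index=False)


# ---------------------------------------------------------------------------
# Two-scale convenience driver and ICC extraction
# ---------------------------------------------------------------------------

def two_scale_fusion(
    subject: ImageVolume,
    library: AtlasLibrary,
    mask: np.ndarray,
    params: FusionParams,
    aggregation: str = "patch",
) -> tuple[ProbabilityMaps, ProbabilityMaps, ProbabilityMaps]:
    """Run ANNF fusion at both patch scales and mix with ``alpha``.

    Returns ``(mixed, p_small, p_large)``.
    """
    per_scale = []
    for patch_size in params.patch_sizes:
        annf_field = build_annf(subject, library, mask, patch_size, params)
        per_scale.append(
            fuse_labels_annf(subject, library, annf_field, patch_size, params, aggregation)
        )
    mixed = fuse_multiscale(per_scale[0], per_scale[1], params.alpha)
    return mixed, per_scale[0], per_scale[1]


def extract_icc(
    subject: ImageVolume, icc_library: AtlasLibrary, params: FusionParams
) -> np.ndarray:
    """Intracranial-cavity mask by two-scale binary label fusion.

    The library labels must be binary (0 background, 1 ICC); the whole grid
    is processed and the argmax of the mixed probability maps is returned as
    a boolean mask. All downstream structure fusion is restricted to it.
    """
    for _, lab in icc_library.members:
        present = np.unique(lab.labels)
        if not np.all(np.isin(present, (0, 1))):
            raise ValueError("ICC library labels must be binary (0/1)")
    full = np.ones(subject.shape, dtype=bool)
    mixed, _, _ = two_scale_fusion(subject, icc_library, full, params)
    lab = argmax_labels(mixed, affine=subject.affine)
    return lab.labels == 1
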