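"""Library-curation operators.

Tools for bringing a heterogeneous labeled library to a consistent state:
simultaneous label renumbering/merging, partial-volume coefficient maps
from a linear two-tissue intensity mixing model, non-local-means
regularization of those maps, interface relabeling driven by partial
volume content, and piecewise-linear intensity normalization anchored at
tissue medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _kernels
from .core_io import ImageVolume, LabelVolume


@dataclass
class RelabelTable:
    """Simultaneous (source_id -> target_id) renumbering rules."""

    rules: list[tuple[int, int]]

    def __post_init__(self) -> None:
        sources = [s for s, _ in self.rules]
        if len(sources) != len(set(sources)):
            raise ValueError("duplicate source ids in relabel table")
        # one-step semantics: rules applied simultaneously, so a cycle in the
        # successor graph means the table is self-contradictory
        succ = dict(self.rules)
        for start in succ:
            seen = {start}
            node = start
            while node in succ:
                node = succ[node]
                if node in seen:
                    raise ValueError(f"cyclic relabel rules involving id {node}")
                seen.add(node)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RelabelTable":
        df = pd.read_csv(path)
        return cls(rules=[(int(r.source_id), int(r.target_id)) for r in df.itertuples()])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.rules, columns=["source_id", "target_id"]).to_csv(path, index=False)


def apply_relabel(labels: LabelVolume, table: RelabelTable) -> LabelVolume:
    """Apply every rule simultaneously; total voxel count is conserved."""
    lab = labels.labels
    max_id = int(lab.max())
    lut = np.arange(max(max_id, max((s for s, _ in table.rules), default=0)) + 1,
                    dtype=lab.dtype)
    for src, dst in table.rules:
        lut[src] = dst
    return LabelVolume(labels=lut[lab], affine=labels.affine.copy(),
                       scheme_id=labels.scheme_id)


@dataclass
class PVMap:
    """Mixing fraction of tissue A vs tissue B per voxel, in [0, 1]."""

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=np.float64)
        if c.min() < 0 or c.max() > 1:
            raise ValueError("PV coefficients must lie in [0, 1]")
        self.coefficients = c


def partial_volume_map(image: ImageVolume, median_a: float, median_b: float) -> PVMap:
    """Linear mixing model: coefficient 1 at the tissue-A median, 0 at the
    tissue-B median, clipped to [0, 1]."""
    if median_a == median_b:
        raise ValueError("tissue medians must differ")
    coeff = (np.asarray(image.voxels, dtype=np.float64) - median_b) / (median_a - median_b)
    return PVMap(coefficients=np.clip(coeff, 0.0, 1.0))


def regularize_pv(
    pv: PVMap,
    patch_size: int = 3,
    search_radius: int = 3,
    filter_strength: float = 1.0,
) -> PVMap:
    """Non-local-means regularization of a PV coefficient grid.

    Weights follow the fusion module's patch-distance / min-distance-h
    rule applied to the PV grid itself; the output is a per-voxel convex
    combination of input values, hence stays within the input range.
    """
    if patch_size % 2 == 0 or patch_size < 1:
        raise ValueError("patch_size must be odd and >= 1")
    out = _kernels.nlm_kernel(
        np.asarray(pv.coefficients, dtype=np.float64),
        patch_size,
        search_radius,
        float(filter_strength),
        1e-6,
    )
    return PVMap(coefficients=np.clip(out, 0.0, 1.0))


def correct_interface(
    labels: LabelVolume,
    pv: PVMap,
    tissue_a_ids,
    tissue_b_ids,
) -> LabelVolume:
    """Relabel interface voxels between two tissue sets by PV content.

    Only voxels of one set with a six-connected neighbour in the other are
    candidates. A candidate switches set when the opposing coefficient
    (1-c for an A voxel, c for a B voxel) exceeds its own; the new id is
    the nearest structure of the target set (ties to the lowest id).
    """
    a_ids = sorted(set(int(i) for i in tissue_a_ids))
    b_ids = sorted(set(int(i) for i in tissue_b_ids))
    if set(a_ids) & set(b_ids):
        raise ValueError("tissue id sets must be disjoint")
    lab = labels.labels
    c = pv.coefficients
    if c.shape != lab.shape:
        raise ValueError("PV map grid mismatch")
    in_a = np.isin(lab, a_ids)
    in_b = np.isin(lab, b_ids)
    struct = ndimage.generate_binary_structure(3, 1)
    a_iface = in_a & ndimage.binary_dilation(in_b, structure=struct)
    b_iface = in_b & ndimage.binary_dilation(in_a, structure=struct)
    switch_to_b = a_iface & ((1.0 - c) > c)
    switch_to_a = b_iface & (c > (1.0 - c))
    out = lab.copy()
    for moved, target_ids in ((switch_to_b, b_ids), (switch_to_a, a_ids)):
        if not moved.any():
            continue
        best_d = np.full(lab.shape, np.inf)
        best_id = np.zeros(lab.shape, dtype=lab.dtype)
        for tid in target_ids:  # ascending: strict < keeps the lowest id on ties
            mask = lab == tid
            if not mask.any():
                continue
            d = ndimage.distance_transform_edt(~mask)
            better = d < best_d
            best_d[better] = d[better]
            best_id[better] = tid
        out[moved] = best_id[moved]
    return LabelVolume(labels=out, affine=labels.affine.copy(), scheme_id=labels.scheme_id)


def normalize_intensity(
    image: ImageVolume,
    measured_medians,
    target_medians,
) -> ImageVolume:
    """Continuous piecewise-linear intensity mapping through tissue anchors.

    Each measured median maps exactly to its target, linearly between
    anchors, with linear extrapolation at the adjacent segment's slope
    beyond the extreme anchors. Requires strictly increasing medians
    (CSF < GM < WM order), which makes the mapping monotone.
    """
    x = np.asarray(measured_medians, dtype=np.float64)
    y = np.asarray(target_medians, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need matching 1-D anchor lists with >= 2 entries")
    if np.any(np.diff(x) <= 0) or np.any(np.diff(y) <= 0):
        raise ValueError("medians must be strictly increasing in tissue order")
    data = np.asarray(image.voxels, dtype=np.float64)
    out = np.interp(data, x, y)
    lo_slope = (y[1] - y[0]) / (x[1] - x[0])
    hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
    below = data < x[0]
    above = data > x[-1]
    out[below] = y[0] + (data[below] - x[0]) * lo_slope
    out[above] = y[-1] + (data[above] - x[-1]) * hi_slope
    return ImageVolume(voxels=out, affine=image.affine.copy())
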