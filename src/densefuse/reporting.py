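"""Multiscale label grouping, volumetry, asymmetry, thickness, CSV report.

A structure segmentation is summarised at several anatomical scales:
structures, the eight tissue classes, cerebrum lobes, and the whole
intracranial cavity (ICC). Volumes are reported both on the template grid
and rescaled to native space through the determinant of the native-to-
template affine; paired structures get a normalized right-left asymmetry,
and cortical regions a thickness mean/SD when a thickness map is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    LabelScheme,
    LabelVolume,
    TISSUE_CLASS_IDS,
    TISSUE_CLASSES,
)

REPORT_COLUMNS = [
    "region",
    "scale",
    "volume_mm3_template",
    "volume_mm3_native",
    "pct_icc",
    "asymmetry_pct",
    "thickness_mean_mm",
    "thickness_sd_mm",
]

_SCALE_ORDER = {"ICC": 0, "tissue": 1, "lobe": 2, "structure": 3}


@dataclass
class VolumeReport:
    """Tabular volumetry report; one row per region per scale."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(REPORT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"report missing columns: {sorted(missing)}")
        vols = self.table["volume_mm3_template"]
        if (vols < 0).any():
            raise ValueError("volumes must be non-negative")
        pct = self.table["pct_icc"].dropna()
        if ((pct < 0) | (pct > 100.0 + 1e-9)).any():
            raise ValueError("pct_icc must lie in [0, 100]")


def scale_class_table(scheme: LabelScheme, scale: str) -> dict[int, str]:
    """Class id -> class name at the requested grouping scale."""
    if scale == "tissue":
        return {TISSUE_CLASS_IDS[t]: t for t in TISSUE_CLASSES}
    if scale == "lobe":
        lobes = sorted({e.lobe_class for e in scheme.entries if e.lobe_class})
        return {i + 1: name for i, name in enumerate(lobes)}
    raise ValueError(f"unknown grouping scale {scale!r}")


def group_labels(labels: LabelVolume, scheme: LabelScheme, scale: str) -> LabelVolume:
    """Replace each structure label by its class id at a coarser scale.

    Voxel counts are conserved per class (each class's count is the sum of
    its member structures'). Every nonzero label must define the requested
    class; for lobe grouping, mask non-lobar structures to 0 beforehand.
    """
    class_ids = scale_class_table(scheme, scale)
    name_to_id = {name: cid for cid, name in class_ids.items()}
    lab = labels.labels
    lut = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    present = np.unique(lab)
    for lid in present:
        if lid == 0:
            continue
        if int(lid) not in scheme:
            raise ValueError(f"label {int(lid)} not in scheme")
        entry = scheme[int(lid)]
        cls = entry.tissue_class if scale == "tissue" else entry.lobe_class
        if cls is None:
            raise ValueError(
                f"structure {entry.name} (id {int(lid)}) has no {scale} class"
            )
        lut[lid] = name_to_id[cls]
    return LabelVolume(labels=lut[lab], affine=labels.affine.copy(), scheme_id=f"{scale}-scale")


def keep_labels(labels: LabelVolume, ids) -> LabelVolume:
    """Zero out every label not in ``ids`` (used to restrict lobe grouping)."""
    keep = np.isin(labels.labels, np.asarray(sorted(set(int(i) for i in ids))))
    return LabelVolume(labels=np.where(keep, labels.labels, 0),
                       affine=labels.affine.copy(), scheme_id=labels.scheme_id)


def structure_volumes(labels: LabelVolume, native_affine_det: float = 1.0) -> pd.DataFrame:
    """Per-region volumes on the template grid and rescaled to native space.

    Template volume is voxel count times the voxel volume from the affine;
    the native volume multiplies by |det| of the native->template affine
    inverse (no resampling).
    """
    if native_affine_det <= 0:
        raise ValueError("native_affine_det must be > 0")
    voxel_vol = float(abs(np.linalg.det(labels.affine[:3, :3])))
    ids, counts = np.unique(labels.labels, return_counts=True)
    rows = []
    for lid, cnt in zip(ids, counts):
        if lid == 0:
            continue
        tvol = float(cnt) * voxel_vol
        rows.append(
            {
                "label_id": int(lid),
                "voxels": int(cnt),
                "volume_mm3_template": tvol,
                "volume_mm3_native": tvol * abs(native_affine_det),
            }
        )
    return pd.DataFrame(rows, columns=["label_id", "voxels", "volume_mm3_template",
                                       "volume_mm3_native"])


def asymmetry_ratios(volumes: pd.DataFrame, scheme: LabelScheme) -> pd.DataFrame:
    """Normalized right-left volume difference per flip pair, in percent.

    ``asymmetry_pct = 100 * (right - left) / ((right + left) / 2)``;
    positive means the right structure is larger. Pairs with both volumes 0
    or a missing member are reported as NaN.
    """
    vol_by_id = dict(zip(volumes["label_id"], volumes["volume_mm3_template"]))
    rows = []
    for id1, id2 in sorted(scheme.flip_pairs):
        left_id, right_id = (
            (id1, id2) if scheme[id1].hemisphere == "left" else (id2, id1)
        )
        left = vol_by_id.get(left_id)
        right = vol_by_id.get(right_id)
        if left is None or right is None or (left == 0 and right == 0):
            asym = np.nan
        else:
            asym = 100.0 * (right - left) / ((right + left) / 2.0)
        rows.append({"left_id": left_id, "right_id": right_id, "asymmetry_pct": asym})
    return pd.DataFrame(rows, columns=["left_id", "right_id", "asymmetry_pct"])


def thickness_summary(
    thickness_map: np.ndarray, labels: LabelVolume, region_ids
) -> pd.DataFrame:
    """Mean/SD thickness (mm) over each region's positive-thickness voxels.

    Regions with no positive-thickness voxels are omitted (missing row).
    """
    t = np.asarray(thickness_map, dtype=np.float64)
    if t.shape != labels.shape:
        raise ValueError("thickness map grid mismatch")
    rows = []
    for rid in sorted(set(int(i) for i in region_ids)):
        sel = (labels.labels == rid) & (t > 0)
        if not sel.any():
            continue
        vals = t[sel]
        rows.append(
            {
                "label_id": rid,
                "thickness_mean_mm": float(vals.mean()),
                "thickness_sd_mm": float(vals.std()),
            }
        )
    return pd.DataFrame(rows, columns=["label_id", "thickness_mean_mm", "thickness_sd_mm"])


def build_report(
    structures: LabelVolume,
    scheme: LabelScheme,
    native_affine_det: float = 1.0,
    thickness_map: np.ndarray | None = None,
) -> VolumeReport:
    """Assemble the multiscale volumetry report for one segmentation.

    The ICC is the nonzero-labeled region, so tissue-scale volumes
    partition it exactly. Asymmetry is filled for paired structures;
    thickness columns are filled for cortical structures and lobes when a
    thickness map is given, else left absent.
    """
    voxel_vol = float(abs(np.linalg.det(structures.affine[:3, :3])))
    icc_voxels = int((structures.labels > 0).sum())
    icc_vol = icc_voxels * voxel_vol
    det = abs(native_affine_det)

    rows = [
        {
            "region": "ICC",
            "scale": "ICC",
            "volume_mm3_template": icc_vol,
            "volume_mm3_native": icc_vol * det,
            "pct_icc": 100.0,
            "asymmetry_pct": np.nan,
            "thickness_mean_mm": np.nan,
            "thickness_sd_mm": np.nan,
        }
    ]

    def pct(vol):
        return 100.0 * vol / icc_vol if icc_vol > 0 else np.nan

    cortical_ids = {e.label_id for e in scheme.entries if e.tissue_class == "cGM"}

    # tissue scale
    tissues = group_labels(structures, scheme, "tissue")
    tis_vols = structure_volumes(tissues, native_affine_det)
    tissue_names = scale_class_table(scheme, "tissue")
    for r in tis_vols.itertuples():
        rows.append(
            {
                "region": tissue_names[r.label_id],
                "scale": "tissue",
                "volume_mm3_template": r.volume_mm3_template,
                "volume_mm3_native": r.volume_mm3_native,
                "pct_icc": pct(r.volume_mm3_template),
                "asymmetry_pct": np.nan,
                "thickness_mean_mm": np.nan,
                "thickness_sd_mm": np.nan,
            }
        )

    # lobe scale (cortical GM structures carrying a lobe class)
    lobed_ids = [e.label_id for e in scheme.entries if e.lobe_class]
    lobe_thick = {}
    if lobed_ids:
        lobes = group_labels(keep_labels(structures, lobed_ids), scheme, "lobe")
        lobe_names = scale_class_table(scheme, "lobe")
        lobe_vols = structure_volumes(lobes, native_affine_det)
        if thickness_map is not None:
            th = thickness_summary(thickness_map, lobes, list(lobe_names))
            lobe_thick = {int(r.label_id): (r.thickness_mean_mm, r.thickness_sd_mm)
                          for r in th.itertuples()}
        for r in lobe_vols.itertuples():
            tmean, tsd = lobe_thick.get(r.label_id, (np.nan, np.nan))
            rows.append(
                {
                    "region": lobe_names[r.label_id],
                    "scale": "lobe",
                    "volume_mm3_template": r.volume_mm3_template,
                    "volume_mm3_native": r.volume_mm3_native,
                    "pct_icc": pct(r.volume_mm3_template),
                    "asymmetry_pct": np.nan,
                    "thickness_mean_mm": tmean,
                    "thickness_sd_mm": tsd,
                }
            )

    # structure scale
    struct_vols = structure_volumes(structures, native_affine_det)
    asym = asymmetry_ratios(struct_vols, scheme)
    asym_by_id: dict[int, float] = {}
    for r in asym.itertuples():
        asym_by_id[r.left_id] = -r.asymmetry_pct if np.isfinite(r.asymmetry_pct) else np.nan
        asym_by_id[r.right_id] = r.asymmetry_pct
    struct_thick = {}
    if thickness_map is not None:
        th = thickness_summary(thickness_map, structures, sorted(cortical_ids))
        struct_thick = {int(r.label_id): (r.thickness_mean_mm, r.thickness_sd_mm)
                        for r in th.itertuples()}
    for r in struct_vols.itertuples():
        tmean, tsd = struct_thick.get(r.label_id, (np.nan, np.nan))
        rows.append(
            {
                "region": scheme[r.label_id].name,
                "scale": "structure",
                "volume_mm3_template": r.volume_mm3_template,
                "volume_mm3_native": r.volume_mm3_native,
                "pct_icc": pct(r.volume_mm3_template),
                "asymmetry_pct": asym_by_id.get(r.label_id, np.nan),
                "thickness_mean_mm": tmean,
                "thickness_sd_mm": tsd,
            }
        )

    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df = df.sort_values(
        by=["scale", "region"],
        key=lambda col: col.map(_SCALE_ORDER) if col.name == "scale" else col,
        kind="stable",
    ).reset_index(drop=True)
    return VolumeReport(table=df)


def write_report(report: VolumeReport, path: str | Path) -> None:
    """Deterministic CSV output: stable row order (ICC, tissues, lobes,
    structures) and stable column order."""
    report.table.to_csv(path, index=False, float_format="%.6f")


def read_report(path: str | Path) -> VolumeReport:
    return VolumeReport(table=pd.read_csv(path))
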