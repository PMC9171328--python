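"""Domain types, volume and label-scheme I/O, mirroring, and Dice evaluation.

All volumes live on a common template grid (affinely pre-registered); voxel
indexing is 0-based and the left-right flip axis is the first voxel axis,
matching the template x axis. World coordinates are obtained through the
4x4 voxel-to-world affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: The eight tissue classes reported at the tissue scale.
TISSUE_CLASSES = ("CSF", "cGM", "cWM", "sGM", "ceGM", "ceWM", "BS", "WML")

#: Stable integer ids used for tissue-scale label maps, in TISSUE_CLASSES order.
TISSUE_CLASS_IDS = {name: i + 1 for i, name in enumerate(TISSUE_CLASSES)}


@dataclass
class ImageVolume:
    """A 3-D scalar intensity grid with a voxel-to-world affine (mm)."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.voxels.ndim}-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class LabelVolume:
    """A 3-D non-negative integer grid; 0 is reserved for background."""

    labels: np.ndarray
    affine: np.ndarray
    scheme_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3-D label volume, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int32)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("label volume must hold integers")
            self.labels = as_int
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class SchemeEntry:
    label_id: int
    name: str
    hemisphere: str  # left | right | none
    tissue_class: str  # one of TISSUE_CLASSES
    lobe_class: str | None = None


@dataclass
class LabelScheme:
    """Structure table: id -> name, hemisphere, tissue class, lobe class,
    plus the set of left<->right flip pairs."""

    entries: list[SchemeEntry]
    flip_pairs: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [e.label_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate label ids in scheme: {dupes}")
        by_id = {e.label_id: e for e in self.entries}
        for e in self.entries:
            if e.hemisphere not in ("left", "right", "none"):
                raise ValueError(f"unknown hemisphere {e.hemisphere!r} for id {e.label_id}")
            if e.tissue_class not in TISSUE_CLASSES:
                raise ValueError(
                    f"unknown tissue_class {e.tissue_class!r} for id {e.label_id}"
                )
        for left_id, right_id in self.flip_pairs:
            if left_id not in by_id or right_id not in by_id:
                raise ValueError(f"flip pair ({left_id},{right_id}) references unknown id")
            if {by_id[left_id].hemisphere, by_id[right_id].hemisphere} != {"left", "right"}:
                raise ValueError(
                    f"flip pair ({left_id},{right_id}) must join opposite hemispheres"
                )
        self._by_id = by_id

    def __contains__(self, label_id: int) -> bool:
        return label_id in self._by_id

    def __getitem__(self, label_id: int) -> SchemeEntry:
        return self._by_id[label_id]

    @property
    def ids(self) -> list[int]:
        return [e.label_id for e in self.entries]

    def flip_map(self) -> dict[int, int]:
        """Symmetric id -> mirrored-id map; unpaired ids map to themselves."""
        m = {e.label_id: e.label_id for e in self.entries}
        for left_id, right_id in self.flip_pairs:
            m[left_id] = right_id
            m[right_id] = left_id
        return m

    def ids_of_tissue(self, tissue_class: str) -> list[int]:
        return [e.label_id for e in self.entries if e.tissue_class == tissue_class]

    def validate_labels(self, labels: LabelVolume) -> None:
        present = set(labels.present_ids().tolist())
        unknown = present - set(self.ids)
        if unknown:
            raise ValueError(f"label ids not in scheme: {sorted(unknown)}")


@dataclass
class AtlasLibrary:
    """An ordered library of co-registered (intensity, label) template pairs."""

    members: list[tuple[ImageVolume, LabelVolume]]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("atlas library must have at least one member")
        shape = self.members[0][0].shape
        for img, lab in self.members:
            if img.shape != shape or lab.shape != shape:
                raise ValueError("all library members must share one grid shape")

    @property
    def N(self) -> int:
        return len(self.members)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.members[0][0].shape

    def images(self) -> list[np.ndarray]:
        return [img.voxels for img, _ in self.members]

    def label_grids(self) -> list[np.ndarray]:
        return [lab.labels for _, lab in self.members]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI-1 volume (.nii / .nii.gz) as an ImageVolume.

    Intensities are kept at their stored scale. Raises for missing files and
    for volumes that are not 3-D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"unreadable NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume in {path}, got {data.ndim}-D")
    return ImageVolume(voxels=data, affine=img.affine)


def read_label_volume(path: str | Path, scheme_id: str | None = None) -> LabelVolume:
    vol = read_volume(path)
    data = np.asarray(vol.voxels)
    labels = np.rint(data).astype(np.int32)
    if not np.allclose(data, labels, atol=1e-6):
        raise ValueError(f"non-integer values in label volume {path}")
    return LabelVolume(labels=labels, affine=vol.affine, scheme_id=scheme_id)


def write_volume(vol: ImageVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; integer grids are stored as int32."""
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int32)
        affine = vol.affine
    else:
        data = np.asarray(vol.voxels)
        affine = vol.affine
    nib.save(nib.Nifti1Image(data, affine), str(path))


_SCHEME_COLUMNS = ["label_id", "name", "hemisphere", "tissue_class", "lobe_class", "flip_partner"]


def load_label_scheme(path: str | Path) -> LabelScheme:
    """Load a label scheme from its CSV representation.

    Columns: ``label_id,name,hemisphere,tissue_class,lobe_class,flip_partner``
    (``flip_partner`` empty when the structure has no mirrored counterpart).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label scheme file not found: {path}")
    df = pd.read_csv(path, dtype={"name": str})
    missing = set(_SCHEME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label scheme {path} missing columns: {sorted(missing)}")
    entries = []
    pairs: set[tuple[int, int]] = set()
    for row in df.itertuples(index=False):
        lobe = None if pd.isna(row.lobe_class) or row.lobe_class == "" else str(row.lobe_class)
        entries.append(
            SchemeEntry(
                label_id=int(row.label_id),
                name=str(row.name),
                hemisphere=str(row.hemisphere),
                tissue_class=str(row.tissue_class),
                lobe_class=lobe,
            )
        )
    known = {e.label_id for e in entries}
    for row in df.itertuples(index=False):
        if pd.isna(row.flip_partner) or row.flip_partner == "":
            continue
        partner = int(row.flip_partner)
        if partner not in known:
            raise ValueError(f"flip partner {partner} of id {int(row.label_id)} unknown")
        pair = tuple(sorted((int(row.label_id), partner)))
        pairs.add(pair)
    return LabelScheme(entries=entries, flip_pairs=pairs)


def save_label_scheme(scheme: LabelScheme, path: str | Path) -> None:
    flip = scheme.flip_map()
    rows = []
    for e in scheme.entries:
        partner = flip[e.label_id]
        rows.append(
            {
                "label_id": e.label_id,
                "name": e.name,
                "hemisphere": e.hemisphere,
                "tissue_class": e.tissue_class,
                "lobe_class": e.lobe_class or "",
                "flip_partner": "" if partner == e.label_id else partner,
            }
        )
    pd.DataFrame(rows, columns=_SCHEME_COLUMNS).to_csv(path, index=False)


def save_atlas_library(library: AtlasLibrary, directory: str | Path) -> None:
    """Write a library as ``member_XXX_t1.nii.gz`` / ``member_XXX_labels.nii.gz``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, (img, lab) in enumerate(library.members):
        write_volume(img, directory / f"member_{i:03d}_t1.nii.gz")
        write_volume(lab, directory / f"member_{i:03d}_labels.nii.gz")


def load_atlas_library(directory: str | Path) -> AtlasLibrary:
    """Load a library written by :func:`save_atlas_library`."""
    directory = Path(directory)
    t1s = sorted(directory.glob("member_*_t1.nii.gz"))
    if not t1s:
        raise FileNotFoundError(f"no library members found under {directory}")
    members = []
    for t1_path in t1s:
        lab_path = Path(str(t1_path).replace("_t1.nii.gz", "_labels.nii.gz"))
        if not lab_path.exists():
            raise FileNotFoundError(f"missing label volume for {t1_path}")
        members.append((read_volume(t1_path), read_label_volume(lab_path)))
    return AtlasLibrary(members=members)


# ---------------------------------------------------------------------------
# Mirroring and evaluation
# ---------------------------------------------------------------------------

def flip_lr(
    image: ImageVolume, labels: LabelVolume, scheme: LabelScheme
) -> tuple[ImageVolume, LabelVolume]:
    """Mirror an (image, labels) pair across the left-right midplane.

    The intensity grid is mirrored along the first voxel axis (index
    x -> nx-1-x) and every label is replaced by its flip-pair partner;
    unpaired labels are kept. Applying the operation twice is the identity.
    """
    if image.shape != labels.shape:
        raise ValueError("image and label grids must share one shape")
    mirrored = image.voxels[::-1, :, :].copy()
    lab = labels.labels[::-1, :, :]
    fmap = scheme.flip_map()
    max_id = max([0] + list(fmap))
    lut = np.arange(max(max_id + 1, int(lab.max()) + 1), dtype=labels.labels.dtype)
    for src, dst in fmap.items():
        lut[src] = dst
    if int(lab.max()) >= len(lut):
        raise ValueError("label volume contains ids not in the scheme")
    out_labels = lut[lab]
    return (
        ImageVolume(voxels=mirrored, affine=image.affine.copy()),
        LabelVolume(labels=out_labels, affine=labels.affine.copy(), scheme_id=labels.scheme_id),
    )


def dice(
    a: LabelVolume, b: LabelVolume, label_ids: Iterable[int] | None = None
) -> pd.Series:
    """Per-label Dice overlap 2|A∩B| / (|A|+|B|) between two segmentations.

    Labels absent from both volumes are reported as NaN (undefined), not 0,
    so that averages run over present labels only.
    """
    if a.shape != b.shape:
        raise ValueError("label volumes must share one grid shape")
    la, lb = a.labels.ravel(), b.labels.ravel()
    if label_ids is None:
        ids = np.union1d(np.unique(la), np.unique(lb))
        ids = ids[ids > 0]
    else:
        ids = np.asarray(sorted(set(int(i) for i in label_ids)))
    n = int(max(la.max(), lb.max(), ids.max() if len(ids) else 0)) + 1
    count_a = np.bincount(la, minlength=n)
    count_b = np.bincount(lb, minlength=n)
    inter = np.bincount(la[la == lb], minlength=n)
    out = {}
    for i in ids:
        denom = count_a[i] + count_b[i]
        out[int(i)] = 2.0 * inter[i] / denom if denom > 0 else np.nan
    return pd.Series(out, name="dice", dtype=float)
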