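"""Labeled brain phantoms and synthetic atlas libraries.

The generator emulates a library of affinely co-registered labeled brains:
nested piecewise-constant tissue geometry (ICC ellipsoid, CSF shell,
cortical GM ribbon over a WM core, subcortical GM blobs, a cerebellum with
its own GM/WM split, a brainstem cylinder), hemisphere-split structure ids
with left-right flip pairs, optional WM lesions with near-GM intensity,
smooth random inter-subject deformations, intensity jitter and Gaussian
noise. Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core_io import (
    AtlasLibrary,
    ImageVolume,
    LabelScheme,
    LabelVolume,
    SchemeEntry,
)

#: Default piecewise-constant tissue intensity means (arbitrary units). The
#: WML mean sits near the cortical GM mean so that a naive intensity
#: classifier would call lesions gray matter — the failure mode a
#: lesion-bearing library is meant to absorb.
DEFAULT_TISSUE_MEANS = {
    "CSF": 20.0,
    "cGM": 70.0,
    "cWM": 120.0,
    "sGM": 85.0,
    "ceGM": 75.0,
    "ceWM": 110.0,
    "BS": 95.0,
    "WML": 72.0,
}

# Fixed structure ids of the phantom scheme.
CSF_L, CSF_R = 1, 2
CGM_ANT_L, CGM_ANT_R = 3, 4
CGM_POST_L, CGM_POST_R = 5, 6
CWM_L, CWM_R = 7, 8
SGM_BASE = 20  # blob b: left 20+2b, right 21+2b
CEGM_L, CEGM_R = 40, 41
CEWM_L, CEWM_R = 42, 43
BS_ID = 45
WML_L, WML_R = 50, 51


@dataclass
class PhantomSpec:
    """Recipe for one phantom and, via deformation, a whole library.

    noise_sigma defaults to 2.5, i.e. 5% of the 50-unit cGM-cWM contrast;
    deformation_amplitude is the maximum displacement in voxels and
    deformation_smoothness the Gaussian correlation length of the field.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    noise_sigma: float = 2.5
    n_subcortical_blobs: int = 2
    lesion_count: int = 1  # per hemisphere
    lesion_radius: tuple[float, float] | None = None  # default: 5-7% of grid edge
    deformation_amplitude: float = 2.0
    deformation_smoothness: float = 6.0
    intensity_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deformation_amplitude < 0:
            raise ValueError("deformation amplitude must be >= 0")
        if len(set(self.tissue_means.values())) != len(self.tissue_means):
            raise ValueError("tissue intensity means must be distinct")
        if min(self.shape) < 16:
            raise ValueError("phantom geometry does not fit grids smaller than 16^3")
        if self.lesion_radius is None:
            # lesions must fit inside the WM core, whose depth scales with
            # the grid; 5-7% of the edge gives 2.4-3.4 voxels at 48^3
            edge = min(self.shape)
            self.lesion_radius = (0.05 * edge, 0.07 * edge)


def phantom_scheme(spec: PhantomSpec) -> LabelScheme:
    """The label scheme matching the phantom geometry (all eight tissues)."""
    entries = [
        SchemeEntry(CSF_L, "csf_left", "left", "CSF"),
        SchemeEntry(CSF_R, "csf_right", "right", "CSF"),
        SchemeEntry(CGM_ANT_L, "cortical_gm_anterior_left", "left", "cGM", "anterior"),
        SchemeEntry(CGM_ANT_R, "cortical_gm_anterior_right", "right", "cGM", "anterior"),
        SchemeEntry(CGM_POST_L, "cortical_gm_posterior_left", "left", "cGM", "posterior"),
        SchemeEntry(CGM_POST_R, "cortical_gm_posterior_right", "right", "cGM", "posterior"),
        SchemeEntry(CWM_L, "cerebral_wm_left", "left", "cWM"),
        SchemeEntry(CWM_R, "cerebral_wm_right", "right", "cWM"),
        SchemeEntry(CEGM_L, "cerebellar_gm_left", "left", "ceGM"),
        SchemeEntry(CEGM_R, "cerebellar_gm_right", "right", "ceGM"),
        SchemeEntry(CEWM_L, "cerebellar_wm_left", "left", "ceWM"),
        SchemeEntry(CEWM_R, "cerebellar_wm_right", "right", "ceWM"),
        SchemeEntry(BS_ID, "brainstem", "none", "BS"),
        SchemeEntry(WML_L, "wm_lesions_left", "left", "WML"),
        SchemeEntry(WML_R, "wm_lesions_right", "right", "WML"),
    ]
    pairs = {
        (CSF_L, CSF_R),
        (CGM_ANT_L, CGM_ANT_R),
        (CGM_POST_L, CGM_POST_R),
        (CWM_L, CWM_R),
        (CEGM_L, CEGM_R),
        (CEWM_L, CEWM_R),
        (WML_L, WML_R),
    }
    for b in range(spec.n_subcortical_blobs):
        left_id, right_id = SGM_BASE + 2 * b, SGM_BASE + 2 * b + 1
        entries.append(SchemeEntry(left_id, f"subcortical_gm_{b}_left", "left", "sGM"))
        entries.append(SchemeEntry(right_id, f"subcortical_gm_{b}_right", "right", "sGM"))
        pairs.add((left_id, right_id))
    return LabelScheme(entries=entries, flip_pairs=pairs)


def _centered_coords(shape):
    nx, ny, nz = shape
    x = np.arange(nx) - (nx - 1) / 2.0
    y = np.arange(ny) - (ny - 1) / 2.0
    z = np.arange(nz) - (nz - 1) / 2.0
    return np.meshgrid(x, y, z, indexing="ij")


def _ellipsoid(xc, yc, zc, center, semi):
    return (
        ((xc - center[0]) / semi[0]) ** 2
        + ((yc - center[1]) / semi[1]) ** 2
        + ((zc - center[2]) / semi[2]) ** 2
    )


def _phantom_affine(shape) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0
    return affine


def _build_geometry(spec: PhantomSpec) -> np.ndarray:
    """Noiseless structure label grid; mirror-symmetric for even first axes."""
    shape = spec.shape
    r = min(shape) / 2.0
    xc, yc, zc = _centered_coords(shape)
    left = xc < 0

    labels = np.zeros(shape, dtype=np.int32)

    icc = _ellipsoid(xc, yc, zc, (0, 0, 0), (0.9 * r, 0.93 * r, 0.88 * r)) <= 1.0
    labels[icc & left] = CSF_L
    labels[icc & ~left] = CSF_R

    # cerebrum: cGM ribbon over a cWM core, shifted up
    cereb_r = _ellipsoid(xc, yc, zc, (0, 0.04 * r, 0.14 * r), (0.72 * r, 0.74 * r, 0.62 * r))
    cereb = (cereb_r <= 1.0) & icc
    ribbon = cereb & (cereb_r > (1.0 - 0.22) ** 2)
    core = cereb & ~ribbon
    anterior = yc >= 0
    labels[ribbon & left & anterior] = CGM_ANT_L
    labels[ribbon & ~left & anterior] = CGM_ANT_R
    labels[ribbon & left & ~anterior] = CGM_POST_L
    labels[ribbon & ~left & ~anterior] = CGM_POST_R
    labels[core & left] = CWM_L
    labels[core & ~left] = CWM_R

    # subcortical GM blobs, symmetric pairs inside the WM core
    blob_radius = 0.17 * r
    for b in range(spec.n_subcortical_blobs):
        by = (-0.12 + 0.28 * b) * r
        bz = 0.12 * r
        for bx, lid in ((-0.3 * r, SGM_BASE + 2 * b), (0.3 * r, SGM_BASE + 2 * b + 1)):
            blob = (xc - bx) ** 2 + (yc - by) ** 2 + (zc - bz) ** 2 <= blob_radius**2
            blob &= np.isin(labels, (CWM_L, CWM_R))
            if not blob.any():
                raise ValueError("subcortical blob does not fit the grid geometry")
            labels[blob] = lid

    # cerebellum: posterior-inferior ellipsoid with its own GM shell / WM core
    cb_r = _ellipsoid(xc, yc, zc, (0, -0.5 * r, -0.52 * r), (0.44 * r, 0.33 * r, 0.3 * r))
    cb = (cb_r <= 1.0) & icc
    cb_shell = cb & (cb_r > (1.0 - 0.35) ** 2)
    cb_core = cb & ~cb_shell
    labels[cb_shell & left] = CEGM_L
    labels[cb_shell & ~left] = CEGM_R
    labels[cb_core & left] = CEWM_L
    labels[cb_core & ~left] = CEWM_R

    # brainstem: midline cylinder below the cerebrum
    bs = (
        (xc**2 + (yc + 0.12 * r) ** 2 <= (0.16 * r) ** 2)
        & (zc <= -0.3 * r)
        & (zc >= -0.95 * r)
        & icc
        & ~cb
    )
    labels[bs] = BS_ID

    required = [CSF_L, CSF_R, CGM_ANT_L, CGM_ANT_R, CGM_POST_L, CGM_POST_R,
                CWM_L, CWM_R, CEGM_L, CEGM_R, CEWM_L, CEWM_R, BS_ID]
    present = set(np.unique(labels).tolist())
    missing = [i for i in required if i not in present]
    if missing:
        raise ValueError(f"phantom geometry does not fit the grid (missing ids {missing})")
    return labels


def _intensity_from_labels(
    labels: np.ndarray, scheme: LabelScheme, means: dict, sigma: float, rng
) -> np.ndarray:
    lut = np.zeros(int(labels.max()) + 1, dtype=np.float64)
    for e in scheme.entries:
        if e.label_id <= labels.max():
            lut[e.label_id] = means[e.tissue_class]
    img = lut[labels]
    if sigma > 0:
        img = img + rng.normal(0.0, sigma, size=img.shape)
    return img


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume, LabelScheme]:
    """Build one labeled phantom: geometry, intensities, lesions, noise.

    Deterministic per spec.seed. With ``lesion_count == 0`` and
    ``noise_sigma == 0`` (and an even first grid axis) the phantom is
    exactly mirror-symmetric about the left-right midplane.
    """
    scheme = phantom_scheme(spec)
    labels = _build_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    affine = _phantom_affine(spec.shape)
    image = _intensity_from_labels(labels, scheme, spec.tissue_means, spec.noise_sigma, rng)
    img_vol = ImageVolume(voxels=image, affine=affine)
    lab_vol = LabelVolume(labels=labels, affine=affine, scheme_id="phantom")
    if spec.lesion_count > 0:
        img_vol, lab_vol = insert_lesions(img_vol, lab_vol, spec)
    return img_vol, lab_vol, scheme


def insert_lesions(
    image: ImageVolume, labels: LabelVolume, spec: PhantomSpec
) -> tuple[ImageVolume, LabelVolume]:
    """Place spherical WM lesions strictly inside cerebral WM.

    Lesion voxels get the hemisphere-appropriate WML label and an intensity
    drawn around the WML mean (near cortical GM). Deterministic per
    ``spec.seed``; raises when no admissible centre exists.
    """
    if spec.lesion_count == 0:
        return image, labels
    rng = np.random.default_rng(spec.seed + 104729)
    lab = labels.labels.copy()
    img = np.asarray(image.voxels, dtype=np.float64).copy()
    for hemi_id, wml_id in ((CWM_L, WML_L), (CWM_R, WML_R)):
        for _ in range(spec.lesion_count):
            radius = rng.uniform(*spec.lesion_radius)
            wm = lab == hemi_id
            if not wm.any():
                raise ValueError("no cerebral WM left to host a lesion")
            depth = ndimage.distance_transform_edt(wm)
            candidates = np.argwhere(depth >= radius)
            if len(candidates) == 0:
                raise ValueError("no room for a lesion of the requested radius")
            cx, cy, cz = candidates[rng.integers(len(candidates))]
            xs, ys, zs = np.ogrid[: lab.shape[0], : lab.shape[1], : lab.shape[2]]
            sphere = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= radius**2
            sphere &= wm  # placement contract: lesions carve only cWM
            lab[sphere] = wml_id
            img[sphere] = spec.tissue_means["WML"]
            if spec.noise_sigma > 0:
                img[sphere] += rng.normal(0.0, spec.noise_sigma, size=int(sphere.sum()))
    return (
        ImageVolume(voxels=img, affine=image.affine.copy()),
        LabelVolume(labels=lab, affine=labels.affine.copy(), scheme_id=labels.scheme_id),
    )


def _smooth_displacement(shape, amplitude, smoothness, rng) -> np.ndarray:
    """Smooth random displacement field (3, nx, ny, nz), max norm = amplitude."""
    disp = rng.normal(0.0, 1.0, size=(3,) + tuple(shape))
    for c in range(3):
        disp[c] = ndimage.gaussian_filter(disp[c], sigma=smoothness)
    norms = np.sqrt((disp**2).sum(axis=0))
    peak = norms.max()
    if peak > 0:
        disp *= amplitude / peak
    return disp


def warp_member(
    image: np.ndarray, labels: np.ndarray, disp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Warp intensities (trilinear) and labels (nearest) by a displacement field."""
    grids = np.meshgrid(*[np.arange(s) for s in image.shape], indexing="ij")
    coords = [g + d for g, d in zip(grids, disp)]
    warped_img = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    warped_lab = ndimage.map_coordinates(labels, coords, order=0, mode="nearest")
    return warped_img, warped_lab.astype(labels.dtype)


def make_library(
    spec: PhantomSpec, n_members: int, seed: int | None = None
) -> tuple[AtlasLibrary, LabelScheme]:
    """A library of deformed, jittered, noisy copies of one base phantom.

    The base phantom is built noiseless; each member applies its own smooth
    random warp (labels nearest-neighbour, intensities trilinear), a
    multiplicative intensity jitter, and fresh Gaussian noise. Ground-truth
    labels are retained per member.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    base_seed = spec.seed if seed is None else seed
    base_spec = replace(spec, noise_sigma=0.0, seed=base_seed)
    base_img, base_lab, scheme = make_phantom(base_spec)
    base_ids = set(np.unique(base_lab.labels).tolist())
    affine = base_img.affine
    members = []
    for m in range(n_members):
        rng = np.random.default_rng(base_seed + 1000 + m)
        if spec.deformation_amplitude > 0:
            disp = _smooth_displacement(
                spec.shape, spec.deformation_amplitude, spec.deformation_smoothness, rng
            )
            img, lab = warp_member(base_img.voxels, base_lab.labels, disp)
        else:
            img, lab = base_img.voxels.copy(), base_lab.labels.copy()
        if set(np.unique(lab).tolist()) != base_ids:
            raise ValueError(
                "deformation amplitude too large: structures vanished in member "
                f"{m}"
            )
        scale = 1.0 + spec.intensity_jitter * rng.normal() if spec.intensity_jitter else 1.0
        img = img * scale
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        members.append(
            (
                ImageVolume(voxels=img, affine=affine.copy()),
                LabelVolume(labels=lab, affine=affine.copy(), scheme_id="phantom"),
            )
        )
    return AtlasLibrary(members=members), scheme


def add_noise(image: ImageVolume, sigma: float, seed: int) -> ImageVolume:
    """A fresh Gaussian-noise realization of an intensity volume."""
    rng = np.random.default_rng(seed)
    return ImageVolume(
        voxels=np.asarray(image.voxels, dtype=np.float64) + rng.normal(0.0, sigma, image.shape),
        affine=image.affine.copy(),
    )


def binarized_library(library: AtlasLibrary) -> AtlasLibrary:
    """The same library with labels collapsed to an ICC mask (labels > 0)."""
    members = [
        (
            img,
            LabelVolume(labels=(lab.labels > 0).astype(np.int32), affine=lab.affine, scheme_id="icc"),
        )
        for img, lab in library.members
    ]
    return AtlasLibrary(members=members)


def corrupt_segmentation(
    labels: LabelVolume,
    scheme: LabelScheme,
    mode: str,
    magnitude: float,
    seed: int = 0,
) -> LabelVolume:
    """Inject a deterministic systematic error into a segmentation.

    ``dilate_cGM_into_cWM``: a stated fraction (``magnitude`` in [0, 1]) of
    cWM voxels 6-adjacent to cortical GM are relabeled to the neighbouring
    cGM id — the overestimation bias an error corrector must learn to undo.
    ``shift``: all labels translated by round(magnitude) voxels along the
    second axis, background-filled.
    """
    lab = labels.labels.copy()
    if mode == "dilate_cGM_into_cWM":
        if not 0.0 <= magnitude <= 1.0:
            raise ValueError("magnitude is a fraction in [0, 1] for dilation mode")
        if magnitude == 0.0:
            return LabelVolume(labels=lab, affine=labels.affine.copy(), scheme_id=labels.scheme_id)
        cgm_ids = scheme.ids_of_tissue("cGM")
        cwm_ids = scheme.ids_of_tissue("cWM")
        cgm = np.isin(lab, cgm_ids)
        cwm = np.isin(lab, cwm_ids)
        if not (cgm.any() and cwm.any()):
            raise ValueError("no cGM/cWM interface to corrupt")
        struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        touching = cwm & ndimage.binary_dilation(cgm, structure=struct)
        cand = np.argwhere(touching)
        if len(cand) == 0:
            raise ValueError("no cGM/cWM interface to corrupt")
        rng = np.random.default_rng(seed)
        n_pick = int(round(magnitude * len(cand)))
        picked = cand[rng.choice(len(cand), size=n_pick, replace=False)]
        # each picked voxel takes the label of its first 6-neighbour in cGM
        offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
        for x, y, z in picked:
            for dx, dy, dz in offsets:
                nx_, ny_, nz_ = x + dx, y + dy, z + dz
                if (
                    0 <= nx_ < lab.shape[0]
                    and 0 <= ny_ < lab.shape[1]
                    and 0 <= nz_ < lab.shape[2]
                    and cgm[nx_, ny_, nz_]
                ):
                    lab[x, y, z] = labels.labels[nx_, ny_, nz_]
                    break
    elif mode == "shift":
        delta = int(round(magnitude))
        if delta != 0:
            shifted = np.zeros_like(lab)
            if delta > 0:
                shifted[:, delta:, :] = lab[:, :-delta, :]
            else:
                shifted[:, :delta, :] = lab[:, -delta:, :]
            lab = shifted
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return LabelVolume(labels=lab, affine=labels.affine.copy(), scheme_id=labels.scheme_id)
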