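"""Patch-based Ensemble Corrector (PEC).

Learns the systematic errors of the label-fusion segmenter for one
structure and edits its output. Each sample voxel near the structure's
automatic contour is described by 112 features — a fully sampled 3x3x3
patch and a subsampled 7x7x7 patch (offsets {-3, 0, +3} per axis, 27
samples) from both the T1 intensities and the automatic segmentation, one
distance-map value, and the three template-space world coordinates — and
mapped to the 27-entry binary membership patch of the structure in the
manual labels. Ten shallow networks (112x83x55x27) are trained with a
boosting strategy that upweights samples the running ensemble misclassifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .core_io import ImageVolume, LabelVolume
from .fusion import ProbabilityMaps

FEATURE_LENGTH = 112
HIDDEN_LAYERS = (83, 55)
N_NETWORKS = 10
PATCH_OUT = 27  # 3x3x3 output membership patch

# fully sampled 3^3 offsets and skip-two-subsampled 7^3 offsets (27 each)
_SMALL_OFFSETS = np.array(
    [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)], dtype=np.int64
)
_LARGE_OFFSETS = np.array(
    [(a, b, c) for a in (-3, 0, 3) for b in (-3, 0, 3) for c in (-3, 0, 3)], dtype=np.int64
)


@dataclass
class PECFeatureSpec:
    """Constants of the 112-long feature layout (27+27+27+27+1+3)."""

    small_offsets: np.ndarray = field(default_factory=lambda: _SMALL_OFFSETS.copy())
    large_offsets: np.ndarray = field(default_factory=lambda: _LARGE_OFFSETS.copy())
    length: int = FEATURE_LENGTH


@dataclass
class PECModel:
    """Boosted ensemble of 10 feed-forward 112x83x55x27 networks.

    Each network is stored as raw weight matrices (ReLU hidden layers,
    sigmoid output heads) together with the per-feature normalisation
    statistics, so inference does not depend on the training backend.
    """

    label_id: int
    networks: list  # list of (W1, b1, W2, b2, W3, b3) or ("const", value)
    feature_mean: np.ndarray
    feature_std: np.ndarray
    band: int = 2
    version: str = "densefuse-pec-1"

    def __post_init__(self) -> None:
        if len(self.networks) != N_NETWORKS:
            raise ValueError(f"PEC ensemble must have exactly {N_NETWORKS} members")

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Ensemble-averaged sigmoid membership outputs, shape (n, 27)."""
        x = (np.asarray(features, dtype=np.float64) - self.feature_mean) / self.feature_std
        if x.ndim == 1:
            x = x[None, :]
        out = np.zeros((x.shape[0], PATCH_OUT))
        for net in self.networks:
            out += _forward(net, x)
        return out / len(self.networks)

    def save(self, path: str | Path) -> None:
        arrays = {
            "version": np.array(self.version),
            "label_id": np.array(self.label_id),
            "band": np.array(self.band),
            "feature_mean": self.feature_mean,
            "feature_std": self.feature_std,
            "n_networks": np.array(len(self.networks)),
        }
        for i, net in enumerate(self.networks):
            if isinstance(net[0], str) and net[0] == "const":
                arrays[f"net{i}_const"] = np.array(net[1])
            else:
                for j, w in enumerate(net):
                    arrays[f"net{i}_w{j}"] = w
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PECModel":
        data = np.load(path, allow_pickle=False)
        version = str(data["version"])
        if not version.startswith("densefuse-pec"):
            raise ValueError(f"unrecognised PEC model archive version {version!r}")
        networks = []
        for i in range(int(data["n_networks"])):
            if f"net{i}_const" in data:
                networks.append(("const", float(data[f"net{i}_const"])))
            else:
                networks.append(tuple(data[f"net{i}_w{j}"] for j in range(6)))
        return cls(
            label_id=int(data["label_id"]),
            networks=networks,
            feature_mean=data["feature_mean"],
            feature_std=data["feature_std"],
            band=int(data["band"]),
            version=version,
        )


def _forward(net, x: np.ndarray) -> np.ndarray:
    if isinstance(net[0], str) and net[0] == "const":
        return np.full((x.shape[0], PATCH_OUT), float(net[1]))
    w1, b1, w2, b2, w3, b3 = net
    h = np.maximum(x @ w1 + b1, 0.0)
    h = np.maximum(h @ w2 + b2, 0.0)
    z = h @ w3 + b3
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Distance map and feature extraction
# ---------------------------------------------------------------------------

def distance_map(labels: LabelVolume, label_id: int) -> np.ndarray:
    """Euclidean distance (voxels) to the structure contour, everywhere.

    The contour is the set of structure voxels having at least one
    six-connected neighbour outside the structure; contour voxels map to 0
    and inside/outside are not sign-distinguished.
    """
    mask = labels.labels == label_id
    if not mask.any():
        raise ValueError(f"label {label_id} absent from volume")
    contour = contour_mask(mask)
    return ndimage.distance_transform_edt(~contour)


def contour_mask(mask: np.ndarray) -> np.ndarray:
    """Structure voxels with >= 1 six-connected neighbour outside."""
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=1)
    return mask & ~eroded


def _gather_patches(grid: np.ndarray, voxels: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Patch samples with edge replication at the border; (n_voxels, n_offsets)."""
    shape = grid.shape
    cols = []
    for off in offsets:
        idx = voxels + off
        x = np.clip(idx[:, 0], 0, shape[0] - 1)
        y = np.clip(idx[:, 1], 0, shape[1] - 1)
        z = np.clip(idx[:, 2], 0, shape[2] - 1)
        cols.append(grid[x, y, z])
    return np.stack(cols, axis=1)


def pec_features_batch(
    t1: ImageVolume,
    auto_labels: LabelVolume,
    dmap: np.ndarray,
    voxels: np.ndarray,
    label_id: int,
) -> np.ndarray:
    """112-long feature rows for many voxels at once.

    Fixed concatenation order: T1 3^3, T1 7^3-subsampled, segmentation 3^3,
    segmentation 7^3-subsampled, distance value, world x/y/z. Segmentation
    patches are the binary membership of the corrected structure.
    """
    voxels = np.atleast_2d(np.asarray(voxels, dtype=np.int64))
    img = np.asarray(t1.voxels, dtype=np.float64)
    seg = (auto_labels.labels == label_id).astype(np.float64)
    parts = [
        _gather_patches(img, voxels, _SMALL_OFFSETS),
        _gather_patches(img, voxels, _LARGE_OFFSETS),
        _gather_patches(seg, voxels, _SMALL_OFFSETS),
        _gather_patches(seg, voxels, _LARGE_OFFSETS),
        dmap[voxels[:, 0], voxels[:, 1], voxels[:, 2]][:, None],
    ]
    homog = np.hstack([voxels.astype(np.float64), np.ones((len(voxels), 1))])
    world = homog @ np.asarray(t1.affine, dtype=np.float64).T
    parts.append(world[:, :3])
    feats = np.hstack(parts)
    assert feats.shape[1] == FEATURE_LENGTH
    return feats


def pec_features(
    t1: ImageVolume,
    auto_labels: LabelVolume,
    dmap: np.ndarray,
    voxel,
    label_id: int,
) -> np.ndarray:
    """The 112-long feature vector of a single voxel."""
    return pec_features_batch(t1, auto_labels, dmap, np.asarray(voxel)[None, :], label_id)[0]


def _band_voxels(auto_labels: LabelVolume, label_id: int, band: int) -> np.ndarray:
    """Voxels within ``band`` voxels of the structure's automatic contour."""
    dmap = distance_map(auto_labels, label_id)
    return np.argwhere(dmap <= band), dmap


def _membership_targets(manual_labels: LabelVolume, label_id: int, voxels: np.ndarray) -> np.ndarray:
    member = (manual_labels.labels == label_id).astype(np.float64)
    return _gather_patches(member, voxels, _SMALL_OFFSETS)


# ---------------------------------------------------------------------------
# Training and application
# ---------------------------------------------------------------------------

def pec_train(
    training_set,
    label_id: int,
    n_samples: int = 4000,
    seed: int = 0,
    band: int = 2,
    beta: float = 2.0,
    max_iter: int = 80,
) -> PECModel:
    """Train the boosted 10-network corrector for one structure.

    Samples come from voxels within ``band`` voxels of the automatic
    contour across all training triples. Networks are trained sequentially;
    after each, the selection weight of every sample the running ensemble
    misclassifies (any of the 27 thresholded patch outputs wrong) is
    multiplied by ``1 + beta`` and the distribution renormalised.
    """
    if len(training_set) < 1:
        raise ValueError("training set must contain at least one (t1, auto, manual) triple")
    rng = np.random.default_rng(seed)
    feats, targets = [], []
    for t1, auto, manual in training_set:
        if auto.shape != manual.shape or auto.shape != t1.shape:
            raise ValueError("training triple grids mismatch")
        if not (auto.labels == label_id).any():
            continue
        voxels, dmap = _band_voxels(auto, label_id, band)
        feats.append(pec_features_batch(t1, auto, dmap, voxels, label_id))
        targets.append(_membership_targets(manual, label_id, voxels))
    if not feats:
        raise ValueError(f"label {label_id} absent from every training segmentation")
    X = np.vstack(feats)
    Y = np.vstack(targets)
    if X.shape[0] == 0:
        raise ValueError("empty candidate sample pool")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xn = (X - mean) / std

    degenerate = len(np.unique(Y)) < 2
    if degenerate:
        warnings.warn(
            f"single-class targets for label {label_id}; storing constant corrector",
            stacklevel=2,
        )
        const = float(Y.flat[0])
        networks = [("const", const)] * N_NETWORKS
        return PECModel(label_id=label_id, networks=networks,
                        feature_mean=mean, feature_std=std, band=band)

    n_pool = X.shape[0]
    weights = np.full(n_pool, 1.0 / n_pool)
    networks: list = []
    ensemble_sum = np.zeros_like(Y)
    for i in range(N_NETWORKS):
        take = min(n_samples, n_pool)
        idx = rng.choice(n_pool, size=take, replace=True, p=weights)
        net_seed = int(rng.integers(0, 2**31 - 1))
        clf = MLPClassifier(
            hidden_layer_sizes=HIDDEN_LAYERS,
            max_iter=max_iter,
            random_state=net_seed,
            early_stopping=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xn[idx], Y[idx].astype(int))
        net = (
            clf.coefs_[0], clf.intercepts_[0],
            clf.coefs_[1], clf.intercepts_[1],
            clf.coefs_[2], clf.intercepts_[2],
        )
        networks.append(net)
        ensemble_sum += _forward(net, Xn)
        pred = (ensemble_sum / (i + 1)) > 0.5
        mis = np.any(pred != (Y > 0.5), axis=1)
        weights = weights * np.where(mis, 1.0 + beta, 1.0)
        weights /= weights.sum()
    return PECModel(label_id=label_id, networks=networks,
                    feature_mean=mean, feature_std=std, band=band)


def pec_apply(
    model: PECModel,
    t1: ImageVolume,
    auto_labels: LabelVolume,
    probs: ProbabilityMaps | None = None,
) -> LabelVolume:
    """Correct one structure of an automatic segmentation.

    For every voxel within the contour band, the ensemble's overlapping
    3^3 membership patch predictions are averaged into per-voxel votes;
    band voxels whose averaged membership crosses 0.5 are toggled in or
    out of the structure. Voxels displaced out of the structure receive
    the runner-up fusion label when probability maps are supplied, else
    the nearest other label. Voxels outside the band never change.
    """
    if t1.shape != auto_labels.shape:
        raise ValueError("t1 and segmentation grids mismatch")
    label_id = model.label_id
    if not (auto_labels.labels == label_id).any():
        return LabelVolume(
            labels=auto_labels.labels.copy(), affine=auto_labels.affine.copy(),
            scheme_id=auto_labels.scheme_id,
        )
    voxels, dmap = _band_voxels(auto_labels, label_id, model.band)
    feats = pec_features_batch(t1, auto_labels, dmap, voxels, label_id)
    pred = model.predict(feats)  # (n_band, 27)

    shape = auto_labels.shape
    votes = np.zeros(shape)
    counts = np.zeros(shape)
    for o, off in enumerate(_SMALL_OFFSETS):
        idx = voxels + off
        x = np.clip(idx[:, 0], 0, shape[0] - 1)
        y = np.clip(idx[:, 1], 0, shape[1] - 1)
        z = np.clip(idx[:, 2], 0, shape[2] - 1)
        np.add.at(votes, (x, y, z), pred[:, o])
        np.add.at(counts, (x, y, z), 1.0)

    out = auto_labels.labels.copy()
    band_mask = np.zeros(shape, dtype=bool)
    band_mask[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = True
    decided = band_mask & (counts > 0)
    membership = np.zeros(shape)
    membership[decided] = votes[decided] / counts[decided]

    in_struct = auto_labels.labels == label_id
    to_add = decided & (membership > 0.5) & ~in_struct
    to_remove = decided & (membership < 0.5) & in_struct
    out[to_add] = label_id
    if to_remove.any():
        out[to_remove] = _replacement_labels(auto_labels, to_remove, label_id, probs)
    return LabelVolume(labels=out, affine=auto_labels.affine.copy(),
                       scheme_id=auto_labels.scheme_id)


def _replacement_labels(
    auto_labels: LabelVolume,
    to_remove: np.ndarray,
    label_id: int,
    probs: ProbabilityMaps | None,
) -> np.ndarray:
    """Labels for voxels displaced out of the structure: the runner-up
    fusion label where probability maps are available, else the nearest
    voxel's label outside the structure."""
    if probs is not None:
        order = np.argsort(probs.labels, kind="stable")
        ids = probs.labels[order]
        maps = probs.maps[order][:, to_remove]  # (L, n_remove)
        maps = maps.copy()
        own = np.where(ids == label_id)[0]
        if len(own):
            maps[own[0]] = -1.0
        return ids[np.argmax(maps, axis=0)].astype(auto_labels.labels.dtype)
    other = auto_labels.labels != label_id
    _, (ix, iy, iz) = ndimage.distance_transform_edt(~other, return_indices=True)
    nearest = auto_labels.labels[ix, iy, iz]
    return nearest[to_remove]
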