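import numpy as np
import pytest

from densefuse.core_io import AtlasLibrary, ImageVolume, LabelVolume
from densefuse.fusion import (
    FusionParams,
    ProbabilityMaps,
    argmax_labels,
    build_annf,
    extract_icc,
    fuse_labels_annf,
    fuse_labels_exhaustive,
    fuse_multiscale,
    patch_distance,
    patch_weights,
)
from densefuse.synthdata import PhantomSpec, binarized_library, make_library, make_phantom


def triple_loop_oracle(subject, library, mask, p, radius, h_eps):
    """Independent brute-force implementation of weighted non-local voting."""
    hw = p // 2
    pad = ((hw, hw),) * 3
    sp = np.pad(subject.voxels.astype(float), pad, mode="edge")
    lps = [np.pad(img.voxels.astype(float), pad, mode="edge") for img, _ in library.members]
    labs = [lab.labels for _, lab in library.members]
    ids = sorted(set(np.concatenate([np.unique(l) for l in labs]).tolist()))
    nx, ny, nz = subject.shape
    out = {}
    for ix, iy, iz in np.argwhere(mask):
        cand = []
        for s in range(len(labs)):
            for jx in range(max(0, ix - radius), min(nx - 1, ix + radius) + 1):
                for jy in range(max(0, iy - radius), min(ny - 1, iy + radius) + 1):
                    for jz in range(max(0, iz - radius), min(nz - 1, iz + radius) + 1):
                        d = 0.0
                        for a in range(p):
                            for b in range(p):
                                for c in range(p):
                                    diff = sp[ix + a, iy + b, iz + c] - lps[s][jx + a, jy + b, jz + c]
                                    d += diff * diff
                        cand.append((d / p**3, labs[s][jx, jy, jz]))
        h2 = min(d for d, _ in cand) + h_eps
        weights = {i: 0.0 for i in ids}
        total = 0.0
        for d, lab in cand:
            w = np.exp(-d / h2)
            weights[lab] += w
            total += w
        out[(ix, iy, iz)] = {i: weights[i] / total for i in ids}
    return ids, out


class TestPatchDistance:
    def test_identical_patches_zero(self):
        p = np.random.default_rng(0).normal(size=(3, 3, 3))
        assert patch_distance(p, p) == 0.0

    def test_constant_patches(self):
        assert patch_distance(np.ones((3, 3, 3)), np.zeros((3, 3, 3))) == 1.0

    def test_matches_explicit_summation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 2, 2, 2))
        expected = sum((a.ravel()[i] - b.ravel()[i]) ** 2 for i in range(8)) / 8
        assert patch_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            patch_distance(np.ones((3, 3, 3)), np.ones((5, 5, 5)))


class TestPatchWeights:
    def test_zero_distance_weight_one(self):
        w = patch_weights([0.0, 1.0, 2.0])
        assert w[0] == 1.0

    def test_known_values(self):
        w = patch_weights([0.5, 1.0], h_epsilon=1e-9)
        assert w[0] == pytest.approx(np.exp(-1.0), abs=1e-6)
        assert w[1] == pytest.approx(np.exp(-2.0), abs=1e-6)

    def test_monotone_in_distance(self):
        rng = np.random.default_rng(2)
        d = np.sort(rng.uniform(0, 5, 20))
        w = patch_weights(d)
        assert np.all(np.diff(w) <= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            patch_weights([])


class TestExhaustiveFusion:
    def test_matches_triple_loop_oracle(self, tiny_random_case):
        subject, library, mask = tiny_random_case
        params = FusionParams(patch_sizes=(3, 3), search_radius=1, seed=1)
        probs = fuse_labels_exhaustive(subject, library, mask, 3, params)
        ids, oracle = triple_loop_oracle(subject, library, mask, 3, 1, params.h_epsilon)
        assert list(probs.labels) == ids
        for (ix, iy, iz), expected in oracle.items():
            for li, lab in enumerate(probs.labels):
                assert probs.maps[li, ix, iy, iz] == pytest.approx(
                    expected[int(lab)], abs=1e-12
                )

    def test_self_match_dominance(self):
        # noise makes the zero-distance self match unique, so h^2 -> epsilon
        # collapses every other weight; a noiseless piecewise-constant image
        # would have exact ties across same-intensity structures instead
        spec = PhantomSpec(shape=(24, 24, 24), noise_sigma=2.5, lesion_count=0, seed=5)
        img, lab, _ = make_phantom(spec)
        rng = np.random.default_rng(6)
        distractor = ImageVolume(rng.normal(60, 30, img.shape), img.affine)
        dist_lab = LabelVolume(
            rng.integers(0, 3, img.shape).astype(np.int32), img.affine
        )
        library = AtlasLibrary(members=[(img, lab), (distractor, dist_lab)])
        mask = lab.labels > 0
        params = FusionParams(patch_sizes=(3, 3), search_radius=2, seed=2)
        probs = fuse_labels_exhaustive(img, library, mask, 3, params)
        seg = argmax_labels(probs, affine=img.affine)
        agreement = (seg.labels[mask] == lab.labels[mask]).mean()
        assert agreement >= 0.999

    def test_identical_images_different_labels_split_evenly(self):
        shape = (6, 6, 6)
        rng = np.random.default_rng(7)
        img = rng.normal(size=shape)
        a = LabelVolume(np.ones(shape, dtype=np.int32), np.eye(4))
        b = LabelVolume(np.full(shape, 2, dtype=np.int32), np.eye(4))
        library = AtlasLibrary(
            members=[(ImageVolume(img, np.eye(4)), a), (ImageVolume(img, np.eye(4)), b)]
        )
        mask = np.zeros(shape, dtype=bool)
        mask[3, 3, 3] = True
        params = FusionParams(patch_sizes=(3, 3), search_radius=1, seed=3)
        probs = fuse_labels_exhaustive(ImageVolume(img, np.eye(4)), library, mask, 3, params)
        i1 = list(probs.labels).index(1)
        i2 = list(probs.labels).index(2)
        assert probs.maps[i1, 3, 3, 3] == pytest.approx(0.5, abs=1e-12)
        assert probs.maps[i2, 3, 3, 3] == pytest.approx(0.5, abs=1e-12)


class TestANNF:
    def test_small_window_equals_exhaustive_best_k(self, tiny_random_case):
        subject, library, mask = tiny_random_case
        pool = 27 * library.N  # radius-1 window across both members
        params = FusionParams(patch_sizes=(3, 3), search_radius=1, annf_k=pool, seed=4)
        field = build_annf(subject, library, mask, 3, params)
        assert field.count.min() > 0
        probs_annf = fuse_labels_annf(subject, library, field, 3, params, "center")
        probs_ex = fuse_labels_exhaustive(subject, library, mask, 3, params)
        np.testing.assert_allclose(probs_annf.maps, probs_ex.maps, atol=1e-12)

    def test_same_seed_identical_field(self, small_phantom):
        img, lab, _, _ = small_phantom
        library, _ = make_library(PhantomSpec(shape=(32, 32, 32), seed=9), 3, seed=13)
        mask = lab.labels > 0
        params = FusionParams(seed=5)
        f1 = build_annf(img, library, mask, 3, params)
        f2 = build_annf(img, library, mask, 3, params)
        np.testing.assert_array_equal(f1.subject_index, f2.subject_index)
        np.testing.assert_array_equal(f1.cand_x, f2.cand_x)
        np.testing.assert_array_equal(f1.distance, f2.distance)

    def test_mean_best_distance_non_increasing(self, small_phantom):
        img, lab, _, _ = small_phantom
        library, _ = make_library(PhantomSpec(shape=(32, 32, 32), seed=9), 3, seed=13)
        mask = lab.labels > 0
        field = build_annf(img, library, mask, 3, FusionParams(seed=6))
        diffs = np.diff(field.mean_best_per_iteration)
        assert np.all(diffs <= 1e-12)

    def test_k_exceeding_pool_rejected(self, tiny_random_case):
        subject, library, mask = tiny_random_case
        params = FusionParams(patch_sizes=(3, 3), search_radius=1, annf_k=55, seed=1)
        with pytest.raises(ValueError, match="candidate pool"):
            build_annf(subject, library, mask, 3, params)

    def test_unanimous_candidates_give_probability_one(self):
        shape = (8, 8, 8)
        rng = np.random.default_rng(8)
        img = rng.normal(size=shape)
        one_label = LabelVolume(np.full(shape, 4, dtype=np.int32), np.eye(4))
        library = AtlasLibrary(members=[(ImageVolume(img, np.eye(4)), one_label)])
        subject = ImageVolume(img, np.eye(4))
        mask = np.zeros(shape, dtype=bool)
        mask[3:5, 3:5, 3:5] = True
        params = FusionParams(patch_sizes=(3, 3), search_radius=1, annf_k=8, seed=9)
        field = build_annf(subject, library, mask, 3, params)
        probs = fuse_labels_annf(subject, library, field, 3, params)
        idx = list(probs.labels).index(4)
        assert np.allclose(probs.maps[idx][mask], 1.0)


class TestMultiscaleMixing:
    def _pair(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        labels = np.array([1, 2])
        rng = np.random.default_rng(10)
        m1 = np.zeros((2, 4, 4, 4))
        m2 = np.zeros((2, 4, 4, 4))
        r1 = rng.uniform(0, 1, mask.sum())
        r2 = rng.uniform(0, 1, mask.sum())
        m1[0][mask], m1[1][mask] = r1, 1 - r1
        m2[0][mask], m2[1][mask] = r2, 1 - r2
        return (
            ProbabilityMaps(labels, m1, mask),
            ProbabilityMaps(labels, m2, mask),
        )

    def test_endpoints_reproduce_inputs_exactly(self):
        p1, p2 = self._pair()
        np.testing.assert_array_equal(fuse_multiscale(p1, p2, 1.0).maps, p1.maps)
        np.testing.assert_array_equal(fuse_multiscale(p1, p2, 0.0).maps, p2.maps)

    def test_midpoint_arithmetic(self):
        p1, p2 = self._pair()
        p1.maps[0, 1, 1, 1], p1.maps[1, 1, 1, 1] = 0.2, 0.8
        p2.maps[0, 1, 1, 1], p2.maps[1, 1, 1, 1] = 0.6, 0.4
        mixed = fuse_multiscale(p1, p2, 0.5)
        assert mixed.maps[0, 1, 1, 1] == pytest.approx(0.4)
        mixed.check_normalized()

    def test_label_set_mismatch_rejected(self):
        p1, p2 = self._pair()
        p2.labels = np.array([1, 3])
        with pytest.raises(ValueError, match="label"):
            fuse_multiscale(p1, p2, 0.5)


class TestArgmax:
    def test_certain_label_wins(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        maps = np.zeros((2, 2, 2, 2))
        maps[1] = 1.0
        seg = argmax_labels(ProbabilityMaps(np.array([3, 7]), maps, mask))
        assert np.all(seg.labels == 7)

    def test_tie_breaks_to_lowest_id(self):
        mask = np.ones((1, 1, 1), dtype=bool)
        maps = np.full((2, 1, 1, 1), 0.5)
        seg = argmax_labels(ProbabilityMaps(np.array([44, 45]), maps, mask))
        assert seg.labels[0, 0, 0] == 44

    def test_matches_per_voxel_scan(self):
        rng = np.random.default_rng(11)
        mask = rng.uniform(size=(5, 5, 5)) > 0.3
        maps = rng.uniform(size=(4, 5, 5, 5))
        maps /= maps.sum(axis=0)
        labels = np.array([2, 5, 9, 11])
        seg = argmax_labels(ProbabilityMaps(labels, maps, mask))
        for ix, iy, iz in np.argwhere(mask):
            best = labels[np.argmax(maps[:, ix, iy, iz])]
            assert seg.labels[ix, iy, iz] == best
        assert np.all(seg.labels[~mask] == 0)


class TestICCExtraction:
    def test_phantom_icc_recovered(self, loo_segmentation):
        result, _, truth, _, _ = loo_segmentation
        true_icc = truth.labels > 0
        inter = (result.icc_mask & true_icc).sum()
        d = 2 * inter / (result.icc_mask.sum() + true_icc.sum())
        assert d >= 0.95

    def test_self_member_dominates(self):
        spec = PhantomSpec(shape=(24, 24, 24), noise_sigma=0.0, lesion_count=0, seed=5)
        img, lab, _ = make_phantom(spec)
        rng = np.random.default_rng(12)
        library = AtlasLibrary(
            members=[
                (img, LabelVolume((lab.labels > 0).astype(np.int32), img.affine)),
                (
                    ImageVolume(rng.normal(60, 30, img.shape), img.affine),
                    LabelVolume(
                        (rng.uniform(size=img.shape) > 0.5).astype(np.int32), img.affine
                    ),
                ),
            ]
        )
        mask = extract_icc(img, library, FusionParams(seed=3))
        agreement = (mask == (lab.labels > 0)).mean()
        assert agreement >= 0.999

    def test_non_binary_library_rejected(self, small_phantom):
        img, lab, _, _ = small_phantom
        library = AtlasLibrary(members=[(img, lab)])
        with pytest.raises(ValueError, match="binary"):
            extract_icc(img, library, FusionParams(seed=1))


class TestNormalization:
    def test_all_fusion_outputs_normalised(self, loo_segmentation):
        result, *_ = loo_segmentation
        result.probabilities.check_normalized(tol=1e-6)


def test_probability_stack_round_trip(tmp_path, tiny_random_case):
    import nibabel as nib
    import pandas as pd

    from densefuse.fusion import write_probability_maps

    subject, library, mask = tiny_random_case
    params = FusionParams(patch_sizes=(3, 3), search_radius=1, seed=1)
    probs = fuse_labels_exhaustive(subject, library, mask, 3, params)
    path = tmp_path / "probs.nii.gz"
    write_probability_maps(probs, path, affine=subject.affine)
    stack = np.asarray(nib.load(str(path)).dataobj)
    assert stack.shape == subject.shape + (len(probs.labels),)
    np.testing.assert_allclose(np.moveaxis(stack, -1, 0), probs.maps, atol=1e-6)
    sidecar = pd.read_csv(tmp_path / "probs_labels.csv")
    assert sidecar.label_id.tolist() == list(probs.labels)
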