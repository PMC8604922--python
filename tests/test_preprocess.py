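"""Entropy selection, resizing and standardization contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sliceleak.errors import DegenerateInputError, InputError
from sliceleak.preprocess import (
    PreprocessConfig,
    SliceRecord,
    VoxelwiseStandardizer,
    preprocess_cohort,
    resize_slice,
    select_top_slices,
    shannon_entropy,
    standardize,
)
from sliceleak.synthetic import VolumeRecord


def entropy_oracle(probabilities) -> float:
    """Independent closed-form -sum p log2 p used to freeze expected values."""
    return -sum(p * math.log2(p) for p in probabilities if p > 0)


class TestShannonEntropy:
    def test_constant_slice_is_zero_bits(self):
        assert shannon_entropy(np.full((8, 8), 3.7)) == 0.0

    def test_two_equiprobable_bins_is_one_bit(self):
        slice_ = np.array([[0.0, 1.0]] * 8)
        assert shannon_entropy(slice_) == pytest.approx(1.0)

    def test_half_quarter_eighth_eighth_is_1_75_bits(self):
        # bin probabilities (1/2, 1/4, 1/8, 1/8); oracle gives 1.75
        values = [0.0] * 4 + [0.3] * 2 + [0.6] + [0.9]
        slice_ = np.array(values).reshape(2, 4)
        expected = entropy_oracle([0.5, 0.25, 0.125, 0.125])
        assert expected == 1.75
        assert shannon_entropy(slice_) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        data=st.lists(st.floats(-100, 100), min_size=4, max_size=64),
        bins=st.sampled_from([2, 16, 256]),
    )
    def test_entropy_within_bounds(self, data, bins):
        n = len(data)
        slice_ = np.array(data).reshape(1, n)
        config = PreprocessConfig(n_gray_bins=bins)
        h = shannon_entropy(slice_, config)
        assert 0.0 <= h <= math.log2(bins) + 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_entropy_invariant_under_pixel_permutation(self, seed):
        rng = np.random.default_rng(seed)
        slice_ = rng.uniform(size=(6, 7))
        shuffled = rng.permutation(slice_.ravel()).reshape(7, 6)
        assert shannon_entropy(slice_) == pytest.approx(shannon_entropy(shuffled))

    @settings(derandomize=True, max_examples=40)
    @given(
        counts=st.lists(st.integers(1, 20), min_size=2, max_size=8),
        merge=st.integers(0, 10_000),
    )
    def test_merging_two_occupied_bins_never_increases_entropy(self, counts, merge):
        # pixels at bin centers; merging bin i into bin j re-labels pixels
        k = len(counts)
        i, j = merge % k, (merge // k) % k
        if i == j:
            j = (i + 1) % k
        config = PreprocessConfig(n_gray_bins=k)
        centers = (np.arange(k) + 0.5) / k
        pixels = np.repeat(centers, counts)
        merged = pixels.copy()
        merged[merged == centers[i]] = centers[j]
        rng = (0.0, 1.0)
        before = shannon_entropy(pixels.reshape(1, -1), config, value_range=rng)
        after = shannon_entropy(merged.reshape(1, -1), config, value_range=rng)
        assert after <= before + 1e-12
        # cross-check against the closed-form oracle
        p = np.array(counts) / sum(counts)
        assert before == pytest.approx(entropy_oracle(p))

    def test_within_mask_domain_requires_nonempty_mask(self):
        config = PreprocessConfig(entropy_domain="within_mask")
        with pytest.raises(InputError):
            shannon_entropy(np.ones((4, 4)), config, mask=np.zeros((4, 4), bool))

    def test_within_mask_domain_ignores_background(self):
        config = PreprocessConfig(entropy_domain="within_mask")
        slice_ = np.zeros((4, 4))
        slice_[0, :2] = [1.0, 2.0]
        mask = np.zeros((4, 4), bool)
        mask[0, :2] = True
        # only two in-mask pixels, one per bin edge -> 1 bit
        assert shannon_entropy(slice_, config, mask=mask) == pytest.approx(1.0)

    def test_non_finite_slice_rejected(self):
        bad = np.ones((3, 3))
        bad[1, 1] = np.inf
        with pytest.raises(InputError):
            shannon_entropy(bad)


def volume_with_increasing_entropy(n_slices=12, size=16) -> VolumeRecord:
    """Slice i holds i+2 equiprobable gray levels, so entropy rises with i."""
    rng = np.random.default_rng(0)
    voxels = np.zeros((n_slices, size, size))
    levels = np.linspace(0.0, 1.0, n_slices + 2)
    for i in range(n_slices):
        vals = np.repeat(levels[: i + 2], size * size // (i + 2) + 1)[: size * size]
        voxels[i] = rng.permutation(vals).reshape(size, size)
    return VolumeRecord(
        subject_id="inc", label=1, voxels=voxels,
        mask=np.ones_like(voxels, dtype=bool),
    )


class TestSelectTopSlices:
    def test_returns_top_entropy_slices_in_descending_order(self):
        volume = volume_with_increasing_entropy()
        config = PreprocessConfig(n_selected_slices=8)
        records = select_top_slices(volume, config)
        # brute-force oracle: rank all slices by independently computed entropy
        domain_range = (float(volume.voxels.min()), float(volume.voxels.max()))
        all_entropies = [
            shannon_entropy(volume.voxels[i], config, value_range=domain_range)
            for i in range(volume.n_slices)
        ]
        expected = sorted(range(12), key=lambda i: (-all_entropies[i], i))[:8]
        assert [r.slice_index for r in records] == expected
        ent = [r.entropy_bits for r in records]
        assert ent == sorted(ent, reverse=True)
        assert all(r.subject_id == "inc" and r.label == 1 for r in records)

    def test_single_slice_selection_is_argmax(self):
        volume = volume_with_increasing_entropy()
        config = PreprocessConfig(n_selected_slices=1)
        (record,) = select_top_slices(volume, config)
        assert record.slice_index == 11

    def test_identical_slices_tie_break_by_ascending_index(self):
        rng = np.random.default_rng(3)
        one = rng.uniform(size=(16, 16))
        voxels = np.stack([one] * 10)
        volume = VolumeRecord(
            subject_id="tie", label=0, voxels=voxels,
            mask=np.ones_like(voxels, dtype=bool),
        )
        records = select_top_slices(volume, PreprocessConfig(n_selected_slices=8))
        assert [r.slice_index for r in records] == list(range(8))

    def test_short_volume_rejected_with_counts(self):
        voxels = np.random.default_rng(0).uniform(size=(4, 8, 8))
        volume = VolumeRecord(
            subject_id="short", label=0, voxels=voxels,
            mask=np.ones_like(voxels, dtype=bool),
        )
        with pytest.raises(InputError, match="4 slices.*8"):
            select_top_slices(volume, PreprocessConfig(n_selected_slices=8))


class TestResizeSlice:
    def test_same_size_is_identity(self):
        slice_ = np.random.default_rng(0).uniform(size=(9, 11))
        assert np.array_equal(resize_slice(slice_, (9, 11)), slice_)

    @pytest.mark.parametrize("target", [(4, 4), (16, 16), (7, 13)])
    def test_constant_preserved_at_any_size(self, target):
        out = resize_slice(np.full((10, 10), 2.5), target)
        assert out.shape == target
        assert np.allclose(out, 2.5)

    def test_bicubic_reproduces_quadratic_ramp_where_bilinear_does_not(self):
        # cubic splines have quadratic precision; the closed form is the oracle
        def f(u, v):
            return 0.03 * u**2 + 0.02 * v**2 + 0.05 * u * v + 0.1 * u - 0.2 * v

        n, (th, tw) = 64, (96, 96)
        src = f(*np.meshgrid(np.arange(float(n)), np.arange(float(n)), indexing="ij"))
        rows = (np.arange(th) + 0.5) * (n / th) - 0.5
        cols = (np.arange(tw) + 0.5) * (n / tw) - 0.5
        expected = f(*np.meshgrid(rows, cols, indexing="ij"))
        # mirror-boundary spline prefilter error decays geometrically from the
        # edges, so quadratic precision holds in the interior
        interior = np.s_[20:-20, 20:-20]
        cubic = resize_slice(src, (th, tw))
        assert np.max(np.abs(cubic[interior] - expected[interior])) < 1e-6
        bilinear = resize_slice(src, (th, tw), order=1)
        assert np.max(np.abs(bilinear[interior] - expected[interior])) > 1e-4

    def test_zero_size_rejected(self):
        with pytest.raises(InputError):
            resize_slice(np.ones((4, 4)), (0, 4))
        with pytest.raises(InputError):
            resize_slice(np.empty((0, 4)), (4, 4))


def random_records(n=4, shape=(6, 6), seed=0, with_mask=True):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        mask = None
        if with_mask:
            mask = np.zeros(shape, bool)
            mask[1:-1, 1:-1] = True
        out.append(
            SliceRecord(
                subject_id=f"s{i}", label=i % 2,
                pixels=rng.standard_normal(shape) * (i + 1) + i,
                slice_index=i, entropy_bits=1.0, mask=mask,
            )
        )
    return out


class TestStandardize:
    def test_per_image_gives_inmask_zero_mean_unit_sd(self):
        out = standardize(random_records())
        for rec in out:
            vals = rec.pixels[rec.mask]
            assert vals.mean() == pytest.approx(0.0, abs=1e-12)
            assert vals.std() == pytest.approx(1.0)

    def test_per_image_is_idempotent(self):
        once = standardize(random_records())
        twice = standardize(once)
        for a, b in zip(once, twice):
            assert np.allclose(a.pixels, b.pixels)

    def test_per_image_zero_sd_rejected(self):
        records = random_records(n=1)
        records[0].pixels = np.full_like(records[0].pixels, 5.0)
        with pytest.raises(DegenerateInputError, match="s0"):
            standardize(records)

    def test_per_voxel_scope_fits_on_training_subset_only(self):
        config = PreprocessConfig(
            standardization_scope="per_voxel_across_training_set"
        )
        records = random_records(n=6, seed=4)
        train_idx = [0, 1, 2]
        out = standardize(records, config, fit_on=train_idx)
        train_stack = np.stack([out[i].pixels for i in train_idx])
        assert np.allclose(train_stack.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(train_stack.std(axis=0), 1.0)
        test_stack = np.stack([out[i].pixels for i in [3, 4, 5]])
        assert not np.allclose(test_stack.mean(axis=0), 0.0, atol=1e-3)

    def test_per_voxel_zero_sd_names_position(self):
        records = random_records(n=3, seed=4)
        for r in records:
            r.pixels[2, 3] = 7.0
        with pytest.raises(DegenerateInputError, match=r"\(2, 3\)"):
            VoxelwiseStandardizer().fit(records)


def test_preprocess_cohort_yields_eight_resized_slices_per_subject(tiny_cohort):
    config = PreprocessConfig(target_size=(16, 16))
    slices = preprocess_cohort(tiny_cohort, config)
    assert len(slices) == len(tiny_cohort) * 8
    for rec in slices:
        assert rec.pixels.shape == (16, 16)
        vals = rec.pixels[rec.mask] if rec.mask is not None else rec.pixels
        assert vals.mean() == pytest.approx(0.0, abs=1e-10)


def test_slice_manifest_round_trip(tmp_path, tiny_cohort):
    from sliceleak.preprocess import load_slices, save_slices

    config = PreprocessConfig(target_size=(16, 16))
    slices = preprocess_cohort(tiny_cohort[:3], config)
    manifest = save_slices(slices, tmp_path)
    loaded = load_slices(manifest)
    assert len(loaded) == len(slices)
    for orig, back in zip(slices, loaded):
        assert back.subject_id == orig.subject_id
        assert back.label == orig.label
        assert back.slice_index == orig.slice_index
        assert back.entropy_bits == orig.entropy_bits
        assert np.array_equal(back.pixels, orig.pixels)
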