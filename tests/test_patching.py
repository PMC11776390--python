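"""Patch extraction, the 5% foreground rule, 75/25 split, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dixonseg.errors import PatchingError
from dixonseg.mri_io import DixonVolume, LabelVolume
from dixonseg.patching import (
    axis_origins,
    extract_patches,
    filter_foreground,
    one_hot_labels,
    reconstruct,
    split_train_val,
)


def _make_volume(labels_arr):
    shape = labels_arr.shape
    rng = np.random.default_rng(0)
    arrs = [rng.random(shape) for _ in range(4)]
    vol = DixonVolume(*arrs)
    return vol, LabelVolume(labels_arr.astype(np.int16))


class TestOrigins:
    def test_single_patch_when_cube_equals_grid(self, rng):
        vol, labels = _make_volume((rng.random((16, 16, 16)) < 0.5).astype(int))
        ps = extract_patches(vol, labels, cube=16, stride=16)
        assert len(ps) == 1 and ps.patches[0].origin == (0, 0, 0)

    def test_non_overlapping_tiling_count(self, rng):
        vol, labels = _make_volume(np.zeros((64, 64, 64), dtype=int))
        ps = extract_patches(vol, labels, cube=32, stride=32)
        assert len(ps) == 8

    @given(
        extent=st.integers(8, 40),
        cube=st.integers(4, 16),
        stride=st.integers(1, 16),
    )
    @settings(max_examples=60, deadline=None)
    def test_axis_origins_match_brute_force(self, extent, cube, stride):
        """Origins = regular grid plus a clamped final origin touching the
        boundary, checked against direct enumeration."""
        if cube > extent or stride > cube:
            return
        got = axis_origins(extent, cube, stride)
        expected = []
        o = 0
        while o + cube <= extent:
            expected.append(o)
            o += stride
        if expected[-1] != extent - cube:
            expected.append(extent - cube)
        assert got == expected
        # full coverage and in-bounds
        assert got[0] == 0 and got[-1] == extent - cube
        assert all(0 <= x <= extent - cube for x in got)

    def test_origin_grid_matches_nested_loop_oracle(self, rng):
        vol, labels = _make_volume(np.zeros((64, 64, 48), dtype=int))
        ps = extract_patches(vol, labels, cube=32, stride=16)
        expected = [
            (ox, oy, oz)
            for ox in axis_origins(64, 32, 16)
            for oy in axis_origins(64, 32, 16)
            for oz in axis_origins(48, 32, 16)
        ]
        assert [p.origin for p in ps.patches] == expected

    def test_cube_larger_than_volume_rejected(self, rng):
        vol, labels = _make_volume(np.zeros((16, 16, 8), dtype=int))
        with pytest.raises(PatchingError):
            extract_patches(vol, labels, cube=16, stride=8)


class TestForegroundFilter:
    def test_all_background_retains_nothing(self):
        vol, labels = _make_volume(np.zeros((16, 16, 16), dtype=int))
        ps = extract_patches(vol, labels, cube=8, stride=8)
        assert len(filter_foreground(ps)) == 0

    def test_exact_five_percent_boundary_is_retained(self):
        arr = np.zeros((20, 20, 20), dtype=int)
        n_fg = int(round(0.05 * 20**3))  # exactly 5% of the single patch
        arr.ravel()[:n_fg] = 1
        vol, labels = _make_volume(arr)
        ps = extract_patches(vol, labels, cube=20, stride=20)
        assert ps.patches[0].foreground_fraction == pytest.approx(0.05)
        assert len(filter_foreground(ps, 0.05)) == 1

    def test_just_below_threshold_is_dropped(self):
        arr = np.zeros((20, 20, 20), dtype=int)
        arr.ravel()[: int(round(0.05 * 20**3)) - 1] = 1
        vol, labels = _make_volume(arr)
        ps = extract_patches(vol, labels, cube=20, stride=20)
        assert len(filter_foreground(ps, 0.05)) == 0

    def test_retained_set_equals_voxel_count_oracle(self, phantom_pair):
        vol, labels = phantom_pair
        ps = extract_patches(vol, labels, cube=32, stride=16)
        got = {p.origin for p in filter_foreground(ps, 0.05).patches}
        expected = set()
        for p in ps.patches:
            ox, oy, oz = p.origin
            block = labels.labels[ox : ox + 32, oy : oy + 32, oz : oz + 32]
            if np.count_nonzero(block) / block.size >= 0.05:
                expected.add(p.origin)
        assert got == expected

    def test_idempotent_and_monotone(self, phantom_pair):
        vol, labels = phantom_pair
        ps = extract_patches(vol, labels, cube=32, stride=16)
        once = filter_foreground(ps, 0.05)
        twice = filter_foreground(once, 0.05)
        assert [p.origin for p in once] == [p.origin for p in twice]
        sizes = [len(filter_foreground(ps, f)) for f in (0.01, 0.05, 0.2, 0.5)]
        assert sizes == sorted(sizes, reverse=True)

    def test_requires_labels(self, phantom_pair):
        vol, _ = phantom_pair
        ps = extract_patches(vol, None, cube=32, stride=16)
        with pytest.raises(PatchingError, match="labels"):
            filter_foreground(ps)


class TestSplit:
    def _patchset(self, n):
        arr = np.ones((8, 8, 8 * n), dtype=int)
        vol, labels = _make_volume(arr)
        return extract_patches(vol, labels, cube=8, stride=8)

    def test_100_patches_split_75_25(self):
        ps = self._patchset(100)
        assert len(ps) == 100
        out = split_train_val(ps, 0.75, seed=1)
        assert len(out.subset("train")) == 75
        assert len(out.subset("val")) == 25

    def test_four_patches_split_3_1(self):
        out = split_train_val(self._patchset(4), 0.75, seed=1)
        assert len(out.subset("train")) == 3 and len(out.subset("val")) == 1

    def test_deterministic_per_seed_and_varies_across_seeds(self):
        ps = self._patchset(40)
        a = split_train_val(ps, seed=5)
        b = split_train_val(ps, seed=5)
        assert [p.split for p in a] == [p.split for p in b]
        assignments = {tuple(p.split for p in split_train_val(ps, seed=s)) for s in range(20)}
        assert len(assignments) > 1

    def test_too_few_patches_rejected(self):
        with pytest.raises(PatchingError):
            split_train_val(self._patchset(1))


class TestReconstruct:
    def test_one_hot_round_trip_covered_voxels(self, phantom_pair):
        vol, labels = phantom_pair
        ps = extract_patches(vol, labels, cube=32, stride=16)
        preds = [one_hot_labels(p.label_data) for p in ps.patches]
        rec = reconstruct(preds, ps)
        np.testing.assert_array_equal(rec.labels, labels.labels)

    def test_mean_vote_arithmetic(self):
        """Two overlapping votes (0.6,0.4) and (0.2,0.8) average to (0.4,0.6)
        -> class 1."""
        vol, labels = _make_volume(np.ones((8, 8, 8), dtype=int))
        ps = extract_patches(vol, labels, cube=8, stride=8)
        ps.patches = [ps.patches[0], ps.patches[0]]  # identical origins
        a = np.zeros((4, 8, 8, 8)); a[0], a[1] = 0.6, 0.4
        b = np.zeros((4, 8, 8, 8)); b[0], b[1] = 0.2, 0.8
        rec = reconstruct([a, b], ps)
        assert (rec.labels == 1).all()

    def test_tie_breaks_toward_lowest_class(self):
        vol, labels = _make_volume(np.zeros((8, 8, 8), dtype=int))
        ps = extract_patches(vol, labels, cube=8, stride=8)
        scores = np.zeros((4, 8, 8, 8))
        scores[1], scores[2] = 0.5, 0.5
        rec = reconstruct([scores], ps)
        assert (rec.labels == 1).all()

    def test_uncovered_voxels_default_to_background(self):
        vol, labels = _make_volume(np.ones((16, 16, 16), dtype=int))
        ps = extract_patches(vol, labels, cube=8, stride=8)
        kept = [p for p in ps.patches if p.origin == (0, 0, 0)]
        import dataclasses

        sub = dataclasses.replace(ps, patches=kept)
        scores = np.zeros((4, 8, 8, 8)); scores[1] = 1.0
        rec = reconstruct(scores[None].repeat(1, axis=0), sub)
        assert (rec.labels[:8, :8, :8] == 1).all()
        assert (rec.labels[8:] == 0).all()

    def test_matches_dense_accumulation_oracle(self, rng):
        """Random scores with overlapping patches reproduce a brute-force
        per-voxel sum/count accumulation."""
        vol, labels = _make_volume(np.ones((24, 24, 16), dtype=int))
        ps = extract_patches(vol, labels, cube=8, stride=4)
        preds = [rng.random((4, 8, 8, 8)) for _ in ps.patches]
        rec = reconstruct(preds, ps)
        sums = np.zeros((4, 24, 24, 16))
        count = np.zeros((24, 24, 16))
        for pred, patch in zip(preds, ps.patches):
            ox, oy, oz = patch.origin
            sums[:, ox : ox + 8, oy : oy + 8, oz : oz + 8] += pred
            count[ox : ox + 8, oy : oy + 8, oz : oz + 8] += 1
        assert (count > 0).all()
        expected = np.argmax(sums / count[None], axis=0)
        np.testing.assert_array_equal(rec.labels, expected)

    def test_coverage_of_all_voxels_before_filtering(self, phantom_pair):
        vol, labels = phantom_pair
        ps = extract_patches(vol, labels, cube=32, stride=16)
        covered = np.zeros(vol.shape, dtype=bool)
        for p in ps.patches:
            ox, oy, oz = p.origin
            covered[ox : ox + 32, oy : oy + 32, oz : oz + 32] = True
        assert covered.all()

    def test_prediction_count_mismatch_rejected(self, phantom_pair):
        vol, labels = phantom_pair
        ps = extract_patches(vol, labels, cube=32, stride=16)
        with pytest.raises(PatchingError):
            reconstruct([np.zeros((4, 32, 32, 32))], ps)
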