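"""Expansion, registration, differencing and pairing contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronomid.imaging_io import DatasetIndex, SliceRecord
from chronomid.preprocess import (
    ABSOLUTE,
    RELATIVE,
    CanvasSpec,
    Translation,
    apply_translation,
    build_samples,
    difference_map,
    estimate_translation,
    expand,
    initial_fill,
    load_samples,
    max_dims,
    pair_slices,
    save_samples,
    select_reference_week,
)
from chronomid.synthdata import SynthConfig, generate_phantom_slice


def rec(pixels, week=0, k=0, mouse="m0"):
    return SliceRecord(mouse_id=mouse, week=week, slice_index=k, label="wild",
                       pixels=np.asarray(pixels))


class TestMaxDims:
    def test_maxima_over_mixed_dims(self):
        idx = DatasetIndex([
            rec(np.zeros((400, 763)), week=0),
            rec(np.zeros((501, 500)), week=1),
        ])
        assert max_dims(idx) == CanvasSpec(501, 763)

    def test_singleton(self):
        idx = DatasetIndex([rec(np.zeros((10, 20)))])
        assert max_dims(idx) == CanvasSpec(10, 20)

    def test_empty_index_rejected(self):
        with pytest.raises(ValueError):
            max_dims(DatasetIndex())


class TestExpand:
    def test_padding_uses_image_minimum_and_centres(self):
        out = expand(rec([[5, 3], [2, 8]]), CanvasSpec(4, 4)).pixels
        assert out.shape == (4, 4)
        assert np.array_equal(out[1:3, 1:3], [[5, 3], [2, 8]])
        border = out.copy()
        border[1:3, 1:3] = 2
        assert np.all(border == 2)

    def test_canvas_sized_image_unchanged(self):
        px = np.arange(12).reshape(3, 4)
        out = expand(rec(px), CanvasSpec(3, 4))
        assert np.array_equal(out.pixels, px)

    def test_odd_remainder_pads_bottom_right(self):
        px = np.full((3, 3), 9)
        out = expand(rec(px), CanvasSpec(4, 4)).pixels
        assert np.array_equal(out[0:3, 0:3], px)  # top-left anchored
        assert np.all(out[3, :] == 9) and np.all(out[:, 3] == 9)

    def test_too_large_rejected(self):
        with pytest.raises(ValueError):
            expand(rec(np.zeros((5, 5))), CanvasSpec(4, 4))

    @given(
        h=st.integers(1, 6), w=st.integers(1, 6),
        th=st.integers(6, 9), tw=st.integers(6, 9),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=40, deadline=None)
    def test_original_survives_as_subgrid(self, h, w, th, tw, seed):
        px = np.random.default_rng(seed).integers(0, 200, (h, w))
        out = expand(rec(px), CanvasSpec(th, tw)).pixels
        top, left = (th - h) // 2, (tw - w) // 2
        assert np.array_equal(out[top : top + h, left : left + w], px)


def exhaustive_best_shift(ref, comp, max_shift=6):
    """Independent oracle: search all integer shifts, scoring the overlap
    product of min-subtracted images, with the package tie-break."""
    a = (ref - ref.min()).astype(float)
    b = (comp - comp.min()).astype(float)
    h, w = a.shape
    best, best_score = None, -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            shifted = np.zeros_like(a)
            ys = slice(max(0, dy), h + min(0, dy))
            xs = slice(max(0, dx), w + min(0, dx))
            ys_s = slice(max(0, -dy), h + min(0, -dy))
            xs_s = slice(max(0, -dx), w + min(0, -dx))
            shifted[ys, xs] = a[ys_s, xs_s]
            score = float((shifted * b).sum())
            key = (abs(dy) + abs(dx), dy, dx)
            if score > best_score + 1e-9 or (
                abs(score - best_score) <= 1e-9 and key < best_key
            ):
                best, best_score, best_key = (dy, dx), score, key
    return best


class TestEstimateTranslation:
    @pytest.mark.parametrize("dy,dx", [(3, -2), (0, 0), (-5, 5), (1, 4), (-4, -4)])
    def test_exact_recovery_of_integer_shifts(self, dy, dx):
        cfg = SynthConfig(noise_sd=0.0, jitter_max=0, height_range=(48, 48),
                         width_range=(48, 48), seed=3)
        base = generate_phantom_slice(cfg, "wild_00", 0, 0)
        shifted = apply_translation(base, Translation(dy, dx))
        shifted = SliceRecord(mouse_id="m0", week=1, slice_index=0, label="wild",
                              pixels=shifted.pixels)
        t = estimate_translation(base, shifted)
        assert (t.dy, t.dx) == (dy, dx)
        assert (t.dy, t.dx) == exhaustive_best_shift(base.pixels, shifted.pixels)

    def test_identical_images_give_zero_shift(self):
        cfg = SynthConfig(noise_sd=0.0, jitter_max=0, seed=3)
        base = generate_phantom_slice(cfg, "wild_00", 0, 0)
        t = estimate_translation(base, base)
        assert (t.dy, t.dx) == (0, 0)

    def test_constant_images_tie_break_to_zero(self):
        a = rec(np.full((8, 8), 7))
        b = rec(np.full((8, 8), 7), week=1)
        t = estimate_translation(a, b)
        assert (t.dy, t.dx) == (0, 0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_translation(rec(np.zeros((4, 4))), rec(np.zeros((5, 5)), week=1))


class TestApplyTranslation:
    def test_zero_shift_is_identity(self, grid_record):
        out = apply_translation(grid_record, Translation(0, 0))
        assert np.array_equal(out.pixels, grid_record.pixels)

    def test_hand_enumerated_2x2_shift(self):
        out = apply_translation(rec([[5, 3], [2, 8]]), Translation(0, 1))
        assert np.array_equal(out.pixels, [[2, 5], [2, 2]])

    def test_round_trip_on_interior_support(self):
        px = np.zeros((9, 9), dtype=int)
        px[3:6, 3:6] = np.arange(9).reshape(3, 3) + 1
        fwd = apply_translation(rec(px), Translation(2, -1))
        back = apply_translation(fwd, Translation(-2, 1))
        assert np.array_equal(back.pixels, px)

    def test_out_of_range_shift_rejected(self, grid_record):
        with pytest.raises(ValueError):
            apply_translation(grid_record, Translation(2, 0))


class TestDifferenceMap:
    def test_pixelwise_subtraction(self):
        d = difference_map(rec([[1, 1], [1, 1]]), rec([[5, 3], [2, 8]], week=1), ABSOLUTE)
        assert np.array_equal(d.values, [[4, 2], [1, 7]])

    def test_self_difference_is_zero(self):
        px = np.arange(16).reshape(4, 4)
        d = difference_map(rec(px), rec(px.copy(), week=2), ABSOLUTE)
        assert np.all(d.values == 0)

    def test_negative_entries_preserved(self):
        d = difference_map(rec([[9, 9]]), rec([[1, 2]], week=1), RELATIVE)
        assert np.array_equal(d.values, [[-8, -7]])

    def test_reference_must_be_earlier(self):
        with pytest.raises(ValueError):
            difference_map(rec(np.zeros((2, 2)), week=3), rec(np.zeros((2, 2)), week=1), ABSOLUTE)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rec(rng.integers(0, 255, (5, 5)), week=0)
        b = rec(rng.integers(0, 255, (5, 5)), week=1)
        fwd = difference_map(a, b, ABSOLUTE).values
        # swap roles (weeks adjusted to keep the precedence contract)
        a2 = rec(b.pixels, week=0)
        b2 = rec(a.pixels, week=1)
        rev = difference_map(a2, b2, ABSOLUTE).values
        assert np.array_equal(fwd, -rev)


class TestInitialFill:
    def test_uniform_minimum(self):
        d = initial_fill(rec([[2, 5], [7, 3]]))
        assert np.all(d.values == 2)
        assert d.mode == "initial"

    def test_all_zero_image(self):
        assert np.all(initial_fill(rec(np.zeros((3, 3)))).values == 0)

    def test_per_image_not_global_minimum(self):
        d = initial_fill(rec(np.array([[17, 42], [99, 23]])))
        assert np.all(d.values == 17)

    def test_non_first_week_rejected(self):
        with pytest.raises(ValueError):
            initial_fill(rec(np.zeros((2, 2)), week=3), available_weeks=[0, 1, 3])


class TestSelectReferenceWeek:
    @pytest.mark.parametrize(
        "mode,current,expected",
        [(RELATIVE, 3, 1), (ABSOLUTE, 3, 0), (RELATIVE, 4, 3), (ABSOLUTE, 1, 0)],
    )
    def test_reference_selection_skips_missing_weeks(self, mode, current, expected):
        assert select_reference_week({0, 1, 3, 4}, current, mode) == expected

    def test_earliest_week_has_no_reference(self):
        assert select_reference_week({0, 1, 3, 4}, 0, ABSOLUTE) is None

    def test_unavailable_week_rejected(self):
        with pytest.raises(ValueError):
            select_reference_week({0, 1}, 5, ABSOLUTE)


class TestPairSlices:
    def test_truncates_to_shorter_list(self):
        pairs, unused = pair_slices(list("abcde"), list("xyz"))
        assert pairs == [("a", "x"), ("b", "y"), ("c", "z")]
        assert unused == ["d", "e"]

    def test_equal_lengths_pair_fully(self):
        pairs, unused = pair_slices([1, 2], [3, 4])
        assert len(pairs) == 2 and not unused

    def test_empty_list_yields_no_pairs(self):
        pairs, unused = pair_slices([], [1, 2])
        assert pairs == [] and unused == [1, 2]


class TestBuildSamples:
    def test_samples_all_on_canvas_and_first_week_initial(self, tiny_dataset):
        index, _ = tiny_dataset
        samples, canvas, unused = build_samples(index, ABSOLUTE)
        assert len(samples) == len(index)  # equal slice counts -> no unused
        for s in samples:
            assert s.image.shape == (canvas.target_height, canvas.target_width)
            assert s.diff.values.shape == s.image.shape
            if s.week == 0:
                assert s.diff.mode == "initial"
                assert np.all(s.diff.values == s.diff.values.flat[0])
            else:
                assert s.diff.mode == ABSOLUTE
                assert s.diff.reference_week == 0

    def test_relative_mode_uses_most_recent_week(self, tiny_dataset):
        index, _ = tiny_dataset
        samples, _, _ = build_samples(index, RELATIVE)
        refs = {(s.week, s.diff.reference_week) for s in samples if s.week > 0}
        assert refs == {(1, 0), (3, 1)}  # week 2 missing -> 3 references 1

    def test_save_load_round_trip(self, tiny_dataset, tmp_path):
        index, _ = tiny_dataset
        samples, canvas, _ = build_samples(index, ABSOLUTE)
        save_samples(samples, canvas, tmp_path / "pp")
        back, canvas2, = load_samples(tmp_path / "pp")
        assert canvas2 == canvas
        assert len(back) == len(samples)
        assert np.array_equal(back[0].image, samples[0].image)
        assert np.array_equal(back[0].diff.values, samples[0].diff.values)
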