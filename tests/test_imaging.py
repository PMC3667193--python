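"""Stack I/O, projections, background removal, registration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from _oracles import exhaustive_shift_search, project_oracle
from microcensus import (
    ImageStack,
    StackIOError,
    ValidationError,
    load_stack,
    project,
    register_stack,
    remove_background,
    to_grayscale,
    write_image,
)

METHODS = ("min", "max", "median", "mean")


class TestLoadStack:
    def test_ordered_pngs_become_stack(self, tmp_path):
        img = np.full((10, 10), 7, dtype=np.uint8)
        paths = []
        for i in range(5):
            p = tmp_path / f"frame_{i}.png"
            write_image(img, p)
            paths.append(p)
        stack = load_stack(paths)
        assert stack.n_frames == 5
        assert stack.frame_shape == (10, 10)
        assert stack.frame_index == tuple(range(5))
        assert np.array_equal(stack.frames[3], img)

    def test_shape_mismatch_names_offending_file(self, tmp_path):
        write_image(np.zeros((10, 10), dtype=np.uint8), tmp_path / "a.png")
        write_image(np.zeros((10, 11), dtype=np.uint8), tmp_path / "b.png")
        with pytest.raises(ValidationError, match="b.png"):
            load_stack([tmp_path / "a.png", tmp_path / "b.png"])

    def test_rgb_tiffs_keep_three_channels(self, tmp_path):
        rgb = np.random.default_rng(0).integers(0, 256, (8, 8, 3)).astype(np.uint8)
        paths = []
        for i in range(3):
            p = tmp_path / f"c{i}.tif"
            write_image(rgb, p)
            paths.append(p)
        stack = load_stack(paths)
        assert stack.is_rgb
        assert stack.frames.shape == (3, 8, 8, 3)

    def test_multipage_tiff_is_one_stack(self, tmp_path):
        import tifffile

        arr = np.random.default_rng(1).integers(0, 256, (4, 6, 6)).astype(np.uint8)
        tifffile.imwrite(tmp_path / "stack.tif", arr)
        stack = load_stack([tmp_path / "stack.tif"])
        assert stack.n_frames == 4
        assert np.array_equal(stack.frames, arr)

    def test_unreadable_file_raises_io_error_naming_path(self, tmp_path):
        bad = tmp_path / "broken.png"
        bad.write_bytes(b"not an image")
        with pytest.raises(StackIOError, match="broken.png"):
            load_stack([bad])


class TestImageStackInvariants:
    def test_frame_index_must_increase(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            ImageStack(np.zeros((2, 4, 4), dtype=np.uint8), (1, 0))

    def test_pixel_range_checked_against_bit_depth(self):
        with pytest.raises(ValidationError, match="outside"):
            ImageStack(np.full((1, 4, 4), 300, dtype=np.int32), (0,))


class TestGrayscale:
    @pytest.mark.parametrize(
        "pixel,expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((100, 200, 50), 168)],
    )
    def test_luminance_values(self, pixel, expected):
        frame = np.array([[pixel]], dtype=np.uint8)
        assert to_grayscale(frame)[0, 0] == expected

    def test_grayscale_input_unchanged(self):
        frame = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert to_grayscale(frame) is frame

    def test_bad_channel_count_rejected(self):
        with pytest.raises(ValidationError):
            to_grayscale(np.zeros((4, 4, 2), dtype=np.uint8))


class TestProject:
    @pytest.mark.parametrize(
        "series,method,expected",
        [
            ((5, 3, 7), "min", 3),
            ((5, 3, 7), "max", 7),
            ((5, 3, 7, 9), "median", 6),  # mean of 5 and 7, half-up
            ((10, 20, 40), "mean", 23),  # 70/3 -> 23.33 -> 23
            ((10, 21), "mean", 16),  # 15.5 rounds up
        ],
    )
    def test_pixel_series(self, series, method, expected):
        frames = np.array(series, dtype=np.uint8).reshape(-1, 1, 1)
        stack = ImageStack.from_arrays(frames)
        assert project(stack, method).image[0, 0] == expected

    @pytest.mark.parametrize("method", METHODS)
    def test_single_frame_is_identity(self, method, rng):
        frame = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        stack = ImageStack.from_arrays(frame[None])
        assert np.array_equal(project(stack, method).image, frame)

    @pytest.mark.parametrize("method", METHODS)
    def test_matches_bruteforce_oracle(self, method, rng):
        for _ in range(40):
            n = int(rng.integers(1, 8))
            frames = rng.integers(0, 256, (n, 8, 8)).astype(np.uint8)
            stack = ImageStack.from_arrays(frames)
            expected = project_oracle(frames, method)
            assert np.array_equal(project(stack, method).image, expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        frames=hnp.arrays(np.uint8, st.tuples(st.integers(2, 6), st.just(5), st.just(5))),
        method=st.sampled_from(METHODS),
        seed=st.integers(0, 10),
    )
    def test_permutation_invariance(self, frames, method, seed):
        stack = ImageStack.from_arrays(frames)
        perm = np.random.default_rng(seed).permutation(frames.shape[0])
        shuffled = ImageStack.from_arrays(frames[perm])
        assert np.array_equal(project(stack, method).image, project(shuffled, method).image)

    def test_min_max_bound_every_frame(self, rng):
        frames = rng.integers(0, 256, (5, 8, 8)).astype(np.uint8)
        stack = ImageStack.from_arrays(frames)
        lo = project(stack, "min").image
        hi = project(stack, "max").image
        assert (frames >= lo).all() and (frames <= hi).all()

    def test_rgb_projected_per_channel(self, rng):
        frames = rng.integers(0, 256, (4, 5, 5, 3)).astype(np.uint8)
        stack = ImageStack.from_arrays(frames)
        assert np.array_equal(project(stack, "min").image, frames.min(axis=0))


class TestRemoveBackground:
    def test_subtract_clips_at_zero(self):
        res = remove_background(np.array([[10]], np.uint8), np.array([[12]], np.uint8), "subtract")
        assert res.image[0, 0] == 0

    def test_difference_takes_absolute_value(self):
        res = remove_background(np.array([[10]], np.uint8), np.array([[12]], np.uint8), "difference")
        assert res.image[0, 0] == 2

    def test_identical_inputs_give_zero_residual(self, rng):
        frame = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        assert not remove_background(frame, frame, "difference").image.any()

    def test_difference_symmetric_and_dominates_subtract(self, rng):
        a = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        b = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        dab = remove_background(a, b, "difference").image
        dba = remove_background(b, a, "difference").image
        sub = remove_background(a, b, "subtract").image
        assert np.array_equal(dab, dba)
        assert (sub <= dab).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            remove_background(np.zeros((4, 4), np.uint8), np.zeros((4, 5), np.uint8))


class TestRegisterStack:
    def test_identical_frames_report_zero_shift(self, rng):
        frame = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        stack = ImageStack.from_arrays([frame] * 3)
        _, shifts = register_stack(stack)
        assert shifts == [(0, 0)] * 3

    def test_injected_translation_recovered_and_realigned(self, rng):
        ref = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        moved = np.roll(ref, (3, -2), axis=(0, 1))  # scene translated by (+3, -2)
        stack = ImageStack.from_arrays([ref, moved])
        aligned, shifts = register_stack(stack, 0)
        assert shifts == [(0, 0), (-3, 2)]
        # the shifted frame must equal the reference on the overlap region
        assert np.array_equal(aligned.frames[1][:-3, 2:], ref[:-3, 2:])

    def test_agrees_with_exhaustive_shift_search(self, rng):
        ref = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        for dr, dc in [(1, 4), (-5, 0), (4, -4), (0, 0)]:
            moved = np.roll(ref, (dr, dc), axis=(0, 1))
            stack = ImageStack.from_arrays([ref, moved])
            _, shifts = register_stack(stack)
            assert shifts[1] == exhaustive_shift_search(ref, moved, radius=5)

    def test_pure_noise_frames_run_without_error(self, rng):
        frames = rng.integers(0, 256, (3, 16, 16)).astype(np.uint8)
        _, shifts = register_stack(ImageStack.from_arrays(frames))
        assert len(shifts) == 3

    def test_reference_index_validated(self, rng):
        frames = rng.integers(0, 256, (3, 8, 8)).astype(np.uint8)
        with pytest.raises(ValidationError):
            register_stack(ImageStack.from_arrays(frames), reference_index=3)
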