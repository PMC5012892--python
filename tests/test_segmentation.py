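import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from oracles import brute_tophat, flood_fill_labels
from phagoquant.phagosim import SimConfig, clumped_pair_frame, simulate_well
from phagoquant.plate_model import AnalysisParams, Channel, Frame
from phagoquant.segmentation import (
    analyze_frame,
    area_filter,
    confluence_mask,
    edge_split,
    label_connected,
    measure_objects,
    threshold_mask,
    tophat_correct,
)


def _gauss(shape, centre, sigma, amp):
    rr = np.arange(shape[0])[:, None] - centre[0]
    cc = np.arange(shape[1])[None, :] - centre[1]
    return amp * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


class TestTophat:
    def test_constant_grid_maps_to_zero(self):
        out = tophat_correct(np.full((16, 16), 7.0), radius_um=5, pixel_size_um=1)
        np.testing.assert_array_equal(out, 0.0)

    def test_ramp_plus_plateau_matches_oracle(self):
        n = 32
        ramp = np.linspace(0, 100, n)[None, :] * np.ones((n, 1))
        img = ramp.copy()
        img[14:17, 14:17] += 50.0
        out = tophat_correct(img, radius_um=5, pixel_size_um=1)
        np.testing.assert_array_equal(out, brute_tophat(img, 5))
        # plateau recovered ~50 above near-zero residual ramp
        assert out[15, 15] == pytest.approx(50.0, abs=16.0)
        assert np.median(out) < 1.0

    def test_radius_unit_conversion(self, rng):
        img = rng.random((24, 24)) * 10
        # 20 um at 2 um/px is a 10 px disk, identical to 10 um at 1 um/px
        np.testing.assert_array_equal(
            tophat_correct(img, radius_um=20, pixel_size_um=2),
            tophat_correct(img, radius_um=10, pixel_size_um=1),
        )

    def test_subpixel_radius_clamped_with_warning(self, rng):
        img = rng.random((8, 8))
        with pytest.warns(UserWarning, match="clamping to 1 px"):
            out = tophat_correct(img, radius_um=0.2, pixel_size_um=1)
        np.testing.assert_array_equal(out, brute_tophat(img, 1))

    @given(
        img=hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=4, max_side=24),
            elements=st.floats(0, 100),
        ),
        radius=st.integers(1, 4),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_bounded_and_exact(self, img, radius):
        out = tophat_correct(img, radius_um=float(radius), pixel_size_um=1.0)
        assert np.all(out >= 0)
        assert np.all(out <= img + 1e-12)
        np.testing.assert_array_equal(out, brute_tophat(img, radius))


class TestThreshold:
    def test_boundary_inclusive(self):
        grid = np.array([[0.0, 1.0], [2.0, 3.0]])
        np.testing.assert_array_equal(
            threshold_mask(grid, 2.0), np.array([[False, False], [True, True]])
        )

    def test_all_zero_grid(self):
        assert not threshold_mask(np.zeros((5, 5)), 2.0).any()

    def test_random_grid_matches_elementwise_count(self, rng):
        grid = rng.uniform(0, 4, size=(10, 10))
        mask = threshold_mask(grid, 2.0)
        assert mask.sum() == sum(v >= 2.0 for v in grid.ravel())


class TestLabeling:
    def test_diagonal_pixels_connect(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_connected(mask).max() == 1

    def test_empty_mask(self):
        assert label_connected(np.zeros((5, 5), dtype=bool)).max() == 0

    def test_disjoint_squares_match_flood_fill(self, rng):
        mask = np.zeros((20, 20), dtype=bool)
        for r, c in [(1, 1), (1, 8), (8, 1), (8, 8), (15, 15)]:
            mask[r : r + 2, c : c + 2] = True
        labels = label_connected(mask)
        assert labels.max() == flood_fill_labels(mask) == 5
        counts = np.bincount(labels.ravel())[1:]
        assert (counts == 4).all()

    def test_raster_deterministic_order(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[4, 0] = True  # later in raster order
        mask[0, 4] = True  # earlier
        labels = label_connected(mask)
        assert labels[0, 4] == 1 and labels[4, 0] == 2

    def test_labels_contiguous(self, rng):
        mask = rng.random((30, 30)) > 0.7
        labels = label_connected(mask)
        present = np.unique(labels)
        np.testing.assert_array_equal(present, np.arange(labels.max() + 1))


class TestEdgeSplit:
    def test_disabled_is_identity(self, params):
        frame, _ = clumped_pair_frame(3)
        corrected = tophat_correct(frame.pixels, 20, 2.0)
        labels = label_connected(threshold_mask(corrected, 2.0))
        out = edge_split(labels, corrected, params.replace(edge_split=False), 2.0)
        np.testing.assert_array_equal(out, labels)

    def test_single_blob_unchanged(self, params):
        img = _gauss((40, 40), (20, 20), 3, 10) + 0.1
        corrected = tophat_correct(img, 20, 2.0)
        labels = label_connected(threshold_mask(corrected, 2.0))
        assert labels.max() == 1
        out = edge_split(labels, corrected, params, 2.0)
        assert out.max() == 1
        np.testing.assert_array_equal(out > 0, labels > 0)

    def test_two_blob_clump_split_at_centres(self, params):
        frame, centres = clumped_pair_frame(7)
        corrected = tophat_correct(frame.pixels, 20, 2.0)
        labels = label_connected(threshold_mask(corrected, 2.0))
        assert labels.max() == 1  # merged by threshold
        out = edge_split(labels, corrected, params, 2.0)
        assert out.max() == 2
        ids = out[tuple(np.round(centres).astype(int).T)]
        assert ids[0] != ids[1] and (ids > 0).all()

    def test_preserves_foreground_and_never_merges(self, params):
        cfg = SimConfig(field_px=(160, 160), n_cells=15, seed=5, frame_times_min=(60.0,))
        green, _, _ = simulate_well(cfg)
        corrected = tophat_correct(green[0].pixels, 20, cfg.pixel_size_um)
        labels = label_connected(threshold_mask(corrected, 2.0))
        out = edge_split(labels, corrected, params, cfg.pixel_size_um)
        np.testing.assert_array_equal(out > 0, labels > 0)
        assert out.max() >= labels.max()
        # every child lies inside exactly one parent
        for child in range(1, out.max() + 1):
            parents = np.unique(labels[out == child])
            assert len(parents) == 1 and parents[0] > 0


class TestAreaFilter:
    def _table(self, areas):
        return pd.DataFrame({"label": np.arange(1, len(areas) + 1), "area_um2": areas})

    def test_exact_boundary_retained(self):
        out = area_filter(self._table([49.9, 50.0, 120.0]), 50.0)
        assert list(out["area_um2"]) == [50.0, 120.0]

    def test_empty_table(self):
        out = area_filter(pd.DataFrame(columns=["label", "area_um2"]), 50.0)
        assert out.empty

    def test_idempotent_and_order_independent(self, rng):
        areas = list(rng.uniform(10, 200, size=20))
        once = area_filter(self._table(areas), 50.0)
        twice = area_filter(once, 50.0)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = self._table(areas).sample(frac=1, random_state=0)
        out = area_filter(shuffled, 50.0)
        assert sorted(out["area_um2"]) == sorted(once["area_um2"])

    def test_minimum_pixel_count_at_2um_pixels(self):
        # 4 um^2 per pixel: 12 px = 48 um^2 removed, 13 px = 52 um^2 kept
        labels = np.zeros((10, 30), dtype=int)
        labels[2, 1:13] = 1   # 12 px
        labels[6, 1:14] = 2   # 13 px
        objects = measure_objects(labels, np.ones_like(labels, dtype=float), 2.0)
        out = area_filter(objects, 50.0)
        assert list(out["label"]) == [2]
        assert out["pixel_count"].iloc[0] == 13


class TestMeasureObjects:
    def test_single_square_arithmetic(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[1:3, 1:3] = 1
        corrected = np.where(labels > 0, 3.0, 0.0)
        df = measure_objects(labels, corrected, pixel_size_um=1.0)
        row = df.iloc[0]
        assert row["area_um2"] == 4.0
        assert row["integrated"] == pytest.approx(12.0)
        assert row["mean"] == pytest.approx(3.0)
        assert (row["row"], row["col"]) == (1.5, 1.5)
        assert (row["bbox0"], row["bbox1"], row["bbox2"], row["bbox3"]) == (1, 1, 3, 3)

    def test_no_labels_empty_table(self):
        df = measure_objects(np.zeros((5, 5), dtype=int), np.zeros((5, 5)), 1.0)
        assert df.empty

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share shape"):
            measure_objects(np.zeros((4, 4), dtype=int), np.zeros((5, 5)), 1.0)

    def test_integrated_matches_masked_sum_oracle(self, params):
        cfg = SimConfig(field_px=(192, 192), n_cells=25, seed=11, frame_times_min=(60.0,))
        green, _, _ = simulate_well(cfg)
        corrected = tophat_correct(green[0].pixels, 20, cfg.pixel_size_um)
        labels = label_connected(threshold_mask(corrected, 2.0))
        df = measure_objects(labels, corrected, cfg.pixel_size_um)
        assert len(df) >= 5
        for _, row in df.iterrows():
            expected = corrected[labels == row["label"]].sum()
            assert row["integrated"] == pytest.approx(expected, rel=1e-12)
        # invariant: integrated == mean * pixel_count
        np.testing.assert_allclose(
            df["integrated"], df["mean"] * df["pixel_count"], rtol=1e-12
        )


class TestConfluence:
    def test_constant_image_zero_fraction_with_warning(self, params):
        with pytest.warns(UserWarning, match="constant phase image"):
            mask, frac = confluence_mask(np.full((64, 64), 5.0), params, 1.0)
        assert frac == 0.0 and not mask.any()

    def test_noise_only_frame_near_zero(self, params):
        cfg = SimConfig(field_px=(192, 192), pixel_size_um=1.0, n_cells=0, seed=5,
                        frame_times_min=(0.0,))
        _, phase, _ = simulate_well(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, frac = confluence_mask(
                phase[0].pixels, params.replace(tophat_radius_um=5.0), 1.0
            )
        assert frac < 0.02

    def test_recovers_known_coverage(self, params):
        cfg = SimConfig(field_px=(256, 256), pixel_size_um=1.0, n_cells=25,
                        cell_radius_um=18.0, seed=3, frame_times_min=(0.0,))
        _, phase, truth = simulate_well(cfg)
        true_frac = truth.cell_mask().mean()
        _, frac = confluence_mask(
            phase[0].pixels, params.replace(tophat_radius_um=5.0), 1.0
        )
        assert frac == pytest.approx(true_frac, abs=0.05)


class TestFullChain:
    def test_deterministic_object_table(self, params):
        cfg = SimConfig(field_px=(160, 160), n_cells=12, seed=21, frame_times_min=(60.0,))
        green, _, _ = simulate_well(cfg)
        _, labels_a, objects_a = analyze_frame(green[0], params)
        _, labels_b, objects_b = analyze_frame(green[0], params)
        np.testing.assert_array_equal(labels_a, labels_b)
        pd.testing.assert_frame_equal(objects_a, objects_b)

    def test_rejects_phase_frame(self, params):
        frame = Frame(np.ones((8, 8)), Channel.PHASE, 0.0, "A01")
        with pytest.raises(ValueError, match="fluorescence"):
            analyze_frame(frame, params)
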