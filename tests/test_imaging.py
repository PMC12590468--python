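"""Densitometry: loading, spot detection, lattice fitting, measurement."""

import numpy as np
import pytest
from PIL import Image

from biospot.errors import GridFitError, ValidationError
from biospot.imaging import (
    IntensityImage,
    PadLayout,
    Spot,
    SpotTable,
    compute_activity,
    detect_candidate_spots,
    enumerate_spots,
    estimate_background,
    fit_spot_grid,
    grid_to_serpentine,
    load_luminescence_image,
    measure_halo,
    measure_spot_intensity,
    merge_spot_tables,
    normalize_by_median,
    serpentine_to_grid,
)
from biospot.synthetic import generate_upad_image, lattice_centers, save_image_png

from conftest import axis_aligned_grid, spanning_active_mask


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoadImage:
    def test_no_inversion_is_identity(self, tmp_path):
        arr = np.array([[0, 1], [2, 3]], dtype=np.uint8)
        p = tmp_path / "t.png"
        Image.fromarray(arr, mode="L").save(p)
        img = load_luminescence_image(p, invert=False)
        assert np.array_equal(img.pixels, arr)

    def test_inversion_symmetry(self, tmp_path):
        arr = np.array([[0, 1], [2, 3]], dtype=np.uint8)
        p = tmp_path / "t.png"
        Image.fromarray(arr, mode="L").save(p)
        img = load_luminescence_image(p, invert=True)
        assert np.array_equal(img.pixels, [[3, 2], [1, 0]])
        assert img.inverted

    def test_rgb_collapses_to_channel_mean(self, tmp_path):
        rgb = np.zeros((2, 2, 3), dtype=np.uint8)
        rgb[..., 0] = 30
        rgb[..., 1] = 60
        rgb[..., 2] = 90
        p = tmp_path / "rgb.png"
        Image.fromarray(rgb, mode="RGB").save(p)
        img = load_luminescence_image(p)
        assert np.allclose(img.pixels, 60.0)

    def test_synthetic_blob_brightest_at_planted_center(self, tmp_path):
        layout = PadLayout(1, 1, pitch=40.0, spot_radius=6.0)
        img, truth = generate_upad_image(layout, [5.0], background=10.0, seed=3)
        p = tmp_path / "blob.png"
        save_image_png(img, p)
        loaded = load_luminescence_image(p)
        y, x = np.unravel_index(np.argmax(loaded.pixels), loaded.pixels.shape)
        cx, cy = truth.spot_centers[0]
        assert abs(x - cx) <= 1 and abs(y - cy) <= 1

    def test_unreadable_file_raises_ioerror(self, tmp_path):
        p = tmp_path / "junk.png"
        p.write_text("not an image")
        with pytest.raises(IOError):
            load_luminescence_image(p)

    def test_negative_pixels_rejected(self):
        with pytest.raises(ValidationError):
            IntensityImage(pixels=np.array([[-1.0, 0.0]]))


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------

class TestDetectCandidates:
    def test_blank_image_yields_nothing(self):
        img = IntensityImage(pixels=np.full((60, 60), 7.0))
        assert len(detect_candidate_spots(img, (3, 6))) == 0

    def test_full_lattice_recovered_within_1px(self, small_layout):
        img, truth = generate_upad_image(
            small_layout, np.full(12, 3.0), background=20.0, seed=1)
        found = detect_candidate_spots(img, (2, 6))
        assert len(found) == 12
        for i in range(12):
            d = np.hypot(*(found - truth.spot_centers[i]).T).min()
            assert d <= 1.0

    def test_partial_activity_detects_active_positions(self, small_layout):
        act = np.zeros(12)
        active = [0, 2, 5, 7, 8, 11]
        act[active] = 4.0
        img, truth = generate_upad_image(small_layout, act, background=20.0, seed=2)
        found = detect_candidate_spots(img, (2, 6))
        assert len(found) >= 6
        # every active spot (grid row-major index -> serpentine truth index)
        for k in active:
            i = grid_to_serpentine(k // 4, k % 4, 4)
            d = np.hypot(*(found - truth.spot_centers[i]).T).min()
            assert d <= 1.0


# ---------------------------------------------------------------------------
# lattice fitting
# ---------------------------------------------------------------------------

class TestFitGrid:
    def test_exact_axis_aligned_lattice_zero_residual(self, small_layout):
        rr, cc = np.mgrid[0:3, 0:4]
        pts = np.column_stack([20 + cc.ravel() * 20.0, 20 + rr.ravel() * 20.0])
        grid = fit_spot_grid(pts, small_layout)
        assert grid.rms_residual == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sorted(np.abs(grid.col_step)), [0, 20])
        assert np.allclose(grid.predict(0, 0), [20, 20], atol=1e-9)

    def test_rotated_lattice_with_dark_spots_within_1px(self, grid_10x10):
        rng = np.random.default_rng(42)
        mask = spanning_active_mask(rng, 10, 10, 0.7)  # 30% dark
        act = np.where(mask.ravel(), 3.0, 0.0)
        img, truth = generate_upad_image(
            grid_10x10, act, rotation_deg=2.0, background=20.0, seed=7)
        found = detect_candidate_spots(img, (2, 6))
        grid = fit_spot_grid(found, grid_10x10)
        for r in range(10):
            for c in range(10):
                i = grid_to_serpentine(r, c, 10)
                err = np.linalg.norm(grid.predict(r, c) - truth.spot_centers[i])
                assert err <= 1.0, f"node ({r},{c}) off by {err:.2f} px"

    @pytest.mark.parametrize("rotation", [0.0, 1.0, 3.0, 5.0])
    def test_center_recovery_across_rotations(self, grid_10x10, rotation):
        rng = np.random.default_rng(int(rotation * 10) + 1)
        mask = spanning_active_mask(rng, 10, 10, 0.5)
        act = np.where(mask.ravel(), 3.0, 0.0)
        img, truth = generate_upad_image(
            grid_10x10, act, rotation_deg=rotation, background=20.0,
            seed=int(rotation * 100) + 5)
        grid = fit_spot_grid(detect_candidate_spots(img, (2, 6)), grid_10x10)
        for r in range(10):
            for c in range(10):
                i = grid_to_serpentine(r, c, 10)
                err = np.linalg.norm(grid.predict(r, c) - truth.spot_centers[i])
                assert err <= 1.0

    def test_collinear_candidates_raise(self, small_layout):
        pts = np.array([[10.0, 10.0], [30.0, 10.0]])
        with pytest.raises(GridFitError):
            fit_spot_grid(pts, small_layout)

    def test_corner_hints_resolve_sparse_detection(self, small_layout):
        # only one bright spot, but hints pin the lattice
        grid = fit_spot_grid(
            np.empty((0, 2)), small_layout,
            corner_hints=[(20, 20), (80, 20), (80, 60), (20, 60)])
        assert np.allclose(grid.predict(2, 3), [80, 60], atol=1e-9)
        assert np.allclose(grid.predict(1, 1), [40, 40], atol=1e-9)


# ---------------------------------------------------------------------------
# serpentine enumeration
# ---------------------------------------------------------------------------

class TestSerpentine:
    def test_2x3_order_and_labels(self, small_layout):
        layout = PadLayout(2, 3, 20.0, 4.0)
        table = enumerate_spots(axis_aligned_grid(layout), layout)
        labels = [s.label for s in table.spots]
        assert labels == ["A1", "A2", "A3", "B3", "B2", "B1"]
        assert [s.serpentine_index for s in table.spots] == list(range(6))

    def test_b1_maps_to_index_5(self):
        assert grid_to_serpentine(1, 0, 3) == 5

    def test_index_offset_shifts_indices_and_row_letters(self):
        layout = PadLayout(10, 10, 16.0, 4.0)
        table = enumerate_spots(axis_aligned_grid(layout), layout,
                                index_offset=100)
        assert table.spots[0].serpentine_index == 100
        assert table.spots[0].label == "K1"  # row 10 of the pad

    @pytest.mark.parametrize("n_rows,n_cols", [(1, 1), (2, 3), (5, 4), (10, 10)])
    def test_serpentine_bijection(self, n_rows, n_cols):
        seen = set()
        for i in range(n_rows * n_cols):
            r, c = serpentine_to_grid(i, n_cols)
            assert 0 <= r < n_rows and 0 <= c < n_cols
            assert grid_to_serpentine(r, c, n_cols) == i
            seen.add((r, c))
        assert len(seen) == n_rows * n_cols


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

class TestMeasurement:
    def test_constant_image_mean_is_value(self):
        img = IntensityImage(pixels=np.full((50, 50), 7.0))
        assert measure_spot_intensity(img, np.array([25, 25]), 5.0) == 7.0

    def test_step_edge_through_center_averages_to_half(self):
        pix = np.zeros((60, 60))
        pix[:, 30:] = 10.0
        img = IntensityImage(pixels=pix)
        # center on the edge between columns 29 and 30
        m = measure_spot_intensity(img, np.array([29.5, 30.0]), 8.0)
        assert m == pytest.approx(5.0, abs=0.3)  # pixel discretization

    def test_blob_mean_between_background_and_peak(self):
        layout = PadLayout(1, 1, 40.0, 6.0)
        amp_scale, bg = 1000.0, 20.0
        img, truth = generate_upad_image(layout, [2.0], background=bg,
                                         amplitude_scale=amp_scale, seed=0)
        m = measure_spot_intensity(img, truth.spot_centers[0], 4.8)
        assert bg < m < 2.0 * amp_scale + bg

    def test_mean_monotone_in_amplitude(self):
        layout = PadLayout(1, 1, 40.0, 6.0)
        means = []
        for amp in [1.0, 2.0, 4.0, 8.0]:
            img, truth = generate_upad_image(layout, [amp], background=20.0, seed=0)
            means.append(measure_spot_intensity(img, truth.spot_centers[0], 4.8))
        assert np.all(np.diff(means) > 0)

    def test_disk_outside_image_raises(self):
        img = IntensityImage(pixels=np.ones((20, 20)))
        with pytest.raises(ValidationError):
            measure_spot_intensity(img, np.array([100.0, 100.0]), 3.0)


class TestHalo:
    def test_flat_background_has_no_halo(self):
        img = IntensityImage(pixels=np.full((80, 80), 30.0))
        r = measure_halo(img, np.array([40, 40]), 6.0, 20.0,
                         background=30.0, background_scale=1.0)
        assert r is None

    def test_planted_annulus_recovered(self):
        layout = PadLayout(1, 1, 44.0, 6.0)
        img, _ = generate_upad_image(
            layout, [3.0], background=30.0, seed=0,
            halos={0: (8.0, 14.0, 200.0)})
        center = lattice_centers(layout)[0].reshape(-1, 2)[0]
        r = measure_halo(img, center, 6.0, 20.0,
                         background=30.0, background_scale=1.0)
        assert r == pytest.approx(14.0, abs=1.0)

    def test_bright_disk_without_ring_is_absent(self):
        pix = np.full((80, 80), 30.0)
        yy, xx = np.mgrid[0:80, 0:80]
        pix[np.hypot(xx - 40, yy - 40) <= 5.0] = 500.0
        img = IntensityImage(pixels=pix)
        r = measure_halo(img, np.array([40, 40]), 6.0, 20.0,
                         background=30.0, background_scale=1.0)
        assert r is None

    def test_halo_radius_oracle_over_seeds(self):
        """Planted outer radii recovered within 1 px across a seed sweep."""
        layout = PadLayout(1, 1, 44.0, 6.0)
        rng = np.random.default_rng(0)
        for seed in range(20):
            r_out = float(rng.integers(10, 18))
            img, _ = generate_upad_image(
                layout, [2.0], background=30.0, noise_sd=2.0, seed=seed,
                halos={0: (8.0, r_out, 250.0)})
            center = lattice_centers(layout)[0].reshape(-1, 2)[0]
            got = measure_halo(img, center, 6.0, 21.0,
                               background=30.0, background_scale=2.0)
            assert got is not None
            assert got == pytest.approx(r_out, abs=1.0), f"seed {seed}"

    def test_background_estimate_is_robust(self, grid_10x10):
        img, _ = generate_upad_image(grid_10x10, np.full(100, 2.0),
                                     background=25.0, noise_sd=1.0, seed=4)
        grid = axis_aligned_grid(grid_10x10, origin=(16.0, 16.0))
        med, scale = estimate_background(img, grid, grid_10x10, 8.0)
        assert med == pytest.approx(25.0, abs=1.0)
        assert 0 < scale < 3.0


# ---------------------------------------------------------------------------
# activity combination + normalization + merging
# ---------------------------------------------------------------------------

class TestActivity:
    def test_no_halo_is_pure_densitometry(self):
        assert compute_activity(4.0, None, 1.0, 16.0, 4.0) == 4.0

    def test_zero_weight_ignores_halo(self):
        assert compute_activity(4.0, 12.0, 0.0, 16.0, 4.0) == 4.0

    def test_commensuration_formula(self):
        # halo diameter = pitch -> adds exactly one intensity-scale unit
        assert compute_activity(4.0, 8.0, 1.0, 16.0, 4.0) == pytest.approx(8.0)


def _table_from_raw(raw, source="img0"):
    spots = [
        Spot(serpentine_index=i, grid_row=0, grid_col=i, label=f"A{i+1}",
             center=np.array([float(i), 0.0]), mean_intensity=v,
             raw_activity=v, source_image=source)
        for i, v in enumerate(raw)
    ]
    return SpotTable(spots=spots, source_images=[source])


class TestNormalization:
    def test_median_division(self):
        out = normalize_by_median(_table_from_raw([2.0, 4.0, 6.0]))
        assert [s.norm_activity for s in out.spots] == [0.5, 1.0, 1.5]
        assert out.normalization_median == 4.0

    def test_all_equal_normalizes_to_one(self):
        out = normalize_by_median(_table_from_raw([3.0] * 5))
        assert all(s.norm_activity == 1.0 for s in out.spots)

    @pytest.mark.parametrize("seed", range(5))
    def test_odd_count_median_is_exactly_one(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(1.0, 10.0, size=21)
        out = normalize_by_median(_table_from_raw(list(raw)))
        assert np.median([s.norm_activity for s in out.spots]) == 1.0

    def test_blank_image_rejected(self):
        with pytest.raises(ValidationError):
            normalize_by_median(_table_from_raw([0.0, 0.0, 0.0]))

    def test_normalization_is_per_image(self):
        t = _table_from_raw([2.0, 4.0, 6.0], source="a")
        t2 = _table_from_raw([10.0, 20.0, 30.0], source="b")
        for i, s in enumerate(t2.spots):
            s.serpentine_index = 3 + i
        merged = merge_spot_tables([t, t2])
        out = normalize_by_median(merged)
        assert [s.norm_activity for s in out.spots] == [0.5, 1.0, 1.5] * 2


class TestMerge:
    def test_contiguous_blocks_merge(self):
        t1 = _table_from_raw(list(range(1, 101)), source="a")
        t2 = _table_from_raw(list(range(1, 101)), source="b")
        for i, s in enumerate(t2.spots):
            s.serpentine_index = 100 + i
        merged = merge_spot_tables([t1, t2])
        assert [s.serpentine_index for s in merged.spots] == list(range(200))

    def test_overlap_rejected(self):
        t1 = _table_from_raw([1.0] * 100)
        t2 = _table_from_raw([1.0] * 110)
        for i, s in enumerate(t2.spots):
            s.serpentine_index = 90 + i
        with pytest.raises(ValidationError, match="overlap"):
            merge_spot_tables([t1, t2])

    def test_single_table_is_identity(self):
        t = _table_from_raw([1.0, 2.0, 3.0])
        merged = merge_spot_tables([t])
        assert [s.serpentine_index for s in merged.spots] == [0, 1, 2]

    def test_csv_roundtrip(self, tmp_path):
        t = normalize_by_median(_table_from_raw([2.0, 4.0, 6.0]))
        p = tmp_path / "spots.csv"
        t.to_csv(p)
        back = SpotTable.from_csv(p)
        assert [s.norm_activity for s in back.spots] == [0.5, 1.0, 1.5]
        assert [s.label for s in back.spots] == ["A1", "A2", "A3"]
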