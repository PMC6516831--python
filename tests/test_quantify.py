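import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_grid, make_mask
from nucratio.errors import (
    EmptyMeasurementError,
    EmptyRegionError,
    GroupingError,
    InsufficientReferenceError,
    UndefinedRatioError,
)
from nucratio.quantify import (
    CellMeasure,
    da_normalize,
    measure_stack,
    nc_ratio,
    nuclear_mean_intensity,
    nuclear_ratio_2d,
    nuclear_ratio_3d,
    render_heatmap,
)
from nucratio.segmentation import CellOutline, segment_nuclei_3d, select_central_plane
from nucratio.synthetic import SyntheticParams, generate_stack, match_to_ground_truth


def toy_cube():
    """2x2x2 nucleus with green {2,2,4,4,2,2,4,4} and red uniform 2."""
    green = np.zeros((2, 2, 2))
    green[:, :, 0] = 2.0
    green[:, :, 1] = 4.0
    red = np.full((2, 2, 2), 2.0)
    labels = np.ones((2, 2, 2), dtype=int)
    return make_grid(green, red), make_mask(labels)


class TestNuclearMean:
    def test_constant_field(self):
        labels = np.zeros((3, 4, 4), dtype=int)
        labels[1, 1:3, 1:3] = 1
        grid = make_grid(np.full((3, 4, 4), 7.5), np.ones((3, 4, 4)))
        assert nuclear_mean_intensity(grid, make_mask(labels), 1, "green") == 7.5

    def test_hand_sum(self):
        grid, mask = toy_cube()
        assert nuclear_mean_intensity(grid, mask, 1, "green") == 3.0  # 24/8

    def test_volume_weighted_plane_identity(self):
        # full-mask mean equals the volume-weighted mean of per-plane means
        rng = np.random.default_rng(0)
        green = rng.random((5, 6, 6)) * 10
        labels = (rng.random((5, 6, 6)) > 0.5).astype(int)
        labels[2, 3, 3] = 1  # ensure nonempty
        grid = make_grid(green, np.ones_like(green))
        mask = make_mask(labels)
        total = 0.0
        weight = 0
        for z in range(5):
            sel = labels[z] == 1
            if sel.any():
                total += green[z][sel].mean() * sel.sum()
                weight += sel.sum()
        assert nuclear_mean_intensity(grid, mask, 1, "green") == pytest.approx(
            total / weight, rel=1e-12
        )

    def test_empty_plane_raises(self):
        labels = np.zeros((4, 3, 3), dtype=int)
        labels[1, 1, 1] = 1
        grid = make_grid(np.ones((4, 3, 3)), np.ones((4, 3, 3)))
        with pytest.raises(EmptyMeasurementError):
            nuclear_mean_intensity(grid, make_mask(labels), 1, "green", plane=3)


class TestRatio3D:
    def test_identity_channels(self):
        rng = np.random.default_rng(1)
        data = rng.random((4, 5, 5)) + 0.5
        labels = np.zeros((4, 5, 5), dtype=int)
        labels[1:3, 1:4, 1:4] = 1
        grid = make_grid(data, data)
        assert nuclear_ratio_3d(grid, make_mask(labels), 1) == pytest.approx(1.0)

    def test_hand_quotient(self):
        grid, mask = toy_cube()
        assert nuclear_ratio_3d(grid, mask, 1) == 1.5

    def test_zero_red_raises(self):
        labels = np.ones((2, 2, 2), dtype=int)
        grid = make_grid(np.ones((2, 2, 2)), np.zeros((2, 2, 2)))
        with pytest.raises(UndefinedRatioError):
            nuclear_ratio_3d(grid, make_mask(labels), 1)


class TestRatio2D:
    def test_uniform_equals_3d(self):
        params = SyntheticParams(n_pl=1, n_da=0, noise_model="none", seed=2)
        grid, _ = generate_stack(params)
        mask = segment_nuclei_3d(grid, "absolute", threshold=50.0)
        assert nuclear_ratio_2d(grid, mask, 1) == pytest.approx(
            nuclear_ratio_3d(grid, mask, 1), rel=1e-9
        )

    def test_central_plane_gradient(self):
        labels = np.zeros((5, 4, 4), dtype=int)
        labels[1:4, 1:3, 1:3] = 1  # central plane = 2
        green = np.ones((5, 4, 4))
        green[2] = 2.0  # doubled on the central plane only
        grid = make_grid(green, np.ones((5, 4, 4)))
        mask = make_mask(labels)
        assert select_central_plane(mask, 1) == 2
        r2 = nuclear_ratio_2d(grid, mask, 1)
        off_plane = nuclear_mean_intensity(grid, mask, 1, "green", plane=1)
        assert r2 == pytest.approx(2.0 * off_plane, rel=1e-12)

    def test_empty_central_plane(self):
        # pathological mask: voxels at z=0 and z=4 only -> central plane 2 empty
        labels = np.zeros((5, 3, 3), dtype=int)
        labels[0, 1, 1] = 1
        labels[4, 1, 1] = 1
        grid = make_grid(np.ones((5, 3, 3)), np.ones((5, 3, 3)))
        with pytest.raises(EmptyMeasurementError):
            nuclear_ratio_2d(grid, make_mask(labels), 1)


class TestNCRatio:
    def _uniform_cell(self, nuc_val, cyto_val):
        labels = np.zeros((3, 20, 20), dtype=int)
        labels[1, 8:12, 8:12] = 1
        green = np.zeros((3, 20, 20))
        green[1] = cyto_val
        green[1, 8:12, 8:12] = nuc_val
        grid = make_grid(green, np.ones((3, 20, 20)))
        verts = np.array([(5.5, 5.5), (5.5, 14.5), (14.5, 14.5), (14.5, 5.5)])
        outline = CellOutline(label=1, z=1, vertices=verts)
        return grid, make_mask(labels), outline

    def test_uniform_cell(self):
        grid, mask, outline = self._uniform_cell(3.0, 3.0)
        assert nc_ratio(grid, mask, outline, 1) == pytest.approx(1.0)

    def test_hand_partition(self):
        grid, mask, outline = self._uniform_cell(5.0, 2.0)
        assert nc_ratio(grid, mask, outline, 1) == pytest.approx(2.5)

    def test_generator_truth_recovery(self):
        params = SyntheticParams(
            n_pl=1, n_da=0, noise_model="none", partition_range=(2.5, 2.5), seed=5
        )
        grid, gt = generate_stack(params)
        mask = segment_nuclei_3d(grid, "absolute", threshold=50.0)
        plane = select_central_plane(mask, 1)
        cy, cx = mask.centroids[1][1], mask.centroids[1][2]
        half = 10  # voxels: inside the 2 µm shell at 0.3 µm xy pitch
        verts = np.array(
            [(cy - half, cx - half), (cy - half, cx + half),
             (cy + half, cx + half), (cy + half, cx - half)]
        )
        outline = CellOutline(label=1, z=plane, vertices=verts)
        assert nc_ratio(grid, mask, outline, 1) == pytest.approx(2.5, rel=1e-9)

    def test_zero_cytoplasm_mean(self):
        grid, mask, outline = self._uniform_cell(5.0, 0.0)
        with pytest.raises(UndefinedRatioError):
            nc_ratio(grid, mask, outline, 1)

    def test_empty_region_propagates(self):
        labels = np.zeros((3, 20, 20), dtype=int)
        labels[1, 5:15, 5:15] = 1
        grid = make_grid(np.ones((3, 20, 20)), np.ones((3, 20, 20)))
        verts = np.array([(6.5, 6.5), (6.5, 12.5), (12.5, 12.5), (12.5, 6.5)])
        outline = CellOutline(label=1, z=1, vertices=verts)
        with pytest.raises(EmptyRegionError):
            nc_ratio(grid, make_mask(labels), outline, 1)


class TestDANormalize:
    def _measure(self, embryo, cid, green, cls="PL"):
        return CellMeasure(
            embryo_id=embryo, cell_id=cid, cell_class=cls, mean_green_nuc_3d=green
        )

    def test_self_reference(self):
        pl = [self._measure("e1", 1, 20.0)]
        das = [self._measure("e1", i + 10, 20.0, "DA") for i in range(6)]
        out = da_normalize(pl, das)
        assert out[0].da_norm == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        pl = [self._measure("e1", 1, 30.0)]
        das = [
            self._measure("e1", i + 10, v, "DA")
            for i, v in enumerate([10, 20, 30, 20, 10, 30])
        ]
        out = da_normalize(pl, das)
        assert out[0].da_norm == pytest.approx(1.5)
        assert out[0].da_ref_ids == tuple(range(10, 16))

    def test_first_n_ref_by_label_order(self):
        pl = [self._measure("e1", 1, 10.0)]
        das = [self._measure("e1", cid, val, "DA") for cid, val in
               [(15, 100.0), (10, 10.0), (11, 10.0), (12, 10.0), (13, 10.0), (14, 10.0), (16, 100.0)]]
        out = da_normalize(pl, das, n_ref=6)
        # first six by ascending cell_id: 10..15 -> mean (5*10+100)/6 = 25
        assert out[0].da_norm == pytest.approx(10.0 / 25.0)

    def test_relaxed_reference_count_warns(self):
        pl = [self._measure("e1", 1, 10.0)]
        das = [self._measure("e1", i + 10, 10.0, "DA") for i in range(4)]
        with pytest.warns(UserWarning):
            out = da_normalize(pl, das, n_ref=6)
        assert out[0].da_norm == pytest.approx(1.0)

    def test_too_few_references(self):
        pl = [self._measure("e1", 1, 10.0)]
        das = [self._measure("e1", 10, 10.0, "DA"), self._measure("e1", 11, 10.0, "DA")]
        with pytest.raises(InsufficientReferenceError):
            da_normalize(pl, das)

    def test_mixed_embryos(self):
        pl = [self._measure("e1", 1, 10.0)]
        das = [self._measure("e2", i + 10, 10.0, "DA") for i in range(6)]
        with pytest.raises(GroupingError):
            da_normalize(pl, das)


class TestHeatmap:
    def test_uniform_silhouette(self):
        labels = np.zeros((3, 6, 6), dtype=int)
        labels[1, 2:4, 2:4] = 1
        green = np.zeros((3, 6, 6))
        green[1, 2:4, 2:4] = 9.0
        grid = make_grid(green, np.ones((3, 6, 6)))
        img, meta = render_heatmap(grid, make_mask(labels))
        assert set(np.unique(img)) == {0.0, 9.0}
        assert (meta["vmin"], meta["vmax"]) == (9.0, 9.0)

    def test_two_nuclei_per_pixel_maxima(self):
        labels = np.zeros((4, 8, 8), dtype=int)
        labels[1, 1:3, 1:3] = 1
        labels[2, 5:7, 5:7] = 2
        green = np.zeros((4, 8, 8))
        green[1, 1:3, 1:3] = 10.0
        green[2, 5:7, 5:7] = 100.0
        grid = make_grid(green, np.ones((4, 8, 8)))
        img, _ = render_heatmap(grid, make_mask(labels))
        assert img[1, 1] == 10.0
        assert img[5, 5] == 100.0

    def test_masked_never_exceeds_unmasked(self):
        params = SyntheticParams(n_pl=3, n_da=0, noise_model="poisson", seed=3)
        grid, _ = generate_stack(params)
        mask = segment_nuclei_3d(grid, "otsu")
        img, _ = render_heatmap(grid, mask)
        assert (img <= grid.green.max(axis=0)).all()

    def test_empty_mask_blank(self):
        grid = make_grid(np.ones((2, 4, 4)), np.zeros((2, 4, 4)))
        mask = segment_nuclei_3d(grid)
        img, meta = render_heatmap(grid, mask)
        assert img.max() == 0.0


class TestGainInvariance:
    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_common_gain_leaves_ratios(self, g):
        grid, mask = toy_cube()
        base = nuclear_ratio_3d(grid, mask, 1)
        scaled = make_grid(grid.green * g, grid.red * g)
        assert nuclear_ratio_3d(scaled, mask, 1) == pytest.approx(base, rel=1e-9)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_green_gain_scales_ratios(self, g):
        grid, mask = toy_cube()
        base = nuclear_ratio_3d(grid, mask, 1)
        scaled = make_grid(grid.green * g, grid.red)
        assert nuclear_ratio_3d(scaled, mask, 1) == pytest.approx(base * g, rel=1e-9)


class TestMeasureStack:
    def test_full_cohort_measures(self, small_stack):
        grid, gt = small_stack
        mask = segment_nuclei_3d(grid, "absolute", threshold=50.0)
        matched = match_to_ground_truth(mask, gt)
        classes = dict(zip(matched["label"], matched["cell_class"]))
        measures = measure_stack(grid, mask, embryo_id="e0", classes=classes)
        assert len(measures) == 7
        by_id = dict(zip(matched["label"], matched["k"]))
        for m in measures:
            assert m.ratio_3d is not None and m.ratio_3d > 0
            truth_ratio = by_id[m.cell_id] * 40.0 / 100.0  # k*cyto/red
            assert m.ratio_3d == pytest.approx(truth_ratio, rel=1e-9)
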