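import numpy as np
import pytest

from synkin import shape_metrics as M
from synkin.synthetic import render_mask_movie, simulate_two_state_track, TwoStateParams
from synkin.trackcore import MaskSeries, build_spot_grid

from conftest import make_track


def _series(masks, pixel_size=1.0, origin=(0.0, 0.0)):
    masks = np.asarray(masks, dtype=bool)
    return MaskSeries(frames=np.arange(masks.shape[0]), masks=masks,
                      pixel_size=pixel_size, origin=origin)


def _disk_mask(shape, center_rc, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius**2


class TestSamplingEfficiency:
    def test_stationary_is_one_over_n_steps(self):
        mask = _disk_mask((32, 32), (16, 16), 6)
        series = _series(np.repeat(mask[None], 20, axis=0))
        results = M.sampling_efficiency(series, n_steps=20)
        assert len(results) == 1
        assert results[0].efficiency == pytest.approx(1.0 / 20.0)

    def test_disjoint_masks_are_one(self):
        masks = np.zeros((20, 20, 40), dtype=bool)
        for i in range(20):
            masks[i, :, 2 * i : 2 * i + 2] = True
        series = _series(masks)
        results = M.sampling_efficiency(series, n_steps=20)
        assert results[0].efficiency == 1.0

    def test_matches_brute_force_set_arithmetic(self):
        # stepping disk on a small raster vs python-set pixel counting
        n, shape = 12, (48, 48)
        masks = np.stack([_disk_mask(shape, (24, 8 + 3 * i), 7) for i in range(n)])
        series = _series(masks)
        results = M.sampling_efficiency(series, n_steps=5)
        for res in results:
            window = masks[res.start : res.start + 5]
            pixel_sets = [set(zip(*np.nonzero(m))) for m in window]
            union = set().union(*pixel_sets)
            total = sum(len(s) for s in pixel_sets)
            assert res.unique_pixels == len(union)
            assert res.total_pixels == total

    def test_bounds_for_constant_area(self):
        rng = np.random.default_rng(2)
        n = 25
        masks = np.zeros((n, 30, 64), dtype=bool)
        for i in range(n):
            c = int(rng.integers(8, 56))
            masks[i] = _disk_mask((30, 64), (15, c), 5)
        series = _series(masks)
        for res in M.sampling_efficiency(series, n_steps=20):
            assert 1.0 / 20.0 <= res.efficiency <= 1.0

    def test_empty_mask_window_skipped(self):
        masks = np.ones((22, 4, 4), dtype=bool)
        masks[10] = False
        series = _series(masks)
        results = M.sampling_efficiency(series, n_steps=20)
        # windows 0..2 all contain frame 10
        assert results == []

    def test_too_few_frames(self):
        series = _series(np.ones((5, 4, 4), dtype=bool))
        with pytest.raises(ValueError, match="need >="):
            M.sampling_efficiency(series, n_steps=20)


class TestProtrusionIndex:
    def _grid_and_spot_raster(self, pixel_size=0.5):
        grid = build_spot_grid(10.0, 30.0, (0.0, 0.0, 90.0, 90.0))
        h = w = int(30.0 / pixel_size)
        series = _series(np.zeros((1, h, w), bool), pixel_size=pixel_size,
                         origin=(15.0, 15.0))
        spot_id = 5  # centre (30, 30)
        raster = M.rasterize_spot(grid, spot_id, series)
        return grid, spot_id, raster, series.origin, pixel_size

    def test_cell_inside_spot(self):
        grid, sid, spot, origin, ps = self._grid_and_spot_raster()
        h, w = spot.shape
        cell = _disk_mask((h, w), (30, 30), 6)  # 3 μm disk at the spot centre
        series = _series(cell[None], pixel_size=ps, origin=origin)
        om = M.protrusion_index(series, grid, sid)
        assert om.fractional_overlap[0] == 1.0
        assert om.max_possible_overlap[0] == 1.0
        assert om.protrusion_index[0] == 0.0

    def test_cell_outside_spot(self):
        grid, sid, spot, origin, ps = self._grid_and_spot_raster()
        h, w = spot.shape
        cell = _disk_mask((h, w), (8, 8), 6)  # far corner, off the spot
        series = _series(cell[None], pixel_size=ps, origin=origin)
        om = M.protrusion_index(series, grid, sid)
        assert om.fractional_overlap[0] == 0.0
        assert om.max_possible_overlap[0] == 1.0
        assert om.protrusion_index[0] == 1.0

    def test_double_area_covering_cell(self):
        grid, sid, spot, origin, ps = self._grid_and_spot_raster()
        # cell = spot pixels plus an equal-sized disjoint copy: area exactly
        # doubles while fully covering the spot
        shifted = np.roll(spot, spot.shape[1] // 2, axis=1)
        assert not (spot & shifted).any()
        cell = spot | shifted
        series = _series(cell[None], pixel_size=ps, origin=origin)
        om = M.protrusion_index(series, grid, sid)
        assert om.fractional_overlap[0] == pytest.approx(0.5)
        assert om.max_possible_overlap[0] == pytest.approx(0.5)
        assert om.protrusion_index[0] == pytest.approx(0.0)

    def test_overlap_matches_brute_force(self):
        grid, sid, spot, origin, ps = self._grid_and_spot_raster()
        h, w = spot.shape
        rng = np.random.default_rng(5)
        masks = np.stack(
            [_disk_mask((h, w), tuple(rng.integers(10, 50, 2)), 8) for _ in range(6)]
        )
        series = _series(masks, pixel_size=ps, origin=origin)
        om = M.protrusion_index(series, grid, sid)
        spot_set = set(zip(*np.nonzero(spot)))
        for k in range(6):
            cell_set = set(zip(*np.nonzero(masks[k])))
            assert om.overlap_area[k] == pytest.approx(
                len(cell_set & spot_set) * ps**2
            )
            assert om.cell_area[k] == pytest.approx(len(cell_set) * ps**2)

    def test_bounds_invariant(self):
        grid, sid, spot, origin, ps = self._grid_and_spot_raster()
        h, w = spot.shape
        rng = np.random.default_rng(9)
        masks = np.stack(
            [_disk_mask((h, w), tuple(rng.integers(5, 55, 2)), int(r)) for r in
             rng.integers(4, 25, 8)]
        )
        om = M.protrusion_index(_series(masks, pixel_size=ps, origin=origin), grid, sid)
        assert np.all(om.fractional_overlap <= om.max_possible_overlap + 1e-12)
        assert np.all(om.protrusion_index >= -1e-12)
        assert np.all(om.protrusion_index <= 1.0 + 1e-12)

    def test_monotone_in_distance_for_rigid_disk(self):
        grid, sid, spot, origin, ps = self._grid_and_spot_raster()
        h, w = spot.shape
        values = []
        for dc in range(0, 40, 4):
            cell = _disk_mask((h, w), (30, 30 + dc), 8)
            om = M.protrusion_index(_series(cell[None], pixel_size=ps, origin=origin),
                                    grid, sid)
            values.append(om.protrusion_index[0])
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_resolution_stability(self):
        # halving pixel size changes both metrics by < 2 %
        grid = build_spot_grid(10.0, 30.0, (0.0, 0.0, 90.0, 90.0))
        pos = np.column_stack([30.0 + 0.8 * np.arange(24), np.full(24, 30.0)])
        track = make_track(pos)
        vals = {}
        for ps in (0.5, 0.25):
            masks = render_mask_movie(track, cell_radius=5.0, pixel_size=ps,
                                      extent=(10.0, 10.0, 60.0, 50.0))
            se = M.mean_sampling_efficiency(masks, n_steps=20)
            om = M.protrusion_index(masks, grid, 5)
            vals[ps] = (se, float(om.protrusion_index.mean()))
        assert vals[0.5][0] == pytest.approx(vals[0.25][0], rel=0.02)
        assert vals[0.5][1] == pytest.approx(vals[0.25][1], rel=0.02)


class TestOverlapContour:
    def test_boundary_trace_values(self):
        grid, = [build_spot_grid(10.0, 30.0, (0.0, 0.0, 90.0, 90.0))]
        om = M.OverlapMetrics(
            frames=np.arange(2),
            cell_area=np.array([40.0, 40.0]),
            overlap_area=np.array([40.0, 40.0]),
            fractional_overlap=np.array([1.0, 1.0]),
            max_possible_overlap=np.array([1.0, 1.0]),
            protrusion_index=np.array([0.0, 0.0]),
            spot_area=80.0,
        )
        summary = M.overlap_contour([om, om], max_ratio=4.0)
        m_at = lambda r: np.interp(r, summary.trace_ratio, summary.trace_m)
        assert m_at(0.5) == pytest.approx(1.0)
        assert m_at(2.0) == pytest.approx(0.5, rel=1e-3)

    def test_stationary_in_spot_mass_at_full_overlap(self):
        grid = build_spot_grid(10.0, 30.0, (0.0, 0.0, 90.0, 90.0))
        track = make_track(np.tile(grid.centers[5], (3, 1)))
        masks = render_mask_movie(track, cell_radius=3.0, pixel_size=0.5,
                                  extent=(15.0, 15.0, 45.0, 45.0))
        om = M.protrusion_index(masks, grid, 5)
        summary = M.overlap_contour([om, om])
        assert np.all(summary.fractional_overlap == 1.0)
        assert np.all(summary.area_ratio < 1.0)

    def test_requires_two_cells(self):
        om = M.OverlapMetrics(
            frames=np.arange(1), cell_area=np.array([1.0]),
            overlap_area=np.array([1.0]), fractional_overlap=np.array([1.0]),
            max_possible_overlap=np.array([1.0]), protrusion_index=np.array([0.0]),
            spot_area=2.0,
        )
        with pytest.raises(ValueError, match=">= 2"):
            M.overlap_contour([om])

    def test_motile_population_lies_below_trace(self):
        # higher planted motility -> higher mean protrusion index
        grid = build_spot_grid(10.0, 30.0, (0.0, 0.0, 90.0, 90.0))

        def cohort_mean_index(dwell_syn, dwell_kin, n=4):
            vals = []
            for seed in range(n):
                params = TwoStateParams(seed=seed, n_frames=40,
                                        dwell_synapse=dwell_syn,
                                        dwell_kinapse=dwell_kin)
                track, _ = simulate_two_state_track(params)
                pos = track.positions - track.positions.mean(axis=0) + grid.centers[5]
                off = pos - grid.centers[5]
                r = np.linalg.norm(off, axis=1)
                cap = 7.0
                pos = grid.centers[5] + off * np.where(r > cap, cap / np.maximum(r, 1e-9), 1.0)[:, None]
                clipped = make_track(pos)
                masks = render_mask_movie(clipped, cell_radius=4.0, pixel_size=0.5,
                                          extent=(15.0, 15.0, 45.0, 45.0))
                om = M.protrusion_index(masks, grid, 5)
                vals.append(om.protrusion_index.mean())
            return np.mean(vals)

        motile = cohort_mean_index(dwell_syn=600.0, dwell_kin=6000.0)
        confined = cohort_mean_index(dwell_syn=6000.0, dwell_kin=600.0)
        assert motile > confined
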