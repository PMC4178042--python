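"""Filter cascade, boundary detection, snake refinement, manual corrections."""

import numpy as np
import pytest

import octfundus as of
from octfundus.segmentation import (
    BoundaryTrace,
    SnakeParams,
    denoise,
    detect_boundaries,
    gradient_response,
    layer_response,
    refine_snakes,
    snake_energy,
    apply_corrections,
)
from conftest import flat_band_image


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 7.0)
        np.testing.assert_array_equal(denoise(img), img)

    def test_impulse_removed(self):
        img = np.zeros((11, 11))
        img[5, 5] = 100.0
        assert denoise(img)[5, 5] == 0.0

    def test_center_of_3x3_becomes_median(self):
        img = np.arange(1.0, 10.0).reshape(3, 3)
        assert denoise(img)[1, 1] == 5.0

    def test_oversized_window_raises(self):
        with pytest.raises(ValueError):
            denoise(np.zeros((2, 2)), size=5)


class TestLayerResponse:
    def test_uniform_image_gives_zero(self):
        assert layer_response(np.full((20, 20), 3.0)).max() == pytest.approx(0.0, abs=1e-12)

    def test_bright_band_peaks_on_band(self):
        img = flat_band_image(band_row=30, thickness=3)
        resp = layer_response(img)
        peak_rows = np.argmax(resp, axis=0)
        assert np.all(np.abs(peak_rows - 31) <= 1)

    def test_orientation_selectivity(self):
        horiz = np.full((40, 40), 0.1)
        horiz[20, :] = 0.9
        vert = horiz.T.copy()
        assert layer_response(vert).max() < layer_response(horiz).max()


class TestGradientResponse:
    def test_uniform_image_gives_zero(self):
        np.testing.assert_array_equal(gradient_response(np.full((10, 10), 2.0)), 0.0)

    def test_dark_to_bright_step_positive_peak_at_step(self):
        img = np.full((40, 10), 0.1)
        img[20:, :] = 0.9
        g = gradient_response(img)
        col = g[:, 5]
        assert col.max() > 0
        assert abs(int(np.argmax(col)) - 20) <= 1

    def test_inverted_step_antisymmetric(self):
        img = np.full((40, 10), 0.1)
        img[20:, :] = 0.9
        np.testing.assert_allclose(gradient_response(img[::-1]), -gradient_response(img)[::-1])


class TestDetectBoundaries:
    def test_noiseless_phantom_recovered_exactly(self, sphere_set_clean):
        scan_set, truth = sphere_set_clean
        for scan, t in zip(scan_set.scans, truth):
            ilm, nfl, bm = detect_boundaries(scan.pixels)
            assert bm.valid.all() and ilm.valid.all()
            np.testing.assert_array_equal(bm.depth_px, t["bm_rows"])
            np.testing.assert_array_equal(ilm.depth_px, t["ilm_rows"])

    def test_nfl_boundary_posterior_to_ilm(self, sphere_set_clean):
        scan_set, _ = sphere_set_clean
        ilm, nfl, bm = detect_boundaries(scan_set.scans[0].pixels)
        ok = nfl.valid & ilm.valid
        assert np.all(nfl.depth_px[ok] > ilm.depth_px[ok])
        assert np.all(bm.depth_px[ok] > nfl.depth_px[ok])

    def test_speckle_rmse_within_two_rows(self, staph_set_speckle):
        scan_set, truth = staph_set_speckle
        errs = []
        for scan, t in zip(scan_set.scans, truth):
            _, _, bm = detect_boundaries(scan.pixels)
            errs.append(bm.depth_px[bm.valid] - t["bm_rows"][bm.valid])
        e = np.concatenate(errs)
        assert np.sqrt(np.mean(e**2)) <= 2.0

    def test_bandless_columns_marked_invalid(self, sphere_model):
        traces = of.sample_radial_traces(sphere_model, n_angles=1, step_um=20.0)
        scan, bm_rows, _ = of.render_bscan(
            traces[0][1], speckle_sigma=0.15, seed=3, band_free_columns=[(0, 30)]
        )
        _, _, bm = detect_boundaries(scan.pixels)
        assert not bm.valid[:30].any()
        assert bm.valid[40:].all()

    def test_masked_columns_skipped(self, sphere_set_clean):
        scan_set, _ = sphere_set_clean
        scan = scan_set.scans[0]
        mask = np.ones(scan.n_cols, bool)
        mask[:50] = False
        _, _, bm = detect_boundaries(scan.pixels, column_valid=mask)
        assert not bm.valid[:50].any() and bm.valid[50:].all()

    def test_featureless_image_raises(self):
        with pytest.raises(of.SegmentationError):
            detect_boundaries(np.full((50, 30), 5.0))

    def test_left_right_flip_equivariance(self, staph_set_speckle):
        """Detection has no lateral asymmetry: flipping the image flips traces."""
        scan_set, _ = staph_set_speckle
        img = scan_set.scans[2].pixels
        _, _, bm = detect_boundaries(img)
        _, _, bm_f = detect_boundaries(img[:, ::-1])
        np.testing.assert_array_equal(bm_f.depth_px, bm.depth_px[::-1])
        np.testing.assert_array_equal(bm_f.valid, bm.valid[::-1])


class TestSnakes:
    def test_straight_trace_on_straight_band_is_fixed_point(self):
        img = flat_band_image(band_row=30, thickness=3)
        n = img.shape[1]
        trace = BoundaryTrace(np.full(n, 31.0), np.ones(n, bool), np.zeros(n, bool))
        refined = refine_snakes(trace, img)
        np.testing.assert_allclose(refined.depth_px, 31.0, atol=0.05)

    def test_zigzag_converges_onto_band(self):
        img = flat_band_image(n_rows=80, n_cols=60, band_row=40, thickness=3)
        n = img.shape[1]
        zigzag = 41.0 + 4.0 * (-1.0) ** np.arange(n)
        trace = BoundaryTrace(zigzag, np.ones(n, bool), np.zeros(n, bool))
        refined = refine_snakes(trace, img, SnakeParams(iterations=500))
        assert np.all(np.abs(refined.depth_px - 41.0) <= 1.0)

    def test_energy_never_increases(self, staph_set_speckle):
        scan_set, _ = staph_set_speckle
        img = scan_set.scans[0].pixels
        _, _, bm = detect_boundaries(img)
        params = SnakeParams()
        refined = refine_snakes(bm, img, params)
        assert snake_energy(refined, img, params) <= snake_energy(bm, img, params) + 1e-9

    def test_manual_columns_are_pinned(self):
        img = flat_band_image(n_rows=80, n_cols=60, band_row=40, thickness=3)
        n = img.shape[1]
        depth = np.full(n, 41.0)
        manual = np.zeros(n, bool)
        depth[30] = 10.0  # pinned far off the band
        manual[30] = True
        trace = BoundaryTrace(depth, np.ones(n, bool), manual)
        refined = refine_snakes(trace, img)
        assert refined.depth_px[30] == 10.0
        assert refined.manual[30]


class TestApplyCorrections:
    def test_empty_list_is_identity(self):
        trace = BoundaryTrace(np.arange(5.0), np.ones(5, bool), np.zeros(5, bool))
        out = apply_corrections(trace, [])
        np.testing.assert_array_equal(out.depth_px, trace.depth_px)
        assert not out.manual.any()

    def test_ten_replots_set_ten_manual_flags(self):
        n = 50
        trace = BoundaryTrace(np.zeros(n), np.ones(n, bool), np.zeros(n, bool))
        corr = [(c, 12.0) for c in range(0, 20, 2)]
        out = apply_corrections(trace, corr)
        assert out.manual.sum() == 10
        assert np.all(out.depth_px[list(range(0, 20, 2))] == 12.0)
        np.testing.assert_array_equal(out.depth_px[1:20:2], 0.0)

    def test_correction_revalidates_invalid_column(self):
        valid = np.ones(10, bool)
        valid[4] = False
        trace = BoundaryTrace(np.zeros(10), valid, np.zeros(10, bool))
        out = apply_corrections(trace, [(4, 7.5)])
        assert out.valid[4] and out.manual[4] and out.depth_px[4] == 7.5

    def test_out_of_range_column_raises(self):
        trace = BoundaryTrace(np.zeros(5), np.ones(5, bool), np.zeros(5, bool))
        with pytest.raises(IndexError):
            apply_corrections(trace, [(9, 1.0)])
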