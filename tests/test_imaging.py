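"""Segmentation, tracking and quantification of plate time-lapses."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from microhet import imaging as im
from microhet.growth import RespirationModel


def _stack_from(frames, interval=10.0, center=None, radius=None):
    frames = np.asarray(frames, dtype=float)
    h, w = frames.shape[1:3]
    if center is None:
        center = ((h - 1) / 2, (w - 1) / 2)
    if radius is None:
        radius = min(h, w) / 2 - 1
    return im.ImageStack(frames, np.arange(frames.shape[0]) * interval,
                         center, radius)


class TestTemporalStd:
    def test_constant_stack_is_zero(self):
        stack = _stack_from(np.full((4, 32, 32, 3), 0.3))
        assert np.all(im.project_temporal_std(stack) == 0.0)

    def test_alternating_pixel_population_sd(self):
        frames = np.zeros((6, 16, 16, 3))
        frames[1::2, 5, 7, :] = 1.0  # alternates 0/1 across 6 frames
        stack = _stack_from(frames)
        std = im.project_temporal_std(stack)
        assert std[5, 7] == pytest.approx(0.5)  # population SD of 0,1,0,1,0,1
        assert std[0, 0] == 0.0

    def test_invariant_to_frame_order(self, rng):
        frames = rng.random((5, 20, 20, 3))
        s1 = im.project_temporal_std(_stack_from(frames))
        s2 = im.project_temporal_std(_stack_from(frames[::-1]))
        np.testing.assert_allclose(s1, s2)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            im.project_temporal_std(_stack_from(np.zeros((1, 16, 16, 3))))


class TestThresholdPlate:
    def test_separates_bimodal_populations(self):
        raster = np.full((40, 40), 0.1)
        bright = np.zeros((40, 40), bool)
        bright[10:20, 10:20] = True
        raster[bright] = 0.9
        mask = np.ones((40, 40), bool)
        fg = im.threshold_plate(raster, mask)
        assert np.array_equal(fg, bright)

    def test_matches_bruteforce_otsu_oracle(self, rng):
        raster = np.full((40, 40), 0.1) + rng.normal(0, 0.005, (40, 40))
        bright = np.zeros((40, 40), bool)
        bright[10:20, 10:20] = True
        raster[bright] = 0.9 + rng.normal(0, 0.005, bright.sum())
        mask = np.ones((40, 40), bool)
        fg = im.threshold_plate(raster, mask)
        # oracle: exhaustive 256-bin between-class-variance maximization
        hist, edges = np.histogram(raster[mask], bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best = None
        for i in range(1, 256):
            w0, w1 = hist[:i].sum(), hist[i:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:i] * centers[:i]).sum() / w0
            m1 = (hist[i:] * centers[i:]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
            if best is None or var > best[0]:
                best = (var, centers[i - 1])
        np.testing.assert_array_equal(fg, (raster > best[1]) & mask)

    def test_mask_excluding_bright_pixels(self, rng):
        raster = np.full((30, 30), 0.1) + rng.normal(0, 0.01, (30, 30))
        raster[0:5, 0:5] = 0.9
        mask = np.ones((30, 30), bool)
        mask[0:5, 0:5] = False
        fg = im.threshold_plate(raster, mask)
        # only noise remains: Otsu splits noise, no true foreground block
        assert not fg[0:5, 0:5].any()

    def test_constant_raster_raises(self):
        with pytest.raises(im.DegenerateThresholdError):
            im.threshold_plate(np.full((20, 20), 0.5), np.ones((20, 20), bool))

    def test_inversion_symmetry(self, rng):
        raster = np.where(rng.random((30, 30)) > 0.7, 0.9, 0.1)
        mask = np.ones((30, 30), bool)
        fg = im.threshold_plate(raster, mask)
        fg_inv = im.threshold_plate(1.0 - raster, mask)
        assert np.array_equal(fg, ~fg_inv)


class TestSegmentColonies:
    def test_two_disjoint_disks(self):
        std = np.zeros((80, 80))
        for center in [(20, 20), (55, 60)]:
            rr, cc = draw_disk(center, 8)
            d = np.hypot(rr - center[0], cc - center[1])
            std[rr, cc] = 0.5 * (1 - d / 10)  # peaked at the center
        mask = std > 0.05
        labels = im.segment_colonies(std, mask)
        assert labels.max() == 2
        from skimage.measure import regionprops
        cents = sorted(tuple(np.round(r.centroid)) for r in regionprops(labels))
        assert np.hypot(cents[0][0] - 20, cents[0][1] - 20) <= 2
        assert np.hypot(cents[1][0] - 55, cents[1][1] - 60) <= 2

    def test_merged_disks_split_by_watershed(self):
        std = np.zeros((60, 100))
        for center in [(30, 35), (30, 65)]:
            rr, cc = draw_disk(center, 17)
            d = np.hypot(rr - center[0], cc - center[1])
            std[rr, cc] = np.maximum(std[rr, cc], 0.6 * (1 - d / 19))
        mask = std > 0.02  # single connected blob with two std maxima
        from skimage.measure import label
        assert label(mask).max() == 1
        labels = im.segment_colonies(std, mask)
        assert labels.max() == 2

    def test_empty_mask_zero_labels(self):
        labels = im.segment_colonies(np.zeros((30, 30)), np.zeros((30, 30), bool))
        assert labels.max() == 0


class TestTracking:
    def _label_frames(self, positions_per_frame, shape=(64, 64), radius=4):
        out = []
        for positions in positions_per_frame:
            lab = np.zeros(shape, dtype=np.int32)
            for i, c in enumerate(positions, start=1):
                rr, cc = draw_disk(c, radius, shape=shape)
                lab[rr, cc] = i
            out.append(lab)
        return out

    def test_stationary_colonies_single_tracks(self):
        frames = self._label_frames([[(20, 20), (40, 45)]] * 5)
        tracks = im.track_colonies(frames)
        assert len(tracks) == 2
        for tr in tracks:
            assert np.allclose(tr.centroids, tr.centroids[0])
            assert tr.n_detected == 5

    def test_late_appearing_colony_zero_area_before_detection(self):
        frames = self._label_frames([[(20, 20)]] * 3 + [[(20, 20), (45, 45)]] * 3)
        tracks = im.track_colonies(frames)
        assert len(tracks) == 2
        late = max(tracks, key=lambda t: t.colony_id)
        assert np.all(late.areas[:3] == 0)
        assert np.all(late.areas[3:] > 0)

    def test_swap_beyond_gate_terminates_tracks(self):
        # two colonies swap positions in one step; displacement far
        # exceeds the gate, so identities must not be exchanged
        a, b = (10, 10), (50, 50)
        frames = self._label_frames([[a, b], [a, b], [b, a], [b, a]])
        tracks = im.track_colonies(frames, max_displacement=8.0)
        for tr in tracks:
            detected = tr.centroids[~np.isnan(tr.centroids[:, 0])]
            assert np.ptp(detected, axis=0).max() <= 1e-9  # no track moved

    def test_deterministic(self, small_plate):
        stack, _ = small_plate
        t1, _ = im.extract_colony_tracks(stack)
        t2, _ = im.extract_colony_tracks(stack)
        assert len(t1) == len(t2)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.areas, b.areas)


class TestFilterArtifacts:
    def _track(self, areas, centroid=(30, 30)):
        n = len(areas)
        return im.ColonyTrack(
            colony_id=0, frame_times=np.arange(n, dtype=float),
            centroids=np.tile(centroid, (n, 1)).astype(float),
            areas=np.asarray(areas, dtype=float),
            mean_rgb=np.full((n, 3), 0.5))

    def test_rim_track_removed(self):
        tr = self._track([5, 6, 7, 8, 9, 10], centroid=(5, 50))
        kept = im.filter_artifacts([tr], im.QCConfig(),
                                   plate_center=(50, 50), plate_radius=48)
        assert kept == []

    def test_growing_interior_track_retained(self):
        tr = self._track([5, 6, 8, 11, 15, 20], centroid=(50, 50))
        kept = im.filter_artifacts([tr], im.QCConfig(),
                                   plate_center=(50, 50), plate_radius=48)
        assert len(kept) == 1

    def test_shrinking_track_removed(self):
        tr = self._track([50, 52, 55, 20, 21, 22])
        kept = im.filter_artifacts([tr], im.QCConfig())
        assert kept == []

    def test_permissive_config_is_identity(self):
        tracks = [self._track([1, 1]), self._track([100, 5], centroid=(1, 1))]
        qc = im.QCConfig(min_frames=None, min_final_area=None,
                         max_final_area=None, edge_margin=None,
                         max_rel_area_drop=None)
        assert im.filter_artifacts(tracks, qc) == tracks


class TestPhenotypeInputs:
    def test_distance_to_center(self, small_plate):
        stack, _ = small_plate
        n = stack.n_frames
        for offset, expected in [((0.0, 0.0), 0.0), ((0.0, 30.0), 30.0)]:
            c = (stack.plate_center[0] + offset[0],
                 stack.plate_center[1] + offset[1])
            tr = im.ColonyTrack(0, stack.frame_times,
                                np.tile(c, (n, 1)).astype(float),
                                np.full(n, 10.0), np.full((n, 3), 0.5))
            series = im.extract_phenotype_inputs(tr, stack)
            assert series["dist_center_px"].iloc[0] == pytest.approx(expected)

    def test_red_slope_recovers_alpha(self, small_plate):
        """End-to-end red-channel quantification: the max-slope fit on a
        tracked colony's mean-red trace recovers the simulated alpha."""
        stack, gt = small_plate
        tracks, series = im.extract_colony_tracks(stack)
        truth = gt.colonies
        recovered = 0
        for tr in tracks:
            r, c = tr.final_centroid
            d = np.hypot(truth.center_row - r, truth.center_col - c)
            j = int(d.idxmin())
            if d[j] > 3:
                continue
            s = series[tr.colony_id]
            ok = s["mean_red"].notna() & (s["time_h"] >= truth.loc[j, "red_onset_h"])
            if ok.sum() < 12:
                continue
            res = RespirationModel(s.loc[ok, "time_h"],
                                   s.loc[ok, "mean_red"]).fit()
            if abs(res.alpha - truth.loc[j, "alpha"]) / truth.loc[j, "alpha"] < 0.05:
                recovered += 1
        assert recovered >= max(1, len(tracks) // 2)

    def test_interpolation_of_missing_frames(self, small_plate):
        stack, _ = small_plate
        n = stack.n_frames
        areas = np.linspace(10, 100, n)
        areas[n // 2] = 0.0  # lost in one frame
        tr = im.ColonyTrack(0, stack.frame_times,
                            np.tile(stack.plate_center, (n, 1)).astype(float),
                            areas, np.full((n, 3), 0.5))
        series = im.extract_phenotype_inputs(tr, stack)
        assert series["interpolated"].iloc[n // 2]
        assert series["area_px2"].iloc[n // 2] == pytest.approx(
            np.linspace(10, 100, n)[n // 2], rel=1e-6)


class TestImageStackValidation:
    def test_plate_must_fit_raster(self):
        with pytest.raises(ValueError):
            im.ImageStack(np.zeros((2, 32, 32, 3)), np.array([0.0, 10.0]),
                          (16, 16), 40.0)

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            im.ImageStack(np.zeros((2, 32, 32, 3)), np.array([10.0, 0.0]),
                          (16, 16), 10.0)
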