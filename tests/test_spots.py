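"""Spot localization, segmentation, per-cell counting, and TS tracking."""

import numpy as np
import pandas as pd
import pytest

from burstkit import (
    SegmentationMasks,
    Spot,
    count_and_classify,
    localize_spots,
    render_image,
    segment,
    track_ts,
)


def _random_separated_points(rng, n, lo, hi, min_sep):
    pts = []
    for p in rng.uniform(lo, hi, size=(10 * n, 2)):
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) > min_sep for q in pts):
            pts.append(tuple(p))
        if len(pts) == n:
            break
    return pts


class TestSegmentation:
    def test_blank_image_has_no_labels(self):
        f = render_image([], shape=(64, 64), background=5.0)
        m = segment(f)
        assert m.empty
        assert m.nuclei.max() == 0

    def test_border_touching_and_small_nuclei_removed(self):
        nuclei = [
            (20, 20, 8, 10, 40),
            (20, 60, 9, 8, 40),
            (60, 30, 8, 8, 40),
            (60, 70, 10, 9, 40),
            (2, 100, 8, 8, 40),  # touches the top border
        ]
        f = render_image([], shape=(128, 128), background=10.0, nuclei=nuclei)
        m = segment(f, min_area=50)
        assert m.nuclei.max() == 4

        tiny = [(30, 30, 2, 2, 40), (80, 80, 9, 9, 40)]
        f2 = render_image([], shape=(128, 128), background=10.0, nuclei=tiny)
        m2 = segment(f2, min_area=50)
        assert m2.nuclei.max() == 1

    def test_watershed_cells_contain_their_nuclei(self):
        cells = [(32, 32, 22, 24, 15), (90, 90, 24, 22, 15)]
        nucl = [(32, 32, 9, 9, 40), (90, 90, 9, 9, 40)]
        f = render_image([], shape=(128, 128), background=5.0, nuclei=nucl, cells=cells)
        m = segment(f, min_area=50, cell_threshold=12.0)
        assert m.n_cells == 2
        for lab in (1, 2):
            nuc = m.nuclei == lab
            assert nuc.sum() > 0
            assert np.all(m.cells[nuc] == lab)


class TestLocalization:
    def test_blank_image_yields_no_spots(self):
        f = render_image([], shape=(64, 64), background=5.0)
        assert localize_spots(f) == []

    def test_single_noiseless_spot_subpixel_accuracy(self):
        f = render_image([(20.3, 41.7, 50.0)], shape=(64, 64), psf_sigma=1.3, background=10.0)
        spots = localize_spots(f, detect_sigma=1.3)
        assert len(spots) == 1
        s = spots[0]
        assert np.hypot(s.row - 20.3, s.col - 41.7) < 0.05
        assert s.intensity == pytest.approx(50.0 * 2 * np.pi * 1.3**2, rel=0.02)

    def test_localization_bias_below_five_hundredths_px(self, rng):
        errs = []
        for _ in range(20):
            r0 = 16 + rng.uniform(-0.5, 0.5)
            c0 = 16 + rng.uniform(-0.5, 0.5)
            f = render_image([(r0, c0, 80.0)], shape=(33, 33), psf_sigma=1.3, background=5.0)
            (s,) = localize_spots(f, detect_sigma=1.3)
            errs.append((s.row - r0, s.col - c0))
        bias = np.abs(np.mean(errs, axis=0))
        assert np.all(bias < 0.05)

    def test_fifty_spots_at_snr10_perfect_recall_and_precision(self):
        rng = np.random.default_rng(0)
        pts = _random_separated_points(rng, 50, 8, 119, 6.0)
        f = render_image(
            [(r, c, 60.0) for r, c in pts],
            shape=(128, 128),
            psf_sigma=1.3,
            background=10.0,
            shot_noise=True,
            read_noise_sd=2.0,
            seed=1,
        )
        spots = localize_spots(f, detect_sigma=1.3)
        assert len(spots) == 50
        matched = sum(
            1
            for r, c in pts
            if min(np.hypot(r - s.row, c - s.col) for s in spots) <= 0.5
        )
        assert matched == 50


class TestCounting:
    def _masks(self):
        nuclei = np.zeros((64, 64), int)
        cells = np.zeros((64, 64), int)
        cells[8:56, 8:56] = 1
        nuclei[24:40, 24:40] = 1
        return SegmentationMasks(nuclei=nuclei, cells=cells)

    def test_ts_rule_arithmetic_on_constructed_field(self):
        """30 unit spots plus one 12-unit nuclear spot: one TS, 30 cytoplasmic."""
        rng = np.random.default_rng(2)
        spots = [
            Spot(row=r, col=c, intensity=1.0, background=0, amplitude=1.0)
            for r, c in _random_separated_points(rng, 30, 9, 22, 1.5)
        ]
        spots.append(Spot(row=30, col=30, intensity=12.0, background=0, amplitude=12.0))
        cells, spots_df = count_and_classify(spots, self._masks(), ts_rule=2.0)
        row = cells.iloc[0]
        assert row.n_ts == 1
        assert row.n_cytoplasmic == 30
        assert row.mrna_count == 31
        # TS counted as intensity-equivalent units on request
        cells_u, _ = count_and_classify(spots, self._masks(), ts_rule=2.0, ts_as_units=True)
        assert cells_u.iloc[0].mrna_count == 30 + 12

    def test_spot_outside_cells_excluded(self):
        spots = [Spot(row=2.0, col=2.0, intensity=1.0, background=0, amplitude=1.0)]
        cells, spots_df = count_and_classify(spots, self._masks())
        assert cells.iloc[0].mrna_count == 0
        assert spots_df.iloc[0].cell_label == 0

    def test_no_bright_nuclear_spot_means_no_ts(self):
        spots = [
            Spot(row=30, col=30, intensity=1.0, background=0, amplitude=1.0),
            Spot(row=10, col=10, intensity=1.1, background=0, amplitude=1.1),
        ]
        cells, _ = count_and_classify(spots, self._masks(), ts_rule=2.0)
        assert cells.iloc[0].n_ts == 0

    def test_counts_table_round_trips_into_fitter_format(self, tmp_path):
        from burstkit.io import read_counts_csv, write_counts_csv

        cells = pd.DataFrame({"cell_id": [1, 2], "mrna_count": [30, 12]})
        cells["dose_uM"] = 12.5
        cells["clone"] = "c1"
        path = tmp_path / "counts.csv"
        write_counts_csv(cells, path)
        back = read_counts_csv(path)
        assert list(back.mrna_count) == [30, 12]
        assert list(back.dose_uM) == [12.5, 12.5]

    def test_segmentation_and_counting_reproduce_truth_exactly(self):
        """Full image -> counts chain is exact at SNR ~10 on rendered fields."""
        rng = np.random.default_rng(7)
        for trial in range(8):
            n_spots = int(rng.integers(5, 15))
            pts = _random_separated_points(rng, n_spots, 20, 100, 7.0)
            f = render_image(
                [(r, c, 60.0) for r, c in pts],
                shape=(128, 128),
                psf_sigma=1.3,
                background=5.0,
                cells=[(60, 60, 50, 52, 12)],
                nuclei=[(60, 60, 14, 15, 30)],
                shot_noise=True,
                read_noise_sd=1.0,
                seed=100 + trial,
            )
            masks = segment(f, min_area=50, cell_threshold=10.0)
            spots = localize_spots(f, detect_sigma=1.3)
            cells, _ = count_and_classify(spots, masks)
            assert cells.iloc[0].mrna_count == n_spots


class TestTracking:
    def _spot(self, r, c, i=10.0):
        return Spot(row=r, col=c, intensity=i, background=0, amplitude=i)

    def test_stationary_spot_gives_single_full_track(self):
        frames = [[self._spot(20, 20)] for _ in range(10)]
        tracks = track_ts(frames, max_jump=3.0, max_gap=2)
        assert len(tracks) == 1
        assert np.all(tracks[0].intensity == 10.0)

    def test_gap_within_limit_bridged_with_zero_intensity(self):
        frames = [[self._spot(20, 20)] for _ in range(12)]
        for f in (5, 6, 7):
            frames[f] = []
        tracks = track_ts(frames, max_jump=3.0, max_gap=3)
        assert len(tracks) == 1
        assert np.all(tracks[0].intensity[[5, 6, 7]] == 0.0)
        assert tracks[0].intensity[8] == 10.0

    def test_gap_beyond_limit_starts_new_track(self):
        frames = [[self._spot(20, 20)] for _ in range(12)]
        for f in (4, 5, 6, 7):
            frames[f] = []
        tracks = track_ts(frames, max_jump=3.0, max_gap=2)
        assert len(tracks) == 2

    def test_distant_spots_never_merged(self):
        frames = [
            [self._spot(10, 10), self._spot(50, 50)] for _ in range(8)
        ]
        tracks = track_ts(frames, max_jump=3.0, max_gap=2)
        assert len(tracks) == 2

    def test_assignment_minimizes_total_displacement(self):
        # two spots swap-adjacent: optimal assignment keeps identities
        frames = [
            [self._spot(20, 20), self._spot(20, 24)],
            [self._spot(20, 21), self._spot(20, 25)],
        ]
        tracks = track_ts(frames, max_jump=3.0, max_gap=1)
        assert len(tracks) == 2
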