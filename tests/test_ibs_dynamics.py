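"""ROI pairing, FOI selection and sliding-window segmentation."""

import numpy as np
import pytest

from dibs.ibs_dynamics import (
    EmptyFOIError,
    FOIBand,
    ROIPairTable,
    build_roi_pair_table,
    channels_to_roi,
    n_pair_combinations,
    pair_index,
    select_foi_from_profiles,
    window_ibs,
)
from dibs.synthgen import DyadRecording


def make_table(z: np.ndarray, annotations, fs=10.0, freqs=None) -> ROIPairTable:
    n_pairs = z.shape[0]
    n_rois = int((np.sqrt(8 * n_pairs + 1) - 1) / 2)
    return ROIPairTable(
        dyad_id="t",
        n_rois=n_rois,
        z=z.astype(np.float32),
        frequencies=freqs if freqs is not None else np.linspace(0.5, 0.01, z.shape[1]),
        times=np.arange(z.shape[2]) / fs,
        annotations=annotations,
        sampling_rate=fs,
    )


class TestChannelsToRoi:
    def _rec(self, hbo, channel_roi, rois):
        channels = list(channel_roi)
        return DyadRecording(
            dyad_id="d",
            hbo={1: hbo.copy(), 2: hbo.copy()},
            hbr={1: -hbo.copy(), 2: -hbo.copy()},
            channels=channels,
            channel_roi=channel_roi,
            rois=rois,
            sampling_rate=10.0,
            annotations=[("rest", 0.0, hbo.shape[1] / 10.0)],
        )

    def test_one_channel_per_roi_is_identity(self):
        x = np.random.default_rng(0).standard_normal((2, 100))
        rec = self._rec(x, {"a": "R1", "b": "R2"}, ["R1", "R2"])
        out = channels_to_roi(rec)
        np.testing.assert_array_equal(out[1], x)

    def test_constant_channels_average(self):
        x = np.vstack([np.full(50, 1.0), np.full(50, 3.0), np.full(50, 5.0)])
        rec = self._rec(x, {"a": "R1", "b": "R1", "c": "R1"}, ["R1"])
        out = channels_to_roi(rec)
        np.testing.assert_allclose(out[1][0], 3.0)

    def test_duplicate_channels_equal_either(self):
        x = np.random.default_rng(1).standard_normal((1, 80))
        rec = self._rec(np.vstack([x, x]), {"a": "R1", "b": "R1"}, ["R1"])
        out = channels_to_roi(rec)
        np.testing.assert_allclose(out[1][0], x[0])


class TestPairTable:
    @pytest.mark.parametrize("n_rois,expected", [(13, 91), (2, 3), (4, 10)])
    def test_combination_counts(self, n_rois, expected):
        assert n_pair_combinations(n_rois) == expected
        assert len(pair_index(n_rois)) == expected

    def test_reciprocal_averaging_participant_swap_invariant(self, rng):
        z = rng.standard_normal((3, 3, 5, 7)) ** 2
        a = build_roi_pair_table(z, 3)
        b = build_roi_pair_table(np.swapaxes(z, 0, 1), 3)
        np.testing.assert_allclose(a.z, b.z, rtol=1e-6)

    def test_diagonal_entries_are_single_pairings(self, rng):
        z = rng.standard_normal((2, 2, 4, 6)) ** 2
        table = build_roi_pair_table(z, 2)
        np.testing.assert_allclose(table.z[0], z[0, 0], rtol=1e-6)  # pair (0, 0)
        np.testing.assert_allclose(table.z[1], 0.5 * (z[0, 1] + z[1, 0]), rtol=1e-6)

    def test_missing_pairing_reported(self):
        z = np.ones((2, 2, 3, 4))
        z[1, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_roi_pair_table(z, 2)


class TestSelectFOI:
    def _profiles(self, n_dyads, n_pairs, n_scales, boost_scales=(), boost=1.0, seed=0):
        r = np.random.default_rng(seed)
        rest = 0.5 + 0.05 * r.standard_normal((n_dyads, n_pairs, n_scales))
        task = 0.5 + 0.05 * r.standard_normal((n_dyads, n_pairs, n_scales))
        for s in boost_scales:
            task[:, 0, s] += boost
        return task, rest

    def test_recovers_boosted_scales(self):
        freqs = np.geomspace(0.7, 0.01, 40)
        task, rest = self._profiles(10, 5, 40, boost_scales=range(10, 16))
        foi = select_foi_from_profiles(task, rest, freqs)
        assert not foi.empty
        assert set(foi.scale_idx) == set(range(10, 16))
        assert foi.f_lo == pytest.approx(freqs[15])
        assert foi.f_hi == pytest.approx(freqs[10])

    def test_null_gives_empty_foi(self):
        freqs = np.geomspace(0.7, 0.01, 40)
        empty = 0
        for seed in range(50):
            task, rest = self._profiles(8, 5, 40, seed=seed)
            if select_foi_from_profiles(task, rest, freqs).empty:
                empty += 1
        assert empty >= 48  # >= 95% of null runs

    def test_looser_threshold_selects_superset(self):
        freqs = np.geomspace(0.7, 0.01, 40)
        task, rest = self._profiles(8, 5, 40, boost_scales=range(12, 18), boost=0.3)
        strict = select_foi_from_profiles(task, rest, freqs, p_threshold=5e-6)
        loose = select_foi_from_profiles(task, rest, freqs, p_threshold=0.05)
        assert set(strict.scale_idx) <= set(loose.scale_idx)

    def test_out_of_range_scales_never_selected(self):
        freqs = np.geomspace(2.0, 0.001, 40)  # extends beyond 0.01-0.7 Hz
        task, rest = self._profiles(10, 3, 40, boost_scales=range(40), boost=1.0)
        foi = select_foi_from_profiles(task, rest, freqs)
        assert np.all(freqs[foi.scale_idx] >= 0.01) and np.all(freqs[foi.scale_idx] <= 0.7)

    def test_too_few_dyads_rejected(self):
        task, rest = self._profiles(2, 3, 10)
        with pytest.raises(ValueError, match=">= 3 dyads"):
            select_foi_from_profiles(task, rest, np.linspace(0.7, 0.01, 10))


class TestWindowing:
    def _foi(self, n_scales):
        return FOIBand(0.1, 0.19, np.arange(n_scales), np.array([]), np.array([]), 5e-6, 5)

    @pytest.mark.parametrize(
        "task_secs,wl,step,expected",
        [((240.0, 240.0), 10.0, 1.0, 471), ((10.0,), 10.0, 1.0, 1), ((20.0,), 5.0, 5.0, 4)],
    )
    def test_window_counts(self, task_secs, wl, step, expected, rng):
        ann, t = [], 0.0
        for i, d in enumerate(task_secs):
            ann.append((f"task{chr(65 + i)}", t, t + d))
            t += d
        n = int(t * 10)
        z = rng.standard_normal((3, 4, n)).astype(np.float32) ** 2
        series = window_ibs(make_table(z, ann), self._foi(4), wl, step)
        assert series.n_windows == expected

    def test_window_values_are_scale_time_means(self, rng):
        ann = [("taskA", 0.0, 20.0)]
        z = rng.standard_normal((3, 4, 200)) ** 2
        series = window_ibs(make_table(z, ann), self._foi(4), 10.0, 5.0)
        expected = z[:, :, :100].mean(axis=(1, 2))
        np.testing.assert_allclose(
            [series.windows[0][0, 0], series.windows[0][0, 1], series.windows[0][1, 1]],
            expected,
            rtol=1e-5,
        )

    def test_task_labels_majority_with_tie_to_earlier(self, rng):
        ann = [("taskA", 0.0, 15.0), ("taskB", 15.0, 30.0)]
        z = np.abs(rng.standard_normal((3, 2, 300))).astype(np.float32)
        series = window_ibs(make_table(z, ann), self._foi(2), 10.0, 1.0)
        assert series.task_labels[0] == "taskA"
        assert series.task_labels[-1] == "taskB"
        # window starting at 10 s spans 10-20 s: 5 s in each task -> earlier wins
        assert series.task_labels[10] == "taskA"
        assert series.task_labels[11] == "taskB"

    def test_window_longer_than_task_rejected(self, rng):
        ann = [("taskA", 0.0, 5.0)]
        z = np.abs(rng.standard_normal((3, 2, 50)))
        with pytest.raises(ValueError, match="longer than task"):
            window_ibs(make_table(z, ann), self._foi(2), 10.0, 1.0)

    def test_empty_foi_halts(self, rng):
        ann = [("taskA", 0.0, 20.0)]
        z = np.abs(rng.standard_normal((3, 2, 200)))
        empty = FOIBand(np.nan, np.nan, np.array([], dtype=int), np.array([]), np.array([]), 5e-6, 5)
        with pytest.raises(EmptyFOIError):
            window_ibs(make_table(z, ann), empty, 10.0, 1.0)

    def test_constant_signal_windowing_commutes_with_averaging(self):
        ann = [("taskA", 0.0, 30.0)]
        z = np.full((3, 4, 300), 0.7, dtype=np.float32)
        series = window_ibs(make_table(z, ann), self._foi(4), 10.0, 1.0)
        np.testing.assert_allclose(series.windows, 0.7, rtol=1e-6)
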