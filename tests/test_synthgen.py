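"""Synthetic cohort generator: state sequences, signals, behaviour logs."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from dibs.behavior import compute_ioc
from dibs.coherence import WaveletSpec, wavelet_coherence
from dibs.synthgen import (
    SimConfig,
    default_state_topologies,
    generate_behavior,
    generate_dyad_recording,
    generate_state_sequence,
)

SHORT_PLAN = (("rest", 60.0), ("taskA", 150.0), ("taskB", 150.0), ("rest", 30.0))


class TestStateSequence:
    def test_single_state_is_constant(self):
        cfg = SimConfig(n_rois=4, n_states=1, coupling_strength=np.zeros((1, 4, 4)), seed=0)
        seq = generate_state_sequence(cfg)
        assert seq.n_transitions == 0
        assert np.all(seq.labels == 0)

    def test_mean_segment_count_matches_dwell_mean(self):
        # 480 s of task with 30 s mean dwell -> ~16 dwell segments on average
        counts = []
        for seed in range(200):
            cfg = SimConfig(
                n_rois=2,
                session_plan=(("taskA", 480.0),),
                n_states=3,
                state_dwell_mean=30.0,
                coupling_strength=default_state_topologies(3, 2),
                seed=seed,
            )
            counts.append(len(generate_state_sequence(cfg).dwell_times))
        assert np.mean(counts) == pytest.approx(16.0, rel=0.2)

    def test_deterministic_under_seed(self, small_cfg):
        a = generate_state_sequence(small_cfg)
        b = generate_state_sequence(small_cfg)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_no_self_transitions_at_boundaries(self, small_cfg):
        seq = generate_state_sequence(small_cfg)
        segs = seq.segments()
        for (s1, *_), (s2, *_) in zip(segs, segs[1:]):
            assert s1 != s2

    def test_subsecond_dwell_rejected(self):
        with pytest.raises(ValueError, match="dwell"):
            SimConfig(n_rois=2, state_dwell_mean=0.01, coupling_strength=default_state_topologies(3, 2))

    def test_session_state_weights_bias_occupancy(self):
        w = {"taskA": (0.9, 0.05, 0.05), "taskB": (0.05, 0.05, 0.9)}
        cfg = SimConfig(
            n_rois=4,
            session_plan=SHORT_PLAN,
            coupling_strength=default_state_topologies(3, 4),
            state_weights_by_session=w,
            state_dwell_mean=10.0,
            seed=5,
        )
        occ_a, occ_b = [], []
        for seed in range(10):
            seq = generate_state_sequence(cfg.with_(seed=seed))
            occ_a.append(np.mean(seq.labels[60:210] == 0))
            occ_b.append(np.mean(seq.labels[210:360] == 0))
        assert np.mean(occ_a) > np.mean(occ_b)


class TestDyadRecording:
    def test_hbr_is_scaled_anticorrelated_copy_without_noise(self):
        cfg = SimConfig(
            n_rois=3,
            session_plan=(("taskA", 120.0), ("rest", 30.0)),
            coupling_strength=default_state_topologies(2, 3, strong=0.8, weak=0.3),
            n_states=2,
            noise_amplitudes={k: 0.0 for k in ("drift", "mayer", "respiration", "cardiac", "white")},
            motion_rate=0.0,
            hbr_ratio=-0.5,
            seed=3,
        )
        rec = generate_dyad_recording(cfg)
        for p in (1, 2):
            for ci in range(rec.hbo[p].shape[0]):
                r = np.corrcoef(rec.hbo[p][ci], rec.hbr[p][ci])[0, 1]
                assert r == pytest.approx(-1.0, abs=1e-9)

    def test_psd_peaks_at_configured_nuisance_frequencies(self):
        cfg = SimConfig(
            n_rois=2,
            session_plan=(("rest", 200.0),),
            n_states=1,
            coupling_strength=np.zeros((1, 2, 2)),
            noise_amplitudes={"drift": 0.0, "mayer": 1.0, "respiration": 1.0, "cardiac": 1.0, "white": 0.1},
            motion_rate=0.0,
            seed=9,
        )
        rec = generate_dyad_recording(cfg)
        f, pxx = sp_signal.welch(rec.hbo[1][0], fs=cfg.sampling_rate, nperseg=1024)
        for f0 in (0.1, 0.3, 1.2):
            near = (f > f0 * 0.8) & (f < f0 * 1.2)
            away = (f > f0 * 1.35) & (f < f0 * 1.6)
            assert pxx[near].max() > 3 * pxx[away].mean()

    def test_coupled_pair_coherence_in_band_beats_out_of_band(self, spec10):
        # one strongly coupled ROI pair: its task-period coherence in the
        # coupling band should exceed its out-of-band coherence
        c = np.zeros((1, 3, 3))
        c[0, 0, 1] = c[0, 1, 0] = 0.9
        diffs = []
        for seed in range(6):
            cfg = SimConfig(
                n_rois=3,
                session_plan=(("taskA", 300.0),),
                n_states=1,
                coupling_strength=c,
                seed=seed,
            )
            rec = generate_dyad_recording(cfg)
            coh = wavelet_coherence(rec.hbo[1][0], rec.hbo[2][1], spec10)
            band = (coh.frequencies >= 0.10) & (coh.frequencies <= 0.19)
            out = (coh.frequencies >= 0.30) & (coh.frequencies <= 0.60)
            diffs.append(coh.r2[band].mean() - coh.r2[out].mean())
        assert np.mean(diffs) > 0.05

    def test_uncoupled_task_vs_rest_coherence_null(self, spec10):
        # with no planted coupling, in-band task coherence is statistically
        # indistinguishable from rest coherence across seeds
        from scipy import stats

        task_vals, rest_vals = [], []
        for seed in range(12):
            cfg = SimConfig(
                n_rois=2,
                session_plan=(("rest", 120.0), ("taskA", 120.0)),
                n_states=1,
                coupling_strength=np.zeros((1, 2, 2)),
                seed=seed,
            )
            rec = generate_dyad_recording(cfg)
            coh = wavelet_coherence(rec.hbo[1][0], rec.hbo[2][0], spec10)
            band = (coh.frequencies >= 0.10) & (coh.frequencies <= 0.19)
            rest_vals.append(coh.r2[band, :1200].mean())
            task_vals.append(coh.r2[band, 1200:].mean())
        p = stats.ttest_rel(task_vals, rest_vals).pvalue
        assert p > 0.01

    def test_determinism_and_annotation_tiling(self, small_cfg):
        a = generate_dyad_recording(small_cfg)
        b = generate_dyad_recording(small_cfg)
        np.testing.assert_array_equal(a.hbo[1], b.hbo[1])
        np.testing.assert_array_equal(a.hbr[2], b.hbr[2])
        assert a.annotations[0][1] == 0.0
        assert a.annotations[-1][2] == pytest.approx(a.duration)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="coupling_band"):
            SimConfig(n_rois=2, coupling_band=(0.005, 0.19), coupling_strength=np.zeros((3, 2, 2)))
        bad = np.zeros((3, 2, 2))
        bad[0, 0, 1] = 0.5  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            SimConfig(n_rois=2, coupling_strength=bad)


class TestBehaviorGeneration:
    def test_forced_convergence_extremes(self, small_cfg):
        aut, _ = generate_behavior(small_cfg, convergence_prob=0.0, pass_prob=0.0, seed=1)
        converge, ioc = compute_ioc(aut)
        assert converge == 0 and ioc == 0.0
        aut1, _ = generate_behavior(small_cfg, convergence_prob=1.0, pass_prob=0.0, seed=1)
        resp = aut1.substantive()
        converge1 = sum(1 for a, b in zip(resp, resp[1:]) if a.category == b.category)
        assert converge1 == len(resp) - 1  # every response repeats the category

    def test_ioc_formula_on_fully_convergent_log(self):
        # 10 distinct responses all in one category: converge 9, IOC 9/(10-9)
        from dibs.behavior import Response, ResponseLog

        records = [
            Response(speaker=1 + i % 2, t=float(i + 1), key=f"idea{i}", category="catA")
            for i in range(10)
        ]
        converge, ioc = compute_ioc(ResponseLog(task="AUT", records=records))
        assert converge == 9
        assert ioc == pytest.approx(9.0)

    def test_same_seed_identical_log(self, small_cfg):
        a, _ = generate_behavior(small_cfg, seed=11)
        b, _ = generate_behavior(small_cfg, seed=11)
        assert a.to_frame().equals(b.to_frame())

    def test_speakers_alternate(self, small_cfg):
        aut, _ = generate_behavior(small_cfg, seed=2, pass_prob=0.0)
        speakers = [r.speaker for r in aut.records]
        assert all(a != b for a, b in zip(speakers, speakers[1:]))
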