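"""Behavioral session and EEG generators: design exactness, race
signatures, and closed-form oracles on the injected condition effects."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import conflictstop as cs
from conflictstop.epochs import CONDITIONS, N_CHANNELS
from conflictstop.synth import background_topographies


class TestSessionDesign:
    def test_default_design_counts(self, default_session):
        df = default_session
        assert len(df) == 936
        assert (df.is_stop == 1).sum() == 216
        assert (df.is_stop == 0).sum() == 720
        go = df[df.is_stop == 0]
        stop = df[df.is_stop == 1]
        assert (go.condition == "congruent").sum() == 360
        assert (stop.condition == "congruent").sum() == 108
        # 24 stop trials in each of the 9 blocks
        assert stop.groupby("block").size().tolist() == [24] * 9

    def test_block_conservation(self, default_session):
        per_block = default_session.groupby(["block", "is_stop", "condition"]).size()
        for b in range(1, 10):
            for cond in CONDITIONS:
                assert per_block[(b, 0, cond)] == 40
                assert per_block[(b, 1, cond)] == 12

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError, match="multiple of 4"):
            cs.TaskDesign(go_per_block=13)
        with pytest.raises(ValueError, match="SSD"):
            cs.TaskDesign(initial_ssd_ms=2000)

    def test_determinism(self):
        a = cs.generate_session(seed=7)
        b = cs.generate_session(seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = cs.generate_session(seed=8)
        assert not a.equals(c)


class TestRaceModel:
    def test_instant_stopping_degenerate(self):
        # a stop process that finishes instantly always wins the race when
        # the go process is slower than the largest possible SSD
        race = cs.RaceParams(
            go={c: cs.ExGauss(1600.0, 0.0, 0.0) for c in CONDITIONS},
            stop={c: cs.ExGauss(0.0, 0.0, 0.0) for c in CONDITIONS},
            miss_rate=0.0,
            error_rate=0.0,
        )
        df = cs.generate_session(race, seed=0)
        stop = df[df.is_stop == 1]
        assert (stop.outcome == "correct_rejection").all()
        for cond in CONDITIONS:
            ssd = stop.loc[stop.condition == cond, "ssd_ms"].to_numpy()
            assert (np.diff(ssd) >= 0).all()
            assert ssd[-1] == 1000.0

    def test_staircase_equilibrium_constant_ssrt(self):
        # with any stationary race the one-up/one-down staircase tracks the
        # delay at which stopping succeeds half the time
        race = cs.RaceParams(
            go=cs.default_race_params().go,
            stop={c: cs.ExGauss(270.0, 0.0, 0.0) for c in CONDITIONS},
            miss_rate=0.0,
            error_rate=0.0,
        )
        ps = []
        for seed in range(40):
            df = cs.generate_session(race, seed=seed)
            stop = df[df.is_stop == 1]
            ps.append((stop.outcome == "failed_stop").mean())
        assert 0.47 <= np.mean(ps) <= 0.53

    def test_race_signature_failed_stop_faster(self):
        for seed in (1, 2, 3, 4, 5):
            s = cs.summarize_subject(cs.generate_session(seed=seed))
            assert (s.mean_failed_stop_rt < s.mean_go_rt).all()

    def test_ssd_follows_staircase(self, default_session):
        stop = default_session[default_session.is_stop == 1]
        for cond in CONDITIONS:
            sel = stop[stop.condition == cond]
            ssd = sel.ssd_ms.to_numpy()
            stopped = (sel.outcome == "correct_rejection").to_numpy()
            for i in range(len(ssd) - 1):
                assert ssd[i + 1] == cs.next_ssd(ssd[i], stopped[i])


class TestEEGGeneration:
    def test_null_construction_identical_means(self):
        truth = cs.null_ground_truth(n_subjects=2, seed=0)
        truth = dataclasses.replace(truth, noise_sd=0.0)
        ep = cs.simulate_epochs(truth, n_trials_per_condition=10)
        c = ep.get("sub-01", "congruent").mean(axis=0)
        i = ep.get("sub-01", "incongruent").mean(axis=0)
        assert np.allclose(c, i)

    def test_noiseless_single_source_rank_one(self):
        truth = cs.default_ground_truth(n_subjects=2, seed=0, n_sources=1)
        truth = dataclasses.replace(truth, noise_sd=0.0)
        ep = cs.simulate_epochs(truth, n_trials_per_condition=5)
        for trial in ep.get("sub-01", "incongruent"):
            s = np.linalg.svd(trial, compute_uv=False)
            assert s[1] < 1e-10 * s[0]

    def test_pointwise_auc_matches_gaussian_oracle(self):
        # effect d = 1 along a unit topography with unit white noise gives a
        # two-sample AUC of Phi(1/sqrt(2)) at each in-window sample
        truth = cs.default_ground_truth(n_subjects=4, seed=7)
        src = dataclasses.replace(truth.sources[0], effect_size=1.0)
        truth = dataclasses.replace(truth, sources=(src,) + truth.sources[1:])
        ep = cs.simulate_epochs(truth, n_trials_per_condition=40)
        topo = truth.sources[0].topography
        mask = truth.sources[0].window_mask()
        vals = []
        for sub in ep.subjects:
            pc = np.einsum("c,tcs->ts", topo, ep.get(sub, "congruent"))[:, mask]
            pi = np.einsum("c,tcs->ts", topo, ep.get(sub, "incongruent"))[:, mask]
            auc = (pi[:, None, :] > pc[None, :, :]).mean(axis=(0, 1))
            vals.append(auc.mean())
        oracle = norm.cdf(1.0 / np.sqrt(2.0))
        assert abs(np.mean(vals) - oracle) < 0.05

    def test_background_orthogonal_to_signal(self, small_truth):
        topos = np.stack([s.topography for s in small_truth.sources])
        for cond in CONDITIONS:
            bg = background_topographies(small_truth, cond)
            assert np.abs(topos @ bg.T).max() < 1e-10
            assert np.allclose(bg @ bg.T, np.eye(len(bg)), atol=1e-10)

    def test_epochs_from_logs_counts_and_determinism(self, small_truth):
        logs = cs.generate_group_sessions(n_subjects=2, seed=5)
        ep1 = cs.generate_group_eeg(logs, small_truth)
        ep2 = cs.generate_group_eeg(logs, small_truth)
        for sub, log in logs.items():
            stop = log[log.is_stop == 1]
            for cond in CONDITIONS:
                arr = ep1.get(sub, cond)
                assert arr.shape == ((stop.condition == cond).sum(), N_CHANNELS, 307)
                assert np.array_equal(arr, ep2.get(sub, cond))

    def test_epochs_hdf5_roundtrip(self, small_epochs, tmp_path):
        path = tmp_path / "epochs.h5"
        cs.save_epochs(path, small_epochs)
        loaded = cs.load_epochs(path)
        assert loaded.subjects == small_epochs.subjects
        assert np.allclose(loaded.times, small_epochs.times)
        orig = small_epochs.get("sub-01", "congruent")
        # stored as float32
        assert np.allclose(loaded.get("sub-01", "congruent"), orig, atol=1e-3)


def test_trial_log_tsv_roundtrip(default_session, tmp_path):
    path = tmp_path / "log.tsv"
    cs.write_trial_log(path, default_session)
    loaded = cs.read_trial_log(path)
    assert len(loaded) == len(default_session)
    assert loaded.outcome.equals(default_session.outcome)
    assert np.allclose(loaded.rt_ms.to_numpy(), default_session.rt_ms.to_numpy(),
                       atol=1e-3, equal_nan=True)
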