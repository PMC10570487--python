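"""Synthetic dyad generator: determinism, ground truth, gaze and mixing contracts."""

import numpy as np
import pytest

from ibsync.connectivity import CANONICAL_BANDS, analytic_band, event_window_mean, pair_connectivity
from ibsync.preprocess import preprocess_recording
from ibsync.simulate import (
    Coupling,
    GridSpec,
    OscBand,
    SimConfig,
    TrialLayout,
    apply_mixing,
    detect_locks,
    simulate_dyad,
    simulate_gaze_pair,
)
from ibsync.io import GazeTrack


class TestConfigContracts:
    def test_trial_length_is_thirteen_seconds(self):
        assert TrialLayout().trial_s == 13.0

    def test_fs_must_clear_nyquist(self):
        with pytest.raises(ValueError, match="fs"):
            SimConfig(fs=80.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            Coupling(-0.1, 0.5)

    def test_attraction_bounds(self):
        with pytest.raises(ValueError, match="attraction"):
            SimConfig(gaze_coupling={"cooperation": 1.5})

    def test_cross_head_mixing_rejected(self):
        m = np.eye(64)
        m[0, 40] = 0.3  # head A sees head B: forbidden
        with pytest.raises(ValueError, match="cross"):
            SimConfig(mixing=m)


class TestSimulateDyad:
    def test_bit_identical_given_seed(self, coupled_config):
        r1, _ = simulate_dyad(coupled_config, 0)
        r2, _ = simulate_dyad(coupled_config, 0)
        np.testing.assert_array_equal(r1.eeg_a, r2.eeg_a)
        np.testing.assert_array_equal(r1.eeg_b, r2.eeg_b)
        np.testing.assert_array_equal(r1.events.times, r2.events.times)

    def test_zero_noise_zero_sigma_gives_perfect_locking(self):
        cfg = SimConfig(
            n_dyads=1, n_trials_per_mode=8, modes=("cooperation",),
            bands=(OscBand("theta", 4, 7, 6.0),),
            coupling={"theta": {"cooperation": Coupling(0.0, 0.0)}},
            noise_sd=0.0, simulate_gaze=False, seed=3,
        )
        rec, truth = simulate_dyad(cfg, 0)
        assert truth.expected_plv[("cooperation", "theta")]["plv_event"] == 1.0
        ep_a, ep_b = preprocess_recording(rec)
        ta = analytic_band(ep_a, CANONICAL_BANDS["theta"])
        tb = analytic_band(ep_b, CANONICAL_BANDS["theta"])
        ev = event_window_mean(pair_connectivity(ta, tb))
        np.testing.assert_allclose(np.diag(ev), 1.0, atol=5e-3)

    def test_ground_truth_monotone_in_sigma(self):
        assert Coupling(0.2, 0.2).expected_plv() > Coupling(0.5, 0.5).expected_plv() > Coupling(1.0, 1.0).expected_plv()
        assert 0.0 <= Coupling(3.0, 3.0).expected_plv() <= 1.0

    def test_event_exceeds_baseline_when_sigma_event_smaller(self, full_dyad):
        (rec, truth), _ = full_dyad
        ep_a, ep_b = preprocess_recording(rec)
        band = CANONICAL_BANDS["theta"]
        idx = np.flatnonzero((ep_a.labels["mode"] == "cooperation").to_numpy())
        ta = analytic_band(ep_a, band).select_trials(idx)
        tb = analytic_band(ep_b, band).select_trials(idx)
        pc = pair_connectivity(ta, tb)
        ev = np.diag(event_window_mean(pc, (0.2, 0.5))).mean()
        base = np.diag(event_window_mean(pc, (-2.5, -0.5))).mean()
        assert ev > base

    def test_stimulus_intervals_equal_trial_length(self, full_dyad):
        (rec, _), cfg = full_dyad
        stims = rec.events.stimulus_onsets
        np.testing.assert_allclose(np.diff(stims), cfg.layout.trial_s, atol=1 / rec.fs)


class TestGazePair:
    def test_full_attraction_follows_leader(self):
        ta, tb, _ = simulate_gaze_pair("cooperation", [5], attraction=1.0, seed=0)
        search = ta.t >= 3.5
        d = np.hypot(ta.x - tb.x, ta.y - tb.y)[search]
        assert d.mean() < 120.0  # follower tracks the leader closely

    def test_repulsion_increases_distance(self):
        d = {}
        for a in (+1.0, -1.0):
            ta, tb, _ = simulate_gaze_pair("cooperation", [5, 10], attraction=a, seed=7)
            mask = ta.t >= 3.0
            d[a] = np.hypot(ta.x - tb.x, ta.y - tb.y)[mask].mean()
        assert d[-1.0] > d[+1.0]

    def test_locks_only_from_player_in_single_mode(self):
        _, _, locks = simulate_gaze_pair("single", [3, 7, 12], attraction=0.0, seed=2)
        assert locks and all(who == "A" for who, *_ in locks)

    def test_errors(self):
        with pytest.raises(ValueError, match="attraction"):
            simulate_gaze_pair("cooperation", [1], attraction=2.0)
        with pytest.raises(ValueError, match="non-empty"):
            simulate_gaze_pair("cooperation", [], attraction=0.0)
        with pytest.raises(ValueError, match="grid"):
            simulate_gaze_pair("cooperation", [99], attraction=0.0)


class TestLockDetection:
    def _track(self, dwell_s, fs=30.0):
        grid = GridSpec()
        cx, cy = grid.cell_center(5)
        n_in = int(round(dwell_s * fs))
        x = np.concatenate([np.full(20, 10.0), np.full(n_in, cx), np.full(20, 10.0)])
        y = np.concatenate([np.full(20, 10.0), np.full(n_in, cy), np.full(20, 10.0)])
        t = np.arange(len(x)) / fs
        return GazeTrack(t, x, y, np.ones(len(x), dtype=bool))

    def test_dwell_just_below_threshold_no_lock(self):
        # 0.69 s of continuous dwell: strictly-greater-than rule -> no lock
        assert detect_locks(self._track(0.69), [5]) == []

    def test_dwell_above_threshold_locks_once(self):
        locks = detect_locks(self._track(0.95), [5])
        assert len(locks) == 1 and locks[0][0] == 5


class TestMixing:
    def test_identity_preserves_recording(self, coupled_dyad):
        rec, _ = coupled_dyad
        out = apply_mixing(rec, np.eye(64))
        np.testing.assert_array_equal(out.eeg_a, rec.eeg_a)
        np.testing.assert_array_equal(out.eeg_b, rec.eeg_b)

    def test_within_head_mixing_applies(self, coupled_dyad):
        rec, _ = coupled_dyad
        m = np.eye(64)
        m[0, 1] = 1.0
        out = apply_mixing(rec, m)
        np.testing.assert_allclose(out.eeg_a[0], rec.eeg_a[0] + rec.eeg_a[1])
        np.testing.assert_array_equal(out.eeg_b, rec.eeg_b)

    def test_cross_head_entry_rejected(self, coupled_dyad):
        rec, _ = coupled_dyad
        m = np.eye(64)
        m[40, 0] = 0.1
        with pytest.raises(ValueError, match="cross"):
            apply_mixing(rec, m)
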