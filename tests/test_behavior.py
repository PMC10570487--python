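"""TST computation, trimmed means, gaze distance and heatmap similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibsync.behavior import (
    Heatmap,
    gaze_distance,
    gaze_heatmap,
    heatmap_similarity,
    lock_onsets,
    trimmed_mean,
    tst_sequence,
    tst_table,
)
from ibsync.io import EventList, GazeTrack


def _events(idents, stim=10.0):
    times = [stim - 3.0, stim, stim]
    codes = ["mode:single:run:1", "stimulus_onset", "targets:3"]
    for t, cell in idents:
        times.append(stim + t)
        codes.append(f"identified:A:{cell}")
    return EventList(np.array(times), codes)


class TestLockOnsets:
    def test_onset_is_identification_minus_lead(self):
        df = lock_onsets(_events([(2.0, 4)]))
        assert df.loc[0, "onset_s"] == pytest.approx(1.3)
        assert not df.loc[0, "clamped"]

    def test_order_preserved_for_multiple_targets(self):
        df = lock_onsets(_events([(2.0, 4), (3.5, 9)]))
        assert list(df["onset_s"]) == pytest.approx([1.3, 2.8])
        assert list(df["cell"]) == [4, 9]

    def test_early_identification_clamped(self):
        df = lock_onsets(_events([(0.5, 2)]))
        assert df.loc[0, "clamped"]
        assert df.loc[0, "onset_s"] == 0.0


class TestTSTSequence:
    def test_worked_example(self):
        np.testing.assert_allclose(
            tst_sequence(np.array([1.3, 2.0, 4.0])), [1.3, 0.7, 2.0]
        )

    def test_single_onset(self):
        np.testing.assert_allclose(tst_sequence(np.array([0.9])), [0.9])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            tst_sequence(np.array([2.0, 1.0]))

    @settings(deadline=None, max_examples=30, derandomize=True, database=None)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8))
    def test_telescoping_sum(self, gaps):
        onsets = np.cumsum(gaps)
        assert tst_sequence(onsets).sum() == pytest.approx(onsets[-1])


class TestTrimmedMean:
    def test_outliers_removed(self):
        assert trimmed_mean([1, 2, 3, 4, 100]) == pytest.approx(3.0)

    def test_constant_and_singleton(self):
        assert trimmed_mean([7.0] * 9) == 7.0
        val, flag = trimmed_mean([42.0], return_flag=True)
        assert val == 42.0 and flag  # median fallback path

    def test_matches_brute_force_convention(self, rng):
        v = rng.normal(size=37)
        k = int(np.ceil(0.05 * 37))
        brute = np.sort(v)[k:-k].mean()
        assert trimmed_mean(v) == pytest.approx(brute)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean([])


class TestGazeDistance:
    def _track(self, x, y, n=100, fs=30.0):
        t = np.arange(n) / fs
        return GazeTrack(t, np.full(n, x), np.full(n, y), np.ones(n, bool))

    def test_identical_tracks(self):
        a = self._track(10, 20)
        assert gaze_distance(a, a) == 0.0

    def test_three_four_five(self):
        assert gaze_distance(self._track(0, 0), self._track(3, 4)) == pytest.approx(5.0)

    def test_validity_required(self):
        a = self._track(0, 0)
        b = GazeTrack(a.t, a.x, a.y, np.zeros(len(a), bool))
        with pytest.raises(ValueError, match="valid"):
            gaze_distance(a, b)


class TestHeatmaps:
    def test_point_mass_and_normalisation(self):
        tr = GazeTrack([0, 1 / 30], [100.0, 100.0], [100.0, 100.0], [True, True])
        hm = gaze_heatmap(tr, extent=(1920, 1080), cells=(96, 54), sigma_px=0.0)
        assert hm.grid.sum() == pytest.approx(1.0)
        assert hm.grid.max() == pytest.approx(1.0)  # all mass in one cell

    def test_smoothed_mass_conserved(self, rng):
        n = 500
        tr = GazeTrack(np.arange(n) / 30, rng.uniform(0, 1920, n), rng.uniform(0, 1080, n),
                       np.ones(n, bool))
        hm = gaze_heatmap(tr, sigma_px=40.0)
        assert hm.grid.sum() == pytest.approx(1.0)

    def test_uniform_samples_not_peaky(self, rng):
        n = 200_000
        tr = GazeTrack(np.arange(n) / 30, rng.uniform(0, 1920, n), rng.uniform(0, 1080, n),
                       np.ones(n, bool))
        hm = gaze_heatmap(tr, cells=(24, 12), sigma_px=0.0)
        assert hm.grid.max() <= 3 * hm.grid.mean()

    def test_no_valid_samples(self):
        tr = GazeTrack([0.0], [5.0], [5.0], [False])
        with pytest.raises(ValueError):
            gaze_heatmap(tr)


class TestSimilarity:
    def _hm(self, grid):
        g = np.asarray(grid, dtype=float)
        return Heatmap(g / g.sum(), extent=(100, 100))

    def test_identity(self, rng):
        g = rng.uniform(0.1, 1.0, (10, 10))
        a = self._hm(g)
        sim = heatmap_similarity(a, a)
        assert sim["pearson"] == pytest.approx(1.0)
        assert sim["ssim"] == pytest.approx(1.0)
        assert sim["jaccard"] == pytest.approx(1.0)

    def test_disjoint_supports_zero_jaccard(self):
        a = np.zeros((10, 10)); a[:5] = 1.0
        b = np.zeros((10, 10)); b[5:] = 1.0
        sim = heatmap_similarity(self._hm(a), self._hm(b))
        assert sim["jaccard"] == 0.0

    def test_checkerboard_anticorrelation(self):
        g = np.indices((10, 10)).sum(axis=0) % 2
        sim = heatmap_similarity(self._hm(g + 0.01), self._hm(1 - g + 0.01))
        assert sim["pearson"] == pytest.approx(-1.0, abs=1e-6)

    def test_grid_mismatch_and_degenerate_pearson(self):
        with pytest.raises(ValueError):
            heatmap_similarity(self._hm(np.ones((5, 5))), self._hm(np.ones((6, 6))))
        sim = heatmap_similarity(self._hm(np.ones((8, 8))), self._hm(np.ones((8, 8))))
        assert np.isnan(sim["pearson"])  # zero-variance sentinel


def test_tst_table_from_generated_events(full_dyad):
    (rec, truth), _ = full_dyad
    table = tst_table(rec.events)
    assert (table["tst"] > 0).all()
    assert (table["k"] <= table["n_targets"]).all()
    # lock onsets in the table match the generator's ground truth count
    assert len(table) == len(truth.locks)
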