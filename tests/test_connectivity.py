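"""Analytic-signal extraction and phase-coupling measure contracts."""

import numpy as np
import pandas as pd
import pytest

from ibsync.connectivity import (
    CANONICAL_BANDS,
    AnalyticTensor,
    aggregate_by_region,
    analytic_band,
    baseline_correct,
    event_window_mean,
    pair_connectivity,
)
from ibsync.montage import CHANNELS, REGION_MAP, REGIONS, region_members
from ibsync.preprocess import EpochSet

FS = 250.0


def _epochs(data):
    n, ch, t = data.shape
    return EpochSet(
        data=data,
        times=-1.0 + np.arange(t) / FS,
        fs=FS,
        channels=tuple(f"ch{i}" for i in range(ch)),
        labels=pd.DataFrame({"trial": range(n), "mode": "x", "run": 1, "n_targets": 1}),
    )


def _tensor(phases, times=None):
    n, ch, t = phases.shape
    return AnalyticTensor(
        values=np.exp(1j * phases),
        times=np.arange(t) / FS if times is None else times,
        fs=FS,
        band=CANONICAL_BANDS["theta"],
        channels=tuple(f"ch{i}" for i in range(ch)),
    )


class TestAnalyticBand:
    def test_phase_slope_matches_frequency(self):
        t = np.arange(int(13 * FS)) / FS
        x = np.sin(2 * np.pi * 5.0 * t)[None, None, :]
        at = analytic_band(_epochs(np.repeat(x, 2, axis=0)), CANONICAL_BANDS["theta"])
        core = slice(400, -400)
        phase = np.unwrap(at.phase[0, 0])[core]
        slope = np.polyfit(t[core], phase, 1)[0]
        assert abs(slope - 2 * np.pi * 5.0) / (2 * np.pi * 5.0) < 1e-3

    def test_quadrature_lead(self):
        t = np.arange(int(13 * FS)) / FS
        data = np.stack([np.cos(2 * np.pi * 5 * t), np.sin(2 * np.pi * 5 * t)])[None]
        at = analytic_band(_epochs(np.repeat(data, 2, axis=0)), CANONICAL_BANDS["theta"])
        core = slice(400, -400)
        diff = np.angle(at.values[0, 0, core] * np.conj(at.values[0, 1, core]))
        np.testing.assert_allclose(diff, np.pi / 2, atol=0.02)

    def test_envelope_constant_for_pure_sine(self):
        t = np.arange(int(13 * FS)) / FS
        x = np.sin(2 * np.pi * 5.5 * t)[None, None, :]
        at = analytic_band(_epochs(np.repeat(x, 2, axis=0)), CANONICAL_BANDS["theta"])
        env = np.abs(at.values[0, 0, 400:-400])
        assert env.std() / env.mean() < 0.01

    def test_short_epoch_rejected(self):
        data = np.zeros((2, 1, 500))
        with pytest.raises(ValueError, match="filter lengths"):
            analytic_band(_epochs(data), CANONICAL_BANDS["delta"])


class TestPairConnectivity:
    def test_constant_phase_difference_gives_unity(self, rng):
        base = rng.uniform(-np.pi, np.pi, (1, 1, 100))
        pa = np.repeat(base, 40, axis=0)
        pb = pa + 1.234  # any constant offset
        pc = pair_connectivity(_tensor(pa), _tensor(pb), "plv")
        np.testing.assert_allclose(pc.values, 1.0, atol=1e-12)

    def test_uniform_phases_rayleigh_floor(self, rng):
        n_rep = 1000
        pa = rng.uniform(-np.pi, np.pi, (40, 1, n_rep))
        pc = pair_connectivity(_tensor(pa), _tensor(np.zeros_like(pa)), "plv")
        vals = pc.values.ravel()
        # oracle: direct Monte-Carlo of the 40-trial resultant
        z = np.exp(1j * rng.uniform(-np.pi, np.pi, (100_000, 40))).mean(axis=1)
        mu, se = np.abs(z).mean(), np.abs(z).std() / np.sqrt(n_rep)
        assert abs(vals.mean() - mu) < 3 * se

    def test_wrapped_normal_closed_form(self, rng):
        sigma = 0.5
        n, n_rep = 400, 200  # large trial count approaches the asymptote
        pa = rng.uniform(-np.pi, np.pi, (n, 1, n_rep))
        pb = pa + rng.normal(0, sigma, (n, 1, n_rep))
        pc = pair_connectivity(_tensor(pa), _tensor(pb), "plv")
        assert abs(pc.values.mean() - np.exp(-(sigma**2) / 2)) < 0.01

    def test_identical_signals_zero_lag_conventions(self, rng):
        phases = rng.uniform(-np.pi, np.pi, (10, 2, 50))
        t = _tensor(phases)
        for measure, expected in [("plv", 1.0), ("ciplv", 0.0), ("wpli", 0.0)]:
            pc = pair_connectivity(t, t, measure)
            diag = np.einsum("iit->it", pc.values)
            np.testing.assert_allclose(diag, expected, atol=1e-7)

    def test_bounds_and_participant_symmetry(self, rng):
        pa = rng.uniform(-np.pi, np.pi, (12, 3, 60))
        pb = rng.uniform(-np.pi, np.pi, (12, 3, 60))
        ta, tb = _tensor(pa), _tensor(pb)
        for measure in ("plv", "ciplv", "wpli"):
            ab = pair_connectivity(ta, tb, measure).values
            ba = pair_connectivity(tb, ta, measure).values
            assert ab.min() >= 0.0 and ab.max() <= 1.0 + 1e-12
            np.testing.assert_allclose(ab, np.transpose(ba, (1, 0, 2)), atol=1e-12)

    def test_trial_resolved_variant(self, rng):
        pa = rng.uniform(-np.pi, np.pi, (8, 2, 100))
        pc = pair_connectivity(_tensor(pa), _tensor(pa), "plv", time_resolved=False)
        assert pc.values.shape == (2, 2, 1)
        # within-trial time-resolved modulus of a self-pair is unity on the diagonal
        np.testing.assert_allclose(np.diag(pc.values[..., 0]), 1.0, atol=1e-12)
        assert (pc.values >= 0).all() and (pc.values <= 1 + 1e-12).all()

    def test_contract_errors(self, rng):
        pa = rng.uniform(-np.pi, np.pi, (1, 2, 30))
        with pytest.raises(ValueError, match="at least 2 trials"):
            pair_connectivity(_tensor(pa), _tensor(pa))
        pb = rng.uniform(-np.pi, np.pi, (3, 2, 40))
        with pytest.raises(ValueError):
            pair_connectivity(_tensor(np.repeat(pa, 3, 0)), _tensor(pb))


class TestWindows:
    def test_baseline_correction(self, rng):
        phases = rng.uniform(-np.pi, np.pi, (10, 1, 3250))
        t = -3 + np.arange(3250) / FS
        pc = pair_connectivity(_tensor(phases, times=t), _tensor(phases, times=t))
        const = baseline_correct(pc)
        # the self-pair time course is constant (unity) -> zero after correction
        np.testing.assert_allclose(const.values, 0.0, atol=1e-9)
        assert const.baseline_corrected
        # correcting twice changes nothing once the baseline mean is zero
        np.testing.assert_allclose(baseline_correct(const).values, const.values, atol=1e-12)
        with pytest.raises(ValueError):
            baseline_correct(pc, window=(20.0, 30.0))

    def test_event_window_inclusive_count_and_mean(self, rng):
        times = -3 + np.arange(3250) / FS
        phases = np.zeros((4, 1, 3250))
        pc = pair_connectivity(_tensor(phases, times), _tensor(phases, times))
        pc.values = rng.normal(size=pc.values.shape)
        mask = (times >= 0.2 - 1e-9) & (times <= 0.5 + 1e-9)
        assert mask.sum() == 76  # inclusive endpoints at 250 Hz
        expected = pc.values[..., mask].sum(axis=-1) / 76
        np.testing.assert_allclose(event_window_mean(pc), expected, atol=1e-12)


class TestRegionAggregation:
    def test_region_sizes_partition_montage(self):
        sizes = {r: len(region_members(r)) for r in REGIONS}
        assert sizes == {"frontal": 11, "central": 3, "temporal": 6, "parietal": 9, "occipital": 3}
        assert sum(sizes.values()) == 32

    def test_all_ones_and_occipital_mean(self, rng):
        mat = rng.normal(size=(32, 32))
        out = aggregate_by_region(mat)
        ones = aggregate_by_region(np.ones((32, 32)))
        np.testing.assert_allclose(ones, 1.0)
        occ = [CHANNELS.index(c) for c in region_members("occipital")]
        brute = np.mean([mat[i, j] for i in occ for j in occ])
        np.testing.assert_allclose(out[REGIONS.index("occipital"), REGIONS.index("occipital")], brute)

    def test_weighted_region_mean_recovers_global_mean(self, rng):
        mat = rng.normal(size=(32, 32))
        out = aggregate_by_region(mat)
        sizes = np.array([len(region_members(r)) for r in REGIONS])
        weights = np.outer(sizes, sizes)
        np.testing.assert_allclose((out * weights).sum() / weights.sum(), mat.mean())

    def test_unmapped_channel_rejected(self):
        bad = dict(REGION_MAP)
        bad.pop("Cz")
        with pytest.raises(ValueError, match="Cz"):
            aggregate_by_region(np.ones((32, 32)), region_map=bad)
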