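"""ANOVA wrappers against brute-force sums-of-squares oracles."""

import numpy as np
import pandas as pd
import pytest

from ibsync.stats import holm_adjust, mixed_anova, rm_anova


def _long(values, subjects=None, groups=None):
    """values: (n_subjects, n_levels) -> long frame."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    rows = []
    for s in range(n):
        for l in range(k):
            rows.append(
                {
                    "subject": f"s{s}",
                    "level": f"l{l}",
                    "value": values[s, l],
                    "group": (groups[s] if groups is not None else "g"),
                }
            )
    return pd.DataFrame(rows)


def _rm_oracle(values):
    """Classical within-subject decomposition, written out long-hand."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = values.mean()
    ss_levels = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_subjects = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_error = ss_total - ss_levels - ss_subjects
    df1, df2 = k - 1, (k - 1) * (n - 1)
    return (ss_levels / df1) / (ss_error / df2), (df1, df2)


class TestRMAnova:
    def test_matches_brute_force_oracle(self, rng):
        values = rng.normal(size=(5, 3)) + np.array([0.0, 0.5, 1.0])
        res = rm_anova(_long(values))
        f_oracle, df = _rm_oracle(values)
        assert res.F == pytest.approx(f_oracle, rel=1e-9)
        assert res.df == (float(df[0]), float(df[1]))

    def test_identical_levels_degenerate(self):
        values = np.tile(np.arange(4.0)[:, None], (1, 3))  # no level effect, no error
        res = rm_anova(_long(values))
        assert np.isnan(res.F) or res.F == pytest.approx(0.0)

    def test_posthoc_holm_directions(self, rng):
        values = rng.normal(0, 0.1, size=(8, 3)) + np.array([0.0, 0.0, 2.0])
        res = rm_anova(_long(values))
        assert len(res.posthoc) == 3
        sig = [c for c, p, _ in res.posthoc if p < 0.05]
        assert any("l2" in c for c in sig)

    def test_contract_minimums(self, rng):
        with pytest.raises(ValueError, match="levels"):
            rm_anova(_long(rng.normal(size=(5, 1))))
        with pytest.raises(ValueError, match="subjects"):
            rm_anova(_long(rng.normal(size=(2, 3))))

    def test_incomplete_subject_dropped(self, rng):
        df = _long(rng.normal(size=(5, 3)))
        df = df[~((df.subject == "s0") & (df.level == "l2"))]
        res = rm_anova(df)
        assert res.notes["dropped_incomplete"] == 1
        assert res.notes["subjects"] == 4


def test_holm_adjustment_worked_example():
    adj = holm_adjust([0.01, 0.03, 0.04])
    np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])
    assert (adj[0] < 0.05) and (adj[1] >= 0.05) and (adj[2] >= 0.05)


def _mixed_oracle(values, groups):
    """Balanced two-group mixed design: brute-force SS decomposition."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n, k = values.shape
    grand = values.mean()
    uniq = np.unique(groups)
    subj_means = values.mean(axis=1)
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_groups = sum(
        k * (groups == g).sum() * (values[groups == g].mean() - grand) ** 2 for g in uniq
    )
    ss_subj_within = ss_between_subj - ss_groups
    ss_levels = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_inter = 0.0
    for g in uniq:
        vg = values[groups == g]
        ss_inter += vg.shape[0] * (
            (vg.mean(axis=0) - vg.mean() - values.mean(axis=0) + grand) ** 2
        ).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_levels - ss_inter
    df_g, df_sw = len(uniq) - 1, n - len(uniq)
    df_l, df_i, df_e = k - 1, (k - 1) * (len(uniq) - 1), (k - 1) * (n - len(uniq))
    return {
        "group": (ss_groups / df_g) / (ss_subj_within / df_sw),
        "level": (ss_levels / df_l) / (ss_err / df_e),
        "interaction": (ss_inter / df_i) / (ss_err / df_e),
    }


class TestMixedAnova:
    def test_matches_brute_force_oracle(self, rng):
        values = rng.normal(size=(8, 3)) + np.array([0.0, 0.4, 0.9])
        groups = np.array(["x"] * 4 + ["y"] * 4)
        values[4:] += 0.7  # group main effect
        res = mixed_anova(_long(values, groups=groups), within="level", between="group")
        oracle = _mixed_oracle(values, groups)
        by_effect = {r.effect.lower(): r for r in res}
        assert by_effect["group"].F == pytest.approx(oracle["group"], rel=1e-6)
        assert by_effect["level"].F == pytest.approx(oracle["level"], rel=1e-6)
        assert by_effect["interaction"].F == pytest.approx(oracle["interaction"], rel=1e-6)

    def test_singleton_group_rejected_with_instruction(self, rng):
        values = rng.normal(size=(5, 3))
        groups = np.array(["x"] * 4 + ["solo"])
        with pytest.raises(ValueError, match="singleton|single subject"):
            mixed_anova(_long(values, groups=groups), within="level", between="group")

    def test_constant_between_reduces_to_rm(self, rng):
        values = rng.normal(size=(6, 3)) + np.array([0.0, 0.5, 1.0])
        res = mixed_anova(_long(values), within="level", between="group")
        assert len(res) == 1
        assert "between_degenerate" in res[0].notes
        assert res[0].F == pytest.approx(rm_anova(_long(values)).F)

    def test_null_calibration_between_effect(self, rng):
        # no true effects: between-group p should be non-extreme most of the time
        pvals = []
        for _ in range(50):
            values = rng.normal(size=(8, 3))
            groups = np.array(["x"] * 4 + ["y"] * 4)
            res = mixed_anova(_long(values, groups=groups), within="level", between="group")
            pvals.append({r.effect.lower(): r.p for r in res}["group"])
        # under the null ~5% of p-values fall below 0.05; allow binomial slack
        assert np.mean(np.array(pvals) < 0.05) < 0.2
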