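"""Condition contrasts: repeated-measures and mixed-design ANOVA.

Thin, contract-checked wrappers around pingouin's classical decompositions:
one-way repeated-measures ANOVA (F = MS_factor / MS_(factor x subject)) with
Holm-Bonferroni-adjusted paired post hoc t-tests, and the mixed factorial
design with a within-subject factor (task mode) and a between-subject factor
(dyadic gender composition).  No sphericity correction is applied by default;
Greenhouse-Geisser is available via ``correction="gg"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from statsmodels.stats.multitest import multipletests

__all__ = ["StatResult", "rm_anova", "mixed_anova", "holm_adjust"]


@dataclass
class StatResult:
    """One tested effect with its post hoc contrasts."""

    effect: str
    F: float
    df: tuple[float, float]
    p: float
    posthoc: list = field(default_factory=list)  # (contrast, adjusted p, direction)
    table: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{self.effect}: F({self.df[0]:g}, {self.df[1]:g}) = {self.F:.2f}, p = {self.p:.4g}"]
        for contrast, p_adj, direction in self.posthoc:
            lines.append(f"  post hoc {contrast}: p_holm = {p_adj:.4g} ({direction})")
        for k, v in self.notes.items():
            lines.append(f"  note: {k} = {v}")
        return "\n".join(lines)


def holm_adjust(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    _, adj, _, _ = multipletests(p, method="holm")
    return adj


def _drop_incomplete(data: pd.DataFrame, subject: str, within: str) -> tuple[pd.DataFrame, int]:
    levels = data[within].unique()
    counts = data.groupby(subject)[within].nunique()
    complete = counts[counts == len(levels)].index
    dropped = int((counts != len(levels)).sum())
    return data[data[subject].isin(complete)], dropped


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    subject: str = "subject",
    correction: str | None = None,
) -> StatResult:
    """One-way repeated-measures ANOVA with Holm-adjusted paired post hocs.

    Subjects missing any factor level are dropped (count in ``notes``).
    A zero within-subject error mean square yields an undefined F (nan
    sentinel) rather than an exception.
    """
    data, dropped = _drop_incomplete(data, subject, within)
    levels = list(pd.unique(data[within]))
    n_subj = data[subject].nunique()
    if len(levels) < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 factor levels")
    if n_subj < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 subjects")
    aov = pg.rm_anova(
        data=data, dv=dv, within=within, subject=subject,
        correction=(correction == "gg"), detailed=True,
    )
    row = aov.loc[aov["Source"] == within].iloc[0]
    p_col = "p_GG_corr" if correction == "gg" and "p_GG_corr" in aov.columns else "p_unc"
    # a zero error mean square makes pingouin drop the F/p columns entirely
    f_raw = row.get("F", float("nan"))
    p_raw = row.get(p_col, float("nan"))
    f_val = float(f_raw) if np.isfinite(f_raw) else float("nan")
    posthoc = []
    if len(levels) > 2:
        ph = pg.pairwise_tests(
            data=data, dv=dv, within=within, subject=subject, padjust="holm"
        )
        for _, r in ph.iterrows():
            tstat = r.get("T", float("nan"))
            if not np.isfinite(tstat):
                direction = "="
            else:
                direction = ">" if tstat > 0 else ("<" if tstat < 0 else "=")
            p_adj = r.get("p_corr", float("nan"))
            if not np.isfinite(p_adj):
                p_adj = float(r.get("p_unc", float("nan")))
            posthoc.append((f"{r['A']} vs {r['B']}", float(p_adj), direction))
    return StatResult(
        effect=within,
        F=f_val,
        df=(float(row["DF"]), float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0])),
        p=float(p_raw) if np.isfinite(p_raw) else float("nan"),
        posthoc=posthoc,
        table=aov,
        notes={"subjects": n_subj, "dropped_incomplete": dropped},
    )


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "mode",
    between: str = "gender",
    subject: str = "subject",
) -> list[StatResult]:
    """Mixed factorial ANOVA: within main effect, between main effect, interaction.

    Between-subject groups with a single subject must be excluded by the
    caller (an error says so); a constant between factor degenerates to the
    repeated-measures ANOVA for the within effect, flagged in ``notes``.
    """
    data, dropped = _drop_incomplete(data, subject, within)
    group_sizes = data.groupby(between)[subject].nunique()
    if (group_sizes == 1).any():
        bad = list(group_sizes[group_sizes == 1].index)
        raise ValueError(
            f"between-subject group(s) {bad} contain a single subject; "
            "exclude singleton groups before calling mixed_anova"
        )
    if len(group_sizes) < 2:
        res = rm_anova(data, dv=dv, within=within, subject=subject)
        res.notes["between_degenerate"] = "between factor constant; within effect only"
        return [res]
    aov = pg.mixed_anova(data=data, dv=dv, within=within, between=between, subject=subject)
    out = []
    for _, row in aov.iterrows():
        out.append(
            StatResult(
                effect=str(row["Source"]),
                F=float(row["F"]) if np.isfinite(row["F"]) else float("nan"),
                df=(float(row["DF1"]), float(row["DF2"])),
                p=float(row["p_unc"]) if np.isfinite(row["p_unc"]) else float("nan"),
                table=aov,
                notes={"dropped_incomplete": dropped},
            )
        )
    return out
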