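"""End-to-end orchestration: recordings -> connectivity -> null -> behavior -> stats.

A :class:`RunConfig` (YAML-loadable) drives a deterministic run over synthetic
dyads or XDF recordings and writes plain CSV/JSON artifacts:

``plv_timecourse.csv``
    baseline-corrected connectivity time courses averaged over all cross-brain
    channel pairs, per dyad/mode/band
``plv_event.csv``
    event-window (200-500 ms) connectivity per dyad/mode/band, with the
    repeated-measures mode contrast in ``stats_plv_event.csv``
``mode_difference.csv``
    per-channel-pair mode differences with FDR-corrected paired-test p-values
``null_test.csv``
    true-vs-shuffled bootstrap z/p/q per channel pair and band/mode
``tst.csv`` / ``gaze_metrics.csv``
    behavioral tables (target-searching times; Dist_gaze and heatmap
    similarity per mode)
``stats_*.csv``
    repeated-measures and mixed (mode x gender composition) ANOVA tables
``manifest.json``
    config hash, seed, package/library versions, per-stage timings and
    exclusion counts
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, is_dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import __version__
from .behavior import dyad_gaze_metrics, tst_summaries, tst_table
from .connectivity import (
    CANONICAL_BANDS,
    aggregate_by_region,
    analytic_band,
    baseline_correct,
    event_window_mean,
    pair_connectivity,
)
from .io import DyadRecording, read_recording, read_xdf, write_recording
from .montage import REGION_MAP_NOTES
from .nulls import connectivity_for_pairs, dyad_null_test, enumerate_shuffled_pairs, fdr_bh
from .preprocess import preprocess_recording
from .simulate import SimConfig, simulate_dyad
from .stats import mixed_anova, rm_anova

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "STAGES"]

STAGES = ("simulate", "preprocess", "connectivity", "null", "behavior", "stats")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    input: str = "synthetic"  # or "xdf"
    xdf_paths: list = field(default_factory=list)
    stream_map: dict = field(default_factory=dict)
    marker_translation: dict = field(default_factory=dict)
    sim: SimConfig = field(default_factory=lambda: SimConfig(n_dyads=2))
    bands: tuple = ("delta", "theta", "alpha", "beta", "gamma")
    measures: tuple = ("plv",)
    baseline_window: tuple = (-3.0, 0.0)
    event_window: tuple = (0.2, 0.5)
    n_boot: int = 1000
    m: int | None = 200
    q: float = 0.05
    heatmap_cells: tuple = (96, 54)
    heatmap_sigma_px: float = 20.0
    search_window_only: bool = True
    seed: int = 0
    outdir: str = "ibsync_out"

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        tmin, tmax = -3.0, 10.0
        for w in (self.baseline_window, self.event_window):
            if not (tmin <= w[0] < w[1] <= tmax):
                raise ValueError(f"window {w} outside the epoch span [{tmin}, {tmax}]")
        for b in self.bands:
            if b not in CANONICAL_BANDS:
                raise ValueError(f"unknown band {b!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim_raw:
            cfg.sim = SimConfig(**sim_raw)
        if "seed" in raw:
            cfg.sim = _with_seed(cfg.sim, int(raw["seed"]))
        return cfg

    def to_dict(self) -> dict:
        def conv(v):
            if is_dataclass(v) and not isinstance(v, type):
                return {k: conv(x) for k, x in asdict(v).items()}
            if isinstance(v, (np.ndarray,)):
                return v.tolist()
            if isinstance(v, (tuple, list)):
                return [conv(x) for x in v]
            if isinstance(v, dict):
                return {str(k): conv(x) for k, x in v.items()}
            return v

        return {k: conv(getattr(self, k)) for k in self.__dataclass_fields__}


def _with_seed(sim: SimConfig, seed: int) -> SimConfig:
    d = {f: getattr(sim, f) for f in sim.__dataclass_fields__}
    d["seed"] = seed
    return SimConfig(**d)


def _load_recordings(config: RunConfig):
    recs, truths = [], []
    if config.input == "synthetic":
        sim = _with_seed(config.sim, config.seed) if config.sim.seed != config.seed else config.sim
        for d in range(sim.n_dyads):
            rec, truth = simulate_dyad(sim, d)
            recs.append(rec)
            truths.append(truth)
    elif config.input == "xdf":
        for k, path in enumerate(config.xdf_paths):
            rec = read_xdf(path, config.stream_map, config.marker_translation or None)
            rec.meta.setdefault("dyad_id", k)
            recs.append(rec)
            truths.append(None)
    else:
        raise ValueError(f"unknown input mode {config.input!r}")
    if not recs:
        raise ValueError("no recordings to analyse")
    return recs, truths


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages and write artifacts to ``config.outdir``.

    Returns a results bundle (dict of DataFrames / NullModels / paths).
    Reruns with an identical config and seed produce identical tables.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "versions": {"ibsync": __version__, "numpy": np.__version__},
        "region_map_note": REGION_MAP_NOTES,
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        recs, truths = _load_recordings(config)
        bundle["recordings"] = recs
        bundle["truths"] = truths
        manifest["stages"]["simulate"] = {"seconds": round(time.perf_counter() - t0, 3),
                                          "n_dyads": len(recs)}
        if "preprocess" in stages or not set(stages).isdisjoint(("connectivity", "null")):
            stage = "preprocess"
            t0 = time.perf_counter()
            epochs = {}
            dropped = {}
            for rec in recs:
                ep_a, ep_b = preprocess_recording(rec)
                did = rec.meta.get("dyad_id", len(epochs))
                epochs[did] = (ep_a, ep_b)
                dropped[str(did)] = ep_a.meta.get("n_dropped", 0)
            bundle["epochs"] = epochs
            manifest["stages"]["preprocess"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "dropped_trials": dropped,
            }
        if "connectivity" in stages or "null" in stages:
            stage = "connectivity"
            t0 = time.perf_counter()
            _connectivity_stage(config, bundle)
            manifest["stages"]["connectivity"] = {"seconds": round(time.perf_counter() - t0, 3)}
        if "null" in stages:
            stage = "null"
            t0 = time.perf_counter()
            _null_stage(config, bundle)
            manifest["stages"]["null"] = {"seconds": round(time.perf_counter() - t0, 3)}
        if "behavior" in stages:
            stage = "behavior"
            t0 = time.perf_counter()
            _behavior_stage(config, bundle)
            manifest["stages"]["behavior"] = {"seconds": round(time.perf_counter() - t0, 3)}
        if "stats" in stages:
            stage = "stats"
            t0 = time.perf_counter()
            _stats_stage(config, bundle)
            manifest["stages"]["stats"] = {"seconds": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, exc) from exc

    _write_outputs(config, bundle, out)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["outdir"] = out
    return bundle


def _connectivity_stage(config: RunConfig, bundle: dict) -> None:
    epochs = bundle["epochs"]
    timecourses = []
    event_rows = []
    event_mats: dict = {}
    phasors: dict = {}
    for did, (ep_a, ep_b) in epochs.items():
        modes = list(pd.unique(ep_a.labels["mode"]))
        for bname in config.bands:
            band = CANONICAL_BANDS[bname]
            ta = analytic_band(ep_a, band)
            tb = analytic_band(ep_b, band)
            for mode in modes:
                idx = np.flatnonzero((ep_a.labels["mode"] == mode).to_numpy())
                ta_m, tb_m = ta.select_trials(idx), tb.select_trials(idx)
                for measure in config.measures:
                    pc = pair_connectivity(ta_m, tb_m, measure)
                    ev_raw = event_window_mean(pc, config.event_window)
                    pc_bc = baseline_correct(pc, config.baseline_window)
                    ev_bc = event_window_mean(pc_bc, config.event_window)
                    mean_tc = pc_bc.values.mean(axis=(0, 1))
                    timecourses.append(
                        pd.DataFrame(
                            {
                                "dyad": did, "mode": mode, "band": bname,
                                "measure": measure, "time_s": pc.times, "value": mean_tc,
                            }
                        )
                    )
                    event_rows.append(
                        {
                            "dyad": did, "mode": mode, "band": bname, "measure": measure,
                            "plv_event_bc": float(ev_bc.mean()),
                            "plv_event_raw": float(ev_raw.mean()),
                        }
                    )
                    event_mats[(did, mode, bname, measure)] = {"raw": ev_raw, "bc": ev_bc}
                # event-window phasors per participant, for the shuffled null
                for role, tt in (("A", ta_m), ("B", tb_m)):
                    eps = 1e-9
                    w = config.event_window
                    mask = (tt.times >= w[0] - eps) & (tt.times <= w[1] + eps)
                    v = tt.values[..., mask]
                    phasors[((did, role), mode, bname)] = (
                        v / np.maximum(np.abs(v), np.finfo(float).eps)
                    ).astype(np.complex64)
    bundle["timecourse"] = pd.concat(timecourses, ignore_index=True)
    bundle["plv_event"] = pd.DataFrame(event_rows)
    bundle["event_mats"] = event_mats
    bundle["phasors"] = phasors

    # per-channel-pair mode differences (paired across dyads) with FDR
    diff_rows = []
    dyads = sorted(epochs)
    if len(dyads) >= 3:
        ev = bundle["plv_event"]
        for bname in config.bands:
            for measure in config.measures:
                for m1, m2 in combinations(sorted(ev["mode"].unique()), 2):
                    stack1 = np.stack([event_mats[(d, m1, bname, measure)]["raw"] for d in dyads])
                    stack2 = np.stack([event_mats[(d, m2, bname, measure)]["raw"] for d in dyads])
                    tstat, pval = sstats.ttest_rel(stack1, stack2, axis=0)
                    qval, rej = fdr_bh(np.nan_to_num(pval, nan=1.0), config.q)
                    mean_diff = (stack1 - stack2).mean(axis=0)
                    ii, jj = np.meshgrid(range(mean_diff.shape[0]), range(mean_diff.shape[1]), indexing="ij")
                    diff_rows.append(
                        pd.DataFrame(
                            {
                                "band": bname, "measure": measure,
                                "contrast": f"{m1}-{m2}",
                                "chanA": ii.ravel(), "chanB": jj.ravel(),
                                "mean_diff": mean_diff.ravel(),
                                "p": pval.ravel(), "q": qval.ravel(),
                                "reject": rej.ravel(),
                            }
                        )
                    )
    bundle["mode_difference"] = (
        pd.concat(diff_rows, ignore_index=True) if diff_rows else pd.DataFrame()
    )


def _null_stage(config: RunConfig, bundle: dict) -> None:
    epochs = bundle["epochs"]
    dyads = sorted(epochs)
    if len(dyads) < 2:
        bundle["null"] = {}
        bundle["null_table"] = pd.DataFrame()
        return
    true_pairs = [((d, "A"), (d, "B")) for d in dyads]
    pseudo = enumerate_shuffled_pairs(true_pairs)
    results = {}
    tables = []
    modes = sorted(bundle["plv_event"]["mode"].unique())
    for bname in config.bands:
        for measure in config.measures:
            for mode in modes:
                tensors = {
                    pid: bundle["phasors"][(pid, mode, bname)]
                    for pid in {p for pair in true_pairs for p in pair}
                }
                shuf = connectivity_for_pairs(tensors, pseudo, measure, config.event_window)
                shuffled = np.stack([shuf[p] for p in pseudo])
                true_vals = np.stack(
                    [bundle["event_mats"][(d, mode, bname, measure)]["raw"] for d in dyads]
                )
                nm = dyad_null_test(
                    true_vals, shuffled,
                    n_boot=config.n_boot, m=config.m, q=config.q,
                    seed=config.seed, measure=measure, band=f"{bname}:{mode}",
                )
                results[(bname, mode, measure)] = nm
                t = nm.to_frame()
                t.insert(0, "mode", mode)
                tables.append(t)
    bundle["null"] = results
    bundle["null_table"] = pd.concat(tables, ignore_index=True)


def _behavior_stage(config: RunConfig, bundle: dict) -> None:
    tst_frames, gaze_frames = [], []
    for rec in bundle["recordings"]:
        did = rec.meta.get("dyad_id", 0)
        if len(rec.gaze_a) == 0:
            continue
        tst_frames.append(tst_table(rec.events, dyad_id=did))
        gaze_frames.append(
            dyad_gaze_metrics(
                rec, cells=tuple(config.heatmap_cells),
                sigma_px=config.heatmap_sigma_px,
                search_window_only=config.search_window_only,
            )
        )
    bundle["tst"] = pd.concat(tst_frames, ignore_index=True) if tst_frames else pd.DataFrame()
    bundle["tst_summary"] = tst_summaries(bundle["tst"]) if len(bundle["tst"]) else pd.DataFrame()
    bundle["gaze_metrics"] = (
        pd.concat(gaze_frames, ignore_index=True) if gaze_frames else pd.DataFrame()
    )


def _stats_stage(config: RunConfig, bundle: dict) -> None:
    stats_tables = {}
    gm = bundle.get("gaze_metrics", pd.DataFrame())
    if len(gm) and gm["dyad"].nunique() >= 3 and gm["mode"].nunique() >= 2:
        for metric in ("dist_gaze", "jaccard", "ssim", "pearson"):
            sub = gm.dropna(subset=[metric])
            try:
                res = rm_anova(sub, dv=metric, within="mode", subject="dyad")
                stats_tables[f"rm_{metric}"] = res
            except ValueError:
                continue
        genders = {
            rec.meta.get("dyad_id", k): rec.meta.get("gender_composition", "FF")
            for k, rec in enumerate(bundle["recordings"])
        }
        gm2 = gm.assign(gender=gm["dyad"].map(genders))
        sizes = gm2.groupby("gender")["dyad"].nunique()
        gm2 = gm2[gm2["gender"].isin(sizes[sizes >= 2].index)]
        if gm2["gender"].nunique() >= 2:
            try:
                stats_tables["mixed_jaccard"] = mixed_anova(
                    gm2.dropna(subset=["jaccard"]), dv="jaccard",
                    within="mode", between="gender", subject="dyad",
                )
            except ValueError:
                pass
    ev = bundle.get("plv_event", pd.DataFrame())
    if len(ev) and ev["dyad"].nunique() >= 3:
        for (bname, measure), sub in ev.groupby(["band", "measure"]):
            try:
                stats_tables[f"rm_event_{measure}_{bname}"] = rm_anova(
                    sub, dv="plv_event_bc", within="mode", subject="dyad"
                )
            except ValueError:
                continue
    tst = bundle.get("tst", pd.DataFrame())
    if len(tst):
        first = tst[(tst["k"] == 1) & (tst["n_targets"] == 1)]
        pivot = first.groupby(["dyad", "participant", "mode"])["tst"].mean().reset_index()
        pivot["subject"] = pivot["dyad"].astype(str) + "/" + pivot["participant"]
        if pivot["subject"].nunique() >= 3 and pivot["mode"].nunique() >= 2:
            try:
                stats_tables["rm_tst_first_one_target"] = rm_anova(
                    pivot, dv="tst", within="mode", subject="subject"
                )
            except ValueError:
                pass
    bundle["stats"] = stats_tables


def _write_outputs(config: RunConfig, bundle: dict, out: Path) -> None:
    if "timecourse" in bundle:
        bundle["timecourse"].to_csv(out / "plv_timecourse.csv", index=False)
        bundle["plv_event"].to_csv(out / "plv_event.csv", index=False)
        bundle["mode_difference"].to_csv(out / "mode_difference.csv", index=False)
        # region-aggregated event matrices
        rows = []
        from .montage import REGIONS
        for (did, mode, bname, measure), mats in bundle["event_mats"].items():
            reg = aggregate_by_region(mats["raw"])
            for i, ra in enumerate(REGIONS):
                for j, rb in enumerate(REGIONS):
                    rows.append(
                        {
                            "dyad": did, "mode": mode, "band": bname, "measure": measure,
                            "regionA": ra, "regionB": rb, "value": reg[i, j],
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "plv_event_regions.csv", index=False)
    if "null_table" in bundle and len(bundle["null_table"]):
        bundle["null_table"].to_csv(out / "null_test.csv", index=False)
    if "tst" in bundle:
        bundle["tst"].to_csv(out / "tst.csv", index=False)
        bundle["tst_summary"].to_csv(out / "tst_summary.csv", index=False)
        bundle["gaze_metrics"].to_csv(out / "gaze_metrics.csv", index=False)
    if "stats" in bundle:
        lines = []
        for name, res in bundle["stats"].items():
            items = res if isinstance(res, list) else [res]
            for r in items:
                lines.append(
                    {
                        "analysis": name, "effect": r.effect, "F": r.F,
                        "df1": r.df[0], "df2": r.df[1], "p": r.p,
                        "posthoc": "; ".join(f"{c}:{p:.4g}{d}" for c, p, d in r.posthoc),
                    }
                )
        pd.DataFrame(lines).to_csv(out / "stats_summary.csv", index=False)


def save_recordings(bundle: dict, out: Path) -> list[Path]:
    paths = []
    for rec in bundle["recordings"]:
        p = Path(out) / f"dyad_{rec.meta.get('dyad_id', 0):02d}.h5"
        write_recording(rec, p)
        paths.append(p)
    return paths
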