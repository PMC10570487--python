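"""Dyadic gaze-behavior metrics.

Target-searching time (TST): the lock onset of a target is defined as 700 ms
before its identification; the first TST of a trial runs from stimulus onset
to the first lock onset, and each subsequent TST from one lock onset to the
next.  Participant-level summaries use a 10%-trimmed mean (ceil(0.05 n) values
removed per tail).

Inter-gaze distance (Dist_gaze): per-sample Euclidean distance between the two
participants' gaze points after interpolation onto a common uniform clock,
averaged over jointly valid samples — by default over the 10-s search window
of each trial.

Gaze heatmaps are occupancy histograms over a cell grid (default 96 x 54
cells, i.e. 20-px cells on a 1920 x 1080 screen), Gaussian-smoothed and
normalised to unit mass; dyad similarity is quantified by Pearson's r, SSIM
and the Jaccard coefficient of the above-uniform-density supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.metrics import structural_similarity

from .io import DyadRecording, EventList, GazeTrack

__all__ = [
    "Heatmap",
    "lock_onsets",
    "tst_sequence",
    "tst_table",
    "trimmed_mean",
    "gaze_distance",
    "gaze_heatmap",
    "heatmap_similarity",
    "dyad_gaze_metrics",
]

LOCK_LEAD_S = 0.7  # lock onset precedes target identification by 700 ms


@dataclass
class Heatmap:
    """Occupancy-probability grid over the screen (rows = y, cols = x)."""

    grid: np.ndarray  # (H, W), non-negative, sums to 1
    extent: tuple[float, float]  # screen (width, height) in pixels
    sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.grid < 0):
            raise ValueError("heatmap cells must be non-negative")


def lock_onsets(events: EventList, participant: str | None = None) -> pd.DataFrame:
    """Per-trial lock-onset times from identification markers.

    Returns a frame with columns trial, participant, cell, ident_s, onset_s
    (identification minus 700 ms, relative to stimulus onset), and ``clamped``
    for identifications less than 700 ms after the stimulus (onset clamped to
    the stimulus time).
    """
    stims = events.stimulus_onsets
    if stims.size == 0:
        raise ValueError("no stimulus_onset events")
    rows = []
    idents = events.select("identified:")
    for t, code in zip(idents.times, idents.codes):
        _, who, cell = code.split(":")
        if participant is not None and who != participant:
            continue
        k = int(np.searchsorted(stims, t + 1e-9) - 1)
        if k < 0:
            continue
        rel = t - stims[k]
        clamped = rel < LOCK_LEAD_S - 1e-9
        rows.append(
            {
                "trial": k,
                "participant": who,
                "cell": int(cell),
                "ident_s": rel,
                "onset_s": 0.0 if clamped else max(rel - LOCK_LEAD_S, 0.0),
                "clamped": clamped,
            }
        )
    df = pd.DataFrame(rows, columns=["trial", "participant", "cell", "ident_s", "onset_s", "clamped"])
    return df.sort_values(["trial", "onset_s"]).reset_index(drop=True)


def tst_sequence(onsets: np.ndarray, stimulus_time: float = 0.0) -> np.ndarray:
    """Target-searching times from ordered lock onsets.

    ``TST_1 = onset_1 - stimulus``; ``TST_k = onset_k - onset_{k-1}``.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        return onsets
    if np.any(np.diff(onsets) < 0):
        raise ValueError("lock onsets must be sorted")
    return np.diff(onsets, prepend=stimulus_time)


def trimmed_mean(values, trim: float = 0.10, return_flag: bool = False):
    """Mean after removing ceil(trim/2 * n) smallest and largest values.

    Falls back to the median when trimming would empty the sample (flag set).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty input")
    k = math.ceil(0.5 * trim * v.size)
    if 2 * k >= v.size:
        out, flag = float(np.median(v)), True
    else:
        out, flag = float(v[k : v.size - k].mean()), False
    return (out, flag) if return_flag else out


def tst_table(events: EventList, dyad_id=0) -> pd.DataFrame:
    """Long-format TST table: one row per (trial, participant, target order k)."""
    stims = events.stimulus_onsets
    locks = lock_onsets(events)
    targets = events.select("targets:")
    n_targets = np.zeros(stims.size, dtype=int)
    for t, code in zip(targets.times, targets.codes):
        k = int(np.searchsorted(stims, t + 1e-9) - 1)
        if 0 <= k < stims.size:
            n_targets[k] = int(code.split(":")[1])
    rows = []
    for (trial, who), grp in locks.groupby(["trial", "participant"]):
        tsts = tst_sequence(grp["onset_s"].to_numpy())
        mode, run = events.mode_at(stims[int(trial)])
        for k, tst in enumerate(tsts, start=1):
            rows.append(
                {
                    "dyad": dyad_id,
                    "participant": who,
                    "mode": mode,
                    "run": run,
                    "trial": int(trial),
                    "n_targets": int(n_targets[int(trial)]),
                    "k": k,
                    "tst": float(tst),
                }
            )
    return pd.DataFrame(
        rows, columns=["dyad", "participant", "mode", "run", "trial", "n_targets", "k", "tst"]
    )


def tst_summaries(table: pd.DataFrame, trim: float = 0.10) -> pd.DataFrame:
    """Trimmed-mean TST per (dyad, participant, mode, n_targets, k)."""
    if table.empty:
        return table
    out = (
        table.groupby(["dyad", "participant", "mode", "n_targets", "k"])["tst"]
        .apply(lambda v: trimmed_mean(v, trim))
        .reset_index(name="tst_trimmed_mean")
    )
    return out


def _interp_track(track: GazeTrack, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.interp(t, track.t, track.x)
    y = np.interp(t, track.t, track.y)
    # a resampled point is valid only if both neighbouring samples are valid
    v = np.interp(t, track.t, track.valid.astype(float)) > 1.0 - 1e-9
    return x, y, v


def gaze_distance(
    a: GazeTrack,
    b: GazeTrack,
    window: tuple[float, float] | None = None,
    fs: float | None = None,
) -> float:
    """Mean Euclidean inter-gaze distance (pixels) over jointly valid samples."""
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    if window is not None:
        t0, t1 = max(t0, window[0]), min(t1, window[1])
    if t1 <= t0:
        raise ValueError("tracks have no overlapping time range in the window")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(a.t))) if len(a) > 1 else 30.0
    t = np.arange(t0, t1, 1.0 / fs)
    xa, ya, va = _interp_track(a, t)
    xb, yb, vb = _interp_track(b, t)
    ok = va & vb
    if not ok.any():
        raise ValueError("no jointly valid samples")
    return float(np.hypot(xa[ok] - xb[ok], ya[ok] - yb[ok]).mean())


def gaze_heatmap(
    track: GazeTrack,
    extent: tuple[float, float] = (1920.0, 1080.0),
    cells: tuple[int, int] = (96, 54),
    sigma_px: float = 0.0,
    window: tuple[float, float] | None = None,
) -> Heatmap:
    """Occupancy histogram of valid gaze samples, smoothed and normalised.

    ``cells`` is (n_x, n_y); the returned grid is (n_y, n_x) row-major in y.
    """
    mask = track.valid.copy()
    if window is not None:
        mask &= (track.t >= window[0]) & (track.t < window[1])
    x, y = track.x[mask], track.y[mask]
    if x.size == 0:
        raise ValueError("no valid gaze samples for the heatmap")
    nx, ny = cells
    h, _, _ = np.histogram2d(
        y, x, bins=(ny, nx), range=((0, extent[1]), (0, extent[0]))
    )
    if sigma_px > 0:
        cell_w = extent[0] / nx
        cell_h = extent[1] / ny
        h = ndimage.gaussian_filter(h, sigma=(sigma_px / cell_h, sigma_px / cell_w))
    total = h.sum()
    if total == 0:
        raise ValueError("all gaze samples fall outside the screen extent")
    return Heatmap(grid=h / total, extent=extent, sigma_px=sigma_px)


def heatmap_similarity(
    a: Heatmap,
    b: Heatmap,
    jaccard_threshold: float | None = None,
    ssim_win: int = 7,
) -> dict[str, float]:
    """Pearson r, SSIM and Jaccard coefficient between two heatmaps.

    Jaccard binarises each map at ``jaccard_threshold`` (default: the uniform
    density 1/(H*W), i.e. cells occupied above chance).  A zero-variance map
    yields ``nan`` for Pearson's r.
    """
    if a.grid.shape != b.grid.shape:
        raise ValueError("heatmap grids must have the same shape")
    ga, gb = a.grid, b.grid
    if ga.std() == 0 or gb.std() == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(ga.ravel(), gb.ravel())[0, 1])
    sa = ga / ga.max() if ga.max() > 0 else ga
    sb = gb / gb.max() if gb.max() > 0 else gb
    ssim = float(structural_similarity(sa, sb, win_size=ssim_win, data_range=1.0))
    thr = 1.0 / ga.size if jaccard_threshold is None else jaccard_threshold
    ba_, bb_ = ga > thr, gb > thr
    union = np.logical_or(ba_, bb_).sum()
    jac = float(np.logical_and(ba_, bb_).sum() / union) if union else 0.0
    return {"pearson": pearson, "ssim": ssim, "jaccard": jac}


def dyad_gaze_metrics(
    rec: DyadRecording,
    cells: tuple[int, int] = (96, 54),
    sigma_px: float = 20.0,
    search_window_only: bool = True,
) -> pd.DataFrame:
    """Per-mode Dist_gaze and heatmap similarity for one dyad's recording.

    Dist_gaze is averaged per trial over the search window (full trial when
    ``search_window_only`` is false) and then across trials of the mode;
    heatmaps pool all trials of the mode.
    """
    events = rec.events
    stims = events.stimulus_onsets
    ends = events.select("trial_end").times
    extent = (
        float(rec.meta.get("screen_w", 1920.0)),
        float(rec.meta.get("screen_h", 1080.0)),
    )
    rows = []
    by_mode: dict[str, list] = {}
    for k, t_stim in enumerate(stims):
        mode, _ = events.mode_at(t_stim)
        t_end = ends[np.searchsorted(ends, t_stim)] if len(ends) else t_stim + 10.0
        win = (t_stim, t_end) if search_window_only else (t_stim - 3.0, t_end)
        by_mode.setdefault(mode, []).append(win)
    for mode, wins in by_mode.items():
        dists = []
        for win in wins:
            try:
                dists.append(gaze_distance(rec.gaze_a, rec.gaze_b, window=win))
            except ValueError:
                continue
        masks = lambda tr: np.logical_or.reduce(
            [(tr.t >= w0) & (tr.t < w1) for w0, w1 in wins]
        )
        ha = gaze_heatmap(
            GazeTrack(rec.gaze_a.t, rec.gaze_a.x, rec.gaze_a.y, rec.gaze_a.valid & masks(rec.gaze_a)),
            extent, cells, sigma_px,
        )
        hb = gaze_heatmap(
            GazeTrack(rec.gaze_b.t, rec.gaze_b.x, rec.gaze_b.y, rec.gaze_b.valid & masks(rec.gaze_b)),
            extent, cells, sigma_px,
        )
        sim = heatmap_similarity(ha, hb)
        rows.append(
            {
                "dyad": rec.meta.get("dyad_id", 0),
                "mode": mode,
                "dist_gaze": float(np.mean(dists)) if dists else float("nan"),
                **sim,
            }
        )
    return pd.DataFrame(rows)
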