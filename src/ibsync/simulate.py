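"""Synthetic dyad recordings with known interbrain coupling and gaze coordination.

The generator emulates a two-person joint-attention paradigm: each trial is a
3-s fixation cross, a 300-ms auditory stimulus, and a 10-s search window on a
4 x 4 character matrix (the stimulus overlaps the start of the search window,
so one trial spans 13 s).  Each mode (single-player, cooperation, competition)
contributes 20 trials per run over 2 runs.

EEG model
---------
Each participant's 32 channels are sums of band-limited oscillators plus 1/f
background noise.  Within a band, participant A's channel phase ramps at the
band's centre frequency with a slow Brownian jitter; participant B's matched
channel follows A's phase up to a fixed channel offset plus wrapped-normal
noise drawn once per trial — with standard deviation ``sigma_event`` inside
the post-stimulus coupling window and ``sigma_base`` elsewhere.  The
asymptotic phase-locking value of such a pair is ``exp(-sigma^2 / 2)``
(resultant length of a wrapped normal), which is the generator's closed-form
ground truth.  Channels without a coupling entry (and all non-matched channel
pairs) receive independent uniform phase offsets per trial and therefore sit
at the finite-trial uniform-phase floor.

Gaze model
----------
Players inspect grid cells in a random order (brief dwell on distractors,
marking dwell on targets: a target locks after a strictly greater than 0.7-s
continuous within-cell dwell).  Partner B's step is a convex combination of
its own search drift and the social term ``attraction x direction toward A``;
repulsion (negative attraction) acts as a proximity-gated avoidance force.
In single-player mode the observer free-drifts over the whole screen and only
the player produces lock events; in competition both participants search and
each target is marked by whoever locks it first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import DyadRecording, EventList, GazeTrack
from .montage import CHANNELS, N_CHANNELS

__all__ = [
    "TrialLayout",
    "OscBand",
    "Coupling",
    "GridSpec",
    "GazeParams",
    "SimConfig",
    "GroundTruth",
    "simulate_dyad",
    "simulate_gaze_pair",
    "apply_mixing",
    "detect_locks",
]

MODES = ("single", "cooperation", "competition")


@dataclass(frozen=True)
class TrialLayout:
    fixation_s: float = 3.0
    stimulus_s: float = 0.3
    search_s: float = 10.0

    @property
    def trial_s(self) -> float:
        # the stimulus overlaps the start of the search window
        return self.fixation_s + self.search_s


@dataclass(frozen=True)
class OscBand:
    name: str
    lo: float
    hi: float
    amplitude: float  # microvolt

    @property
    def fc(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class Coupling:
    """Wrapped-normal phase-noise SDs (radians) outside/inside the event window."""

    sigma_base: float
    sigma_event: float

    def __post_init__(self) -> None:
        if self.sigma_base < 0 or self.sigma_event < 0:
            raise ValueError("phase-noise sigma must be non-negative")

    def expected_plv(self, window: str = "event") -> float:
        s = self.sigma_event if window == "event" else self.sigma_base
        return math.exp(-0.5 * s * s)


@dataclass(frozen=True)
class GridSpec:
    """Screen and 4 x 4 target-matrix geometry, in pixels."""

    width: int = 1920
    height: int = 1080
    n_rows: int = 4
    n_cols: int = 4
    cell_px: float = 180.0

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def origin(self) -> tuple[float, float]:
        return (
            (self.width - self.n_cols * self.cell_px) / 2.0,
            (self.height - self.n_rows * self.cell_px) / 2.0,
        )

    def cell_center(self, cell: int) -> tuple[float, float]:
        if not 0 <= cell < self.n_cells:
            raise ValueError(f"cell {cell} outside the {self.n_rows}x{self.n_cols} grid")
        r, c = divmod(cell, self.n_cols)
        x0, y0 = self.origin
        return (x0 + (c + 0.5) * self.cell_px, y0 + (r + 0.5) * self.cell_px)

    def cell_at(self, x: float, y: float) -> int:
        x0, y0 = self.origin
        c = int((x - x0) // self.cell_px)
        r = int((y - y0) // self.cell_px)
        if 0 <= c < self.n_cols and 0 <= r < self.n_rows:
            return r * self.n_cols + c
        return -1


@dataclass(frozen=True)
class GazeParams:
    fs: float = 30.0  # consumer eye-tracker class
    saccade_speed: float = 5000.0  # px/s toward the current waypoint
    jitter_px: float = 6.0  # fixational noise around the waypoint
    inspect_s: tuple[float, float] = (0.12, 0.28)  # distractor dwell range
    reaction_s: tuple[float, float] = (0.15, 0.35)  # delay before the search starts
    mark_dwell_s: float = 0.85  # target dwell (> lock threshold)
    lock_threshold_s: float = 0.7  # strictly greater than
    repel_scale_px: float = 250.0  # e-folding distance of the avoidance force
    observer_sd_px: float = 430.0  # stationary SD of the observer's drift


DEFAULT_BANDS: tuple[OscBand, ...] = (
    OscBand("delta", 1.0, 3.0, 8.0),
    OscBand("theta", 4.0, 7.0, 6.0),
    OscBand("alpha", 8.0, 12.0, 10.0),
    OscBand("beta", 13.0, 30.0, 4.0),
    OscBand("gamma", 31.0, 50.0, 2.0),
)

# Mode-dependent interbrain phase coupling in the slow bands: strongest and
# most event-locked during cooperation, weaker during competition, weakest in
# the player-observer mode.  Fast bands carry no built-in coupling.
DEFAULT_COUPLING: dict[str, dict[str, Coupling]] = {
    "delta": {
        "single": Coupling(1.3, 1.0),
        "cooperation": Coupling(1.1, 0.55),
        "competition": Coupling(1.2, 0.75),
    },
    "theta": {
        "single": Coupling(1.3, 1.0),
        "cooperation": Coupling(1.1, 0.55),
        "competition": Coupling(1.2, 0.75),
    },
}

DEFAULT_GAZE_COUPLING = {"single": 0.0, "cooperation": 0.8, "competition": -0.8}


@dataclass
class SimConfig:
    n_dyads: int = 1
    fs: float = 250.0
    layout: TrialLayout = field(default_factory=TrialLayout)
    n_trials_per_mode: int = 40  # 20 trials x 2 runs
    modes: tuple[str, ...] = MODES
    bands: tuple[OscBand, ...] = DEFAULT_BANDS
    coupling: dict = field(default_factory=lambda: {b: dict(m) for b, m in DEFAULT_COUPLING.items()})
    event_coupling_window: tuple[float, float] = (0.0, 1.0)  # s after stimulus
    noise_sd: float = 2.0  # microvolt RMS of the 1/f background
    phase_jitter: float = 0.02  # rad/sample Brownian jitter of the driver phase
    mixing: np.ndarray | None = None  # optional 64 x 64 instantaneous mixing
    gaze_coupling: dict = field(default_factory=lambda: dict(DEFAULT_GAZE_COUPLING))
    grid: GridSpec = field(default_factory=GridSpec)
    gaze: GazeParams = field(default_factory=GazeParams)
    simulate_gaze: bool = True
    simulate_eeg: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce plain-config (YAML) structures into their dataclasses
        if isinstance(self.layout, dict):
            self.layout = TrialLayout(**self.layout)
        if isinstance(self.grid, dict):
            self.grid = GridSpec(**self.grid)
        if isinstance(self.gaze, dict):
            self.gaze = GazeParams(**self.gaze)
        self.bands = tuple(
            b if isinstance(b, OscBand) else (OscBand(**b) if isinstance(b, dict) else OscBand(*b))
            for b in self.bands
        )
        if not self.bands:
            raise ValueError("at least one oscillator band is required")
        self.modes = tuple(self.modes)
        hi = max(b.hi for b in self.bands)
        if self.fs <= 2 * hi:
            raise ValueError(f"fs={self.fs} must exceed twice the highest band edge {hi}")
        if self.n_trials_per_mode % 2:
            raise ValueError("n_trials_per_mode must split evenly over 2 runs")
        for band, per_mode in self.coupling.items():
            for mode, c in per_mode.items():
                if mode not in MODES:
                    raise ValueError(f"unknown mode {mode!r} in coupling[{band!r}]")
                if c is not None and not isinstance(c, Coupling):
                    per_mode[mode] = Coupling(*c)
        for mode, a in self.gaze_coupling.items():
            if not -1.0 <= a <= 1.0:
                raise ValueError(f"gaze attraction for {mode!r} must be in [-1, 1], got {a}")
        if self.mixing is not None:
            _check_mixing(np.asarray(self.mixing))

    @property
    def n_trials_total(self) -> int:
        return self.n_trials_per_mode * len(self.modes)


@dataclass
class GroundTruth:
    """Closed-form targets for parameter recovery on one simulated dyad."""

    #: (mode, band) -> {"sigma_base", "sigma_event", "plv_base", "plv_event"}
    expected_plv: dict
    #: matched cross-brain channel pairs carrying the coupling, per band
    coupled_pairs: dict
    #: per-trial schedule: trial, mode, run, n_targets, target cells
    trials: pd.DataFrame
    #: true lock onsets: list of (trial, participant, cell, onset_s, ident_s)
    locks: list


def _check_mixing(m: np.ndarray) -> None:
    if m.shape != (2 * N_CHANNELS, 2 * N_CHANNELS):
        raise ValueError(f"mixing matrix must be {2 * N_CHANNELS} x {2 * N_CHANNELS}, got {m.shape}")
    ab = m[:N_CHANNELS, N_CHANNELS:]
    ba = m[N_CHANNELS:, :N_CHANNELS]
    if np.any(ab != 0) or np.any(ba != 0):
        raise ValueError("mixing must not cross heads: off-diagonal blocks must be zero")


def apply_mixing(rec: DyadRecording, m: np.ndarray) -> DyadRecording:
    """Instantaneous within-head channel mixing (volume-conduction emulation)."""
    m = np.asarray(m, dtype=float)
    _check_mixing(m)
    stacked = np.vstack([rec.eeg_a, rec.eeg_b])
    mixed = m @ stacked
    return replace(rec, eeg_a=mixed[:N_CHANNELS], eeg_b=mixed[N_CHANNELS:])


# ---------------------------------------------------------------------------
# Gaze simulation
# ---------------------------------------------------------------------------

class _Scanner:
    """Serial search agent: saccade to a waypoint cell, dwell, move on."""

    def __init__(self, grid: GridSpec, params: GazeParams, targets: list[int], rng, pos):
        self.grid, self.p, self.rng = grid, params, rng
        self.targets = set(targets)
        self.order = list(rng.permutation(grid.n_cells))
        self.idx = 0
        self.pos = np.array(pos, dtype=float)
        self.dwell_left = 0.0
        self.entry_time: float | None = None
        self.done = False
        self.start_delay = float(rng.uniform(*params.reaction_s))

    def waypoint(self, marked: set) -> np.ndarray:
        if not self.targets - marked:
            self.done = True
            return np.array([self.grid.width - 100.0, self.grid.height - 60.0])
        while self.order[self.idx] in marked:
            self.idx = (self.idx + 1) % len(self.order)
        return np.asarray(self.grid.cell_center(self.order[self.idx]), dtype=float)

    def own_step(self, t: float, dt: float, marked: set, locks: list, who: str) -> np.ndarray:
        """Return the drift step for this frame; may emit a lock into ``locks``."""
        if t < self.start_delay:  # reaction time before the search begins
            return self.rng.normal(0.0, self.p.jitter_px, 2)
        wp = self.waypoint(marked)
        delta = wp - self.pos
        dist = float(np.hypot(*delta))
        max_step = self.p.saccade_speed * dt
        if dist > max_step:
            return delta / dist * max_step
        # arrived at the waypoint: dwell bookkeeping
        step = delta + self.rng.normal(0.0, self.p.jitter_px, 2)
        if self.done:
            return step
        cell = self.order[self.idx]
        if self.entry_time is None:
            self.entry_time = t
            is_target = cell in self.targets and cell not in marked
            self.dwell_left = (
                self.p.mark_dwell_s if is_target else float(self.rng.uniform(*self.p.inspect_s))
            )
        if cell in self.targets and cell not in marked:
            if t - self.entry_time > self.p.lock_threshold_s:
                onset = self.entry_time
                locks.append((who, cell, onset, onset + self.p.lock_threshold_s))
                marked.add(cell)
                self._advance()
        elif t - self.entry_time >= self.dwell_left:
            self._advance()
        return step

    def _advance(self) -> None:
        self.idx = (self.idx + 1) % len(self.order)
        self.entry_time = None


def simulate_gaze_pair(
    mode: str,
    targets: list[int],
    attraction: float,
    seed=None,
    grid: GridSpec | None = None,
    layout: TrialLayout | None = None,
    params: GazeParams | None = None,
):
    """Simulate one trial's paired gaze tracks.

    Returns ``(track_a, track_b, locks)`` with trial-relative timestamps;
    ``locks`` is a list of ``(participant, cell, onset_s, ident_s)``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not -1.0 <= attraction <= 1.0:
        raise ValueError(f"attraction must be in [-1, 1], got {attraction}")
    if not targets:
        raise ValueError("target list must be non-empty")
    grid = grid or GridSpec()
    layout = layout or TrialLayout()
    p = params or GazeParams()
    for c in targets:
        if not 0 <= c < grid.n_cells:
            raise ValueError(f"target cell {c} outside the grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dt = 1.0 / p.fs
    n = int(round(layout.trial_s * p.fs))
    t = np.arange(n) * dt
    center = np.array([grid.width / 2.0, grid.height / 2.0])
    xa = np.empty((n, 2))
    xb = np.empty((n, 2))
    locks: list = []
    marked: set = set()

    a = _Scanner(grid, p, targets, rng, center)
    b_scan = _Scanner(grid, p, targets, rng, center) if mode != "single" else None
    pos_b = center.copy()
    b_marked: set = set()  # cooperation: B's private view of marked targets

    for k in range(n):
        tk = t[k]
        if tk < layout.fixation_s:  # fixation cross at screen centre
            xa[k] = center + rng.normal(0, p.jitter_px, 2)
            xb[k] = center + rng.normal(0, p.jitter_px, 2)
            a.pos = xa[k].copy()
            pos_b = xb[k].copy()
            if b_scan is not None:
                b_scan.pos = pos_b.copy()
            continue
        ts = tk - layout.fixation_s  # time in the search window
        step_a = a.own_step(ts, dt, marked, locks, "A")
        a.pos = np.clip(a.pos + step_a, [0, 0], [grid.width, grid.height])
        xa[k] = a.pos
        if mode == "single":
            # observer: mean-reverting free drift over the whole screen
            theta, sd = 0.5, p.observer_sd_px
            pos_b = pos_b + theta * (center - pos_b) * dt + rng.normal(
                0.0, sd * math.sqrt(2 * theta * dt), 2
            )
            pos_b = np.clip(pos_b, [0, 0], [grid.width, grid.height])
            xb[k] = pos_b
        else:
            b_scan.pos = pos_b.copy()
            if mode == "competition":
                step_own = b_scan.own_step(ts, dt, marked, locks, "B")
            else:
                # cooperation: B searches too, but marking is led by A
                b_marked.update(marked)
                step_own = b_scan.own_step(ts, dt, b_marked, [], "B")
            delta = a.pos - pos_b
            dist = float(np.hypot(*delta)) or 1.0
            gate = 1.0 if attraction >= 0 else math.exp(-dist / p.repel_scale_px)
            social = attraction * gate * (delta / dist) * p.saccade_speed * dt
            pos_b = pos_b + (1.0 - abs(attraction)) * step_own + social
            pos_b = np.clip(pos_b, [0, 0], [grid.width, grid.height])
            xb[k] = pos_b

    valid = np.ones(n, dtype=bool)
    track_a = GazeTrack(t, xa[:, 0], xa[:, 1], valid)
    track_b = GazeTrack(t, xb[:, 0], xb[:, 1], valid.copy())
    locks.sort(key=lambda e: e[2])
    return track_a, track_b, locks


def detect_locks(
    track: GazeTrack,
    targets: list[int],
    grid: GridSpec | None = None,
    threshold_s: float = 0.7,
) -> list[tuple[int, float]]:
    """Detect target locks from a gaze track: (cell, onset) for every strictly
    greater-than-``threshold_s`` continuous within-cell dwell on a target."""
    grid = grid or GridSpec()
    out = []
    marked: set = set()
    cur, entry = -1, 0.0
    emitted = False
    for tk, x, y, ok in zip(track.t, track.x, track.y, track.valid):
        cell = grid.cell_at(x, y) if ok else -1
        if cell != cur:
            cur, entry, emitted = cell, tk, False
            continue
        if (
            not emitted
            and cur in targets
            and cur not in marked
            and tk - entry > threshold_s
        ):
            out.append((cur, entry))
            marked.add(cur)
            emitted = True
    return out


# ---------------------------------------------------------------------------
# EEG + full dyad simulation
# ---------------------------------------------------------------------------

def _one_over_f(rng, n: int, fs: float, sd: float, n_ch: int = 1) -> np.ndarray:
    """1/f-amplitude noise band-limited to 0.5 Hz .. Nyquist, unit-scaled to ``sd``.

    Returns an (n_ch, n) array of independent channels.
    """
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs >= 0.5
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    spec = shape * (
        rng.normal(size=(n_ch, freqs.size)) + 1j * rng.normal(size=(n_ch, freqs.size))
    )
    x = np.fft.irfft(spec, n, axis=-1)
    s = x.std(axis=-1, keepdims=True)
    return x * np.where(s > 0, sd / s, 1.0)


def _schedule(config: SimConfig, dyad_index: int) -> pd.DataFrame:
    """Block schedule: 2 runs x one block per mode, order rotated per dyad/run."""
    rows = []
    trial = 0
    per_block = config.n_trials_per_mode // 2
    n_targets_cycle = (1, 3, 5)
    for run in (1, 2):
        k = (dyad_index + run - 1) % len(config.modes)
        order = config.modes[k:] + config.modes[:k]
        for mode in order:
            for j in range(per_block):
                rows.append(
                    {
                        "trial": trial,
                        "mode": mode,
                        "run": run,
                        "n_targets": n_targets_cycle[trial % 3],
                    }
                )
                trial += 1
    return pd.DataFrame(rows)


def simulate_dyad(config: SimConfig, dyad_index: int = 0) -> tuple[DyadRecording, GroundTruth]:
    """Generate one dyad's recording plus its ground truth.

    Deterministic given ``config.seed`` and ``dyad_index``.
    """
    if not 0 <= dyad_index < max(config.n_dyads, 1):
        raise ValueError(f"dyad_index {dyad_index} out of range for n_dyads={config.n_dyads}")
    ss = np.random.SeedSequence([int(config.seed) % (2**31), dyad_index])
    rng_eeg, rng_gaze, rng_meta = (np.random.default_rng(s) for s in ss.spawn(3))

    layout = config.layout
    fs = config.fs
    trial_len = int(round(layout.trial_s * fs))
    sched = _schedule(config, dyad_index)
    n_trials = len(sched)
    n_total = n_trials * trial_len
    t = np.arange(n_total) / fs
    trial_idx = np.minimum((t / layout.trial_s).astype(int), n_trials - 1)
    t_in_trial = t - trial_idx * layout.trial_s
    w0, w1 = config.event_coupling_window
    stim = layout.fixation_s
    in_event = (t_in_trial >= stim + w0) & (t_in_trial < stim + w1)

    modes_per_trial = sched["mode"].to_numpy()
    eeg_a = np.zeros((N_CHANNELS, n_total))
    eeg_b = np.zeros((N_CHANNELS, n_total))
    expected_plv: dict = {}
    coupled_pairs: dict = {}

    for band in config.bands if config.simulate_eeg else ():
        per_mode = config.coupling.get(band.name, {})
        # Coupling lives at the band level: one cross-brain phase offset and one
        # per-trial noise draw shared by all channels.  A linear re-reference
        # (e.g. mean mastoids) then rotates both participants' band phasors
        # identically and the closed-form expected PLV survives the pipeline.
        # The offset is drawn away from 0 and pi so coupled pairs carry a
        # genuine lag visible to ciPLV/wPLI.
        offset = float(rng_eeg.choice([-1.0, 1.0]) * rng_eeg.uniform(np.pi / 6, 5 * np.pi / 6))
        phi0_a = rng_eeg.uniform(-np.pi, np.pi, (n_trials, N_CHANNELS))
        jitter = np.cumsum(
            rng_eeg.normal(0.0, config.phase_jitter, (N_CHANNELS, n_total)), axis=1
        )
        ramp = 2 * np.pi * band.fc * t
        phase_a = ramp[None, :] + phi0_a[trial_idx].T + jitter
        eeg_a += band.amplitude * np.cos(phase_a)

        # per-trial phase noise for B: wrapped normal where coupled, uniform
        # (per channel, breaking the phase relation entirely) otherwise
        eps_base = np.empty((n_trials, N_CHANNELS))
        eps_event = np.empty((n_trials, N_CHANNELS))
        for k in range(n_trials):
            c = per_mode.get(modes_per_trial[k])
            if c is None:
                u = rng_eeg.uniform(-np.pi, np.pi, N_CHANNELS)
                eps_base[k] = u
                eps_event[k] = u
            else:
                eps_base[k] = rng_eeg.normal(0.0, c.sigma_base)
                eps_event[k] = rng_eeg.normal(0.0, c.sigma_event)
        eps = np.where(in_event[None, :], eps_event[trial_idx].T, eps_base[trial_idx].T)
        phase_b = phase_a + offset + eps
        eeg_b += band.amplitude * np.cos(phase_b)

        if any(c is not None for c in per_mode.values()):
            coupled_pairs[band.name] = [(i, i) for i in range(N_CHANNELS)]
        for mode in config.modes:
            c = per_mode.get(mode)
            if c is not None:
                expected_plv[(mode, band.name)] = {
                    "sigma_base": c.sigma_base,
                    "sigma_event": c.sigma_event,
                    "plv_base": c.expected_plv("base"),
                    "plv_event": c.expected_plv("event"),
                }

    if config.simulate_eeg and config.noise_sd > 0:
        eeg_a += _one_over_f(rng_eeg, n_total, fs, config.noise_sd, N_CHANNELS)
        eeg_b += _one_over_f(rng_eeg, n_total, fs, config.noise_sd, N_CHANNELS)

    # events and gaze
    ev_times: list[float] = []
    ev_codes: list[str] = []
    gaze_a_parts, gaze_b_parts, all_locks = [], [], []
    prev_block = None
    for k in range(n_trials):
        t0 = k * layout.trial_s
        mode, run = sched.loc[k, "mode"], int(sched.loc[k, "run"])
        if (mode, run) != prev_block:
            ev_times.append(t0)
            ev_codes.append(f"mode:{mode}:run:{run}")
            prev_block = (mode, run)
        n_targets = int(sched.loc[k, "n_targets"])
        targets = list(rng_gaze.choice(config.grid.n_cells, n_targets, replace=False))
        sched.loc[k, "targets"] = ",".join(map(str, targets))
        ev_times += [t0, t0 + layout.fixation_s, t0 + layout.fixation_s]
        ev_codes += ["fixation_onset", "stimulus_onset", f"targets:{n_targets}"]
        if config.simulate_gaze:
            ta, tb, locks = simulate_gaze_pair(
                mode, targets, config.gaze_coupling.get(mode, 0.0),
                seed=rng_gaze, grid=config.grid, layout=layout, params=config.gaze,
            )
            gaze_a_parts.append((ta.t + t0, ta.x, ta.y, ta.valid))
            gaze_b_parts.append((tb.t + t0, tb.x, tb.y, tb.valid))
            for who, cell, onset, ident in locks:
                abs_ident = t0 + layout.fixation_s + ident
                ev_times.append(abs_ident)
                ev_codes.append(f"identified:{who}:{cell}")
                all_locks.append((k, who, cell, t0 + layout.fixation_s + onset, abs_ident))
        ev_times.append(t0 + layout.trial_s)
        ev_codes.append("trial_end")

    if config.simulate_gaze:
        gaze_a = GazeTrack(*(np.concatenate([p[i] for p in gaze_a_parts]) for i in range(4)))
        gaze_b = GazeTrack(*(np.concatenate([p[i] for p in gaze_b_parts]) for i in range(4)))
    else:
        empty = np.empty(0)
        gaze_a = GazeTrack(empty, empty, empty, np.empty(0, dtype=bool))
        gaze_b = GazeTrack(empty.copy(), empty.copy(), empty.copy(), np.empty(0, dtype=bool))

    gender = ("FF", "FM", "MM")[int(rng_meta.choice(3, p=(0.62, 0.345, 0.035)))]
    rec = DyadRecording(
        eeg_a=eeg_a,
        eeg_b=eeg_b,
        fs=fs,
        channels=CHANNELS,
        gaze_a=gaze_a,
        gaze_b=gaze_b,
        events=EventList(np.asarray(ev_times), ev_codes),
        meta={
            "dyad_id": dyad_index,
            "gender_composition": gender,
            "seed": int(config.seed),
            "n_trials": n_trials,
        },
    )
    if config.mixing is not None:
        rec = apply_mixing(rec, config.mixing)
    truth = GroundTruth(
        expected_plv=expected_plv,
        coupled_pairs=coupled_pairs,
        trials=sched,
        locks=all_locks,
    )
    return rec, truth
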