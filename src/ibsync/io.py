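"""Dyad recording containers and stream IO.

A :class:`DyadRecording` bundles one dyad's paired 32-channel EEG, paired gaze
tracks, event markers and metadata on a single relative clock (seconds from the
start of the aligned recording).  Recordings can be read from XDF files written
by LabStreamingLayer recorders (:func:`read_xdf`) and round-tripped through a
self-describing HDF5 container (:func:`write_recording` /
:func:`read_recording`).

Event-code vocabulary
---------------------
The canonical marker vocabulary used throughout the package:

``fixation_onset``
    start of the 3-s fixation cross of a trial
``stimulus_onset``
    onset of the 300-ms auditory stimulus (epoching reference)
``identified:<participant>:<cell>``
    a target in grid cell ``<cell>`` (0..15) was marked by participant A or B;
    the gaze lock began 700 ms earlier
``trial_end``
    end of the 13-s trial
``mode:<name>:run:<k>``
    block tag; the mode/run active for all subsequent trials until the next tag

Real deposits use recorder-specific marker strings; ``read_xdf`` accepts a
``marker_translation`` mapping from raw strings (or prefixes) to this
vocabulary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from . import _xdf
from .montage import CHANNELS

__all__ = [
    "GazeTrack",
    "EventList",
    "DyadRecording",
    "IntegrityError",
    "read_xdf",
    "write_recording",
    "read_recording",
    "recording_to_xdf",
    "events_to_csv",
]

STREAM_ROLES = ("eeg_a", "eeg_b", "gaze_a", "gaze_b", "markers")


class IntegrityError(IOError):
    """A container file is truncated or structurally inconsistent."""


@dataclass
class GazeTrack:
    """Timestamped gaze-point track in screen pixels."""

    t: np.ndarray  # seconds, monotone non-decreasing
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray  # bool per sample

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("gaze arrays must have equal length")
        if n and np.any(np.diff(self.t) < 0):
            raise ValueError("gaze timestamps must be sorted")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class EventList:
    """Sorted (time, code) event markers."""

    times: np.ndarray
    codes: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.codes):
            raise ValueError("times and codes must have equal length")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.codes = [self.codes[i] for i in order]

    def __len__(self) -> int:
        return len(self.times)

    def select(self, prefix: str) -> "EventList":
        """Events whose code equals or starts with ``prefix``."""
        keep = [i for i, c in enumerate(self.codes) if c == prefix or c.startswith(prefix)]
        return EventList(self.times[keep], [self.codes[i] for i in keep])

    @property
    def stimulus_onsets(self) -> np.ndarray:
        return self.select("stimulus_onset").times

    def mode_at(self, t: float) -> tuple[str, int]:
        """(mode, run) active at time ``t`` per the last preceding block tag."""
        mode, run = "unknown", 0
        for ti, code in zip(self.times, self.codes):
            if ti > t:
                break
            if code.startswith("mode:"):
                parts = code.split(":")
                mode, run = parts[1], int(parts[3])
        return mode, run


@dataclass
class DyadRecording:
    """One dyad's aligned multi-stream recording."""

    eeg_a: np.ndarray  # (32, n_samples) microvolt
    eeg_b: np.ndarray
    fs: float
    channels: tuple[str, ...]
    gaze_a: GazeTrack
    gaze_b: GazeTrack
    events: EventList
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eeg_a = np.asarray(self.eeg_a, dtype=float)
        self.eeg_b = np.asarray(self.eeg_b, dtype=float)
        if self.eeg_a.shape[0] != len(self.channels) or self.eeg_b.shape[0] != len(self.channels):
            raise ValueError("EEG matrices must have one row per montage channel")
        if self.eeg_a.shape != self.eeg_b.shape:
            raise ValueError("participants' EEG matrices must have equal shape")
        if set(self.channels) != set(CHANNELS):
            raise ValueError("channel labels must match the 32-channel montage")

    @property
    def n_samples(self) -> int:
        return self.eeg_a.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# XDF
# ---------------------------------------------------------------------------

def _translate(code: str, table: dict[str, str] | None) -> str:
    if not table:
        return code
    if code in table:
        return table[code]
    for raw, canon in table.items():
        if code.startswith(raw):
            return canon + code[len(raw):]
    return code


def read_xdf(
    path,
    stream_map: dict[str, str],
    marker_translation: dict[str, str] | None = None,
) -> DyadRecording:
    """Read an XDF file into an aligned :class:`DyadRecording`.

    Parameters
    ----------
    stream_map
        Mapping from XDF stream name to role, covering the five roles
        ``eeg_a``, ``eeg_b``, ``gaze_a``, ``gaze_b`` and ``markers``.
    marker_translation
        Optional mapping from recorder-specific marker strings (or prefixes)
        to the canonical event vocabulary.

    The two EEG streams are aligned to a common start; if their sampling rates
    differ, both are resampled to the lower rate (recorded in
    ``meta['resampled_to']``).  All times are re-expressed relative to the
    aligned EEG start.
    """
    streams = {s.name: s for s in _xdf.load_xdf(path)}
    roles: dict[str, _xdf.XDFStream] = {}
    for name, role in stream_map.items():
        if role not in STREAM_ROLES:
            raise ValueError(f"unknown stream role {role!r}")
        if name not in streams:
            raise ValueError(f"stream {name!r} (role {role!r}) not present in {path}")
        roles[role] = streams[name]
    for role in STREAM_ROLES:
        if role not in roles:
            raise ValueError(f"stream_map does not resolve required role {role!r}")

    from .preprocess import resample_to  # local import to avoid a cycle

    ea, eb = roles["eeg_a"], roles["eeg_b"]
    fs_a, fs_b = ea.nominal_srate, eb.nominal_srate
    fs = min(fs_a, fs_b)
    meta: dict = {}
    sig_a = np.asarray(ea.data, dtype=float).T
    sig_b = np.asarray(eb.data, dtype=float).T
    if fs_a != fs_b:
        if fs_a != fs:
            sig_a = resample_to(sig_a, fs_a, fs)
        if fs_b != fs:
            sig_b = resample_to(sig_b, fs_b, fs)
        meta["resampled_to"] = fs

    t0 = max(ea.timestamps[0], eb.timestamps[0])
    # trim the earlier-starting stream so both begin at t0 (within one sample)
    off_a = int(round((t0 - ea.timestamps[0]) * fs))
    off_b = int(round((t0 - eb.timestamps[0]) * fs))
    sig_a = sig_a[:, off_a:]
    sig_b = sig_b[:, off_b:]
    n = min(sig_a.shape[1], sig_b.shape[1])
    sig_a, sig_b = sig_a[:, :n], sig_b[:, :n]

    def gaze_from(st: _xdf.XDFStream) -> GazeTrack:
        t = st.timestamps - t0
        if np.any(np.diff(t) < 0):
            raise ValueError(f"non-monotone gaze clock in stream {st.name!r}")
        data = np.asarray(st.data, dtype=float)
        x, y = data[:, 0], data[:, 1]
        valid = data[:, 2] > 0.5 if data.shape[1] > 2 else np.isfinite(x) & np.isfinite(y)
        return GazeTrack(t, x, y, valid)

    mk = roles["markers"]
    times = mk.timestamps - t0
    if np.any(np.diff(times) < 0):
        raise ValueError("non-monotone marker clock after alignment")
    codes = [_translate(row[0], marker_translation) for row in mk.data]
    meta.setdefault("source", str(path))
    return DyadRecording(
        eeg_a=sig_a,
        eeg_b=sig_b,
        fs=fs,
        channels=CHANNELS,
        gaze_a=gaze_from(roles["gaze_a"]),
        gaze_b=gaze_from(roles["gaze_b"]),
        events=EventList(times, codes),
        meta=meta,
    )


def recording_to_xdf(rec: DyadRecording, path) -> None:
    """Write a recording as a five-stream XDF file (testing / interchange).

    Stream names are the role names; gaze streams carry (x, y, valid)
    channels; markers are a string stream.
    """
    fs = rec.fs
    n = rec.n_samples
    t_eeg = np.arange(n) / fs
    streams = []
    for sid, (role, sig) in enumerate(
        [("eeg_a", rec.eeg_a), ("eeg_b", rec.eeg_b)], start=1
    ):
        streams.append(
            _xdf.XDFStream(
                stream_id=sid, name=role, type="EEG", channel_count=sig.shape[0],
                nominal_srate=fs, channel_format="double64",
                timestamps=t_eeg, data=sig.T,
            )
        )
    for sid, (role, gz) in enumerate(
        [("gaze_a", rec.gaze_a), ("gaze_b", rec.gaze_b)], start=3
    ):
        data = np.column_stack([gz.x, gz.y, gz.valid.astype(float)])
        streams.append(
            _xdf.XDFStream(
                stream_id=sid, name=role, type="Gaze", channel_count=3,
                nominal_srate=0.0, channel_format="double64",
                timestamps=gz.t, data=data,
            )
        )
    streams.append(
        _xdf.XDFStream(
            stream_id=5, name="markers", type="Markers", channel_count=1,
            nominal_srate=0.0, channel_format="string",
            timestamps=rec.events.times, data=[[c] for c in rec.events.codes],
        )
    )
    _xdf.save_xdf(path, streams)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

_FORMAT_ATTR = "ibsync-dyad-recording"
_FORMAT_VERSION = 1


def write_recording(rec: DyadRecording, path) -> None:
    """Write a recording to the internal HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT_ATTR
        f.attrs["version"] = _FORMAT_VERSION
        f.attrs["fs"] = float(rec.fs)
        f.attrs["channels"] = json.dumps(list(rec.channels))
        f.attrs["meta"] = json.dumps(rec.meta, default=str)
        f.create_dataset("eeg_a", data=rec.eeg_a)
        f.create_dataset("eeg_b", data=rec.eeg_b)
        for name, gz in (("gaze_a", rec.gaze_a), ("gaze_b", rec.gaze_b)):
            g = f.create_group(name)
            g.create_dataset("t", data=gz.t)
            g.create_dataset("x", data=gz.x)
            g.create_dataset("y", data=gz.y)
            g.create_dataset("valid", data=gz.valid.astype(np.uint8))
        g = f.create_group("events")
        g.create_dataset("times", data=rec.events.times)
        g.create_dataset(
            "codes", data=np.array(rec.events.codes, dtype=h5py.string_dtype())
        )
        f.attrs["complete"] = True


def read_recording(path) -> DyadRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`IntegrityError` for truncated or foreign files rather than
    returning partial data.
    """
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != _FORMAT_ATTR or not f.attrs.get("complete", False):
                raise IntegrityError(f"{path}: not a complete dyad-recording container")
            gaze = {}
            for name in ("gaze_a", "gaze_b"):
                g = f[name]
                gaze[name] = GazeTrack(
                    g["t"][()], g["x"][()], g["y"][()], g["valid"][()].astype(bool)
                )
            codes = [c.decode() if isinstance(c, bytes) else str(c) for c in f["events/codes"][()]]
            return DyadRecording(
                eeg_a=f["eeg_a"][()],
                eeg_b=f["eeg_b"][()],
                fs=float(f.attrs["fs"]),
                channels=tuple(json.loads(f.attrs["channels"])),
                gaze_a=gaze["gaze_a"],
                gaze_b=gaze["gaze_b"],
                events=EventList(f["events/times"][()], codes),
                meta=json.loads(f.attrs["meta"]),
            )
    except OSError as exc:  # h5py raises OSError on truncation/corruption
        raise IntegrityError(f"{path}: unreadable container ({exc})") from exc


def events_to_csv(events: EventList, path) -> None:
    import pandas as pd

    pd.DataFrame({"time_s": events.times, "code": events.codes}).to_csv(path, index=False)


def copy_with(rec: DyadRecording, **kwargs) -> DyadRecording:
    """Shallow copy of a recording with replaced fields."""
    return replace(rec, **kwargs)
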