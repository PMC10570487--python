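"""Band-wise analytic signals and cross-brain phase-coupling measures.

For each canonical EEG band the epoched signals are band-pass filtered
(mirror-padded to suppress edge transients) and turned into analytic signals,
whose argument is the instantaneous phase in (-pi, pi].  Connectivity between
every channel of participant A and every channel of participant B is then
computed across trials, per time sample:

phase locking value (PLV)
    ``plv(t) = | (1/N) sum_n exp(i dphi_n(t)) |`` — modulus of the
    trial-averaged unit phasor of the phase difference.  1 means the phase
    difference is identical on every trial; the finite-N floor for unrelated
    phases is ~sqrt(pi / (4 N)).
corrected imaginary PLV (ciPLV)
    imaginary part of the mean phasor normalised by the non-real remainder,
    ``|Im V| / sqrt(1 - Re V^2)`` — insensitive to zero-lag (volume-conducted)
    coupling.
weighted phase lag index (wPLI)
    ``|sum_n Im S_n| / sum_n |Im S_n|`` with ``S_n`` the cross-spectrum of the
    analytic signals; 0/0 is defined as 0, since pure zero-lag dependence
    carries no lag information.

PLV is time-resolved by default (one value per post/peri-stimulus sample,
averaged over trials); a trial-resolved variant (modulus over time within
trial, averaged across trials) is available via ``time_resolved=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .montage import CHANNELS, REGION_MAP, REGION_MAP_NOTES, REGIONS
from .preprocess import EpochSet, _filt_mirror, _fir_taps

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "AnalyticTensor",
    "PairConnectivity",
    "analytic_band",
    "pair_connectivity",
    "baseline_correct",
    "event_window_mean",
    "aggregate_by_region",
]

MEASURES = ("plv", "ciplv", "wpli")


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band edges {self.lo}-{self.hi}")


CANONICAL_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 3.0),
    "theta": BandSpec("theta", 4.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 31.0, 50.0),
}


@dataclass
class AnalyticTensor:
    """Complex analytic signal per trial/channel/sample for one band."""

    values: np.ndarray  # complex, (n_trials, n_channels, n_samples)
    times: np.ndarray
    fs: float
    band: BandSpec
    channels: tuple[str, ...]
    labels: object = None  # per-trial label frame carried from the EpochSet

    @property
    def phase(self) -> np.ndarray:
        """Instantaneous phase in (-pi, pi]."""
        return np.angle(self.values)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def select_trials(self, idx) -> "AnalyticTensor":
        lab = self.labels.iloc[idx].reset_index(drop=True) if self.labels is not None else None
        return AnalyticTensor(self.values[idx], self.times, self.fs, self.band, self.channels, lab)


@dataclass
class PairConnectivity:
    """Cross-brain channel-pair connectivity for one band and measure.

    ``values[i, j, t]`` couples channel i of participant A with channel j of
    participant B; exchanging participants transposes the matrix.
    """

    measure: str
    band: BandSpec
    values: np.ndarray  # (n_ch_a, n_ch_b, n_times) or (..., 1)
    times: np.ndarray
    n_trials: int
    baseline_corrected: bool = False
    channels_a: tuple[str, ...] = CHANNELS
    channels_b: tuple[str, ...] = CHANNELS
    meta: dict = field(default_factory=dict)


def analytic_band(epochs: EpochSet, band: BandSpec) -> AnalyticTensor:
    """Band-pass the epochs and build the analytic signal per trial/channel.

    The epoch is mirror-extended by the filter length before filtering and the
    Hilbert construction, so filter and FFT edge transients fall outside the
    retained window.
    """
    if band.hi >= epochs.fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist at fs={epochs.fs}")
    h = _fir_taps(band.lo, band.hi, epochs.fs)
    n = epochs.data.shape[-1]
    if n < 3 * len(h):
        raise ValueError(
            f"epoch length {n} shorter than 3 filter lengths ({3 * len(h)}) for band {band.name}"
        )
    pad = len(h)
    x = epochs.data
    left = 2 * x[..., :1] - x[..., pad:0:-1]
    right = 2 * x[..., -1:] - x[..., -2 : -pad - 2 : -1]
    ext = np.concatenate([left, x, right], axis=-1)
    filt = sps.fftconvolve(ext, h[None, None, :], axes=-1)
    m = len(h) // 2
    filt = filt[..., m : m + ext.shape[-1]]  # delay-compensated, still padded
    analytic = sps.hilbert(filt, axis=-1)[..., pad : pad + n]
    return AnalyticTensor(
        values=analytic,
        times=epochs.times,
        fs=epochs.fs,
        band=band,
        channels=epochs.channels,
        labels=epochs.labels,
    )


def _mean_phasor(za: np.ndarray, zb: np.ndarray) -> np.ndarray:
    """Trial-averaged cross phasor ``V[i, j, t]`` from unit phasors (n,ch,T)."""
    n = za.shape[0]
    a = np.transpose(za, (2, 1, 0))  # (T, chA, n)
    b = np.transpose(np.conj(zb), (2, 0, 1))  # (T, n, chB)
    return np.transpose(a @ b, (1, 2, 0)) / n  # (chA, chB, T)


def pair_connectivity(
    a: AnalyticTensor,
    b: AnalyticTensor,
    measure: str = "plv",
    time_resolved: bool = True,
) -> PairConnectivity:
    """Cross-brain connectivity between all channel pairs of two tensors."""
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    if a.values.shape[0] != b.values.shape[0] or a.values.shape[2] != b.values.shape[2]:
        raise ValueError("analytic tensors must share trial and sample counts")
    if a.band != b.band:
        raise ValueError("analytic tensors must share the band")
    n = a.values.shape[0]
    if n < 2:
        raise ValueError("connectivity across trials requires at least 2 trials")

    eps = np.finfo(float).eps
    za = a.values / np.maximum(np.abs(a.values), eps)
    zb = b.values / np.maximum(np.abs(b.values), eps)

    if not time_resolved:
        # modulus over time within trial, then mean across trials
        cross = za[:, :, None, :] * np.conj(zb[:, None, :, :])  # (n, chA, chB, T)
        if measure == "plv":
            vals = np.abs(cross.mean(axis=-1)).mean(axis=0)[..., None]
        elif measure == "ciplv":
            v = cross.mean(axis=-1)
            vals = (np.abs(v.imag) / np.sqrt(np.clip(1 - v.real**2, eps, None))).mean(axis=0)[..., None]
        else:
            s = a.values[:, :, None, :] * np.conj(b.values[:, None, :, :])
            num = np.abs(s.imag.sum(axis=-1))
            den = np.abs(s.imag).sum(axis=-1)
            vals = np.where(den > 0, num / np.maximum(den, eps), 0.0).mean(axis=0)[..., None]
        times = np.array([np.mean(a.times)])
    elif measure in ("plv", "ciplv"):
        v = _mean_phasor(za, zb)
        if measure == "plv":
            vals = np.abs(v)
        else:
            vals = np.abs(v.imag) / np.sqrt(np.clip(1.0 - v.real**2, eps, None))
        times = a.times
    else:  # wpli, time-resolved
        num = np.zeros((za.shape[1], zb.shape[1], za.shape[2]))
        den = np.zeros_like(num)
        for k in range(n):  # per-trial outer products; keeps memory bounded
            s_im = np.einsum("it,jt->ijt", a.values[k], np.conj(b.values[k])).imag
            num += s_im
            den += np.abs(s_im)
        vals = np.where(den > 0, np.abs(num) / np.maximum(den, eps), 0.0)
        times = a.times
    return PairConnectivity(
        measure=measure,
        band=a.band,
        values=vals,
        times=times,
        n_trials=n,
        channels_a=a.channels,
        channels_b=b.channels,
    )


def baseline_correct(pc: PairConnectivity, window: tuple[float, float] = (-3.0, 0.0)) -> PairConnectivity:
    """Subtract the per-pair mean over the (half-open) baseline window."""
    mask = (pc.times >= window[0]) & (pc.times < window[1])
    if not mask.any():
        raise ValueError(f"baseline window {window} outside the time axis")
    base = pc.values[..., mask].mean(axis=-1, keepdims=True)
    return replace(pc, values=pc.values - base, baseline_corrected=True)


def event_window_mean(pc: PairConnectivity, window: tuple[float, float] = (0.2, 0.5)) -> np.ndarray:
    """Per-pair scalar mean over the event window (endpoints inclusive)."""
    eps = 1e-9  # endpoint samples are included
    mask = (pc.times >= window[0] - eps) & (pc.times <= window[1] + eps)
    if not mask.any():
        raise ValueError(f"event window {window} contains no samples")
    return pc.values[..., mask].mean(axis=-1)


def aggregate_by_region(
    matrix: np.ndarray,
    region_map: dict[str, str] | None = None,
    channels_a: tuple[str, ...] = CHANNELS,
    channels_b: tuple[str, ...] = CHANNELS,
) -> np.ndarray:
    """Average channel-pair values into a 5 x 5 region-pair matrix.

    Rows and columns follow :data:`ibsync.montage.REGIONS` order; each cell is
    the unweighted mean of its member channel pairs.
    """
    rmap = dict(REGION_MAP if region_map is None else region_map)
    for ch in (*channels_a, *channels_b):
        if ch not in rmap:
            raise ValueError(f"channel {ch!r} has no region assignment")
    matrix = np.asarray(matrix)
    out = np.zeros((len(REGIONS), len(REGIONS)))
    for ri, ra in enumerate(REGIONS):
        ia = [k for k, ch in enumerate(channels_a) if rmap[ch] == ra]
        for rj, rb in enumerate(REGIONS):
            ib = [k for k, ch in enumerate(channels_b) if rmap[ch] == rb]
            out[ri, rj] = matrix[np.ix_(ia, ib)].mean()
    return out


REGION_NOTES = REGION_MAP_NOTES
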