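"""Band-limited amplitude envelopes from continuous multichannel recordings.

The broadband-gamma amplitude (BGA, 50-150 Hz) is extracted by
band-pass filtering the signal in successive 10-Hz sub-bands with a
zero-phase FIR filter, taking the Hilbert-transform magnitude of each
sub-band, normalising each sub-band envelope to its session mean (x100,
so the session mean is 100 % by construction — this per-sub-band step
counteracts the 1/f amplitude drop-off across the broadband interval),
and averaging the normalised sub-bands.  The envelope is then smoothed
with a 250-ms sliding window, down-sampled to 100 Hz, epoched around
task events, and z-scored across trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.signal import hilbert

__all__ = [
    "RawRecording",
    "BandSpec",
    "EnvelopeSeries",
    "EnvelopeEpochs",
    "BANDS",
    "bipolar_rereference",
    "band_envelope",
    "postprocess_envelope",
    "epoch",
    "zscore_epochs",
]


@dataclass
class RawRecording:
    """Continuous multichannel voltage recording with event markers.

    ``signal`` is sites x samples (microvolts); ``events`` is a DataFrame
    with columns ``label`` and ``time`` (seconds from recording start).
    """

    signal: np.ndarray
    sampling_rate: float
    site_labels: list
    events: pd.DataFrame
    site_roles: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.site_labels) != self.signal.shape[0]:
            raise ValueError("site label count does not match signal rows")
        if len(self.events) and self.events["time"].max() > self.duration:
            raise ValueError("event beyond recording duration")

    @property
    def n_sites(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.sampling_rate

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=self.signal, compression="gzip")
            f.attrs["sampling_rate"] = self.sampling_rate
            f.create_dataset(
                "site_labels", data=np.array(self.site_labels, dtype=h5py.string_dtype())
            )
            roles = [self.site_roles.get(s, "null") for s in self.site_labels]
            f.create_dataset("site_roles", data=np.array(roles, dtype=h5py.string_dtype()))
            ev = f.create_group("events")
            ev.create_dataset(
                "label", data=self.events["label"].astype(str).to_numpy(dtype=object),
                dtype=h5py.string_dtype(),
            )
            ev.create_dataset("time", data=self.events["time"].to_numpy(dtype=float))

    @classmethod
    def load(cls, path) -> "RawRecording":
        with h5py.File(path, "r") as f:
            labels = [s.decode() if isinstance(s, bytes) else s for s in f["site_labels"][()]]
            roles = [s.decode() if isinstance(s, bytes) else s for s in f["site_roles"][()]]
            events = pd.DataFrame(
                {
                    "label": [
                        s.decode() if isinstance(s, bytes) else s for s in f["events/label"][()]
                    ],
                    "time": f["events/time"][()],
                }
            )
            return cls(
                signal=f["signal"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                site_labels=labels,
                events=events,
                site_roles=dict(zip(labels, roles)),
            )


@dataclass(frozen=True)
class BandSpec:
    """A frequency band split into equal sub-bands for envelope extraction."""

    name: str
    low: float
    high: float
    sub_band_step: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("band low must be below high")
        n = (self.high - self.low) / self.sub_band_step
        if n < 1 or abs(n - round(n)) > 1e-9:
            raise ValueError("sub-band step must divide the band into >= 1 sub-bands")

    @property
    def sub_bands(self) -> list:
        edges = np.arange(self.low, self.high + 1e-9, self.sub_band_step)
        return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


#: band definitions used throughout: broadband gamma plus the four classical bands
BANDS = {
    "bga": BandSpec("bga", 50.0, 150.0, 10.0),
    "gamma": BandSpec("gamma", 33.0, 49.0, 4.0),
    "beta": BandSpec("beta", 13.0, 33.0, 5.0),
    "alpha": BandSpec("alpha", 8.0, 13.0, 1.0),
    "theta": BandSpec("theta", 4.0, 8.0, 1.0),
}


@dataclass
class EnvelopeSeries:
    """Continuous amplitude envelope per site, in % of session mean."""

    values: np.ndarray
    sampling_rate: float
    site_labels: list
    band: str = "bga"

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.values.shape[1] / self.sampling_rate


@dataclass
class EnvelopeEpochs:
    """Trial-epoched envelope tensor (trials x sites x time)."""

    data: np.ndarray
    times: np.ndarray
    site_labels: list
    sampling_rate: float
    zscored: bool = False
    trial_indices: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def bipolar_rereference(raw: RawRecording, electrode_groups: dict) -> RawRecording:
    """Re-reference each contact to its nearest neighbour on the same electrode.

    ``electrode_groups`` maps electrode name -> ordered list of contact
    labels; an electrode with k contacts yields k-1 bipolar channels
    labelled "c1-c2".  Singleton electrodes are dropped with a warning.
    """
    index = {lab: i for i, lab in enumerate(raw.site_labels)}
    out_rows, out_labels = [], []
    for electrode, contacts in electrode_groups.items():
        if len(contacts) < 2:
            warnings.warn(f"electrode {electrode} has a single contact; dropped")
            continue
        for a, b in zip(contacts[:-1], contacts[1:]):
            out_rows.append(raw.signal[index[a]] - raw.signal[index[b]])
            out_labels.append(f"{a}-{b}")
    signal = (
        np.array(out_rows)
        if out_rows
        else np.empty((0, raw.signal.shape[1]))
    )
    return RawRecording(
        signal=signal,
        sampling_rate=raw.sampling_rate,
        site_labels=out_labels,
        events=raw.events.copy(),
    )


def _fir_bandpass(low: float, high: float, fs: float, transition: float = 0.5) -> np.ndarray:
    """Odd-length windowed-sinc band-pass kernel with the given transition width."""
    # Hamming window: transition ~= 3.3 / numtaps (in normalised frequency)
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # symmetric (zero-phase when applied centred)
    return sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs, window="hamming")


def band_envelope(raw: RawRecording, band: BandSpec | str) -> EnvelopeSeries:
    """Sub-band Hilbert envelope, normalised per sub-band to session mean 100."""
    if isinstance(band, str):
        band = BANDS[band]
    if raw.sampling_rate <= 2 * band.high:
        raise ValueError(
            f"sampling rate {raw.sampling_rate} Hz too low for band up to {band.high} Hz"
        )
    n_samples = raw.signal.shape[1]
    acc = np.zeros_like(raw.signal)
    for lo, hi in band.sub_bands:
        taps = _fir_bandpass(lo, hi, raw.sampling_rate)
        for i in range(raw.n_sites):
            filtered = sps.fftconvolve(raw.signal[i], taps, mode="same")
            env = np.abs(hilbert(filtered))
            m = env.mean()
            if m <= 0:
                raise ValueError(f"degenerate (zero-mean) envelope on site {raw.site_labels[i]}")
            acc[i] += 100.0 * env / m
    acc /= len(band.sub_bands)
    return EnvelopeSeries(
        values=acc,
        sampling_rate=raw.sampling_rate,
        site_labels=list(raw.site_labels),
        band=band.name,
    )


def postprocess_envelope(
    env: EnvelopeSeries, smooth_s: float = 0.25, out_rate: float = 100.0
) -> EnvelopeSeries:
    """250-ms sliding-window smoothing, then down-sampling to 100 Hz.

    Smoothing uses reflection padding; down-sampling picks one sample per
    10-ms grid step (the moving average acts as the anti-alias stage).
    """
    win = int(round(smooth_s * env.sampling_rate))
    if win < 1 or env.values.shape[1] < win:
        raise ValueError("recording shorter than the smoothing window")
    kernel = np.ones(win) / win
    half = win // 2
    padded = np.pad(env.values, ((0, 0), (half, half)), mode="reflect")
    smoothed = np.apply_along_axis(
        lambda x: np.convolve(x, kernel, mode="valid"), 1, padded
    )[:, : env.values.shape[1]]
    t_out = np.arange(0.0, env.duration - 1e-9, 1.0 / out_rate)
    idx = np.minimum(
        np.round(t_out * env.sampling_rate).astype(int), env.values.shape[1] - 1
    )
    return EnvelopeSeries(
        values=smoothed[:, idx],
        sampling_rate=out_rate,
        site_labels=list(env.site_labels),
        band=env.band,
    )


def epoch(env: EnvelopeSeries, event_times, window: tuple) -> EnvelopeEpochs:
    """Cut fixed windows around events on the envelope's sampling grid.

    The grid is inclusive of both endpoints: a (-4, 0) s window at
    100 Hz yields 401 samples.  Events whose window exceeds the
    recording are excluded with a warning.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    fs = env.sampling_rate
    n_rel = int(round((end - start) * fs)) + 1
    rel = start + np.arange(n_rel) / fs
    event_times = np.asarray(event_times, dtype=float)
    epochs, kept = [], []
    for k, t0 in enumerate(event_times):
        idx = np.round((t0 + rel) * fs).astype(int)
        if idx.min() < 0 or idx.max() >= env.values.shape[1]:
            warnings.warn(f"event at {t0:.2f}s: window outside recording; trial excluded")
            continue
        epochs.append(env.values[:, idx])
        kept.append(k)
    data = (
        np.array(epochs)
        if epochs
        else np.empty((0, env.n_sites, n_rel))
    )
    return EnvelopeEpochs(
        data=data,
        times=rel,
        site_labels=list(env.site_labels),
        sampling_rate=fs,
        trial_indices=np.array(kept, dtype=int),
    )


def zscore_epochs(ep: EnvelopeEpochs, per_sample: bool = True) -> EnvelopeEpochs:
    """Z-score across trials, per site and (by default) per time sample.

    With ``per_sample=False`` the mean/sd are pooled over the whole epoch
    per site instead.
    """
    if ep.n_trials < 2:
        raise ValueError("need at least 2 trials to z-score")
    if per_sample:
        mean = ep.data.mean(axis=0, keepdims=True)
        sd = ep.data.std(axis=0, ddof=0, keepdims=True)
        bad = np.argwhere(sd[0] == 0)
        if bad.size:
            s, t = bad[0]
            raise ValueError(
                f"zero cross-trial sd at site {ep.site_labels[s]}, sample {int(t)}"
            )
    else:
        mean = ep.data.mean(axis=(0, 2), keepdims=True)
        sd = ep.data.std(axis=(0, 2), ddof=0, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero pooled sd for some site")
    return EnvelopeEpochs(
        data=(ep.data - mean) / sd,
        times=ep.times.copy(),
        site_labels=list(ep.site_labels),
        sampling_rate=ep.sampling_rate,
        zscored=True,
        trial_indices=None if ep.trial_indices is None else ep.trial_indices.copy(),
    )
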