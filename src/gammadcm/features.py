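"""Time-frequency gamma features from virtual-sensor trials.

Per-trial epochs spanning [-2, +2] s around stimulus onset are turned
into percent-change Hilbert-envelope spectrograms: for each center
frequency the data are zero-phase bandpass filtered, the analytic-signal
magnitude taken, averaged over trials and expressed as percent change
from the prestimulus baseline.  Peak gamma features (frequency in Hz,
amplitude in % change) are read off by averaging the map over a time
window and locating the band maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .microcircuit import ConfigurationError

__all__ = [
    "TrialSet",
    "TimeFrequencyMap",
    "PeakFeature",
    "WINDOWS",
    "hilbert_spectrogram",
    "extract_peak",
]

#: Analysis windows (s relative to stimulus onset).
WINDOWS = {
    "transient": (0.0, 0.3),
    "sustained": (0.3, 0.8),
    "prestimulus": (-1.5, -0.5),
}

#: Default per-frequency filter half-bandwidth (Hz), filter order, and the
#: edge interval trimmed before any statistic (s).
DEFAULT_BAND = {"fmin": 1.0, "fmax": 100.0, "step": 0.5, "half_bandwidth": 2.0,
                "order": 4, "edge_trim": 0.25, "average": "before"}


@dataclass
class TrialSet:
    """Per-trial virtual-sensor epochs, onset at t = 0.

    ``epochs`` has shape (n_trials, n_samples); all epochs cover
    [t_start, t_start + n_samples/sampling_rate).
    """

    sampling_rate: float
    epochs: np.ndarray
    t_start: float = -2.0

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        if self.sampling_rate < 600:
            raise ConfigurationError("sampling_rate must be >= 600 Hz")

    @property
    def times(self) -> np.ndarray:
        n = self.epochs.shape[1]
        return self.t_start + np.arange(n) / self.sampling_rate

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def to_text(self, path) -> None:
        """Delimited text: one row per sample, one column per trial, plus a
        JSON header sidecar (sampling rate, epoch start)."""
        path = Path(path)
        np.savetxt(path, self.epochs.T, delimiter="\t")
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"sampling_rate": self.sampling_rate, "t_start": self.t_start})
        )

    @classmethod
    def from_text(cls, path) -> "TrialSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        epochs = np.loadtxt(path, delimiter="\t")
        return cls(meta["sampling_rate"], np.atleast_2d(epochs).T, meta["t_start"])


@dataclass
class TimeFrequencyMap:
    """Percent-change spectrogram: values[frequency, time] in % of baseline."""

    times: np.ndarray
    center_frequencies: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.center_frequencies = np.asarray(self.center_frequencies, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.center_frequencies), len(self.times)):
            raise ConfigurationError("values must be (n_frequencies, n_times)")


@dataclass(frozen=True)
class PeakFeature:
    """Peak gamma response in one analysis window."""

    window: str
    frequency: float        # Hz
    amplitude: float        # % change from baseline


def hilbert_spectrogram(trials: TrialSet, band_config: dict | None = None) -> TimeFrequencyMap:
    """Percent-change Hilbert-envelope spectrogram of a trial set.

    For each center frequency (default 1–100 Hz in 0.5 Hz steps, 199
    bands): zero-phase Butterworth bandpass (order 4, ±2 Hz), analytic
    envelope per trial, average over trials, then percent change relative
    to the mean envelope over the baseline window (epoch start to 0 s).
    Edge intervals (0.25 s) are trimmed from both ends before any
    statistics.  ``band_config`` overrides any :data:`DEFAULT_BAND` key;
    ``average="after"`` computes percent change per trial before
    averaging (induced-only emphasis).
    """
    cfg = dict(DEFAULT_BAND)
    if band_config:
        unknown = set(band_config) - set(cfg)
        if unknown:
            raise ConfigurationError(f"unknown band_config keys: {sorted(unknown)}")
        cfg.update(band_config)
    fs = trials.sampling_rate
    nyq = fs / 2.0
    cfs = np.arange(cfg["fmin"], cfg["fmax"] + cfg["step"] / 2, cfg["step"])
    if cfs[-1] + cfg["half_bandwidth"] >= nyq:
        raise ConfigurationError(
            f"band {cfs[-1]:.1f}+{cfg['half_bandwidth']:.1f} Hz exceeds the "
            f"Nyquist frequency {nyq:.1f} Hz"
        )
    times = trials.times
    trim = cfg["edge_trim"]
    keep = (times >= times[0] + trim) & (times <= times[-1] - trim)
    t_kept = times[keep]
    baseline = t_kept < 0.0
    if not baseline.any():
        raise ConfigurationError("no baseline samples before stimulus onset")

    values = np.empty((len(cfs), keep.sum()))
    x = trials.epochs
    for i, cf in enumerate(cfs):
        lo = max(cf - cfg["half_bandwidth"], 0.25)
        sos = butter(cfg["order"], [lo, cf + cfg["half_bandwidth"]],
                     btype="bandpass", fs=fs, output="sos")
        filt = sosfiltfilt(sos, x, axis=-1)
        env = np.abs(hilbert(filt, axis=-1))[:, keep]
        if cfg["average"] == "before":
            env = env.mean(axis=0)
            base = env[baseline].mean()
            values[i] = 100.0 * (env - base) / base
        else:
            base = env[:, baseline].mean(axis=1, keepdims=True)
            values[i] = (100.0 * (env - base) / base).mean(axis=0)
    return TimeFrequencyMap(t_kept, cfs, values, {"band_config": cfg})


def extract_peak(tfmap: TimeFrequencyMap, window: str | tuple[float, float],
                 band: tuple[float, float] = (30.0, 80.0)) -> PeakFeature:
    """Peak frequency/amplitude of the window-averaged map within ``band``.

    The map is averaged over the window's time samples per frequency and
    the maximum located within the band; ties break toward the lower
    frequency (first maximum).
    """
    name = window if isinstance(window, str) else f"{window[0]:g}-{window[1]:g}s"
    if isinstance(window, str):
        if window not in WINDOWS:
            raise ConfigurationError(f"unknown window {window!r}")
        window = WINDOWS[window]
    tmask = (tfmap.times >= window[0]) & (tfmap.times <= window[1])
    fmask = (tfmap.center_frequencies >= band[0]) & (tfmap.center_frequencies <= band[1])
    if not tmask.any() or not fmask.any():
        raise ConfigurationError("empty analysis window or frequency band")
    profile = tfmap.values[np.ix_(fmask, tmask)].mean(axis=1)
    j = int(np.argmax(profile))          # argmax returns the first (lowest) tie
    return PeakFeature(name, float(tfmap.center_frequencies[fmask][j]),
                       float(profile[j]))
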