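"""Synthetic study cohorts with the statistical structure of the real study.

Generates two groups (controls and SZ) of model-based subjects: each
subject carries generating microcircuit parameters, a noisy sensor
spectrum built through the spectral forward model, a sustained gamma peak
read off that spectrum, orientation-discrimination thresholds coupled to
the II->SP inhibition (g11), and — for the SZ group — a negative-symptom
score (SANS) coupled to the II self-inhibition (g4).

Group structure under the defaults:

* sustained gamma peak frequency ~ N(58, sd) in controls and N(55, sd)
  in SZ, with sd derived from the configured standard errors and group
  sizes;
* coupling log-scalings shifted downward in SZ on the superficial-layer
  inhibitory edges (g4, g7, g11) and on g6/g12;
* SANS ~ a - b*g4 + noise, calibrated analytically to a target Pearson r;
* thresholds ~ c - d*g11 + noise per condition, calibrated to a target
  within-group R^2, with oblique thresholds above vertical.

Per-subject gamma frequency is set by a "synaptic speed" dilation: a
factor c added to every rate-constant and coupling log-scaling rescales
time, so the model spectrum is an exact frequency-dilated copy of itself
(peak frequency proportional to exp(c)) with stability preserved.  c is
solved in a few fixed-point steps so each subject's measured spectral
peak lands on their drawn target frequency.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .microcircuit import CMCParameters, ConfigurationError
from .psychophysics import simulate_observer, threshold_from_noise, DEFAULT_LAPSE
from .spectral import (
    PowerSpectrum,
    default_grid,
    neuronal_power_batch,
)
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm

__all__ = ["CohortConfig", "SubjectRecord", "Cohort", "generate_cohort",
           "generate_trials", "generate_behavior", "measure_sustained_peak"]

_FREE_IDX = np.array([3, 4, 5, 6, 7, 8, 10, 11])  # g4..g9, g11, g12 (0-based)


@dataclass
class CohortConfig:
    """Generator settings; defaults reproduce the study's group structure."""

    n_control: int = 29
    n_sz: int = 27
    freq_mean: tuple[float, float] = (58.0, 55.0)      # Hz (control, SZ)
    freq_se: tuple[float, float] = (0.92, 0.95)        # Hz standard errors
    coupling_shift: dict = field(default_factory=lambda: {
        "g4": -0.25, "g6": -0.20, "g7": -0.20, "g11": -0.25, "g12": -0.15})
    gamma_sd: float = 0.2
    sans_mean: float = 40.0
    sans_sd: float = 18.0
    sans_r: float = -0.7                               # target corr(g4, SANS)
    threshold_r2: float = 0.38                         # target within-group R^2 vs g11
    threshold_base: dict = field(default_factory=lambda: {"vertical": 2.0, "oblique": 6.0})
    threshold_sd: dict = field(default_factory=lambda: {"vertical": 0.6, "oblique": 1.5})
    threshold_sz_offset: dict = field(default_factory=lambda: {"vertical": 0.5, "oblique": 1.5})
    obs_noise_sd: float = 0.1                          # sd of log-power noise
    gaba_mean: float = 1.5
    gaba_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_sz) < 2:
            raise ConfigurationError("group sizes must be >= 2")
        if abs(self.sans_r) >= 1:
            raise ConfigurationError("target SANS correlation must satisfy |r| < 1")
        if not 0 <= self.threshold_r2 < 1:
            raise ConfigurationError("threshold R^2 target must be in [0, 1)")
        if self.gamma_sd <= 0 or self.sans_sd <= 0 or self.obs_noise_sd < 0:
            raise ConfigurationError("all variances must be > 0")

    @property
    def freq_sd(self) -> tuple[float, float]:
        """Between-subject SDs implied by the configured SEs and group sizes."""
        return (self.freq_se[0] * np.sqrt(self.n_control),
                self.freq_se[1] * np.sqrt(self.n_sz))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class SubjectRecord:
    """One synthetic subject: generating parameters plus derived measures."""

    id: str
    group: str                       # "control" | "SZ"
    gamma: np.ndarray                # generating coupling log-scalings (12,)
    kappa_log: np.ndarray            # generating rate-constant log-scalings (4,)
    freq_target: float               # drawn target peak frequency (Hz)
    spectrum: PowerSpectrum | None
    sustained_freq: float            # peak of the observed spectrum, 30-80 Hz
    sustained_amp: float             # observed power at that peak (sensor units)
    thresholds: dict                 # condition -> deg
    sans: float                      # SZ only; NaN for controls
    gaba: float


class Cohort:
    """A generated cohort: subject records plus provenance."""

    def __init__(self, subjects: list[SubjectRecord], config: CohortConfig,
                 seed: int):
        self.subjects = subjects
        self.config = config
        self.seed = seed

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-subject covariate table."""
        rows = []
        for s in self.subjects:
            row = {"subject": s.id, "group": s.group,
                   "freq_target_hz": s.freq_target,
                   "sustained_freq_hz": s.sustained_freq,
                   "sustained_amp": s.sustained_amp,
                   "sans": s.sans, "gaba": s.gaba}
            for cond, thr in s.thresholds.items():
                row[f"threshold_{cond}_deg"] = thr
            for k in range(12):
                row[f"g{k + 1}"] = s.gamma[k]
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, directory) -> None:
        """Write subjects.csv, per-subject spectra and a manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "subjects.csv", index=False)
        for s in self.subjects:
            if s.spectrum is not None:
                s.spectrum.to_text(directory / f"{s.id}_spectrum.tsv")
        manifest = {"seed": self.seed, "config_hash": self.config.hash(),
                    "config": json.loads(self.config.to_json()),
                    "n_subjects": len(self.subjects)}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "Cohort":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = CohortConfig(**manifest["config"])
        df = pd.read_csv(directory / "subjects.csv")
        subjects = []
        for _, row in df.iterrows():
            spec_path = directory / f"{row['subject']}_spectrum.tsv"
            spectrum = PowerSpectrum.from_text(spec_path) if spec_path.exists() else None
            gamma = np.array([row[f"g{k + 1}"] for k in range(12)])
            thresholds = {c.replace("threshold_", "").replace("_deg", ""): row[c]
                          for c in df.columns if c.startswith("threshold_")}
            subjects.append(SubjectRecord(
                id=row["subject"], group=row["group"], gamma=gamma,
                kappa_log=np.zeros(4), freq_target=row["freq_target_hz"],
                spectrum=spectrum, sustained_freq=row["sustained_freq_hz"],
                sustained_amp=row["sustained_amp"], thresholds=thresholds,
                sans=row["sans"], gaba=row["gaba"]))
        return cls(subjects, config, manifest["seed"])


def measure_sustained_peak(power: np.ndarray, grid: np.ndarray,
                           band: tuple[float, float] = (30.0, 80.0),
                           smooth_hz: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Gamma peak frequency/amplitude from sensor power rows.

    The log spectrum is Gaussian-smoothed (default 2 Hz) and the band
    maximum refined by parabolic interpolation — the spectral analogue of
    locating the peak of a window-averaged envelope spectrum.  Returns
    (frequency Hz, power at the nearest grid bin) for each row of
    ``power``.
    """
    power = np.atleast_2d(power)
    df = grid[1] - grid[0]
    sm = gaussian_filter1d(np.log(power), smooth_hz / df, axis=1)
    mask = (grid >= band[0]) & (grid <= band[1])
    gb = grid[mask]
    sb = sm[:, mask]
    j = np.clip(np.argmax(sb, axis=1), 1, len(gb) - 2)
    ar = np.arange(len(j))
    y0, y1, y2 = sb[ar, j - 1], sb[ar, j], sb[ar, j + 1]
    den = y0 - 2.0 * y1 + y2
    off = np.where(np.abs(den) > 1e-12,
                   np.clip(0.5 * (y0 - y2) / den, -0.5, 0.5), 0.0)
    return gb[j] + off * df, power[:, mask][ar, j]


def _dilated_power(gamma: np.ndarray, c: np.ndarray, grid: np.ndarray,
                   base: CMCParameters) -> np.ndarray:
    """Sensor power with the synaptic-speed factor c applied per subject."""
    g = gamma + c[:, None]
    kl = np.tile(c[:, None], (1, 4))
    return (neuronal_power_batch(g, kl, grid, base)
            + base.noise_alpha + base.noise_beta / grid)


def _solve_frequency_factor(gamma: np.ndarray, targets: np.ndarray,
                            base: CMCParameters, grid: np.ndarray,
                            refinements: int = 3) -> np.ndarray:
    """Synaptic-speed factor c putting each subject's measured peak on target.

    Scaling every kappa and every coupling by exp(c) rescales time, so
    the peak frequency is proportional to exp(c) up to the (non-dilating)
    channel-noise floor; a log-ratio fixed-point iteration therefore
    converges in a few steps.
    """
    c = np.zeros(len(targets))
    for _ in range(refinements + 1):
        f, _ = measure_sustained_peak(_dilated_power(gamma, c, grid, base), grid)
        c = c + np.log(targets / f)
    return c


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None,
                    spectra: bool = True,
                    base_params: CMCParameters | None = None) -> Cohort:
    """Draw a full synthetic cohort; fully reproducible from the seed.

    With ``spectra=False`` the per-subject sensor spectra are still
    computed (they define the gamma peak) but not stored on the records,
    which keeps large replicate sweeps light.
    """
    config = config or CohortConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    base = base_params or CMCParameters()
    grid = default_grid()

    n = config.n_control + config.n_sz
    is_sz = np.zeros(n, bool)
    is_sz[config.n_control:] = True
    sd = config.gamma_sd

    # per-subject coupling log-scalings
    gamma = np.zeros((n, 12))
    gamma[:, _FREE_IDX] = rng.normal(0.0, sd, (n, len(_FREE_IDX)))
    for name, shift in config.coupling_shift.items():
        k = int(name.lstrip("g")) - 1
        gamma[is_sz, k] += shift

    # target sustained frequencies
    sds = config.freq_sd
    f_t = np.where(
        is_sz,
        rng.normal(config.freq_mean[1], sds[1], n),
        rng.normal(config.freq_mean[0], sds[0], n),
    )
    f_t = np.clip(f_t, 32.0, 78.0)

    c = _solve_frequency_factor(gamma, f_t, base, grid)
    gamma = gamma + c[:, None]
    kappa_log = np.tile(c[:, None], (1, 4))

    # noisy observed spectra and the measured sustained gamma peak
    power = neuronal_power_batch(gamma, kappa_log, grid, base)
    power = power + base.noise_alpha + base.noise_beta / grid
    power = power * np.exp(rng.normal(0.0, config.obs_noise_sd, power.shape))
    sustained_freq, sustained_amp = measure_sustained_peak(power, grid)

    # SANS (SZ only), calibrated to the target correlation with the
    # subject's effective II self-inhibition (slope = r*sd_SANS/sd_g4).
    # Because the synaptic-speed factor enters g4, slower/lower-frequency
    # subjects also score higher, echoing the frequency-symptom link.
    g4_sz = gamma[is_sz, 3]
    sd4 = max(float(np.std(g4_sz)), 1e-6)
    slope = config.sans_r * config.sans_sd / sd4
    eps_sd = config.sans_sd * np.sqrt(1.0 - config.sans_r**2)
    sans_sz = (config.sans_mean + slope * (g4_sz - g4_sz.mean())
               + rng.normal(0.0, eps_sd, is_sz.sum()))
    sans = np.full(n, np.nan)
    sans[is_sz] = np.clip(sans_sz, 0.0, 125.0)

    # thresholds per condition, calibrated to the target within-group R^2:
    # stronger II->SP inhibition (higher effective g11) => lower threshold
    g11 = gamma[:, 10]
    g11_dev = np.where(is_sz, g11 - g11[is_sz].mean(), g11 - g11[~is_sz].mean())
    sd11 = max(float(np.std(g11[is_sz])), 1e-6)
    thresholds = {}
    for cond in config.threshold_base:
        d = np.sqrt(config.threshold_r2) * config.threshold_sd[cond] / sd11
        eps = config.threshold_sd[cond] * np.sqrt(1.0 - config.threshold_r2)
        thr = (config.threshold_base[cond]
               + np.where(is_sz, config.threshold_sz_offset[cond], 0.0)
               - d * g11_dev + rng.normal(0.0, eps, n))
        thresholds[cond] = np.maximum(thr, 0.1)

    gaba = rng.normal(config.gaba_mean, config.gaba_sd, n)

    subjects = []
    for i in range(n):
        group = "SZ" if is_sz[i] else "control"
        spectrum = None
        if spectra:
            spectrum = PowerSpectrum(grid, power[i], {"kind": "synthetic"})
        subjects.append(SubjectRecord(
            id=f"sub{i + 1:03d}", group=group, gamma=gamma[i],
            kappa_log=kappa_log[i], freq_target=float(f_t[i]),
            spectrum=spectrum, sustained_freq=float(sustained_freq[i]),
            sustained_amp=float(sustained_amp[i]),
            thresholds={k: float(v[i]) for k, v in thresholds.items()},
            sans=float(sans[i]), gaba=float(gaba[i])))
    return Cohort(subjects, config, seed)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """Unit-variance 1/f-weighted background noise per trial."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec = amp * (rng.standard_normal((shape[0], len(freqs)))
                  + 1j * rng.standard_normal((shape[0], len(freqs))))
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n, axis=1)
    return x / x.std(axis=1, keepdims=True)


def generate_trials(subject: SubjectRecord, n_trials: int = 30,
                    sampling_rate: float = 600.0, seed: int | None = 0,
                    sustained_amp: float = 0.6, transient_amp: float = 1.0,
                    stimulus: bool = True):
    """Synthetic virtual-sensor epochs for one subject ([-2, 2] s, onset 0).

    Baseline is 1/f background noise; the stimulus adds a broadband
    (30-80 Hz) transient burst over 0-300 ms and a narrowband sustained
    oscillation at the subject's model peak frequency from 300 ms to 2 s.
    Deterministic given the seed.
    """
    from .features import TrialSet
    from scipy.signal import butter, sosfiltfilt

    rng = np.random.default_rng(seed)
    fs = sampling_rate
    n = int(round(4.0 * fs))
    t = -2.0 + np.arange(n) / fs
    x = _pink_noise(rng, (n_trials, n), fs)
    if stimulus:
        f0 = subject.freq_target
        sus = (t >= 0.3) & (t <= 2.0)
        phases = rng.uniform(0, 2 * np.pi, (n_trials, 1))
        jitter = rng.normal(0.0, 0.3, (n_trials, 1))
        x[:, sus] += sustained_amp * np.cos(
            2 * np.pi * (f0 + jitter) * t[sus][None, :] + phases)
        # broadband transient: bandpassed noise burst with a raised-cosine edge
        burst = (t >= 0.0) & (t <= 0.3)
        sos = butter(4, [30.0, 80.0], btype="bandpass", fs=fs, output="sos")
        bb = sosfiltfilt(sos, rng.standard_normal((n_trials, n)), axis=1)
        bb = bb / bb.std(axis=1, keepdims=True)
        envelope = np.zeros(n)
        envelope[burst] = np.sin(np.pi * (t[burst] / 0.3)) ** 2
        x += transient_amp * bb * envelope[None, :]
    return TrialSet(fs, x, t_start=-2.0)


def generate_behavior(subject: SubjectRecord, n_per_delta: int = 40,
                      lapse: float = DEFAULT_LAPSE, seed: int | None = 0) -> pd.DataFrame:
    """2AFC trial tables for both conditions from the subject's thresholds.

    The generating internal noise per condition is the noise whose
    psychometric function crosses 75% correct at the stored threshold.
    """
    z = norm.ppf((0.75 - lapse / 2.0) / (1.0 - lapse))
    tables = []
    for i, (cond, thr) in enumerate(sorted(subject.thresholds.items())):
        noise = thr / (np.sqrt(2.0) * z)
        deltas = np.geomspace(max(thr / 4.0, 1e-3), thr * 4.0, 7)
        df = simulate_observer(noise, deltas, n_per_delta, lapse,
                               seed=None if seed is None else seed + i,
                               condition=cond)
        df.insert(0, "subject", subject.id)
        tables.append(df)
    return pd.concat(tables, ignore_index=True)
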