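"""Canonical microcircuit (CMC) neural-mass model of a cortical column.

Four interconnected neuronal populations — layer-4 spiny stellate cells
(SS), layer-2/3 superficial pyramidal cells (SP), multi-layer inhibitory
interneurons (II) and layer-5/6 deep pyramidal cells (DP) — each with
second-order synaptic dynamics and a sigmoid voltage-to-firing transform.
Signed intrinsic couplings G1..G12 connect the populations; each coupling
is modulated by a dimensionless log-scaling parameter (prior mean 0), so
the effective strength ``G_k = Gbar_k * exp(gamma_k)`` is always positive
while the excitatory/inhibitory sign lives in the fixed edge table.

Exogenous drive (endogenous afferent input in the generative model)
enters the spiny stellate population only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "POPULATIONS",
    "Edge",
    "EdgeTable",
    "DEFAULT_EDGES",
    "CMCParameters",
    "ConfigurationError",
    "InstabilityError",
    "default_parameters",
    "firing_rate",
    "firing_rate_gain",
    "state_derivative",
    "integrate",
    "scale_free_drive",
]

#: Population order used for all per-population arrays.
POPULATIONS = ("SS", "SP", "II", "DP")

_POP_INDEX = {p: i for i, p in enumerate(POPULATIONS)}


class ConfigurationError(ValueError):
    """Raised for unknown parameter names or invalid configuration values."""


class InstabilityError(RuntimeError):
    """Raised when integration diverges beyond the documented voltage bound."""


@dataclass(frozen=True)
class Edge:
    """A signed intrinsic connection ``source -> target``.

    ``sign`` is +1 (excitatory) or -1 (inhibitory); ``index`` is the
    coupling number k in 1..12 and ``gbar`` its prior-mean strength in
    units of the synaptic rate constant.
    """

    source: str
    target: str
    sign: int
    index: int
    gbar: float

    def __post_init__(self) -> None:
        if self.source not in POPULATIONS or self.target not in POPULATIONS:
            raise ConfigurationError(f"unknown population in edge {self}")
        if self.sign not in (-1, 1):
            raise ConfigurationError(f"edge sign must be +/-1, got {self.sign}")
        if not (1 <= self.index <= 12):
            raise ConfigurationError(f"edge index must be 1..12, got {self.index}")
        if self.gbar <= 0:
            raise ConfigurationError(f"prior-mean strength must be > 0, got {self.gbar}")


class EdgeTable:
    """Immutable table of the 12 intrinsic couplings of the microcircuit.

    Self-connections model synaptic gain control and must be inhibitory.
    """

    def __init__(self, edges: Sequence[Edge]):
        indices = [e.index for e in edges]
        if sorted(indices) != list(range(1, 13)):
            raise ConfigurationError(
                "edge table must contain each coupling index 1..12 exactly once"
            )
        for e in edges:
            if e.source == e.target and e.sign != -1:
                raise ConfigurationError(
                    f"self-connection G{e.index} on {e.source} must be inhibitory"
                )
        self._edges = tuple(sorted(edges, key=lambda e: e.index))

    @property
    def edges(self) -> tuple[Edge, ...]:
        return self._edges

    def __iter__(self):
        return iter(self._edges)

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other) -> bool:
        return isinstance(other, EdgeTable) and self._edges == other._edges

    @property
    def gbar(self) -> np.ndarray:
        """Prior-mean strengths ordered by coupling index (shape (12,))."""
        return np.array([e.gbar for e in self._edges])

    def coupling_matrix(self, coupling: np.ndarray) -> np.ndarray:
        """Signed 4x4 connectivity ``C[target, source]`` for strengths ``coupling``.

        ``coupling`` holds the positive effective strengths G_1..G_12.
        """
        C = np.zeros((4, 4))
        for e in self._edges:
            C[_POP_INDEX[e.target], _POP_INDEX[e.source]] += e.sign * coupling[e.index - 1]
        return C

    def to_json(self) -> str:
        return json.dumps(
            [
                {"source": e.source, "target": e.target, "sign": e.sign,
                 "index": e.index, "gbar": e.gbar}
                for e in self._edges
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EdgeTable":
        return cls([Edge(**d) for d in json.loads(text)])


# Intrinsic coupling layout.  Four edges follow the standard naming of this
# circuit (G4 = II self-inhibition, G6 = DP->II excitation, G7 = SP
# self-inhibition, G11 = II->SP inhibition); the remaining indices complete
# a conventional laminar layout: granular input cells excite both pyramidal
# layers and the interneurons, interneurons inhibit every population, and
# every population carries inhibitory self-gain control.
#
# Prior-mean strengths are in units of the synaptic rate constant and were
# calibrated once (scripts/calibrate_priors.py) so that the prior-mean
# sensor spectrum peaks in the high gamma range characteristic of visual
# cortex; see docs/methods.md.
DEFAULT_EDGES = EdgeTable(
    [
        Edge("SS", "SS", -1, 1, 400.0),
        Edge("SS", "SP", +1, 2, 800.0),
        Edge("SS", "II", +1, 3, 4500.0),
        Edge("II", "II", -1, 4, 1200.0),
        Edge("SP", "DP", +1, 5, 900.0),
        Edge("DP", "II", +1, 6, 600.0),
        Edge("SP", "SP", -1, 7, 1200.0),
        Edge("II", "DP", -1, 8, 200.0),
        Edge("II", "SS", -1, 9, 2800.0),
        Edge("DP", "DP", -1, 10, 100.0),
        Edge("II", "SP", -1, 11, 1500.0),
        Edge("SS", "DP", +1, 12, 200.0),
    ]
)

#: Default synaptic rate constants (1/s) for (SS, SP, II, DP).
KAPPA_BAR = np.array([440.0, 256.0, 325.0, 96.0])

#: Coupling indices free by default during inversion (the 8 couplings whose
#: group effects the pipeline reports).
DEFAULT_FREE_COUPLINGS = (4, 5, 6, 7, 8, 9, 11, 12)


@dataclass
class CMCParameters:
    """Full parameter set of the microcircuit and its observation model.

    ``gamma`` and ``kappa_log`` are dimensionless log-scalings around the
    fixed prior means (edge table ``gbar`` and ``kappa_bar``); the
    remaining fields are on their natural scale.
    """

    gamma: np.ndarray = field(default_factory=lambda: np.zeros(12))
    kappa_log: np.ndarray = field(default_factory=lambda: np.zeros(4))
    slope: float = 2.0 / 3.0            # sigmoid slope, 1/mV
    input_alpha: float = 1.0            # endogenous input amplitude
    input_beta: float = 1.0             # 1/f mixing weight of the input
    noise_alpha: float = 0.002          # white channel-noise floor
    noise_beta: float = 0.008           # 1/f channel-noise amplitude
    obs_weight: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.8, 0.0, 0.2]))
    obs_gain: float = 1.7e6             # overall electrode gain (sensor units)
    edges: EdgeTable = field(default_factory=lambda: DEFAULT_EDGES)
    kappa_bar: np.ndarray = field(default_factory=lambda: KAPPA_BAR.copy())

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.kappa_log = np.asarray(self.kappa_log, dtype=float)
        self.obs_weight = np.asarray(self.obs_weight, dtype=float)
        self.kappa_bar = np.asarray(self.kappa_bar, dtype=float)
        if self.gamma.shape != (12,):
            raise ConfigurationError("gamma must have shape (12,)")
        if self.kappa_log.shape != (4,):
            raise ConfigurationError("kappa_log must have shape (4,)")
        if self.obs_weight.shape != (4,):
            raise ConfigurationError("obs_weight must have shape (4,)")
        if self.slope <= 0:
            raise ConfigurationError("sigmoid slope must be > 0")

    @property
    def coupling(self) -> np.ndarray:
        """Effective strengths G_k = Gbar_k * exp(gamma_k), shape (12,)."""
        return self.edges.gbar * np.exp(self.gamma)

    @property
    def kappa(self) -> np.ndarray:
        """Effective rate constants (1/s) per population, shape (4,)."""
        return self.kappa_bar * np.exp(self.kappa_log)

    def replace(self, **changes) -> "CMCParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def copy(self) -> "CMCParameters":
        return replace(
            self,
            gamma=self.gamma.copy(),
            kappa_log=self.kappa_log.copy(),
            obs_weight=self.obs_weight.copy(),
            kappa_bar=self.kappa_bar.copy(),
        )

    def to_json(self) -> str:
        d = {
            "gamma": self.gamma.tolist(),
            "kappa_log": self.kappa_log.tolist(),
            "slope": self.slope,
            "input_alpha": self.input_alpha,
            "input_beta": self.input_beta,
            "noise_alpha": self.noise_alpha,
            "noise_beta": self.noise_beta,
            "obs_weight": self.obs_weight.tolist(),
            "obs_gain": self.obs_gain,
            "kappa_bar": self.kappa_bar.tolist(),
            "edges": json.loads(self.edges.to_json()),
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CMCParameters":
        d = json.loads(text)
        edges = EdgeTable([Edge(**e) for e in d.pop("edges")])
        return cls(edges=edges, **d)


def default_parameters(config: Mapping[str, float] | None = None) -> CMCParameters:
    """Build a parameter set at the prior means, with optional overrides.

    ``config`` maps parameter names to values: ``gamma_4`` / ``g4`` for
    coupling log-scalings, ``kappa_ss`` .. ``kappa_dp`` for rate-constant
    log-scalings, and any scalar field name of :class:`CMCParameters`.
    Unknown names raise :class:`ConfigurationError`.
    """
    params = CMCParameters()
    if not config:
        return params
    for name, value in config.items():
        key = name.lower()
        if key.startswith(("gamma_", "g")) and key.lstrip("gamma_g").isdigit():
            k = int(key.lstrip("gamma_g"))
            if not 1 <= k <= 12:
                raise ConfigurationError(f"coupling index out of range: {name}")
            params.gamma[k - 1] = float(value)
        elif key.startswith("kappa_") and key[6:].upper() in _POP_INDEX:
            params.kappa_log[_POP_INDEX[key[6:].upper()]] = float(value)
        elif key in ("slope", "input_alpha", "input_beta", "noise_alpha",
                     "noise_beta", "obs_gain"):
            setattr(params, key, float(value))
        elif key == "obs_weight":
            params.obs_weight = np.asarray(value, dtype=float)
            if params.obs_weight.shape != (4,):
                raise ConfigurationError("obs_weight must have 4 entries")
        else:
            raise ConfigurationError(f"unknown parameter name: {name!r}")
    return params


def firing_rate(v, slope: float = 2.0 / 3.0):
    """Rest-centred sigmoid voltage-to-firing transform.

    A logistic function with the resting value subtracted, so that
    ``firing_rate(0) == 0`` and the origin is an exact fixed point of the
    circuit at zero drive.  Bounded in (-1/2, 1/2); monotone increasing.
    """
    if slope <= 0:
        raise ConfigurationError("sigmoid slope must be > 0")
    return expit(slope * np.asarray(v, dtype=float)) - 0.5


def firing_rate_gain(v, slope: float = 2.0 / 3.0):
    """Derivative of :func:`firing_rate` with respect to voltage."""
    s = expit(slope * np.asarray(v, dtype=float))
    return slope * s * (1.0 - s)


def state_derivative(state: np.ndarray, params: CMCParameters,
                     drive: float = 0.0) -> np.ndarray:
    """Time derivative of the 8-dimensional neural state.

    ``state`` stacks the four membrane depolarizations (mV) followed by
    the four synaptic current proxies (mV/s).  Each population obeys a
    second-order synaptic kernel::

        dv_p/dt = i_p
        di_p/dt = kappa_p * (u_p - 2 i_p) - kappa_p**2 * v_p

    where ``u_p`` sums the signed, firing-rate-transformed presynaptic
    inputs; exogenous ``drive`` enters the SS population only.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (8,):
        raise ConfigurationError("state must have shape (8,)")
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite neural state")
    v, i = state[:4], state[4:]
    kappa = params.kappa
    C = params.edges.coupling_matrix(params.coupling)
    u = C @ firing_rate(v, params.slope)
    u[0] += drive
    dv = i
    di = kappa * (u - 2.0 * i) - kappa**2 * v
    return np.concatenate([dv, di])


def scale_free_drive(params: CMCParameters, n: int, dt: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample a drive series whose one-sided PSD follows the input spectrum.

    The endogenous input is a mixture of white and scale-free (1/f)
    fluctuations, ``g_u(f) = input_alpha * (1 + input_beta / f)``.  The
    series is synthesised in the frequency domain; the 1/f term is capped
    below 1 Hz so that very-low-frequency power stays bounded over finite
    records (the fitted band starts well above this).
    """
    freqs = np.fft.rfftfreq(n, dt)
    psd = params.input_alpha * (1.0 + params.input_beta / np.maximum(freqs, 1.0))
    psd[0] = 0.0
    fs = 1.0 / dt
    # one-sided PSD -> rfft coefficient scale for a real series of length n
    amp = np.sqrt(psd * fs * n / 2.0)
    phases = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    phases /= np.sqrt(2.0)
    spec = amp * phases
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1] * rng.standard_normal()
    return np.fft.irfft(spec, n)


_V_BOUND = 500.0  # mV; beyond this the trajectory is declared divergent


def integrate(
    params: CMCParameters,
    drive_series=None,
    dt: float = 5e-4,
    duration: float = 1.0,
    seed: int | None = None,
    initial_state: np.ndarray | None = None,
    scheme: str = "rk4",
) -> np.ndarray:
    """Integrate the microcircuit and return per-population voltage traces.

    ``drive_series`` may be ``None`` (zero drive), a scalar (constant
    drive), a 1-D array sampled at ``dt``, or the string ``"scale_free"``
    to draw an endogenous-input realisation from ``seed`` matching the
    model's input spectrum.  The default scheme is fixed-step RK4 with
    midpoint interpolation of the (band-limited) drive path; a first-order
    Euler–Maruyama step is available as ``scheme="euler"``.  Returns an
    array of shape ``(n_steps + 1, 4)`` of membrane voltages.
    """
    if dt > 1e-3:
        raise ConfigurationError("dt must be <= 1 ms")
    if scheme not in ("rk4", "euler"):
        raise ConfigurationError(f"unknown integration scheme {scheme!r}")
    n = int(round(duration / dt))
    if n * dt < 1.0 - 1e-9:
        raise ConfigurationError("duration must be >= 1 s")

    if drive_series is None:
        drive = np.zeros(n + 1)
    elif isinstance(drive_series, str):
        if drive_series != "scale_free":
            raise ConfigurationError(f"unknown drive kind {drive_series!r}")
        rng = np.random.default_rng(seed)
        drive = scale_free_drive(params, n + 1, dt, rng)
    elif np.isscalar(drive_series):
        drive = np.full(n + 1, float(drive_series))
    else:
        drive = np.asarray(drive_series, dtype=float)
        if drive.ndim != 1 or len(drive) < n:
            raise ConfigurationError("drive series too short for requested duration")
        if len(drive) == n:  # tolerate a series of exactly n steps
            drive = np.append(drive, drive[-1])
        drive = drive[: n + 1]

    x = np.zeros(8) if initial_state is None else np.asarray(initial_state, dtype=float).copy()
    out = np.empty((n + 1, 4))
    out[0] = x[:4]

    kappa = params.kappa
    C = params.edges.coupling_matrix(params.coupling)
    slope = params.slope

    def f(x, d):
        v, i = x[:4], x[4:]
        u = C @ (expit(slope * v) - 0.5)
        u[0] += d
        return np.concatenate([i, kappa * (u - 2.0 * i) - kappa**2 * v])

    for k in range(n):
        if scheme == "euler":
            x = x + dt * f(x, drive[k])
        else:
            dm = 0.5 * (drive[k] + drive[k + 1])
            k1 = f(x, drive[k])
            k2 = f(x + 0.5 * dt * k1, dm)
            k3 = f(x + 0.5 * dt * k2, dm)
            k4 = f(x + dt * k3, drive[k + 1])
            x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.max(np.abs(x[:4])) > _V_BOUND:
            raise InstabilityError(
                f"integration diverged at t={k * dt:.3f}s (|v| > {_V_BOUND} mV); "
                f"gamma={np.round(params.gamma, 3).tolist()}, "
                f"kappa_log={np.round(params.kappa_log, 3).tolist()}"
            )
        out[k + 1] = x[:4]
    return out
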