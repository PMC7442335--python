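"""Linearized spectral forward model of the microcircuit.

Predicts the power spectrum seen by a single virtual sensor from a
:class:`~gammadcm.microcircuit.CMCParameters` set: find the operating
(fixed) point, linearize the dynamics there, form the transfer function
from the endogenous input to each population's depolarization, shape it
by the scale-free input spectrum, and pass it through a
weighted-contribution observation model with additive channel noise.

The default fitting grid spans 4–90 Hz at 0.5 Hz spacing (173 points).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import root

from .microcircuit import (
    CMCParameters,
    ConfigurationError,
    firing_rate_gain,
    state_derivative,
)

__all__ = [
    "default_grid",
    "PowerSpectrum",
    "StabilityError",
    "fixed_point",
    "jacobian",
    "spectral_abscissa",
    "transfer_function",
    "input_spectrum",
    "predict_spectrum",
    "neuronal_power",
    "neuronal_power_batch",
    "peak_frequency",
    "peak_frequency_batch",
]


class StabilityError(RuntimeError):
    """Raised when the linearized operating point is not asymptotically stable."""


def default_grid(fmin: float = 4.0, fmax: float = 90.0, df: float = 0.5) -> np.ndarray:
    """Uniform frequency grid in Hz (inclusive of both endpoints)."""
    n = int(round((fmax - fmin) / df))
    grid = fmin + df * np.arange(n + 1)
    if not np.all(np.diff(grid) > 0):
        raise ConfigurationError("frequency grid must be strictly increasing")
    return grid


@dataclass
class PowerSpectrum:
    """A real, nonnegative power spectrum on a frequency grid.

    ``meta['kind']`` tags provenance: ``predicted``, ``observed`` or
    ``synthetic``.
    """

    freqs: np.ndarray
    power: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ConfigurationError("freqs and power must be 1-D and equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ConfigurationError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ConfigurationError("power must be nonnegative")

    def __len__(self) -> int:
        return len(self.freqs)

    def to_text(self, path) -> None:
        """Write two-column delimited text plus a JSON sidecar for metadata."""
        path = Path(path)
        header = "frequency_hz\tpower"
        np.savetxt(path, np.column_stack([self.freqs, self.power]),
                   header=header, comments="", delimiter="\t")
        if self.meta:
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def from_text(cls, path) -> "PowerSpectrum":
        path = Path(path)
        arr = np.loadtxt(path, skiprows=1, delimiter="\t")
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(arr[:, 0], arr[:, 1], meta)


def fixed_point(params: CMCParameters, drive_mean: float = 0.0,
                tol: float = 1e-9) -> np.ndarray:
    """Operating point of the circuit under constant mean drive.

    With the rest-centred sigmoid and zero mean drive the origin is an
    exact fixed point and is returned immediately; otherwise a root of
    the state derivative is found numerically and verified to ``tol``.
    """
    if drive_mean == 0.0:
        return np.zeros(8)
    sol = root(lambda x: state_derivative(x, params, drive_mean), np.zeros(8),
               method="hybr", tol=1e-12)
    resid = np.linalg.norm(state_derivative(sol.x, params, drive_mean))
    if resid >= tol:
        raise RuntimeError(
            f"fixed-point search did not converge (residual {resid:.3e})"
        )
    return sol.x


def jacobian(params: CMCParameters, state: np.ndarray | None = None) -> np.ndarray:
    """Analytic Jacobian of the state derivative at ``state`` (default: rest).

    Block structure: d(v)/dt = i and
    d(i_p)/dt = kappa_p * sum_q C[p,q] f'(v_q) v_q-terms - 2 kappa_p i_p
    - kappa_p^2 v_p.
    """
    if state is None:
        state = np.zeros(8)
    v = np.asarray(state, dtype=float)[:4]
    kappa = params.kappa
    C = params.edges.coupling_matrix(params.coupling)
    gain = firing_rate_gain(v, params.slope)            # (4,)
    J = np.zeros((8, 8))
    J[:4, 4:] = np.eye(4)
    J[4:, :4] = kappa[:, None] * C * gain[None, :] - np.diag(kappa**2)
    J[4:, 4:] = -2.0 * np.diag(kappa)
    return J


def spectral_abscissa(J: np.ndarray) -> float:
    """Largest real part over the eigenvalues of ``J``."""
    return float(np.max(np.linalg.eigvals(J).real))


def _input_column(params: CMCParameters) -> np.ndarray:
    """Input vector B: drive enters the SS current equation scaled by kappa_SS."""
    B = np.zeros(8)
    B[4] = params.kappa[0]
    return B


def transfer_function(params: CMCParameters, freqs: np.ndarray,
                      state: np.ndarray | None = None,
                      check_stability: bool = True) -> np.ndarray:
    """Complex gain from the drive to each population voltage, shape (n_f, 4).

    ``H_p(f)`` is the voltage row of ``(i 2 pi f I - J)^{-1} B`` where B
    routes the drive into the spiny stellate current equation.
    """
    freqs = np.asarray(freqs, dtype=float)
    J = jacobian(params, state)
    if check_stability and spectral_abscissa(J) >= 0:
        raise StabilityError(
            f"operating point unstable (spectral abscissa "
            f"{spectral_abscissa(J):.4g} >= 0)"
        )
    B = _input_column(params)
    iw = 2j * np.pi * freqs
    A = iw[:, None, None] * np.eye(8)[None] - J[None]
    H = np.linalg.solve(A, np.broadcast_to(B, (len(freqs), 8))[..., None])[..., 0]
    return H[:, :4]


def input_spectrum(params: CMCParameters, freqs: np.ndarray) -> np.ndarray:
    """Endogenous input spectrum g_u(f) = alpha * (1 + beta / f)."""
    if params.input_alpha <= 0:
        raise ConfigurationError("input_alpha must be > 0")
    freqs = np.asarray(freqs, dtype=float)
    return params.input_alpha * (1.0 + params.input_beta / freqs)


def neuronal_power(params: CMCParameters, freqs: np.ndarray,
                   state: np.ndarray | None = None) -> np.ndarray:
    """Sensor power without channel noise: gain * |sum_p w_p H_p|^2 * g_u."""
    H = transfer_function(params, freqs, state)
    sensor = H @ params.obs_weight
    return params.obs_gain * np.abs(sensor) ** 2 * input_spectrum(params, freqs)


def predict_spectrum(params: CMCParameters, grid: np.ndarray | None = None,
                     drive_mean: float = 0.0) -> PowerSpectrum:
    """Predicted virtual-sensor power spectrum on ``grid`` (default 4–90 Hz).

    power(f) = obs_gain * |sum_p w_p H_p(f)|^2 * g_u(f)
               + noise_alpha + noise_beta / f
    """
    if grid is None:
        grid = default_grid()
    state = fixed_point(params, drive_mean)
    power = neuronal_power(params, grid, state)
    power = power + params.noise_alpha + params.noise_beta / grid
    return PowerSpectrum(grid, power, {"kind": "predicted"})


def neuronal_power_batch(gamma: np.ndarray, kappa_log: np.ndarray,
                         freqs: np.ndarray,
                         base: CMCParameters | None = None) -> np.ndarray:
    """Vectorized neuronal power for many parameter draws, shape (m, n_f).

    ``gamma`` is (m, 12) and ``kappa_log`` (m, 4); remaining parameters
    are taken from ``base``.  Stability is not checked per draw (an
    unstable draw simply yields a sharp spectral line; callers performing
    inference should use :func:`predict_spectrum` instead).
    """
    base = base or CMCParameters()
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    kappa_log = np.atleast_2d(np.asarray(kappa_log, dtype=float))
    m = gamma.shape[0]
    freqs = np.asarray(freqs, dtype=float)
    nf = len(freqs)

    gbar = base.edges.gbar
    G = gbar[None, :] * np.exp(gamma)                      # (m, 12)
    kappa = base.kappa_bar[None, :] * np.exp(kappa_log)    # (m, 4)
    gain0 = firing_rate_gain(0.0, base.slope)

    # signed connectivity per draw
    C = np.zeros((m, 4, 4))
    for e in base.edges:
        C[:, _pop(e.target), _pop(e.source)] += e.sign * G[:, e.index - 1]

    J = np.zeros((m, 8, 8))
    J[:, :4, 4:] = np.eye(4)
    J[:, 4:, :4] = kappa[:, :, None] * C * gain0
    idx = np.arange(4)
    J[:, 4 + idx, idx] -= kappa**2
    J[:, 4 + idx, 4 + idx] = -2.0 * kappa

    B = np.zeros((m, 8))
    B[:, 4] = kappa[:, 0]

    iw = 2j * np.pi * freqs
    A = iw[None, :, None, None] * np.eye(8) - J[:, None]   # (m, nf, 8, 8)
    rhs = np.broadcast_to(B[:, None, :, None], (m, nf, 8, 1))
    H = np.linalg.solve(A.reshape(m * nf, 8, 8), rhs.reshape(m * nf, 8, 1))
    H = H.reshape(m, nf, 8)[:, :, :4]
    sensor = H @ base.obs_weight
    g_u = base.input_alpha * (1.0 + base.input_beta / freqs)
    return base.obs_gain * np.abs(sensor) ** 2 * g_u[None, :]


def _pop(label: str) -> int:
    return {"SS": 0, "SP": 1, "II": 2, "DP": 3}[label]


def peak_frequency(params: CMCParameters, band: tuple[float, float] = (30.0, 80.0),
                   df: float = 0.25) -> float:
    """Frequency of the neuronal-power maximum within ``band`` (Hz)."""
    grid = default_grid(band[0], band[1], df)
    power = neuronal_power(params, grid)
    return float(grid[int(np.argmax(power))])


def peak_frequency_batch(gamma: np.ndarray, kappa_log: np.ndarray,
                         band: tuple[float, float] = (30.0, 80.0),
                         df: float = 0.25,
                         base: CMCParameters | None = None) -> np.ndarray:
    """Vectorized peak frequency of the neuronal power for many draws."""
    grid = default_grid(band[0], band[1], df)
    power = neuronal_power_batch(gamma, kappa_log, grid, base)
    return grid[np.argmax(power, axis=1)]
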