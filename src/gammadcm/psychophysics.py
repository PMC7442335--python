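"""2AFC orientation-discrimination psychophysics.

Observers judge which of two sequentially presented grating patches is
oriented more rightward.  The vertical condition varies the orientation
difference around a 0 deg reference, the oblique condition around 45 deg
(the classically harder case).  A cumulative-Gaussian psychometric
function links the orientation difference ``delta`` to accuracy::

    P(correct | delta) = lapse/2 + (1 - lapse) * Phi(delta / (noise * sqrt(2)))

where ``noise`` is the internal orientation noise (deg) and the sqrt(2)
reflects the comparison of two noisy samples.  The discrimination
threshold is the delta at 75% correct on the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .microcircuit import ConfigurationError

__all__ = [
    "CONDITIONS",
    "ThresholdEstimate",
    "EstimationError",
    "default_deltas",
    "simulate_observer",
    "PsychometricModel",
    "estimate_threshold",
]

CONDITIONS = ("vertical", "oblique")
DEFAULT_LAPSE = 0.02


class EstimationError(RuntimeError):
    """Raised when the psychometric fit is degenerate."""


@dataclass(frozen=True)
class ThresholdEstimate:
    """Fitted 2AFC threshold for one condition."""

    condition: str
    threshold: float        # deg at 75% correct on the fitted curve
    slope: float            # dP/d(delta) at the threshold (1/deg)
    loglik: float
    n_trials: int


def p_correct(delta, noise: float, lapse: float = DEFAULT_LAPSE):
    """Psychometric function of the 2AFC task."""
    return lapse / 2.0 + (1.0 - lapse) * norm.cdf(np.asarray(delta, float) / (noise * np.sqrt(2.0)))


def default_deltas(lo: float = 0.3, hi: float = 12.0, n: int = 7) -> np.ndarray:
    """Log-spaced orientation-difference grid for the method of constant stimuli."""
    return np.geomspace(lo, hi, n)


def simulate_observer(noise: float, deltas=None, n_per_delta: int = 40,
                      lapse: float = DEFAULT_LAPSE, seed: int | None = None,
                      condition: str = "vertical") -> pd.DataFrame:
    """Simulate Bernoulli 2AFC responses of a cumulative-Gaussian observer.

    Returns a tidy trial table with columns ``condition``, ``delta_deg``,
    ``correct``.
    """
    if noise <= 0:
        raise ConfigurationError("internal noise must be > 0")
    if not 0 <= lapse < 0.1:
        raise ConfigurationError("lapse must be in [0, 0.1)")
    if condition not in CONDITIONS:
        raise ConfigurationError(f"condition must be one of {CONDITIONS}")
    deltas = default_deltas() if deltas is None else np.asarray(deltas, float)
    if deltas.size == 0:
        raise ConfigurationError("empty delta grid")
    if np.any(deltas <= 0):
        raise ConfigurationError("orientation differences must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for d in deltas:
        p = p_correct(d, noise, lapse)
        correct = rng.random(n_per_delta) < p
        rows.append(pd.DataFrame({"condition": condition, "delta_deg": d,
                                  "correct": correct.astype(int)}))
    return pd.concat(rows, ignore_index=True)


def threshold_from_noise(noise: float, lapse: float = DEFAULT_LAPSE,
                         criterion: float = 0.75) -> float:
    """Delta at which the psychometric function crosses ``criterion``."""
    z = norm.ppf((criterion - lapse / 2.0) / (1.0 - lapse))
    return float(noise * np.sqrt(2.0) * z)


class PsychometricModel:
    """Maximum-likelihood cumulative-Gaussian fit to 2AFC trial records.

    ``records`` is a tidy trial table (``delta_deg``, ``correct`` and
    optionally ``condition``).  The lapse rate is fixed; the single free
    parameter is the internal noise, optimized on a log scale with a
    deterministic start at the median tested delta.
    """

    def __init__(self, records: pd.DataFrame, condition: str | None = None,
                 lapse: float = DEFAULT_LAPSE):
        if condition is not None and "condition" in records:
            records = records[records["condition"] == condition]
        self.condition = condition or (
            records["condition"].iloc[0] if "condition" in records and len(records)
            else "unspecified"
        )
        self.delta = np.asarray(records["delta_deg"], float)
        self.correct = np.asarray(records["correct"], int)
        self.lapse = lapse
        if len(np.unique(self.delta)) < 2:
            raise EstimationError("need >= 2 distinct deltas to fit a threshold")
        if self.correct.all() or not self.correct.any():
            raise EstimationError(
                "all responses identical; widen the delta range toward the "
                "psychometric transition before fitting"
            )

    def _nll(self, log_noise: float) -> float:
        p = p_correct(self.delta, np.exp(log_noise), self.lapse)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(self.correct * np.log(p) + (1 - self.correct) * np.log1p(-p)))

    def fit(self) -> ThresholdEstimate:
        start = np.log(np.median(self.delta))
        res = minimize_scalar(self._nll, bracket=(start - 2.0, start, start + 2.0),
                              method="brent", options={"xtol": 1e-8})
        noise = float(np.exp(res.x))
        thr = threshold_from_noise(noise, self.lapse)
        z = norm.ppf((0.75 - self.lapse / 2.0) / (1.0 - self.lapse))
        slope = (1.0 - self.lapse) * norm.pdf(z) / (noise * np.sqrt(2.0))
        return ThresholdEstimate(self.condition, thr, float(slope),
                                 -float(res.fun), len(self.delta))


def estimate_threshold(records: pd.DataFrame, condition: str | None = None,
                       lapse: float = DEFAULT_LAPSE) -> ThresholdEstimate:
    """Fit the psychometric model and return the 75%-correct threshold."""
    return PsychometricModel(records, condition, lapse).fit()
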