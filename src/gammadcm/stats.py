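"""Group-level inference: t-tests, 2x2 mixed ANOVA, Pearson correlation,
Bonferroni correction, and default-prior (JZS) Bayes factors.

The Bayes factor follows the default two-sample construction: a Cauchy
prior with scale ``rscale`` on the standardized effect size, integrated
numerically via its normal-by-inverse-gamma mixture representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import integrate, stats

from .microcircuit import ConfigurationError

__all__ = [
    "GroupSummary",
    "TestResult",
    "BayesResult",
    "UndefinedStatisticError",
    "t_test",
    "mixed_anova",
    "pearson",
    "bonferroni",
    "jzs_bf",
    "jzs_bf_from_t",
    "bf_best_ratio",
]


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined (e.g. zero variance everywhere)."""


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("group size must be >= 2")
        if self.sd <= 0:
            raise ConfigurationError("group sd must be > 0")


@dataclass(frozen=True)
class TestResult:
    """A frequentist test outcome (statistic, df, two-sided p, direction)."""

    statistic: float
    df: float
    p: float
    direction: int          # sign of the effect (first minus second / named)
    method: str


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    rscale: float
    method: str


def _summarize(x) -> tuple[int, float, float]:
    if isinstance(x, GroupSummary):
        return x.n, x.mean, x.sd
    x = np.asarray(x, float)
    if x.ndim != 1 or len(x) < 2:
        raise ConfigurationError("need >= 2 samples per group")
    return len(x), float(x.mean()), float(x.std(ddof=1))


def t_test(a, b, variant: str = "pooled") -> TestResult:
    """Independent two-sample t-test from samples or group summaries.

    ``variant="pooled"`` assumes equal variances (df = n1 + n2 - 2);
    ``variant="welch"`` uses the Satterthwaite df.
    """
    if variant not in ("pooled", "welch"):
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    (na, ma, sda), (nb, mb, sdb) = _summarize(a), _summarize(b)
    if sda == 0 and sdb == 0:
        raise UndefinedStatisticError("zero variance in both groups")
    equal_var = variant == "pooled"
    t, p = stats.ttest_ind_from_stats(ma, sda, na, mb, sdb, nb,
                                      equal_var=equal_var)
    if equal_var:
        df = na + nb - 2
    else:
        va, vb = sda**2 / na, sdb**2 / nb
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return TestResult(float(t), float(df), float(p),
                      int(np.sign(ma - mb)), f"t-test ({variant})")


def mixed_anova(data: pd.DataFrame, dv: str = "value", within: str = "condition",
                between: str = "group", subject: str = "subject") -> dict[str, TestResult]:
    """Two-way mixed ANOVA (one between-group factor, one within factor).

    ``data`` is tidy/long with one row per subject x within-level.
    Returns TestResults keyed ``"group"``, ``"within"`` and
    ``"interaction"``.  Incomplete subjects raise an error naming them.
    """
    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    missing = counts[counts < n_levels]
    if len(missing):
        raise ConfigurationError(
            f"subjects with missing within-factor cells: {sorted(missing.index)}"
        )
    if np.isclose(data[dv].std(ddof=0), 0.0):
        raise UndefinedStatisticError("response is constant; F is undefined")
    aov = pg.mixed_anova(data=data, dv=dv, within=within, between=between,
                         subject=subject)
    aov = aov.set_index("Source")
    out = {}
    for key, source in (("group", between), ("within", within),
                        ("interaction", "Interaction")):
        row = aov.loc[source]
        if not np.isfinite(row["F"]):
            raise UndefinedStatisticError(f"F undefined for {key} effect")
        out[key] = TestResult(float(row["F"]), float(row["DF1"]),
                              float(row["p_unc"]), 0,
                              "mixed ANOVA (2-level within x group)")
    return out


def pearson(x, y) -> TestResult:
    """Pearson correlation with the t-based two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ConfigurationError("need n >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConfigurationError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), len(x) - 2, float(p), int(np.sign(r)),
                      "Pearson correlation")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if not 0 <= p <= 1:
        raise ConfigurationError("p must be in [0, 1]")
    if m < 1:
        raise ConfigurationError("number of comparisons must be >= 1")
    return min(1.0, m * p)


def _jzs_integrand(g, t, n_eff, df, rscale):
    # normal-by-inverse-gamma mixture representation of the Cauchy prior
    a = 1.0 + n_eff * g
    return (
        a ** -0.5
        * (1.0 + t * t / (a * df)) ** (-(df + 1.0) / 2.0)
        * (2.0 * np.pi) ** -0.5
        * rscale
        * g ** -1.5
        * np.exp(-rscale * rscale / (2.0 * g))
    )


def jzs_bf_from_t(t: float, n1: int, n2: int, rscale: float = np.sqrt(2) / 2) -> BayesResult:
    """Default-prior two-sample BF10 from a t statistic and group sizes.

    Numerator: marginal likelihood under a Cauchy(0, rscale) prior on the
    standardized effect, evaluated by adaptive quadrature of the
    inverse-gamma mixture over the relative prior variance g; denominator:
    the point-null likelihood.
    """
    df = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    null = (1.0 + t * t / df) ** (-(df + 1.0) / 2.0)
    alt, err = integrate.quad(_jzs_integrand, 0.0, np.inf,
                              args=(t, n_eff, df, rscale), limit=200)
    if not np.isfinite(alt) or alt <= 0 or err > 1e-6 * max(alt, 1e-300):
        raise RuntimeError(
            f"Bayes-factor quadrature failed (value {alt}, abs err {err})"
        )
    return BayesResult(float(alt / null), rscale, "JZS t-test (quadrature)")


def jzs_bf(x, y, rscale: float = np.sqrt(2) / 2) -> BayesResult:
    """Default-prior (JZS) Bayes factor for a two-sample comparison."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("need >= 2 samples per group")
    res = t_test(x, y, "pooled")
    return jzs_bf_from_t(res.statistic, len(x), len(y), rscale)


def pearson_bf(x, y) -> BayesResult:
    """Default-prior Bayes factor for a Pearson correlation."""
    res = pearson(x, y)
    bf = float(pg.bayesfactor_pearson(res.statistic, len(np.asarray(x))))
    return BayesResult(bf, np.nan, "Pearson correlation BF (default prior)")


def bf_best_ratio(bfs) -> pd.Series:
    """Evidence ratios BF(best) / BF per parameter (best parameter = 1.0)."""
    s = pd.Series(bfs, dtype=float)
    if (s <= 0).any():
        raise ConfigurationError("all Bayes factors must be > 0")
    return s.max() / s
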