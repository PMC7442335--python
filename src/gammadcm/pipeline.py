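"""Stage orchestration: simulate -> features -> fit -> thresholds -> stats.

Each stage reads and writes plain files under an output directory, logs a
JSON line (stage, seed, wall time, config hash) to ``run.log``, and is
deterministic given the configuration and seed, so deleting outputs and
rerunning reproduces them exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortConfig, generate_behavior, generate_cohort, generate_trials
from .features import extract_peak, hilbert_spectrogram
from .inversion import DEFAULT_FREE_NAMES, PriorSpec, SpectralDCM
from .microcircuit import ConfigurationError
from .psychophysics import estimate_threshold
from .stats import (
    GroupSummary,
    bf_best_ratio,
    bonferroni,
    jzs_bf,
    mixed_anova,
    pearson,
    pearson_bf,
    t_test,
)

__all__ = ["DEFAULT_CONFIG", "STAGES", "load_config", "run"]

STAGES = ("simulate", "features", "fit", "thresholds", "stats", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {},                # CohortConfig field overrides
    "features": {
        "n_trials": 20,
        "sampling_rate": 600.0,
        "band": {"fmin": 30.0, "fmax": 80.0, "step": 0.5},
    },
    "fit": {
        "free_kappa": True,      # include rate constants in the free set
        "max_iter": 128,
    },
    "thresholds": {
        "n_per_delta": 60,
    },
    "stats": {
        "n_comparisons": 8,      # Bonferroni family: the reported couplings
        "parameters": ["g4", "g5", "g6", "g7", "g8", "g9", "g11", "g12"],
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise ConfigurationError(f"unknown configuration key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict) and key != "cohort":
            out[key] = _merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Load a YAML run configuration merged over the defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigurationError("run configuration must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=float)
                          .encode()).hexdigest()[:12]


def _log(out_dir: Path, record: dict) -> None:
    with open(out_dir / "run.log", "a") as fh:
        fh.write(json.dumps(record) + "\n")


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config, out_dir: Path, seed: int) -> None:
    cohort = generate_cohort(CohortConfig(**config["cohort"]), seed=seed)
    cohort.save(out_dir / "cohort")


def _stage_features(config, out_dir: Path, seed: int) -> None:
    cohort = Cohort.load(out_dir / "cohort")
    fc = config["features"]
    rows = []
    for i, s in enumerate(cohort.subjects):
        trials = generate_trials(s, n_trials=fc["n_trials"],
                                 sampling_rate=fc["sampling_rate"],
                                 seed=seed + 1000 + i)
        tfmap = hilbert_spectrogram(trials, fc["band"])
        for window in ("transient", "sustained", "prestimulus"):
            pk = extract_peak(tfmap, window)
            rows.append({"subject": s.id, "group": s.group, "window": window,
                         "frequency_hz": pk.frequency, "amplitude_pct": pk.amplitude})
    pd.DataFrame(rows).to_csv(out_dir / "features.csv", index=False)


def _stage_fit(config, out_dir: Path, seed: int) -> None:
    cohort = Cohort.load(out_dir / "cohort")
    names = DEFAULT_FREE_NAMES
    if config["fit"]["free_kappa"]:
        names = names + ("kappa_ss", "kappa_sp", "kappa_ii", "kappa_dp")
    priors = PriorSpec(names=names)
    post_dir = out_dir / "posteriors"
    post_dir.mkdir(exist_ok=True)
    rows = []
    for s in cohort.subjects:
        if s.spectrum is None:
            raise ConfigurationError(f"subject {s.id} has no stored spectrum")
        res = SpectralDCM(s.spectrum, priors).fit(
            seed=seed, max_iter=config["fit"]["max_iter"])
        (post_dir / f"{s.id}.json").write_text(res.posterior.to_json())
        row = {"subject": s.id, "group": s.group,
               "free_energy": res.free_energy, "converged": res.converged}
        row.update(res.params.to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "params.csv", index=False)


def _stage_thresholds(config, out_dir: Path, seed: int) -> None:
    cohort = Cohort.load(out_dir / "cohort")
    rows = []
    for i, s in enumerate(cohort.subjects):
        trials = generate_behavior(s, n_per_delta=config["thresholds"]["n_per_delta"],
                                   seed=seed + 2000 + i)
        for cond in sorted(s.thresholds):
            est = estimate_threshold(trials, cond)
            rows.append({"subject": s.id, "group": s.group, "condition": cond,
                         "threshold_deg": est.threshold, "slope": est.slope,
                         "n_trials": est.n_trials,
                         "generating_threshold_deg": s.thresholds[cond]})
    pd.DataFrame(rows).to_csv(out_dir / "thresholds.csv", index=False)


def _stage_stats(config, out_dir: Path, seed: int) -> None:
    cohort = Cohort.load(out_dir / "cohort")
    cov = cohort.to_frame()
    params = pd.read_csv(out_dir / "params.csv")
    thresholds = pd.read_csv(out_dir / "thresholds.csv")
    names = config["stats"]["parameters"]
    m = config["stats"]["n_comparisons"]

    # group demographics / gamma summary with pooled t-tests
    demo_rows = []
    for col in ("sustained_freq_hz",):
        groups = {g: cov.loc[cov.group == g, col] for g in ("control", "SZ")}
        res = t_test(groups["control"].values, groups["SZ"].values)
        for g, vals in groups.items():
            demo_rows.append({"measure": col, "group": g, "n": len(vals),
                              "mean": vals.mean(), "sd": vals.std(ddof=1),
                              "t": res.statistic, "p": res.p})
    pd.DataFrame(demo_rows).to_csv(out_dir / "group_summary.csv", index=False)

    # per-parameter group effects: F (= t^2 for two groups), p, BF, BF ratios
    ctrl = params[params.group == "control"]
    sz = params[params.group == "SZ"]
    rows = []
    bfs = {}
    for name in names:
        res = t_test(ctrl[name].values, sz[name].values)
        bf = jzs_bf(ctrl[name].values, sz[name].values)
        bfs[name] = bf.bf10
        rows.append({"parameter": name, "F": res.statistic**2, "df1": 1,
                     "df2": res.df, "p": res.p,
                     "p_bonferroni": bonferroni(res.p, m), "bf10": bf.bf10})
    table2 = pd.DataFrame(rows)
    ratios = bf_best_ratio(bfs)
    table2["bf_best_ratio"] = table2["parameter"].map(ratios)
    table2.to_csv(out_dir / "parameter_group_stats.csv", index=False)

    # threshold mixed ANOVA (group x condition)
    long = thresholds.rename(columns={"threshold_deg": "value"})
    aov = mixed_anova(long[["subject", "group", "condition", "value"]])
    pd.DataFrame([
        {"effect": k, "F": v.statistic, "df": v.df, "p": v.p}
        for k, v in aov.items()
    ]).to_csv(out_dir / "threshold_anova.csv", index=False)

    # SANS correlations within SZ (posterior parameters)
    sz_cov = cov[cov.group == "SZ"].set_index("subject")
    szp = sz.set_index("subject")
    rows = []
    for name in names:
        res = pearson(szp[name].values, sz_cov.loc[szp.index, "sans"].values)
        rows.append({"parameter": name, "r": res.statistic, "p": res.p,
                     "p_bonferroni": bonferroni(res.p, m)})
    pd.DataFrame(rows).to_csv(out_dir / "sans_correlations.csv", index=False)

    # Bayes-factor grid: parameter vs threshold per condition, within SZ
    sz_thr = thresholds[thresholds.group == "SZ"].pivot_table(
        index="subject", columns="condition", values="threshold_deg")
    rows = []
    for cond in sz_thr.columns:
        row = {"condition": cond}
        for name in names:
            bf = pearson_bf(szp[name].values, sz_thr.loc[szp.index, cond].values)
            row[name] = bf.bf10
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "threshold_bf_grid.csv", index=False)


def _stage_report(config, out_dir: Path, seed: int) -> None:
    parts = [f"# Pipeline report (seed {seed}, config {config_hash(config)})\n"]
    for name in ("group_summary", "parameter_group_stats", "threshold_anova",
                 "sans_correlations", "threshold_bf_grid"):
        path = out_dir / f"{name}.csv"
        if path.exists():
            parts.append(f"## {name}\n")
            parts.append(pd.read_csv(path).to_string(index=False))
            parts.append("")
    (out_dir / "report.md").write_text("\n".join(parts))


_STAGE_FN = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "fit": _stage_fit,
    "thresholds": _stage_thresholds,
    "stats": _stage_stats,
    "report": _stage_report,
}


def run(stages, config: dict | None = None, out_dir="pipeline_out",
        seed: int | None = None) -> Path:
    """Execute a contiguous subset of pipeline stages.

    Raises on the first stage failure; partial outputs of completed
    stages remain valid (each stage is atomic at file granularity).
    """
    config = config or load_config(None)
    seed = config["seed"] if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(stages, str):
        stages = [stages]
    order = [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    for stage in order:
        t0 = time.time()
        _STAGE_FN[stage](config, out_dir, seed)
        _log(out_dir, {"stage": stage, "seed": seed,
                       "wall_time_s": round(time.time() - t0, 3),
                       "config_hash": config_hash(config)})
    return out_dir
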