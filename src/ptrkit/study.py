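"""Monte Carlo study runner and application workflow.

Orchestrates the method comparison: for each (scenario, sample size, caliper)
cell, draw independent train/test trials, fit each requested method on the
training draw (observed variables only), evaluate theta_T via the IPW value
estimator and the misclassification rate against the known optimal arm on
the test draw, and aggregate across replicates into a results table of mean
theta (SD) and mean misclassification per method.

A method failure on one replicate (singular fit, no matched pairs, constant
composite) is recorded with its reason and excluded from the aggregates; the
failure rate is reported alongside, the denominator of every aggregate being
the non-failed replicates of that cell.

Per-replicate seeds are derived from the master seed by a counter-based
scheme: SeedSequence([master_seed, cell_index, rep]) hashed to an int below
2^31, so no stream is reused across (scenario, n, caliper, rep) cells and a
study is fully reproducible from its config and master seed.

The module also covers the application workflow for real trial data: apply a
serialised rule to a CSV, or run the half-split analysis (fit each method on
a random half, evaluate a theta contrast on the other half with bootstrap
inference) end-to-end.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import PTRError
from .evaluation import bootstrap_theta, ipw_value, misclassification_rate
from .methods import (
    PTRRule,
    fit_kraemer_ptr,
    fit_modified_kraemer_ptr,
    fit_regression_ptr,
)
from .scenarios import ScenarioSpec, get_scenario, make_train_test
from .trial import TrialData

logger = logging.getLogger("ptrkit")

METHODS = ("regression", "kraemer", "modified_kraemer")


def _fit_method(method: str, data: TrialData, caliper_sd: float) -> PTRRule:
    if method == "regression":
        return fit_regression_ptr(data)
    if method == "kraemer":
        return fit_kraemer_ptr(data)
    if method == "modified_kraemer":
        return fit_modified_kraemer_ptr(data, caliper_sd=caliper_sd)
    raise ValueError(f"unknown method {method!r}; known: {METHODS}")


@dataclasses.dataclass
class StudyConfig:
    """Configuration of a Monte Carlo comparison."""

    scenarios: Sequence[str]
    sample_sizes: Sequence[int]
    n_reps: int = 5000
    methods: Sequence[str] = METHODS
    caliper_sds: Sequence[float] = (0.1,)
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if not self.scenarios or not self.methods or not self.sample_sizes:
            raise ValueError("scenarios, sample_sizes and methods must be non-empty")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; known: {METHODS}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclasses.dataclass
class StudyResult:
    """Per-replicate records and cell-level aggregates."""

    replicates: pd.DataFrame
    aggregate: pd.DataFrame


def replicate_seed(master_seed: int, cell_index: int, rep: int) -> int:
    """Deterministic per-replicate seed, below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), int(cell_index), int(rep)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_replicate(spec: ScenarioSpec, n: int, methods: Sequence[str],
                  caliper_sd: float, seed: int) -> list[dict]:
    """One train/test replicate; returns one record per requested method.

    A method failure yields a flagged record (``failed=True`` with the
    reason), never an exception.
    """
    train, test = make_train_test(spec, n, seed)
    records = []
    for method in methods:
        rec = {
            "scenario": spec.scenario_id, "n": n, "method": method,
            "caliper_sd": caliper_sd, "seed": seed,
            "theta_T": math.nan, "theta_C": math.nan,
            "misclassification": math.nan, "failed": False, "reason": "",
        }
        try:
            rule = _fit_method(method, train.data, caliper_sd)
            res = ipw_value(test.data, rule)
            rec["theta_T"] = res.theta_T
            rec["theta_C"] = res.theta_C
            rec["misclassification"] = misclassification_rate(
                rule, test.optimal, data=test.data)
        except PTRError as err:
            rec["failed"] = True
            rec["reason"] = f"{type(err).__name__}: {err}"
        records.append(rec)
    return records


def aggregate_records(replicates: pd.DataFrame) -> pd.DataFrame:
    """Cell-level means/SDs over non-failed replicates plus failure rates.

    SD is the across-replicate sample SD of theta_T and is reported as NA
    when fewer than two non-failed replicates exist.
    """
    rows = []
    keys = ["scenario", "n", "caliper_sd", "method"]
    for cell, grp in replicates.groupby(keys, sort=False):
        ok = grp[~grp["failed"]]
        rows.append({
            **dict(zip(keys, cell)),
            "n_reps": len(grp),
            "n_failed": int(grp["failed"].sum()),
            "failure_rate": float(grp["failed"].mean()),
            "mean_theta_T": float(ok["theta_T"].mean()) if len(ok) else math.nan,
            "sd_theta_T": float(ok["theta_T"].std(ddof=1)) if len(ok) > 1 else math.nan,
            "mean_misclassification": (float(ok["misclassification"].mean())
                                       if len(ok) else math.nan),
        })
    return pd.DataFrame(rows)


def format_aggregate(aggregate: pd.DataFrame) -> pd.DataFrame:
    """Results-table view: one row per scenario/n/parameter, methods across."""
    rows = []
    for (scen, n, cal), grp in aggregate.groupby(
            ["scenario", "n", "caliper_sd"], sort=False):
        theta = {"scenario": scen, "n": n, "caliper_sd": cal,
                 "parameter": "theta (SD)"}
        mis = {"scenario": scen, "n": n, "caliper_sd": cal,
               "parameter": "misclass. rate"}
        for _, row in grp.iterrows():
            sd = row["sd_theta_T"]
            sd_txt = "NA" if pd.isna(sd) else f"{sd:.3f}"
            theta[row["method"]] = f"{row['mean_theta_T']:.2f} ({sd_txt})"
            mis[row["method"]] = f"{row['mean_misclassification']:.2f}"
        rows += [theta, mis]
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full Monte Carlo grid; write CSVs if an output dir is set.

    Writes ``replicates.csv``, ``aggregate.csv`` and a formatted
    ``results_table.csv``; partial results are flushed if interrupted.
    """
    records: list[dict] = []
    try:
        cell_index = 0
        for scen in config.scenarios:
            spec = get_scenario(scen)
            for n in config.sample_sizes:
                for caliper_sd in config.caliper_sds:
                    logger.info("cell scenario=%s n=%d caliper=%g (%d reps)",
                                scen, n, caliper_sd, config.n_reps)
                    for rep in range(config.n_reps):
                        seed = replicate_seed(config.master_seed, cell_index, rep)
                        records.extend(run_replicate(
                            spec, n, config.methods, caliper_sd, seed))
                    cell_index += 1
    finally:
        replicates = pd.DataFrame(records)
        aggregate = (aggregate_records(replicates)
                     if len(replicates) else pd.DataFrame())
        if config.out_dir is not None and len(replicates):
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            replicates.to_csv(out / "replicates.csv", index=False)
            aggregate.to_csv(out / "aggregate.csv", index=False)
            format_aggregate(aggregate).to_csv(out / "results_table.csv",
                                               index=False)
    return StudyResult(replicates=replicates, aggregate=aggregate)


# ---------------------------------------------------------------------------
# Application to user data
# ---------------------------------------------------------------------------

def apply_rule(rule: PTRRule, data: TrialData, contrast: str = "theta_C",
               B: int = 1000, seed=None) -> dict:
    """Evaluate a fixed rule on a dataset with bootstrap inference."""
    res = ipw_value(data, rule)
    boot = bootstrap_theta(data, rule, contrast=contrast, B=B, seed=seed)
    rec = rule.recommend(data)
    return {
        "rule": str(rule),
        "contrast": contrast,
        "estimate": boot.estimate,
        "se": boot.se,
        "ci_low": boot.ci_low,
        "ci_high": boot.ci_high,
        "p_value": boot.p_value,
        "n": data.n,
        "B": B,
        "n_recommended_treatment": int(np.sum(rec > 0)),
        "mu_ptr": res.mu_ptr,
        "mu_treat": res.mu_treat,
        "mu_control": res.mu_control,
    }


def half_split_analysis(data: TrialData, methods: Sequence[str] = METHODS,
                        contrast: str = "theta_C", B: int = 1000,
                        seed: int = 0, caliper_sd: float = 0.1) -> pd.DataFrame:
    """Trial-application workflow: random half split, fit on one half,
    evaluate the contrast on the other half with bootstrap inference.

    Returns one row per method (rule, estimate, SE, 95% CI, p); a method
    that fails on the training half is reported with its failure reason.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    perm = rng.permutation(data.n)
    n_train = math.ceil(data.n / 2)
    train = data.subset(perm[:n_train])
    test = data.subset(perm[n_train:])
    rows = []
    for k, method in enumerate(methods):
        row = {"method": method, "contrast": contrast, "n_train": train.n,
               "n_test": test.n, "B": B}
        try:
            rule = _fit_method(method, train, caliper_sd)
            boot_seed = np.random.SeedSequence([int(seed), 1, k])
            boot = bootstrap_theta(test, rule, contrast=contrast, B=B,
                                   seed=boot_seed)
            row.update(rule=str(rule), estimate=boot.estimate, se=boot.se,
                       ci_low=boot.ci_low, ci_high=boot.ci_high,
                       p_value=boot.p_value, failed=False, reason="")
        except PTRError as err:
            row.update(rule="", estimate=math.nan, se=math.nan,
                       ci_low=math.nan, ci_high=math.nan, p_value=math.nan,
                       failed=True, reason=f"{type(err).__name__}: {err}")
        rows.append(row)
    return pd.DataFrame(rows)
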