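"""Parameter-sweep experiments over proliferation and migration rates.

Reproduces the computational studies: per-condition replicate runs at day
20, the PR x MR factorial sweep (optionally crossed with regression
distance), and Table-style min-max (mean) summaries across conditions.
Replicate seeds derive deterministically from a master seed, so a sweep is
one reproducible object.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig, baseline_config
from .engine import SimulationResult, run

#: default sweep grid: endpoints from the studied ranges, interior points
#: covering every rate highlighted in the analyses
DEFAULT_MR = (0.24, 1.0, 4.0, 10.0, 20.0, 40.0)
DEFAULT_PR = (0.015, 0.02, 0.025, 0.05, 0.083)

METRIC_COLUMNS = ("vld", "bd", "vsl_mean", "vst_mean", "fd")


@dataclass
class SweepSpec:
    """Factorial sweep specification."""

    mr_values: Sequence[float] = DEFAULT_MR
    pr_values: Sequence[float] = DEFAULT_PR
    d_r_values: Sequence[float] = (100.0,)
    n_replicates: int = 10
    duration_days: float = 20.0
    master_seed: int = 0
    base_config: Optional[SimulationConfig] = None

    def validate(self) -> None:
        for name, vals in (("mr_values", self.mr_values),
                           ("pr_values", self.pr_values),
                           ("d_r_values", self.d_r_values)):
            if not len(vals) or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be positive and non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def replicate_seed(master_seed: int, condition_index: int, replicate: int) -> int:
    """Deterministic per-run seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(condition_index, replicate))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _condition_config(pr: float, mr: float, d_r: float, duration: float,
                      seed: int, base: Optional[SimulationConfig]) -> SimulationConfig:
    if base is None:
        return baseline_config(pr=pr, mr=mr, d_r=d_r, seed=seed,
                               duration_days=duration)
    cfg = dataclasses.replace(base, seed=seed, duration_days=duration)
    cfg.migration = dataclasses.replace(base.migration, d_base=float(mr))
    cfg.growth = dataclasses.replace(base.growth, cycle_mean=1.0 / pr,
                                     cycle_sd=0.1 / pr, d_r=float(d_r))
    cfg.validate()
    return cfg


def run_condition(pr: float, mr: float, d_r: float, duration_days: float,
                  n_reps: int, base_config: Optional[SimulationConfig] = None,
                  master_seed: int = 0, condition_index: int = 0,
                  keep_results: bool = False):
    """Run ``n_reps`` independently seeded replicates of one condition.

    Returns a list of final-time :class:`~angiosprout.metrics.MetricsReport`
    (and, with ``keep_results=True``, the full :class:`SimulationResult`
    bundles including time series).
    """
    if min(pr, mr, d_r, duration_days) <= 0:
        raise ValueError("condition parameters must be positive")
    reports = []
    results = []
    for rep in range(n_reps):
        seed = replicate_seed(master_seed, condition_index, rep)
        cfg = _condition_config(pr, mr, d_r, duration_days, seed, base_config)
        res = run(cfg)
        reports.append(res.final_metrics)
        if keep_results:
            results.append(res)
    return (reports, results) if keep_results else reports


@dataclass
class SweepResult:
    """Long-form per-replicate table plus per-condition aggregates."""

    table: pd.DataFrame  # columns: pr, mr, d_r, replicate, metric, value
    spec: SweepSpec

    def aggregates(self) -> pd.DataFrame:
        """Per-condition replicate means and standard deviations."""
        g = self.table.groupby(["pr", "mr", "d_r", "metric"])["value"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out

    def condition_means(self, metric: str) -> pd.DataFrame:
        agg = self.aggregates()
        return agg[agg["metric"] == metric].reset_index(drop=True)

    def overall_mean(self, metric: str, d_r: Optional[float] = None) -> float:
        """Unweighted mean over conditions of per-condition replicate means."""
        m = self.condition_means(metric)
        if d_r is not None:
            m = m[np.isclose(m["d_r"], d_r)]
        return float(m["mean"].mean())


def run_sweep(spec: SweepSpec, checkpoint_dir=None) -> SweepResult:
    """Full factorial sweep over mr x pr (x d_r) with replicate averaging.

    With ``checkpoint_dir`` each completed condition is cached as a CSV and
    reloaded on resume, so an interrupted sweep keeps its finished work.
    """
    spec.validate()
    rows = []
    ci = 0
    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)
    for d_r in spec.d_r_values:
        for pr in spec.pr_values:
            for mr in spec.mr_values:
                cache = (ckpt / f"cond_{ci:04d}.csv") if ckpt else None
                if cache is not None and cache.exists():
                    rows.append(pd.read_csv(cache))
                    ci += 1
                    continue
                reports = run_condition(
                    pr, mr, d_r, spec.duration_days, spec.n_replicates,
                    base_config=spec.base_config,
                    master_seed=spec.master_seed, condition_index=ci)
                rec = []
                for rep, report in enumerate(reports):
                    d = report.to_dict()
                    for metric in METRIC_COLUMNS:
                        rec.append({"pr": pr, "mr": mr, "d_r": d_r,
                                    "replicate": rep, "metric": metric,
                                    "value": d[metric]})
                frame = pd.DataFrame(rec)
                if cache is not None:
                    frame.to_csv(cache, index=False)
                rows.append(frame)
                ci += 1
    return SweepResult(table=pd.concat(rows, ignore_index=True), spec=spec)


def summarize_model_ranges(sweep_result: SweepResult,
                           metrics: Sequence[str] = METRIC_COLUMNS) -> pd.DataFrame:
    """Per metric: min-max across condition means and the overall mean,
    formatted ``"min-max (mean)"`` alongside the numeric columns."""
    rows = []
    for metric in metrics:
        m = sweep_result.condition_means(metric)["mean"].dropna()
        if not len(m):
            rows.append({"metric": metric, "min": np.nan, "max": np.nan,
                         "mean": np.nan, "summary": "n/a"})
            continue
        lo, hi, mean = float(m.min()), float(m.max()), float(m.mean())
        rows.append({"metric": metric, "min": lo, "max": hi, "mean": mean,
                     "summary": f"{lo:.3g}-{hi:.3g} ({mean:.3g})"})
    return pd.DataFrame(rows)
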