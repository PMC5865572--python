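"""Scenario grid driver: empirical power, Monte-Carlo error, sample size.

A scenario pairs a direct hazard ratio (1, 0.66 or 0.5) with a fractional
reduction of the ALSFRS-R decline rate (0, 0.15 or 0.30) at a follow-up
horizon of 12 or 18 months.  ``run_scenario`` replicates complete trials,
analyzes each replicate with every requested strategy on the same dataset
(paired comparison), and reports per-strategy rejection proportions with
binomial Monte-Carlo standard errors and non-convergence tallies.

Empirical power translates to the sample size reaching a target power by
the normal-quantile relation

    N = n_total * ((z_{1-alpha/2} + z_target) /
                   (z_{1-alpha/2} + Phi^{-1}(power)))**2
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import JointModelParameters, TrialDesign
from .simulate import generate_trial
from .strategies import STRATEGIES, analyze_trial

__all__ = [
    "Scenario",
    "PowerResult",
    "replicate_rng",
    "run_scenario",
    "sample_size_from_power",
    "summarize_power_table",
    "SCENARIO_GRID",
]

HR_GRID = (1.0, 0.66, 0.5)
SLOPE_GRID = (0.0, 0.15, 0.30)
SCENARIO_GRID = [(hr, sr) for hr in HR_GRID for sr in SLOPE_GRID]


@dataclass(frozen=True)
class Scenario:
    hr: float
    slope_reduction: float
    max_followup: float = 18.0

    def __post_init__(self):
        if self.hr <= 0 or not (0 <= self.slope_reduction < 1):
            raise ValueError("invalid scenario")

    @property
    def gamma(self) -> float:
        return math.log(self.hr)

    def label(self) -> str:
        return f"hr={self.hr:g}, slope_reduction={self.slope_reduction:g}, " \
               f"{self.max_followup:g}mo"


@dataclass
class PowerResult:
    scenario: Scenario
    n_reps: int
    master_seed: int
    rejections: dict = field(default_factory=dict)     # strategy -> count
    nonconverged: dict = field(default_factory=dict)   # strategy -> count
    runtime_s: float = 0.0

    def power(self, strategy: str) -> float:
        return self.rejections[strategy] / self.n_reps

    def mc_se(self, strategy: str) -> float:
        p = self.power(strategy)
        return math.sqrt(p * (1.0 - p) / self.n_reps)

    def as_row(self) -> dict:
        row = {"hr": self.scenario.hr,
               "slope_reduction": self.scenario.slope_reduction,
               "max_followup": self.scenario.max_followup,
               "n_reps": self.n_reps, "master_seed": self.master_seed}
        for s in self.rejections:
            row[s] = self.power(s)
            row[f"{s}_mc_se"] = self.mc_se(s)
            row[f"{s}_nonconverged"] = self.nonconverged[s]
        return row


def replicate_rng(master_seed: int, rep: int) -> np.random.Generator:
    """Independent, individually reproducible RNG stream for one replicate."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(rep),)))


def run_scenario(base_params: JointModelParameters, scenario: Scenario,
                 strategies=("cox", "lme", "cox_lme_omnibus", "composite",
                             "cafs", "jm_omnibus"),
                 n_reps: int = 1000, master_seed: int = 0,
                 design: TrialDesign | None = None,
                 strategy_kwargs: dict | None = None,
                 alpha: float = 0.05,
                 progress: bool = False) -> PowerResult:
    """Empirical power of the requested strategies under one scenario.

    Each replicate simulates a fresh trial from a counter-derived seed and
    runs every strategy on that same dataset.  Non-convergent fits count
    as non-rejections (conservative) and are tallied.  Any unexpected
    error aborts with the replicate index for exact reproduction.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    if not strategies:
        raise ValueError("at least one strategy required")
    unknown = [s for s in strategies if s not in STRATEGIES]
    if unknown:
        raise ValueError(f"unknown strategies {unknown}")
    params = base_params.with_scenario(scenario.hr, scenario.slope_reduction)
    if design is None:
        design = TrialDesign(max_followup=scenario.max_followup)
    elif design.max_followup != scenario.max_followup:
        raise ValueError("design horizon disagrees with scenario horizon")
    kwargs = strategy_kwargs or {}
    result = PowerResult(scenario=scenario, n_reps=n_reps,
                         master_seed=master_seed,
                         rejections={s: 0 for s in strategies},
                         nonconverged={s: 0 for s in strategies})
    t0 = time.time()
    for rep in range(n_reps):
        rng = replicate_rng(master_seed, rep)
        dataset = generate_trial(params, design, rng)
        for s in strategies:
            try:
                res = analyze_trial(dataset, s, alpha=alpha, **kwargs.get(s, {}))
            except ValueError as exc:
                raise RuntimeError(
                    f"strategy {s!r} failed on replicate {rep} "
                    f"(master_seed={master_seed}): {exc}") from exc
            if not res.converged:
                result.nonconverged[s] += 1
                continue          # non-convergence counts as non-rejection
            result.rejections[s] += int(res.reject)
        if progress and (rep + 1) % 50 == 0:
            el = time.time() - t0
            print(f"  [{scenario.label()}] {rep + 1}/{n_reps} replicates, "
                  f"{el:.0f}s elapsed", flush=True)
    result.runtime_s = time.time() - t0
    return result


def sample_size_from_power(empirical_power: float, n_total: int,
                           target_power: float = 0.80,
                           alpha: float = 0.05) -> int:
    """Sample size reaching ``target_power`` given an observed power.

    Deterministic normal-quantile translation; monotone decreasing in the
    empirical power and equal to ``n_total`` at the target.  Rounded up to
    the next whole patient.
    """
    if not (0.0 < empirical_power < 1.0):
        raise ValueError("empirical power must lie strictly in (0, 1)")
    if empirical_power <= alpha / 2.0:
        raise ValueError(
            "empirical power at or below alpha/2: translation meaningless")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zt = stats.norm.ppf(target_power)
    zp = stats.norm.ppf(empirical_power)
    n = n_total * ((za + zt) / (za + zp)) ** 2
    return int(np.ceil(n - 1e-9))


def summarize_power_table(results, path=None, plot_path=None) -> pd.DataFrame:
    """Assemble scenario-grid results into a report table.

    ``results`` is an iterable of PowerResult covering the full 3x3
    scenario grid for one follow-up horizon (missing cells raise, listing
    them).  The table mirrors rows = scenarios, columns = strategies, with
    MC standard errors and non-convergence counts appended.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to summarize")
    horizon = {r.scenario.max_followup for r in results}
    if len(horizon) != 1:
        raise ValueError("mixed follow-up horizons in one table")
    have = {(r.scenario.hr, r.scenario.slope_reduction) for r in results}
    missing = [c for c in SCENARIO_GRID if c not in have]
    if missing:
        raise ValueError(f"incomplete scenario grid; missing cells: {missing}")
    order = {c: k for k, c in enumerate(SCENARIO_GRID)}
    results.sort(key=lambda r: order[(r.scenario.hr, r.scenario.slope_reduction)])
    df = pd.DataFrame([r.as_row() for r in results])
    warn = [
        (r.scenario.label(), s, r.nonconverged[s] / r.n_reps)
        for r in results for s in r.nonconverged
        if r.nonconverged[s] / r.n_reps > 0.02
    ]
    if warn:
        import warnings
        warnings.warn(f"non-convergence above 2% in cells: {warn}")
    if path is not None:
        df.to_csv(path, index=False)
    if plot_path is not None:
        _plot_power(df, plot_path)
    return df


def _plot_power(df: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strategies = [c for c in df.columns
                  if c in STRATEGIES]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, sr in zip(axes, SLOPE_GRID):
        sub = df[df.slope_reduction == sr]
        for s in strategies:
            ax.plot(sub.hr, sub[s], marker="o", label=s)
        ax.set_title(f"slope reduction {sr:g}")
        ax.set_xlabel("hazard ratio")
        ax.invert_xaxis()
    axes[0].set_ylabel("empirical power")
    axes[-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
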