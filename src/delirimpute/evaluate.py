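"""Monte-Carlo evaluation grid: replicates, metrics, and the full design.

Each replicate of a scenario runs the complete pipeline: cluster-resample
``n_participants`` from the base cohort, generate the outcome from the true
slope, calibrate and impose the scenario's missingness, then apply the
requested strategies to the masked data.  Per scenario x strategy the loop
reports bias, the mean standard error, coverage of the nominal confidence
interval, the Monte-Carlo error of the bias, and the number of estimable
replicates.

The full design crosses 4 missingness proportions (1, 5, 20, 35%) with 7
mechanism configurations (MCAR, three MAR strengths, three MNAR strengths);
applying all 5 strategies to each of the 28 cells yields 140 scenario
results.

Reproducibility: every source of randomness in a replicate is derived from
``(master seed, scenario cell code, replicate index)``, so any replicate can
be re-run in isolation and strategy comparisons within a replicate are
paired (identical data, masked identically).
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, cluster_resample, generate_outcome
from .missingness import MissingnessSpec, calibrated, impose_missingness
from .strategies import ALL_STRATEGIES, STRATEGIES, NonEstimableError, StrategyEstimate
from .synthbase import BaseCohortParams, generate_base_cohort

__all__ = [
    "DESIGN_PROPORTIONS",
    "MAR_STRENGTHS",
    "MNAR_STRENGTHS",
    "Scenario",
    "ScenarioSummary",
    "design_grid",
    "run_replicate",
    "collect_estimates",
    "compute_metrics",
    "run_scenario",
    "GridConfig",
    "run_grid",
]

DESIGN_PROPORTIONS = (0.01, 0.05, 0.20, 0.35)
MAR_STRENGTHS = (0.01, 0.1, 0.2)   # weak, moderate, strong slope on SOFA
MNAR_STRENGTHS = (0.1, 0.5, 1.0)   # weak, moderate, strong slope on delirium


@dataclasses.dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid plus the design constants it runs under."""

    mechanism: str
    proportion: float
    strength: float = 0.0
    n_participants: int = 200
    n_replicates: int = 1000
    beta_del_true: float = -1.0

    @property
    def spec(self) -> MissingnessSpec:
        return MissingnessSpec(self.mechanism, self.proportion, self.strength)

    @property
    def label(self) -> str:
        return f"{self.spec.label}@{self.proportion:g}"


@dataclasses.dataclass
class ScenarioSummary:
    """Performance of one strategy in one scenario over the replicates."""

    scenario: Scenario | None
    strategy_name: str
    bias: float
    mean_se: float
    coverage: float
    mc_error_bias: float
    n_estimable: int
    n_replicates: int

    def to_row(self) -> dict:
        row = {}
        if self.scenario is not None:
            row.update(
                config_id=self.scenario.label,
                mechanism=self.scenario.mechanism,
                proportion=self.scenario.proportion,
                strength=self.scenario.strength,
                n_participants=self.scenario.n_participants,
                beta_del_true=self.scenario.beta_del_true,
            )
        row.update(
            strategy=self.strategy_name,
            bias=self.bias,
            mean_se=self.mean_se,
            coverage=self.coverage,
            mc_error_bias=self.mc_error_bias,
            n_estimable=self.n_estimable,
            n_replicates=self.n_replicates,
        )
        return row


def design_grid(
    proportions=DESIGN_PROPORTIONS,
    mar_strengths=MAR_STRENGTHS,
    mnar_strengths=MNAR_STRENGTHS,
    mechanisms=("MCAR", "MAR", "MNAR"),
    **scenario_kwargs,
) -> list[Scenario]:
    """Expand the missingness design: proportions x (MCAR + MAR + MNAR strengths)."""
    grid: list[Scenario] = []
    for p in proportions:
        if "MCAR" in mechanisms:
            grid.append(Scenario("MCAR", p, 0.0, **scenario_kwargs))
        if "MAR" in mechanisms:
            grid.extend(Scenario("MAR", p, s, **scenario_kwargs) for s in mar_strengths)
        if "MNAR" in mechanisms:
            grid.extend(
                Scenario("MNAR", p, s, **scenario_kwargs) for s in mnar_strengths
            )
    return grid


def _cell_code(scenario: Scenario) -> int:
    """Stable 32-bit code for a scenario cell, used in seed derivation."""
    key = f"{scenario.mechanism}|{scenario.proportion:.10g}|{scenario.strength:.10g}"
    return zlib.crc32(key.encode())


def _replicate_rngs(scenario: Scenario, replicate_index: int, seed: int):
    ss = np.random.SeedSequence(
        entropy=seed, spawn_key=(_cell_code(scenario), replicate_index)
    )
    return [np.random.default_rng(child) for child in ss.spawn(3)]


def run_replicate(
    base: Cohort,
    scenario: Scenario,
    replicate_index: int,
    seed: int = 0,
    strategies=None,
    b: int = 10,
    intercept: float = 80.0,
    resid_sd: float = 12.0,
    strategy_kwargs: dict | None = None,
) -> dict[str, StrategyEstimate | None]:
    """One full pipeline pass; deterministic given (seed, scenario, index).

    Returns a mapping from strategy name to its estimate, with ``None``
    recording a non-estimable outcome (tallied by the caller, never raised).
    """
    strategies = tuple(strategies or ALL_STRATEGIES)
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")
    rng_data, rng_passive, rng_active = _replicate_rngs(
        scenario, replicate_index, seed
    )

    sample = cluster_resample(base, scenario.n_participants, rng_data)
    sample = generate_outcome(
        sample,
        intercept=intercept,
        beta_del=scenario.beta_del_true,
        resid_sd=resid_sd,
        rng=rng_data,
    )
    spec = calibrated(scenario.spec, sample)
    masked = impose_missingness(sample, spec, rng_data)

    mi_rngs = {"passive_mi": rng_passive, "active_mi": rng_active}
    kwargs = strategy_kwargs or {}
    results: dict[str, StrategyEstimate | None] = {}
    for name in strategies:
        try:
            results[name] = STRATEGIES[name](
                masked, rng=mi_rngs.get(name), b=b, **kwargs.get(name, {})
            )
        except NonEstimableError:
            results[name] = None
    return results


def collect_estimates(
    base: Cohort,
    scenario: Scenario,
    seed: int = 0,
    strategies=None,
    b: int = 10,
    intercept: float = 80.0,
    resid_sd: float = 12.0,
    strategy_kwargs: dict | None = None,
) -> dict[str, list[StrategyEstimate | None]]:
    """Replicate-level estimates for a scenario, keyed by strategy.

    Lists are index-aligned across strategies (paired replicates), enabling
    head-to-head comparisons on identical datasets.
    """
    strategies = tuple(strategies or ALL_STRATEGIES)
    out: dict[str, list[StrategyEstimate | None]] = {s: [] for s in strategies}
    for r in range(scenario.n_replicates):
        res = run_replicate(
            base,
            scenario,
            r,
            seed=seed,
            strategies=strategies,
            b=b,
            intercept=intercept,
            resid_sd=resid_sd,
            strategy_kwargs=strategy_kwargs,
        )
        for s in strategies:
            out[s].append(res[s])
    return out


def compute_metrics(
    estimates,
    beta_true: float,
    ci_level: float = 0.95,
    strategy_name: str | None = None,
    scenario: Scenario | None = None,
) -> ScenarioSummary:
    """Bias, mean SE, coverage and Monte-Carlo error over estimable replicates.

    Non-estimable replicates (``None`` entries) are excluded from every
    metric denominator; their count is recoverable as
    ``n_replicates - n_estimable``.
    """
    estimates = list(estimates)
    usable = [e for e in estimates if e is not None]
    n_est = len(usable)
    name = strategy_name or (usable[0].strategy_name if usable else "unknown")
    if n_est == 0:
        return ScenarioSummary(
            scenario, name, np.nan, np.nan, np.nan, np.nan, 0, len(estimates)
        )
    betas = np.array([e.beta_hat for e in usable])
    ses = np.array([e.se for e in usable])
    covered = np.array([e.covers(beta_true, ci_level) for e in usable])
    mc = betas.std(ddof=1) / np.sqrt(n_est) if n_est > 1 else np.nan
    return ScenarioSummary(
        scenario=scenario,
        strategy_name=name,
        bias=float(betas.mean() - beta_true),
        mean_se=float(ses.mean()),
        coverage=float(covered.mean()),
        mc_error_bias=float(mc),
        n_estimable=n_est,
        n_replicates=len(estimates),
    )


def run_scenario(
    base: Cohort,
    scenario: Scenario,
    seed: int = 0,
    strategies=None,
    b: int = 10,
    ci_level: float = 0.95,
    intercept: float = 80.0,
    resid_sd: float = 12.0,
    strategy_kwargs: dict | None = None,
) -> list[ScenarioSummary]:
    strategies = tuple(strategies or ALL_STRATEGIES)
    per_strategy = collect_estimates(
        base,
        scenario,
        seed=seed,
        strategies=strategies,
        b=b,
        intercept=intercept,
        resid_sd=resid_sd,
        strategy_kwargs=strategy_kwargs,
    )
    return [
        compute_metrics(
            per_strategy[s],
            scenario.beta_del_true,
            ci_level=ci_level,
            strategy_name=s,
            scenario=scenario,
        )
        for s in strategies
    ]


# ----------------------------------------------------------------------
# full grid runner
# ----------------------------------------------------------------------
@dataclasses.dataclass
class GridConfig:
    """Everything needed to reproduce a grid run."""

    base_params: BaseCohortParams = dataclasses.field(default_factory=BaseCohortParams)
    proportions: tuple = DESIGN_PROPORTIONS
    mar_strengths: tuple = MAR_STRENGTHS
    mnar_strengths: tuple = MNAR_STRENGTHS
    mechanisms: tuple = ("MCAR", "MAR", "MNAR")
    n_participants: int = 200
    n_replicates: int = 200
    b: int = 10
    beta_del: float = -1.0
    intercept: float = 80.0
    resid_sd: float = 12.0
    ci_level: float = 0.95
    seed: int = 0
    strategies: tuple = ALL_STRATEGIES

    def scenarios(self) -> list[Scenario]:
        return design_grid(
            proportions=tuple(self.proportions),
            mar_strengths=tuple(self.mar_strengths),
            mnar_strengths=tuple(self.mnar_strengths),
            mechanisms=tuple(self.mechanisms),
            n_participants=self.n_participants,
            n_replicates=self.n_replicates,
            beta_del_true=self.beta_del,
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "GridConfig":
        raw = dict(raw)
        base = raw.pop("base_params", None) or raw.pop("base", None) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("proportions", "mar_strengths", "mnar_strengths",
                    "mechanisms", "strategies"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(base_params=BaseCohortParams(**base), **raw)

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


def run_grid(
    config: GridConfig,
    outdir=None,
    base: Cohort | None = None,
    progress: bool = True,
) -> pd.DataFrame:
    """Run every scenario of the configured grid and assemble a long table.

    One row per scenario cell x strategy.  When ``outdir`` is given,
    ``results.csv`` and a JSON ``manifest.json`` (config, seed, row count,
    timing) are written there.  Partial failures never abort the run: a
    strategy that is non-estimable in a replicate is simply tallied.
    """
    t0 = time.time()
    if base is None:
        base_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(0xBA5E,))
        )
        base = generate_base_cohort(config.base_params, rng=base_rng)
    scenarios = config.scenarios()
    rows = []
    for i, scenario in enumerate(scenarios):
        if progress:
            print(
                f"[{i + 1}/{len(scenarios)}] {scenario.label} "
                f"({scenario.n_replicates} replicates)",
                file=sys.stderr,
                flush=True,
            )
        summaries = run_scenario(
            base,
            scenario,
            seed=config.seed,
            strategies=config.strategies,
            b=config.b,
            ci_level=config.ci_level,
            intercept=config.intercept,
            resid_sd=config.resid_sd,
        )
        rows.extend(s.to_row() for s in summaries)
    results = pd.DataFrame(rows)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results.to_csv(outdir / "results.csv", index=False)
        manifest = {
            "schema_version": 1,
            "config": config.to_dict(),
            "n_rows": len(results),
            "n_scenarios": len(scenarios),
            "elapsed_seconds": round(time.time() - t0, 2),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results
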