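"""Replicate experiments: validation, strategy comparison, sensitivity.

Every result is aggregated over independent replicates; replicate ``r``
derives all of its randomness (arrival order of the network growth,
environmental coefficients, stochastic targeting) from ``base_seed + r``,
so a control run and an intervention run with the same base seed share
their network and environment and their difference isolates the
intervention (paired design).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import ModelParams, Trajectory, run_simulation
from .interventions import Intervention, InterventionSpec, STRATEGIES
from .network import HomophilyParams, generate_network
from .population import BMI_OBESE_CUTOFF, BMI_OVERWEIGHT_CUTOFF

__all__ = [
    "SimulationConfig",
    "ResultSet",
    "SensitivityRow",
    "run_replicates",
    "compare_strategies",
    "outcome_metrics",
    "paired_t_test",
    "sensitivity_scan",
    "calibrate_impacts",
]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Everything but the population and the seed: network + dynamics + horizon."""

    params: ModelParams = ModelParams()
    density: float = 0.267
    homophily: HomophilyParams = HomophilyParams()
    network_seed_size: int = 3
    weeks: int = 104

    def with_params(self, **updates) -> "SimulationConfig":
        return dataclasses.replace(self, params=dataclasses.replace(self.params, **updates))


@dataclasses.dataclass
class ResultSet:
    """Per-replicate outcome metrics with across-replicate summaries."""

    strategy: Optional[str]
    seeds: List[int]
    mean_bw_change: np.ndarray  # kg, one entry per replicate
    mean_bmi_change: np.ndarray  # kg/m^2
    overweight_pct: np.ndarray  # percent at final week
    obesity_pct: np.ndarray
    final_weights: np.ndarray  # (replicates, agents)
    initial_weights: np.ndarray  # (agents,)
    config: SimulationConfig

    @property
    def n_replicates(self) -> int:
        return len(self.seeds)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("mean_bw_change", "mean_bmi_change", "overweight_pct", "obesity_pct"):
            vals = getattr(self, name)
            mean = float(vals.mean())
            if len(vals) > 1:
                sd = float(vals.std(ddof=1))
                half = 1.96 * sd / np.sqrt(len(vals))
                ci = (mean - half, mean + half)
            else:
                sd = float("nan")
                ci = (float("nan"), float("nan"))
            rows.append({"metric": name, "mean": mean, "sd": sd, "ci_low": ci[0], "ci_high": ci[1]})
        return pd.DataFrame(rows)

    def stat(self, name: str) -> Tuple[float, float, Tuple[float, float]]:
        row = self.summary().set_index("metric").loc[name]
        return float(row["mean"]), float(row["sd"]), (float(row["ci_low"]), float(row["ci_high"]))


def outcome_metrics(initial_states, final_states, persons=None) -> Dict[str, float]:
    """End-of-run population metrics from initial and final states."""
    if list(initial_states.ids) != list(final_states.ids):
        raise ValueError("initial and final states must cover the same agents in order")
    bmi_f = final_states.bmi()
    return {
        "mean_bw_change": float((final_states.bw - initial_states.bw).mean()),
        "mean_bmi_change": float((final_states.bmi() - initial_states.bmi()).mean()),
        "overweight_pct": 100.0 * float(((bmi_f >= BMI_OVERWEIGHT_CUTOFF) & (bmi_f < BMI_OBESE_CUTOFF)).mean()),
        "obesity_pct": 100.0 * float((bmi_f >= BMI_OBESE_CUTOFF).mean()),
    }


def _one_replicate(population, config: SimulationConfig, seed: int,
                   spec: Optional[InterventionSpec], network=None) -> Trajectory:
    if network is None:
        network = generate_network(
            population, config.density, config.homophily, seed=seed,
            seed_size=config.network_seed_size,
        )
    intervention = Intervention(spec, network) if spec is not None else None
    return run_simulation(population, network, config.params, weeks=config.weeks,
                          intervention=intervention, seed=seed)


def run_replicates(
    population,
    config: SimulationConfig = SimulationConfig(),
    n_runs: int = 100,
    base_seed: int = 0,
    intervention: Optional[InterventionSpec] = None,
) -> ResultSet:
    """Average ``n_runs`` independent replicates of one scenario."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = [base_seed + r for r in range(n_runs)]
    metrics = {k: [] for k in ("mean_bw_change", "mean_bmi_change", "overweight_pct", "obesity_pct")}
    finals = []
    initial_weights = None
    for seed in seeds:
        traj = _one_replicate(population, config, seed, intervention)
        m = outcome_metrics(traj.initial, traj.final)
        for k in metrics:
            metrics[k].append(m[k])
        finals.append(traj.final.bw.copy())
        if initial_weights is None:
            initial_weights = traj.initial.bw.copy()
    return ResultSet(
        strategy=intervention.strategy if intervention else None,
        seeds=seeds,
        mean_bw_change=np.array(metrics["mean_bw_change"]),
        mean_bmi_change=np.array(metrics["mean_bmi_change"]),
        overweight_pct=np.array(metrics["overweight_pct"]),
        obesity_pct=np.array(metrics["obesity_pct"]),
        final_weights=np.array(finals),
        initial_weights=initial_weights,
        config=config,
    )


def compare_strategies(
    population,
    config: SimulationConfig = SimulationConfig(),
    strategies: Sequence[str] = STRATEGIES,
    n_runs: int = 100,
    base_seed: int = 0,
    spec_kwargs: Optional[dict] = None,
) -> Dict[Optional[str], ResultSet]:
    """Control plus each strategy, paired per replicate (shared networks).

    Returns a mapping ``{None: control, strategy: ResultSet, ...}``.
    """
    spec_kwargs = spec_kwargs or {}
    scenarios: List[Optional[InterventionSpec]] = [None] + [
        InterventionSpec(strategy=s, **spec_kwargs) for s in strategies
    ]
    seeds = [base_seed + r for r in range(n_runs)]
    store = {
        (sp.strategy if sp else None): {
            "metrics": {k: [] for k in ("mean_bw_change", "mean_bmi_change",
                                        "overweight_pct", "obesity_pct")},
            "finals": [],
        }
        for sp in scenarios
    }
    initial_weights = None
    for seed in seeds:
        network = generate_network(population, config.density, config.homophily,
                                   seed=seed, seed_size=config.network_seed_size)
        for sp in scenarios:
            traj = _one_replicate(population, config, seed, sp, network=network)
            key = sp.strategy if sp else None
            m = outcome_metrics(traj.initial, traj.final)
            for k in store[key]["metrics"]:
                store[key]["metrics"][k].append(m[k])
            store[key]["finals"].append(traj.final.bw.copy())
            if initial_weights is None:
                initial_weights = traj.initial.bw.copy()
    out = {}
    for sp in scenarios:
        key = sp.strategy if sp else None
        s = store[key]
        out[key] = ResultSet(
            strategy=key,
            seeds=seeds,
            mean_bw_change=np.array(s["metrics"]["mean_bw_change"]),
            mean_bmi_change=np.array(s["metrics"]["mean_bmi_change"]),
            overweight_pct=np.array(s["metrics"]["overweight_pct"]),
            obesity_pct=np.array(s["metrics"]["obesity_pct"]),
            final_weights=np.array(s["finals"]),
            initial_weights=initial_weights,
            config=config,
        )
    return out


def paired_t_test(x, y) -> Tuple[float, float]:
    """Classical paired t on x - y with n-1 degrees of freedom.

    Zero-variance convention: all differences zero -> (0, 1); constant
    nonzero differences -> (signed inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t_test needs two equal-length samples of size >= 2")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# sensitivity and calibration

@dataclasses.dataclass(frozen=True)
class SensitivityRow:
    parameter: str  # {baseline, t_ei, t_pa, lambda_discount, env}
    delta: float  # 0 for baseline, else +/-0.10
    mean_weight_change: float  # kg


def sensitivity_scan(
    population,
    config: SimulationConfig = SimulationConfig(),
    n_runs: int = 100,
    delta: float = 0.10,
    base_seed: int = 0,
) -> List[SensitivityRow]:
    """Baseline plus the 8 one-at-a-time +/-delta perturbations, no
    intervention. The Env perturbation scales both interval endpoints."""
    rows = []
    scenarios: List[Tuple[str, float, SimulationConfig]] = [("baseline", 0.0, config)]
    for sign in (-1.0, +1.0):
        f = 1.0 + sign * delta
        p = config.params
        scenarios += [
            ("t_ei", sign * delta, config.with_params(t_ei=p.t_ei * f)),
            ("t_pa", sign * delta, config.with_params(t_pa=p.t_pa * f)),
            ("lambda_discount", sign * delta, config.with_params(lambda_discount=p.lambda_discount * f)),
            ("env", sign * delta, config.with_params(env_low=p.env_low * f, env_high=p.env_high * f)),
        ]
    for name, d, cfg in scenarios:
        res = run_replicates(population, cfg, n_runs=n_runs, base_seed=base_seed)
        rows.append(SensitivityRow(parameter=name, delta=d,
                                   mean_weight_change=float(res.mean_bw_change.mean())))
    return rows


def calibrate_impacts(
    population,
    config: SimulationConfig = SimulationConfig(),
    grid: Sequence[float] = (0.02, 0.05, 0.08, 0.12),
    n_runs: int = 10,
    base_seed: int = 0,
    target_mean: float = 0.2,
    target_sd: float = 1.9,
) -> Tuple[Tuple[float, float], pd.DataFrame]:
    """Grid-search the unpublished impact constants (I_EI, I_PA).

    Scores each (i_ei, i_pa) pair by the relative misfit of the
    no-intervention run against the validation moments: the mean biennial
    population weight change and the SD of individual weight changes.
    Returns the best pair and the full grid table.
    """
    records = []
    best = None
    for i_ei in grid:
        for i_pa in grid:
            cfg = config.with_params(i_ei=i_ei, i_pa=i_pa)
            res = run_replicates(population, cfg, n_runs=n_runs, base_seed=base_seed)
            drift = float(res.mean_bw_change.mean())
            indiv_sd = float((res.final_weights - res.initial_weights).std(ddof=1))
            score = abs(drift / target_mean - 1.0) + abs(indiv_sd / target_sd - 1.0)
            records.append({"i_ei": i_ei, "i_pa": i_pa, "mean_change": drift,
                            "individual_sd": indiv_sd, "score": score})
            if best is None or score < best[0]:
                best = (score, (i_ei, i_pa))
    return best[1], pd.DataFrame(records)
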