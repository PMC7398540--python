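"""Weekly energy-balance dynamics on the social network.

Each agent carries evolving daily energy intake (EI), physical-activity
energy (PA) and body weight. Every seven-day cycle:

1. social influence per channel = mean neighbour value minus own value,
   using last week's values (synchronous update);
2. an agent-level environmental coefficient Env in (0, 2) modulates the
   influence — for intake a harmful environment (Env < 1) amplifies
   upward pressure (divide positive influence by Env) and dampens downward
   pressure; for activity the roles are reversed;
3. if the modulated influence exceeds a fixed fraction (threshold) of the
   agent's current level, EI or PA moves by a fixed impact fraction,
   otherwise nothing changes (behavioural deadband);
4. the resulting energy imbalance EI - EE, discounted by lambda because
   habits change gradually, converts to weight change via an energy
   density (kcal per kg of tissue);
5. expenditure EE is recomputed as REE(current weight) + 10% of current
   EI (thermic effect of food) + PA.

Identical EI and PA across a component is a fixed point: no influence, no
change, weight constant at equilibrium.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .population import (
    Person,
    partition_energy,
    BMI_OVERWEIGHT_CUTOFF,
    BMI_OBESE_CUTOFF,
)
from .network import SocialNetwork

__all__ = [
    "ModelParams",
    "AgentState",
    "States",
    "Trajectory",
    "social_influence",
    "env_modulate",
    "apply_threshold",
    "weight_update",
    "step_week",
    "run_simulation",
    "initialize_states",
]


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """All constants of the weekly dynamics.

    ``t_ei``/``t_pa`` are the calibrated influence thresholds (fractions of
    the agent's own EI/PA); ``i_ei``/``i_pa`` the adjustment impacts (not
    published with the calibrated set; see the calibration helper in
    :mod:`obesinet.experiments`); ``lambda_discount`` the fraction of each
    cycle's imbalance converted to weight; ``env_low``/``env_high`` the
    calibrated range of the per-agent environmental coefficient;
    ``energy_density`` kcal per kg of weight change, either a constant or a
    function of initial body weight.
    """

    t_ei: float = 0.07
    t_pa: float = 0.12
    i_ei: float = 0.05
    i_pa: float = 0.05
    lambda_discount: float = 0.25
    env_low: float = 0.82
    env_high: float = 1.08
    cycle_days: float = 7.0
    energy_density: Union[float, Callable[[np.ndarray], np.ndarray]] = 7700.0
    bw_floor: float = 30.0
    redraw_env_weekly: bool = False

    def __post_init__(self) -> None:
        if self.t_ei <= 0 or self.t_pa <= 0 or self.i_ei <= 0 or self.i_pa <= 0:
            raise ValueError("thresholds and impacts must be > 0")
        if not (0 < self.lambda_discount <= 1):
            raise ValueError("lambda_discount must be in (0, 1]")
        if not (0 < self.env_low <= self.env_high < 2):
            raise ValueError("Env bounds must satisfy 0 < low <= high < 2")

    def rho(self, bw_initial: np.ndarray) -> np.ndarray:
        """Energy density (kcal/kg) evaluated at initial body weight."""
        if callable(self.energy_density):
            out = np.asarray(self.energy_density(np.asarray(bw_initial, dtype=float)), dtype=float)
        else:
            out = np.full_like(np.asarray(bw_initial, dtype=float), float(self.energy_density))
        if np.any(out <= 0):
            raise ValueError("energy_density must be positive everywhere")
        return out


@dataclasses.dataclass
class AgentState:
    """Scalar view of one agent's time-varying state (kcal/day, kg)."""

    ei: float
    pa: float
    bw: float
    bw_initial: float
    env: float


@dataclasses.dataclass
class States:
    """Vectorized state of the whole population, aligned on ``ids``."""

    ids: List
    ei: np.ndarray
    pa: np.ndarray
    bw: np.ndarray
    bw_initial: np.ndarray
    env: np.ndarray
    # fixed attributes needed to recompute REE as weight evolves
    male: np.ndarray
    age: np.ndarray
    height_cm: np.ndarray

    def copy(self) -> "States":
        return States(
            ids=list(self.ids),
            ei=self.ei.copy(), pa=self.pa.copy(), bw=self.bw.copy(),
            bw_initial=self.bw_initial.copy(), env=self.env.copy(),
            male=self.male, age=self.age, height_cm=self.height_cm,
        )

    def __len__(self) -> int:
        return len(self.ids)

    def agent(self, agent_id) -> AgentState:
        i = self.ids.index(agent_id)
        return AgentState(
            ei=float(self.ei[i]), pa=float(self.pa[i]), bw=float(self.bw[i]),
            bw_initial=float(self.bw_initial[i]), env=float(self.env[i]),
        )

    def bmi(self) -> np.ndarray:
        return self.bw / (self.height_cm / 100.0) ** 2

    def ree(self) -> np.ndarray:
        """Vectorized REE at the current body weight."""
        m = 66.5 + 13.6 * self.bw + 5.0 * self.height_cm - 6.8 * self.age
        f = 655.1 + 9.5 * self.bw + 1.8 * self.height_cm - 4.1 * self.age
        return np.where(self.male, m, f)


@dataclasses.dataclass
class Trajectory:
    """Weekly population metrics plus initial and final per-agent state."""

    week: np.ndarray
    mean_bw: np.ndarray
    mean_bmi: np.ndarray
    overweight_rate: np.ndarray  # percent
    obesity_rate: np.ndarray  # percent
    initial: States
    final: States

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "week": self.week,
                "mean_bw": self.mean_bw,
                "mean_bmi": self.mean_bmi,
                "overweight_rate": self.overweight_rate,
                "obesity_rate": self.obesity_rate,
            }
        )


# ---------------------------------------------------------------------------
# scalar operations (the algebra of one agent; step_week vectorizes these)

def social_influence(states: States, network: SocialNetwork, agent_id, channel: str) -> float:
    """Mean neighbour-minus-self difference for one agent and channel."""
    values = states.ei if channel == "EI" else states.pa
    idx = {v: i for i, v in enumerate(states.ids)}
    i = idx[agent_id]
    nbrs = [idx[v] for v in network.graph.neighbors(agent_id)]
    if not nbrs:
        return 0.0
    return float(np.mean([values[j] - values[i] for j in nbrs]))


def env_modulate(raw: float, env: float, channel: str):
    """Combine social influence with the environmental coefficient.

    Intake channel: positive influence divided by Env (harmful Env < 1
    amplifies), negative multiplied. Activity channel: the reverse.
    """
    if np.any(np.asarray(env) <= 0):
        raise ValueError("env must be > 0")
    raw = np.asarray(raw, dtype=float)
    if channel == "EI":
        out = np.where(raw >= 0, raw / env, raw * env)
    elif channel == "PA":
        out = np.where(raw >= 0, raw * env, raw / env)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return float(out) if out.ndim == 0 else out


def apply_threshold(prev, combined, threshold: float, impact: float):
    """Deadband update: move by +/- impact only if |combined| exceeds
    threshold*prev (strict inequalities; no change at exact equality)."""
    prev = np.asarray(prev, dtype=float)
    combined = np.asarray(combined, dtype=float)
    up = combined > threshold * prev
    down = combined < -threshold * prev
    out = np.where(up, prev * (1 + impact), np.where(down, prev * (1 - impact), prev))
    return float(out) if out.ndim == 0 else out


def weight_update(state: AgentState, params: ModelParams, ee: float) -> float:
    """New body weight after one cycle's discounted energy imbalance."""
    rho = float(params.rho(np.array([state.bw_initial]))[0])
    delta = params.lambda_discount * params.cycle_days * (state.ei - ee) / rho
    return max(state.bw + delta, params.bw_floor)


# ---------------------------------------------------------------------------
# vectorized weekly step

def adjacency_matrix(network: SocialNetwork, ids: Sequence) -> sp.csr_matrix:
    """CSR adjacency of the network in the given id order."""
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    rows, cols = [], []
    for u, v in network.graph.edges:
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def step_week(
    states: States,
    adjacency: sp.csr_matrix,
    params: ModelParams,
    ei_mult: Optional[np.ndarray] = None,
    pa_mult: Optional[np.ndarray] = None,
    ei_floor: Optional[np.ndarray] = None,
) -> States:
    """One synchronous weekly update; returns a new ``States``.

    ``ei_mult``/``pa_mult`` are per-agent multiplicative intervention
    effects applied after the threshold update; ``ei_floor`` bounds
    intervention-driven intake from below (default: current REE).
    """
    new = states.copy()
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    safe_deg = np.where(deg > 0, deg, 1.0)

    inf_ei = np.where(deg > 0, adjacency @ states.ei / safe_deg - states.ei, 0.0)
    inf_pa = np.where(deg > 0, adjacency @ states.pa / safe_deg - states.pa, 0.0)

    comb_ei = env_modulate(inf_ei, states.env, "EI")
    comb_pa = env_modulate(inf_pa, states.env, "PA")

    new.ei = apply_threshold(states.ei, comb_ei, params.t_ei, params.i_ei)
    new.pa = apply_threshold(states.pa, comb_pa, params.t_pa, params.i_pa)

    if ei_mult is not None or pa_mult is not None:
        floor = new.ree() if ei_floor is None else ei_floor
        if ei_mult is not None:
            new.ei = np.maximum(new.ei * ei_mult, np.minimum(new.ei, floor))
        if pa_mult is not None:
            new.pa = new.pa * pa_mult

    ee = new.ree() + 0.10 * new.ei + new.pa
    rho = params.rho(new.bw_initial)
    delta = params.lambda_discount * params.cycle_days * (new.ei - ee) / rho
    new.bw = np.maximum(new.bw + delta, params.bw_floor)
    return new


# ---------------------------------------------------------------------------
# simulation driver

def initialize_states(persons: Sequence[Person], params: ModelParams, rng) -> States:
    """Equilibrium initial state: EI = TEE, PA from the energy partition,
    weight at baseline, Env ~ Uniform(env_low, env_high) per agent."""
    profiles = [partition_energy(p) for p in persons]
    return States(
        ids=[p.id for p in persons],
        ei=np.array([pr.tee for pr in profiles]),
        pa=np.array([pr.pa for pr in profiles]),
        bw=np.array([p.bw0 for p in persons], dtype=float),
        bw_initial=np.array([p.bw0 for p in persons], dtype=float),
        env=rng.uniform(params.env_low, params.env_high, size=len(persons)),
        male=np.array([p.sex == "male" for p in persons]),
        age=np.array([p.age for p in persons], dtype=float),
        height_cm=np.array([p.height_m * 100.0 for p in persons]),
    )


def _metrics(states: States):
    b = states.bmi()
    return (
        float(states.bw.mean()),
        float(b.mean()),
        100.0 * float(((b >= BMI_OVERWEIGHT_CUTOFF) & (b < BMI_OBESE_CUTOFF)).mean()),
        100.0 * float((b >= BMI_OBESE_CUTOFF).mean()),
    )


def run_simulation(
    persons: Sequence[Person],
    network: SocialNetwork,
    params: ModelParams = ModelParams(),
    weeks: int = 104,
    intervention=None,
    seed: int = 0,
) -> Trajectory:
    """Run ``weeks`` synchronous cycles; deterministic given ``seed``.

    ``intervention``, when given, must expose
    ``weekly_multipliers(week, states, rng) -> (ei_mult, pa_mult)`` (either
    may be None); see :mod:`obesinet.interventions`.
    """
    if weeks < 0:
        raise ValueError("weeks must be >= 0")
    rng = np.random.default_rng(seed)
    states = initialize_states(persons, params, rng)
    adjacency = adjacency_matrix(network, states.ids)
    initial = states.copy()

    rows = [(0, *_metrics(states))]
    for week in range(1, weeks + 1):
        if params.redraw_env_weekly:
            states.env = rng.uniform(params.env_low, params.env_high, size=len(states))
        ei_mult = pa_mult = None
        if intervention is not None:
            ei_mult, pa_mult = intervention.weekly_multipliers(week, states, rng)
        states = step_week(states, adjacency, params, ei_mult=ei_mult, pa_mult=pa_mult)
        rows.append((week, *_metrics(states)))

    arr = np.array(rows)
    return Trajectory(
        week=arr[:, 0].astype(int),
        mean_bw=arr[:, 1],
        mean_bmi=arr[:, 2],
        overweight_rate=arr[:, 3],
        obesity_rate=arr[:, 4],
        initial=initial,
        final=states,
    )
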