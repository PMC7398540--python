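"""Weekly intervention targeting and effects.

Five strategies select 5% of the population each week: two conventional
(uniformly at random; among currently overweight/obese "high-risk"
agents) and three network-based (highest degree, betweenness or closeness
centrality on the static network). Targeted agents receive a 5% decrease
in energy intake or a 5% increase in activity energy that week.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np

from .network import SocialNetwork, centrality, top_fraction
from .population import BMI_OVERWEIGHT_CUTOFF
from .dynamics import States

__all__ = ["STRATEGIES", "InterventionSpec", "Intervention", "select_targets", "apply_intervention"]

logger = logging.getLogger(__name__)

STRATEGIES = ("random", "high-risk", "degree", "betweenness", "closeness")
_CENTRALITY_STRATEGIES = ("degree", "betweenness", "closeness")


@dataclasses.dataclass(frozen=True)
class InterventionSpec:
    """Strategy, coverage, effect sizes and scheduling of an intervention."""

    strategy: str = "random"
    coverage: float = 0.05
    ei_effect: float = 0.95  # multiplicative weekly effect on intake
    pa_effect: float = 1.05  # multiplicative weekly effect on activity
    mode: str = "either-random"  # {ei-only, pa-only, either-random, both}
    schedule: str = "weekly-resample"  # {weekly-fixed-set, weekly-resample}

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must be in [0, 1]")
        if self.ei_effect <= 0 or self.pa_effect <= 0:
            raise ValueError("effect factors must be > 0")
        if self.mode not in ("ei-only", "pa-only", "either-random", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.schedule not in ("weekly-fixed-set", "weekly-resample"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


def select_targets(
    spec: InterventionSpec,
    network: SocialNetwork,
    states: States,
    rng,
    centrality_scores: Optional[Dict] = None,
) -> Set:
    """Choose the target set for one week under the spec's strategy.

    Centrality strategies rank on the static network (scores may be passed
    in to avoid recomputation); high-risk draws uniformly from agents with
    current BMI >= 24 (all of them when the pool is smaller than the
    coverage).
    """
    n = len(states)
    k = int(round(spec.coverage * n))
    if k == 0:
        return set()
    if spec.strategy == "random":
        idx = rng.choice(n, size=k, replace=False)
        return {states.ids[i] for i in idx}
    if spec.strategy == "high-risk":
        pool = [states.ids[i] for i in np.flatnonzero(states.bmi() >= BMI_OVERWEIGHT_CUTOFF)]
        if not pool:
            logger.warning("high-risk strategy: no agent with BMI >= %.0f; empty target set",
                           BMI_OVERWEIGHT_CUTOFF)
            return set()
        if len(pool) <= k:
            return set(pool)
        idx = rng.choice(len(pool), size=k, replace=False)
        return {pool[i] for i in idx}
    if spec.strategy in _CENTRALITY_STRATEGIES:
        scores = centrality_scores if centrality_scores is not None else centrality(network, spec.strategy)
        return top_fraction(scores, spec.coverage, rng)
    raise ValueError(f"unknown strategy {spec.strategy!r}")


def apply_intervention(states: States, targets: Set, spec: InterventionSpec, rng,
                       ei_floor: Optional[np.ndarray] = None) -> States:
    """Apply the weekly effects to the targeted agents; others untouched.

    In ``either-random`` mode each target gets exactly one of the two
    effects, chosen uniformly each week. Intake is bounded below by
    ``ei_floor`` (default: current REE) so compounding never pushes intake
    to starvation levels.
    """
    ei_mult, pa_mult = weekly_effect_multipliers(states, targets, spec, rng)
    new = states.copy()
    if ei_mult is not None:
        floor = new.ree() if ei_floor is None else ei_floor
        new.ei = np.maximum(new.ei * ei_mult, np.minimum(new.ei, floor))
    if pa_mult is not None:
        new.pa = new.pa * pa_mult
    return new


def weekly_effect_multipliers(states: States, targets: Set, spec: InterventionSpec, rng):
    """Per-agent multiplicative (ei, pa) effect arrays for one week."""
    if not targets:
        return None, None
    n = len(states)
    mask = np.array([i in targets for i in states.ids])
    ei_mult = np.ones(n)
    pa_mult = np.ones(n)
    if spec.mode == "ei-only":
        ei_mult[mask] = spec.ei_effect
    elif spec.mode == "pa-only":
        pa_mult[mask] = spec.pa_effect
    elif spec.mode == "both":
        ei_mult[mask] = spec.ei_effect
        pa_mult[mask] = spec.pa_effect
    else:  # either-random: one channel per target per week
        pick_ei = rng.random(n) < 0.5
        ei_mult[mask & pick_ei] = spec.ei_effect
        pa_mult[mask & ~pick_ei] = spec.pa_effect
    return ei_mult, pa_mult


class Intervention:
    """Weekly targeting+effects engine plugged into ``run_simulation``.

    Caches centrality scores (the network is static, so centrality target
    sets are effectively fixed across weeks); re-evaluates random and
    high-risk target sets weekly unless ``schedule`` is weekly-fixed-set.
    """

    def __init__(self, spec: InterventionSpec, network: SocialNetwork):
        self.spec = spec
        self.network = network
        self._scores: Optional[Dict] = None
        self._fixed_targets: Optional[Set] = None
        self.target_log: list = []

    def weekly_multipliers(self, week: int, states: States, rng) -> Tuple:
        spec = self.spec
        if spec.strategy in _CENTRALITY_STRATEGIES and self._scores is None:
            self._scores = centrality(self.network, spec.strategy)
        if spec.schedule == "weekly-fixed-set" and self._fixed_targets is not None:
            targets = self._fixed_targets
        else:
            targets = select_targets(spec, self.network, states, rng, centrality_scores=self._scores)
            if spec.schedule == "weekly-fixed-set":
                self._fixed_targets = targets
        self.target_log.append((week, frozenset(targets)))
        return weekly_effect_multipliers(states, targets, spec, rng)
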