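"""Simulated players for the training game and the assessment task.

An agent is a small stochastic response policy: Go latencies are drawn from
a truncated normal, inhibition failures are Bernoulli, and (for learning
agents) per-game geometric decay shrinks the latency mean and the
commission probability toward configurable floors.  This is deliberately
not a cognitive model (no evidence accumulation); it exists to exercise the
engine and to produce training logs with realistic session trends —
reaction time falling and correct Go/Nogo counts rising across a course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import DEFAULT_GRACE_MS, GO, NOGO, Trial


@dataclass(frozen=True)
class AgentParams:
    """Speed, inhibition-failure and learning parameters of one agent.

    ``learning_rate_rt`` and ``learning_rate_inhib`` are per-game
    multiplicative decays (1.0 disables learning); floors are respected at
    all times.
    """

    rt_mean_ms: float = 430.0
    rt_sd_ms: float = 50.0
    p_commission: float = 0.70
    p_omission: float = 0.25
    learning_rate_rt: float = 0.9975
    learning_rate_inhib: float = 0.985
    learning_rate_omission: float = 0.98
    rt_floor_ms: float = 295.0
    p_commission_floor: float = 0.05
    p_omission_floor: float = 0.02
    rt_trunc_lo_ms: float = 100.0

    def __post_init__(self) -> None:
        for p in (self.p_commission, self.p_omission, self.p_commission_floor):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.rt_mean_ms, self.rt_sd_ms, self.rt_floor_ms) <= 0:
            raise ValueError("latency parameters must be positive")
        for r in (
            self.learning_rate_rt,
            self.learning_rate_inhib,
            self.learning_rate_omission,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("learning decays must lie in [0, 1]")


#: Named presets loadable from config files.  "learner" is calibrated so a
#: 140-game course shows falling session-mean RT and rising correct Go/Nogo
#: counts; "static" freezes learning; "fast-guesser" is fast and error-prone.
PRESETS: dict[str, AgentParams] = {
    "static": AgentParams(
        learning_rate_rt=1.0, learning_rate_inhib=1.0, learning_rate_omission=1.0
    ),
    "learner": AgentParams(),
    "fast-guesser": AgentParams(
        rt_mean_ms=260.0,
        rt_sd_ms=40.0,
        p_commission=0.90,
        p_omission=0.02,
        learning_rate_rt=1.0,
        learning_rate_inhib=1.0,
        learning_rate_omission=1.0,
    ),
}


class Agent:
    """Mutable play state of one simulated participant."""

    def __init__(self, params: AgentParams):
        self.params = params
        self.rt_mean_ms = params.rt_mean_ms
        self.p_commission = params.p_commission
        self.p_omission = params.p_omission

    @classmethod
    def preset(cls, name: str) -> "Agent":
        try:
            return cls(PRESETS[name])
        except KeyError:
            raise KeyError(
                f"unknown agent preset {name!r}; choose from {sorted(PRESETS)}"
            ) from None

    def _sample_rt(self, rng: np.random.Generator, hi_ms: float) -> float:
        lo = self.params.rt_trunc_lo_ms
        mu, sd = self.rt_mean_ms, self.params.rt_sd_ms
        a, b = (lo - mu) / sd, (hi_ms - mu) / sd
        return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))

    def respond(
        self, trial: Trial, rng: np.random.Generator
    ) -> tuple[bool, float | None]:
        """Response policy for one trial: ``(responded, rt_ms or None)``.

        On stop trials the sampled latency decides the regime: a latency
        before the healthy-to-unhealthy change is an ordinary Go tap; a
        later latency is emitted only on an inhibition failure
        (probability ``p_commission``).
        """
        hi = trial.rtd_ms + DEFAULT_GRACE_MS
        if trial.kind == GO:
            if rng.random() < self.p_omission:
                return False, None
            return True, self._sample_rt(rng, hi)
        if trial.kind == NOGO:
            if rng.random() < self.p_commission:
                return True, self._sample_rt(rng, hi)
            return False, None
        # stop trial
        rt = self._sample_rt(rng, hi)
        if rt < trial.change_latency_ms:
            if rng.random() < self.p_omission:
                return False, None
            return True, rt
        if rng.random() < self.p_commission:
            return True, rt
        return False, None

    def learn(self) -> None:
        """One game's worth of geometric improvement, respecting floors."""
        self.rt_mean_ms = max(
            self.params.rt_floor_ms, self.rt_mean_ms * self.params.learning_rate_rt
        )
        self.p_commission = max(
            self.params.p_commission_floor,
            self.p_commission * self.params.learning_rate_inhib,
        )
        self.p_omission = max(
            self.params.p_omission_floor,
            self.p_omission * self.params.learning_rate_omission,
        )
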