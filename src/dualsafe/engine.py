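"""Discrete-event layer: disturbances, intervention policies, daily stepping.

Seven cyclic events drive the model around the continuous stock dynamics:

  E1  draw the six daily disturbances
  E2  active (calendar) intervention: first day of every system month
  E3  intervention duration end (inputs return to zero after one day)
  E4  passive (threshold) intervention: fires on a month's first day only
      when the preceding month's safety-behavior value fell below 0.2
  E5  cap: clip stocks into [0, cap]
  E6  forgetting-curve decay of the stocks
  E7  complete forgetting: after >60 intervention-free days the decay rate
      reverts to its initial value

Within a day the order is: E1 sample -> E7 reset check -> E6 decay ->
E2/E4 increments if due -> E5 clamp -> compute the output equations.
Both policies fire a pre-entry intervention at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CoefficientSet,
    DisturbanceVector,
    ImplicitState,
    InterventionVector,
    explicit_factors,
    intervention_increments,
    negative_effect,
    positive_effect,
    safety_behavior,
)
from .memory import MemoryParams, MemoryPhase, clamp, forgetting_reset_check, phase_decay_rate

__all__ = [
    "Policy",
    "DailyOutputs",
    "sample_disturbances",
    "active_due",
    "passive_due",
    "step",
    "initial_state",
]


@dataclass(frozen=True)
class Policy:
    """Intervention policy: periodic ("active") or threshold ("passive").

    ``month_length`` is the system month in days; ``threshold`` is the
    passive trigger level on the preceding month's safety behavior;
    ``absorption`` G is the fraction of each intervention input workers
    actually take up; ``passive_statistic`` selects whether the preceding
    month is judged by its last day's SB or by its mean SB.
    """

    kind: str = "active"
    month_length: int = 30
    threshold: float = 0.2
    absorption: float = 0.5
    passive_statistic: str = "last_day"

    def __post_init__(self) -> None:
        if self.kind not in ("active", "passive"):
            raise ValueError(f"policy kind must be 'active' or 'passive', got {self.kind!r}")
        if self.month_length < 1:
            raise ValueError(f"month_length must be >= 1, got {self.month_length}")
        if not 0 < self.absorption <= 1:
            raise ValueError(f"absorption G must lie in (0, 1], got {self.absorption}")
        if self.passive_statistic not in ("last_day", "month_mean"):
            raise ValueError(
                "passive_statistic must be 'last_day' or 'month_mean', "
                f"got {self.passive_statistic!r}"
            )


@dataclass
class DailyOutputs:
    """Everything recorded for one simulated day."""

    t: int
    disturbances: DisturbanceVector
    USPH: float
    USPS: float
    PWE: float
    SBPV: float
    SBNV: float
    SB: float
    fired_events: set[str] = field(default_factory=set)


def sample_disturbances(rng: np.random.Generator) -> DisturbanceVector:
    """Event 1: PH ~ U(0, 0.5); PF, WP, LP, PW, WI ~ U(0, 1)."""
    u = rng.random(6)
    return DisturbanceVector(
        PH=0.5 * u[0], PF=u[1], WP=u[2], LP=u[3], PW=u[4], WI=u[5]
    )


def active_due(t: int, policy: Policy) -> bool:
    """Event 2 schedule: t = 0, then the first day of every later month.

    With the 30-day default month this is t in {0, 31, 61, 91, ...}: the
    pre-entry intervention at t=0 starts a 31-day first phase, after which
    interventions land on each month's first day.
    """
    if t < 0:
        raise ValueError(f"day index must be nonnegative, got {t}")
    m = policy.month_length
    return t == 0 or (t >= m + 1 and t % m == 1)


def passive_due(t: int, month_end_SB: float | None, policy: Policy) -> bool:
    """Event 4 trigger, evaluated on month-first days only.

    The pre-entry intervention at t=0 always fires; afterwards an
    intervention fires iff the preceding month's safety-behavior statistic
    fell strictly below the threshold.
    """
    if t == 0:
        return True
    if month_end_SB is None:
        raise ValueError("passive trigger needs the preceding month's SB statistic")
    return month_end_SB < policy.threshold


def initial_state() -> ImplicitState:
    """All-zero stocks, no interventions fired yet."""
    return ImplicitState(SCA=0.0, SCO=0.0, SM=0.0, phase=MemoryPhase())


def step(
    state: ImplicitState,
    t: int,
    policy: Policy,
    rng: np.random.Generator,
    params: MemoryParams,
    coeffs: CoefficientSet,
    month_statistic: float | None = None,
) -> DailyOutputs:
    """Advance the model by one day, mutating ``state`` in place.

    ``month_statistic`` is the preceding month's SB statistic, needed only
    by the passive policy on month-first days.
    """
    phase: MemoryPhase = state.phase
    events: set[str] = {"E1", "E6"}

    d = sample_disturbances(rng)

    # E7: complete forgetting clears the accumulated slowing, once per gap.
    if phase.H > 1 and forgetting_reset_check(phase, params):
        phase.H = 1
        phase.forgetting_reset = True
        events.add("E7")

    # E6: forgetting-curve decay at the current phase's rate.
    if phase.H >= 1:
        rate = phase_decay_rate(phase.H, params)
        decay = np.exp(-rate)
        state.SCA *= decay
        state.SCO *= decay
        state.SM *= decay

    # E2/E4: intervention increments (one-day duration, Event 3).
    m = policy.month_length
    on_boundary = t == 0 or (t >= m + 1 and t % m == 1)
    if policy.kind == "active":
        due = active_due(t, policy)
    else:
        due = on_boundary and passive_due(t, month_statistic, policy)
    if due:
        g = policy.absorption
        iv = InterventionVector(ST=g, SCL=g, SCU=g, IM=g)
        d_sca, d_sco, d_sm = intervention_increments(iv, coeffs)
        state.SCA += d_sca
        state.SCO += d_sco
        state.SM += d_sm
        phase.H += 1
        phase.forgetting_reset = False
        phase.days_since_intervention = 0
        events.add("E2" if policy.kind == "active" else "E4")
    else:
        phase.days_since_intervention += 1
        if phase.days_since_intervention == 1 and phase.H >= 1:
            events.add("E3")  # intervention inputs returned to zero today

    # E5: cap.
    capped = max(state.SCA, state.SCO, state.SM) > params.cap or min(
        state.SCA, state.SCO, state.SM
    ) < 0
    state.SCA = clamp(state.SCA, params.cap)
    state.SCO = clamp(state.SCO, params.cap)
    state.SM = clamp(state.SM, params.cap)
    if capped:
        events.add("E5")

    usph, usps, pwe = explicit_factors(d, coeffs)
    sbpv = positive_effect(state, coeffs)
    sbnv = negative_effect(usph, usps, pwe, coeffs)
    sb = safety_behavior(sbpv, sbnv)
    return DailyOutputs(
        t=t,
        disturbances=d,
        USPH=usph,
        USPS=usps,
        PWE=pwe,
        SBPV=sbpv,
        SBNV=sbnv,
        SB=sb,
        fired_events=events,
    )
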