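"""Forgetting-curve memory dynamics for the implicit-attitude stocks.

Implicit safety attitudes (capability, consciousness, motivation) behave like
memory traces: each managerial intervention tops them up, and between
interventions they erode along an Ebbinghaus retention curve

    R(t) = exp(-t / S),

where ``S`` is the memory stability in days.  Repeated interventions
strengthen the trace, so the per-day decay rate in the phase following the
H-th intervention is slowed geometrically,

    rate_H = (1/S) * Z**(H - 1),      0 < Z < 1,

and a long enough intervention-free gap ("complete forgetting", more than
``forget_after`` consecutive days) restores the initial, fastest rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MemoryParams",
    "MemoryPhase",
    "retention",
    "phase_decay_rate",
    "decay_step",
    "clamp",
    "forgetting_reset_check",
]


@dataclass(frozen=True)
class MemoryParams:
    """Parameters of the forgetting-curve decay law.

    Parameters
    ----------
    S : float
        Memory stability in days; larger S means slower forgetting.
    Z : float
        Per-intervention decay multiplier in (0, 1]; each additional
        intervention multiplies the decay rate by Z.  Z=1 disables the
        slowing entirely (a control condition: every phase then decays
        at the bare rate 1/S).
    cap : float
        Ceiling applied to every stock after an intervention boost.
    forget_after : int
        Complete forgetting fires after strictly more than this many
        consecutive intervention-free days.
    """

    S: float = 10.0
    Z: float = 0.9
    cap: float = 1.0
    forget_after: int = 60

    def __post_init__(self) -> None:
        if not self.S > 0:
            raise ValueError(f"memory stability S must be > 0, got {self.S}")
        if not 0 < self.Z <= 1:
            raise ValueError(f"decay multiplier Z must lie in (0, 1], got {self.Z}")
        if not self.cap > 0:
            raise ValueError(f"stock cap must be > 0, got {self.cap}")
        if not self.forget_after > 0:
            raise ValueError(f"forget_after must be > 0, got {self.forget_after}")


@dataclass
class MemoryPhase:
    """Bookkeeping of where the memory system is between interventions.

    ``H`` counts fired interventions (including the pre-entry one at t=0);
    ``days_since_intervention`` is 0 on an intervention day and increments
    daily otherwise; ``forgetting_reset`` records whether complete
    forgetting has cleared the H-effect during the current gap.
    """

    H: int = 0
    days_since_intervention: int = 0
    forgetting_reset: bool = False


def retention(t: float, S: float) -> float:
    """Retrievability R = exp(-t/S) after ``t`` intervention-free days.

    Strictly decreasing in ``t``, equal to 1 at t=0.
    """
    if t < 0:
        raise ValueError(f"elapsed time must be nonnegative, got {t}")
    if not S > 0:
        raise ValueError(f"memory stability S must be > 0, got {S}")
    return math.exp(-t / S)


def phase_decay_rate(H: int, params: MemoryParams) -> float:
    """Per-day decay rate (1/S) * Z**(H-1) in the phase after intervention H.

    The first phase (H=1) decays at the bare forgetting-curve rate 1/S;
    each later intervention slows decay by the factor Z.
    """
    if H < 1:
        raise ValueError(f"intervention count H must be >= 1, got {H}")
    return (1.0 / params.S) * params.Z ** (H - 1)


def decay_step(stock: float, rate: float) -> float:
    """One day of continuously-compounded decay: stock * exp(-rate).

    Thirty consecutive steps at rate 1/S equal one application of
    ``retention(30, S)`` up to floating-point round-off.
    """
    if stock < 0:
        raise ValueError(f"stock must be nonnegative, got {stock}")
    if rate < 0:
        raise ValueError(f"decay rate must be nonnegative, got {rate}")
    return stock * math.exp(-rate)


def clamp(stock: float, cap: float = 1.0) -> float:
    """Clip a stock into [0, cap] (cyclic cap event)."""
    return min(max(stock, 0.0), cap)


def forgetting_reset_check(phase: MemoryPhase, params: MemoryParams) -> bool:
    """True iff complete forgetting is due: strictly more than
    ``forget_after`` consecutive days without an intervention.

    When true, the engine resets the effective decay rate to its initial
    value 1/S (H-effect cleared); stock values themselves are untouched.
    """
    return phase.days_since_intervention > params.forget_after
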