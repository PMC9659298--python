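"""System-dynamics equations of the dual-attitude safety-behavior model.

Daily safety behavior is the balance of two channels:

    SB = SBPV - SBNV

where the positive value SBPV is driven by the slow implicit stocks
(safety capability SCA, safety consciousness SCO, safety motivation SM)
and the negative value SBNV by the fast explicit factors (unsafe
physiology USPH, unsafe psychology USPS, poor working environment PWE),
which are themselves linear mixes of six daily disturbances.  Intervention
inputs (safety training ST, safety climate SCL, safety culture SCU,
incentive mechanism IM) feed one-day increments into the stocks.  All path
coefficients come from a correlation-pooling meta-analysis, normalized so
that the parents of each dependent variable sum to 1 in absolute value;
the structural error terms are fixed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "PATH_IDS",
    "STRUCTURE",
    "CoefficientSet",
    "DisturbanceVector",
    "InterventionVector",
    "explicit_factors",
    "positive_effect",
    "negative_effect",
    "safety_behavior",
    "intervention_increments",
]

#: Dependent variable -> parent causal paths ("A->B" labels).
STRUCTURE: dict[str, tuple[str, ...]] = {
    "SCA": ("ST->SCA",),
    "SM": ("IM->SM",),
    "SCO": ("SCL->SCO", "SCU->SCO"),
    "USPH": ("PH->USPH", "PF->USPH"),
    "USPS": ("WP->USPS", "LP->USPS"),
    "WE": ("PW->WE", "WI->WE"),
    "SB": (
        "SCA->SB",
        "SCO->SB",
        "SM->SB",
        "USPH->SB",
        "USPS->SB",
        "WE->SB",
    ),
}

PATH_IDS: tuple[str, ...] = tuple(p for parents in STRUCTURE.values() for p in parents)

#: The three explicit->SB paths carry negative coefficients by convention.
_NEGATIVE_PATHS = frozenset({"USPH->SB", "USPS->SB", "WE->SB"})


@dataclass(frozen=True)
class CoefficientSet:
    """Normalized path coefficients of the system-dynamics equations.

    ``paths`` maps each causal-path label (e.g. ``"ST->SCA"``) to its
    signed coefficient; ``sigma`` is the common structural error term,
    fixed at zero.  Multi-parent dependent variables must have parent
    coefficients summing to 1 in absolute value, and the three explicit
    paths into SB must be negative.
    """

    paths: Mapping[str, float]
    sigma: float = 0.0

    def __post_init__(self) -> None:
        missing = [p for p in PATH_IDS if p not in self.paths]
        if missing:
            raise ValueError(f"coefficient set is missing paths: {missing}")
        if self.sigma != 0.0:
            raise ValueError("structural error terms sigma are fixed at 0")
        for p in _NEGATIVE_PATHS:
            if self.paths[p] >= 0:
                raise ValueError(f"coefficient of {p} must be negative, got {self.paths[p]}")
        for dep, parents in STRUCTURE.items():
            if len(parents) < 2:
                continue
            total = sum(abs(self.paths[p]) for p in parents)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"parent coefficients of {dep} must sum to 1 in absolute "
                    f"value, got {total!r}"
                )

    def __getitem__(self, path_id: str) -> float:
        return self.paths[path_id]


@dataclass(frozen=True)
class DisturbanceVector:
    """One day's disturbance draws: PH in [0, 0.5], the rest in [0, 1]."""

    PH: float
    PF: float
    WP: float
    LP: float
    PW: float
    WI: float


@dataclass(frozen=True)
class InterventionVector:
    """Intervention inputs for one day: 0 off-day, absorption G on-day."""

    ST: float = 0.0
    SCL: float = 0.0
    SCU: float = 0.0
    IM: float = 0.0


@dataclass
class ImplicitState:
    """The three implicit-attitude stocks plus memory-phase bookkeeping."""

    SCA: float = 0.0
    SCO: float = 0.0
    SM: float = 0.0
    # imported lazily to avoid a cycle in type checkers; plain attribute
    phase: object = field(default=None)


def explicit_factors(
    d: DisturbanceVector, c: CoefficientSet
) -> tuple[float, float, float]:
    """Explicit factors (USPH, USPS, PWE) as linear mixes of disturbances.

    USPH = c[PH->USPH]*PH + c[PF->USPH]*PF, and analogously for unsafe
    psychology (work/life pressure) and poor working environment
    (poor workplace / work intensity).
    """
    usph = c["PH->USPH"] * d.PH + c["PF->USPH"] * d.PF
    usps = c["WP->USPS"] * d.WP + c["LP->USPS"] * d.LP
    pwe = c["PW->WE"] * d.PW + c["WI->WE"] * d.WI
    return usph, usps, pwe


def positive_effect(s: ImplicitState, c: CoefficientSet) -> float:
    """SBPV: implicit-stock contribution to safety behavior."""
    return c["SCA->SB"] * s.SCA + c["SCO->SB"] * s.SCO + c["SM->SB"] * s.SM


def negative_effect(usph: float, usps: float, pwe: float, c: CoefficientSet) -> float:
    """SBNV: explicit-factor drag on safety behavior.

    The stored coefficients are negative; SBNV uses their magnitudes so
    that SB = SBPV - SBNV applies the negative contribution exactly once.
    """
    return (
        abs(c["USPH->SB"]) * usph
        + abs(c["USPS->SB"]) * usps
        + abs(c["WE->SB"]) * pwe
    )


def safety_behavior(sbpv: float, sbnv: float) -> float:
    """SB = SBPV - SBNV; may be negative early on, when stocks are low."""
    return sbpv - sbnv


def intervention_increments(
    iv: InterventionVector, c: CoefficientSet
) -> tuple[float, float, float]:
    """Stock increments (dSCA, dSCO, dSM) produced by one intervention day.

    dSCA = c[ST->SCA]*ST; dSCO = c[SCL->SCO]*SCL + c[SCU->SCU]*SCU;
    dSM = c[IM->SM]*IM.  All zero on non-intervention days.
    """
    d_sca = c["ST->SCA"] * iv.ST
    d_sco = c["SCL->SCO"] * iv.SCL + c["SCU->SCO"] * iv.SCU
    d_sm = c["IM->SM"] * iv.IM
    return d_sca, d_sco, d_sm
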