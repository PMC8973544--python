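"""Dermal daily-intake model and acceptable surface-contamination level.

Dermal contact with contaminated surfaces is treated as the dominant
exposure route for drug-handling health workers.  The worst-case uptake
model assumes the daily dermal intake (DDI) equals the drug load on a
skin-sized patch of surface:

    DDI (ng/day) = SA_Ex (cm²) × SC (ng/cm²) / AF_Bio

with SA_Ex the exposed skin area (default 200 cm², both palms) and
AF_Bio a bioavailability adjustment factor (default 1, i.e. 100 %
uptake).  Inverting at DDI = ADI gives the acceptable surface
contamination level:

    ASCL (ng/cm²) = ADI (ng/day) / SA_Ex (cm²)

Safe working conditions are assumed while DDI/ADI ≤ 1 (boundary
inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "DermalModel",
    "DdiResult",
    "Verdict",
    "compute_ddi",
    "compute_ascl",
    "assess_safe",
]


class Verdict(str, Enum):
    SAFE = "safe"
    EXCEEDS = "exceeds"
    NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class DermalModel:
    """Exposed skin area (cm²) and bioavailability factor (fraction)."""

    sa_ex: float = 200.0
    af_bio: float = 1.0

    def __post_init__(self) -> None:
        if not self.sa_ex > 0:
            raise ValueError("sa_ex must be > 0")
        if not 0 < self.af_bio <= 1:
            raise ValueError("af_bio must be in (0, 1]")
        if self.af_bio < 1:
            warnings.warn(
                "af_bio < 1 departs from the worst-case assumption of "
                "100 % dermal uptake",
                stacklevel=3,
            )


@dataclass(frozen=True)
class DdiResult:
    """A daily dermal intake, optionally assessed against an ADI."""

    ddi: float  # ng/day
    sc: float  # ng/cm²
    model: DermalModel
    adi_ref: float | None = None  # ng/day
    risk_ratio: float | None = None
    verdict: Verdict = Verdict.NOT_ASSESSED


def compute_ddi(
    sc: float,
    model: DermalModel | None = None,
    adi_ref: float | None = None,
) -> DdiResult:
    """Daily dermal intake (ng/day) from a surface contamination (ng/cm²).

    When ``adi_ref`` (ng/day) is given, the result also carries the
    DDI/ADI risk ratio and its safe/exceeds verdict.
    """
    if sc < 0:
        raise ValueError("surface contamination must be >= 0")
    model = model or DermalModel()
    ddi = model.sa_ex * sc / model.af_bio
    if adi_ref is None:
        return DdiResult(ddi=ddi, sc=sc, model=model)
    assessment = assess_safe(ddi, adi_ref)
    return DdiResult(
        ddi=ddi,
        sc=sc,
        model=model,
        adi_ref=adi_ref,
        risk_ratio=assessment["risk_ratio"],
        verdict=assessment["verdict"],
    )


def compute_ascl(adi: float, sa_ex: float = 200.0) -> float:
    """Acceptable surface contamination level (ng/cm²).

    ``adi`` is in ng/day.  Conventionally derived from the *reported*
    (policy-rounded) ADI — e.g. 4000 ng/day over 200 cm² gives the
    round 20 ng/cm² — though any positive intake may be passed.
    """
    if not adi > 0:
        raise ValueError("adi must be > 0")
    if not sa_ex > 0:
        raise ValueError("sa_ex must be > 0")
    return adi / sa_ex


def assess_safe(ddi: float, adi: float) -> dict:
    """DDI/ADI risk ratio and verdict; safe while the ratio is ≤ 1."""
    if not adi > 0:
        raise ValueError("adi must be > 0")
    if ddi < 0:
        raise ValueError("ddi must be >= 0")
    ratio = ddi / adi
    return {
        "risk_ratio": ratio,
        "verdict": Verdict.SAFE if ratio <= 1 else Verdict.EXCEEDS,
    }
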