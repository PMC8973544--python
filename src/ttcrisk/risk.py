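"""Duration- and risk-adjusted acceptable daily intakes for genotoxic drugs.

The model anchors on a lifetime acceptable daily intake (ADI) at a stated
excess lifetime cancer risk — by default the ICH M7 value of 1.5 μg/day at
a risk of 1:100,000 over a 70-year (25,550-day) lifetime.  Because linear
low-dose extrapolation makes risk proportional to the total lifetime
intake, the anchor is converted to a maximum lifetime intake (MLI)

    MLI (μg) = ADI_lifetime (μg/day) × lifetime_days

which can then be redistributed over an occupational exposure window of
t_Ex days and rescaled to another acceptable risk level:

    ADI     (μg/day) = MLI / t_Ex
    ADI_adj (μg/day) = MLI / t_Ex × ECR_adj / ECR_def

Exact values are always retained; reported values follow a fixed policy
of two significant figures rounded half-away-from-zero, the convention
used when such limits are published.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

__all__ = [
    "PodBasis",
    "PointOfDeparture",
    "ExposureScenario",
    "RiskPolicy",
    "AdiResult",
    "POD_PRESETS",
    "RISK_POLICY_PRESETS",
    "LIFETIME_DAYS",
    "STAGED_TTC_LESS_THAN_1_MONTH_UG_PER_DAY",
    "lifetime_exposure_days",
    "compute_mli",
    "compute_adi",
    "adjust_adi",
    "round_to_policy",
    "parse_risk_fraction",
]

#: Lifetime convention: 70 years × 365 days; leap days ignored.
LIFETIME_DAYS = 70 * 365  # 25,550

#: ICH M7 staged (less-than-lifetime) acceptable intake for exposures
#: shorter than one month.  Documented constant only: it is NOT derivable
#: from the MLI redistribution above and is never used in computations.
STAGED_TTC_LESS_THAN_1_MONTH_UG_PER_DAY = 120.0


class PodBasis(str, Enum):
    SINGLE_SUBSTANCE = "single_substance"
    MULTIPLE_SUBSTANCES = "multiple_substances"


@dataclass(frozen=True)
class PointOfDeparture:
    """Lifetime ADI anchor with its excess-risk fraction and duration.

    Parameters
    ----------
    adi_lifetime:
        Acceptable daily intake at lifetime exposure, μg/day.
    excess_risk:
        Excess lifetime cancer risk fraction the anchor corresponds to
        (the default excess cancer risk, ECR_def).
    lifetime_days:
        Exposure days in the lifetime convention.
    basis:
        Whether the anchor covers a single substance or simultaneous
        exposure to multiple substances.
    """

    adi_lifetime: float = 1.5
    excess_risk: float = 1e-5
    lifetime_days: float = LIFETIME_DAYS
    basis: PodBasis = PodBasis.SINGLE_SUBSTANCE

    def __post_init__(self) -> None:
        if not self.adi_lifetime > 0:
            raise ValueError("adi_lifetime must be > 0")
        if not 0 < self.excess_risk < 1:
            raise ValueError("excess_risk must be a fraction in (0, 1)")
        if not self.lifetime_days > 0:
            raise ValueError("lifetime_days must be > 0")


#: Named anchors: the ICH single-substance POD (default), the ICH
#: multiple-substances POD, and the original TTC value (0.15 μg/day at
#: a lifetime risk of 1:1,000,000).
POD_PRESETS = {
    "single": PointOfDeparture(),
    "multiple": PointOfDeparture(
        adi_lifetime=5.0, basis=PodBasis.MULTIPLE_SUBSTANCES
    ),
    "ttc": PointOfDeparture(adi_lifetime=0.15, excess_risk=1e-6),
}


@dataclass(frozen=True)
class ExposureScenario:
    """A working-life description: years worked × exposure days per year."""

    working_years: float = 40
    exposure_days_per_year: float = 240

    def __post_init__(self) -> None:
        if not self.working_years > 0:
            raise ValueError("working_years must be > 0")
        if not self.exposure_days_per_year > 0:
            raise ValueError("exposure_days_per_year must be > 0")

    @property
    def t_ex(self) -> float:
        return self.working_years * self.exposure_days_per_year


@dataclass(frozen=True)
class RiskPolicy:
    """An acceptable excess lifetime cancer-risk level (ECR_adj)."""

    ecr_adj: float = 1e-5
    label: str = "default"

    def __post_init__(self) -> None:
        if not 0 < self.ecr_adj < 1:
            raise ValueError("ecr_adj must be a fraction in (0, 1)")


#: German TRGS 910 tiers alongside the ICH default.
RISK_POLICY_PRESETS = {
    "default": RiskPolicy(1e-5, "default"),
    "trgs_acceptance": RiskPolicy(4e-5, "trgs_acceptance"),
    "trgs_tolerance": RiskPolicy(4e-3, "trgs_tolerance"),
}


@dataclass(frozen=True)
class AdiResult:
    """An acceptable daily intake with full precision and reported form."""

    exact_value: float  # μg/day, full precision
    reported_value: float  # μg/day, 2 significant figures
    mli: float  # μg
    t_ex: float  # days
    ecr: float | None = None  # fraction; None when no risk adjustment applied

    def as_dict(self) -> dict:
        return {
            "mli_ug": self.mli,
            "t_ex_days": self.t_ex,
            "ecr": self.ecr,
            "adi_exact": self.exact_value,
            "adi_reported": self.reported_value,
        }


def lifetime_exposure_days(scenario: ExposureScenario) -> float:
    """Total exposure days over the working life (exact product)."""
    return scenario.t_ex


def compute_mli(pod: PointOfDeparture) -> float:
    """Maximum lifetime intake (μg): lifetime ADI × lifetime days."""
    return pod.adi_lifetime * pod.lifetime_days


def compute_adi(mli: float, t_ex: float) -> AdiResult:
    """Redistribute an MLI over ``t_ex`` exposure days.

    The excess risk is unchanged: only the duration shrinks, so the
    daily allowance grows by the same factor.
    """
    if not t_ex > 0:
        raise ValueError("t_ex must be > 0")
    if not mli > 0:
        raise ValueError("mli must be > 0")
    exact = mli / t_ex
    return AdiResult(
        exact_value=exact,
        reported_value=round_to_policy(exact),
        mli=mli,
        t_ex=t_ex,
    )


def adjust_adi(
    mli: float,
    t_ex: float,
    policy: RiskPolicy,
    pod: PointOfDeparture,
) -> AdiResult:
    """Duration- and risk-adjusted ADI.

    Scales the duration-adjusted intake by the ratio of the policy's
    acceptable risk to the anchor's default risk.  With
    ``policy.ecr_adj == pod.excess_risk`` this reduces exactly to
    :func:`compute_adi` (the ratio is computed only when it differs
    from 1, keeping the two paths bit-identical).
    """
    base = compute_adi(mli, t_ex)
    if policy.ecr_adj == pod.excess_risk:
        exact = base.exact_value
    else:
        exact = base.exact_value * (policy.ecr_adj / pod.excess_risk)
    return AdiResult(
        exact_value=exact,
        reported_value=round_to_policy(exact),
        mli=mli,
        t_ex=t_ex,
        ecr=policy.ecr_adj,
    )


def round_to_policy(value: float) -> float:
    """Round to two significant figures, half-away-from-zero.

    The single reporting rule that reproduces the published limits
    (3.9921875 → 4.0, 15.96875 → 16, 1596.875 → 1600).
    """
    if not value > 0:
        raise ValueError("value must be > 0")
    exponent = math.floor(math.log10(value))
    quantum = Decimal(1).scaleb(exponent - 1)
    rounded = Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP)
    # a half-up carry can add a digit (99.5 → 100): re-quantize once
    if rounded.adjusted() > exponent:
        quantum = Decimal(1).scaleb(rounded.adjusted() - 1)
        rounded = rounded.quantize(quantum, rounding=ROUND_HALF_UP)
    return float(rounded)


_RATIO_RE = re.compile(r"^\s*(\d+)\s*:\s*([\d.,]+)\s*$")


def parse_risk_fraction(text: str) -> float:
    """Parse a risk stated as ``1:100000``, ``4:100.000`` or ``1e-5``.

    In ratio notation, ``.`` and ``,`` inside the denominator are read
    as thousands separators (European style), not decimal points.
    """
    m = _RATIO_RE.match(text)
    if m:
        num = float(m.group(1))
        den = float(m.group(2).replace(".", "").replace(",", ""))
        if den <= 0:
            raise ValueError(f"invalid risk ratio: {text!r}")
        value = num / den
    else:
        value = float(text)
    if not 0 < value < 1:
        raise ValueError(f"risk must be a fraction in (0, 1): {text!r}")
    return value
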