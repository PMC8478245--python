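"""Incremental cost-effectiveness: SD improvement per US$100 invested.

The ICER for an arm and outcome is the intention-to-treat effect size (in SD
units, versus control) divided by the per-child cost expressed in hundreds of
dollars. Costs are treated as fixed, so the ICER's standard error is the
impact SE under the same linear transformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import normal_quantile, round_half_up
from .ledger import CostBreakdown

OUTCOMES = ("cognition", "receptive_language", "socioemotional")


class CEAError(ValueError):
    """Invalid impact estimate or cost input."""


def ci_to_se(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric normal confidence interval."""
    if ci_high < ci_low:
        raise CEAError(f"inverted CI ({ci_low}, {ci_high})")
    if not 0.0 < level < 1.0:
        raise CEAError("confidence level must lie in (0, 1)")
    z = normal_quantile(0.5 + level / 2.0)
    return (ci_high - ci_low) / (2.0 * z)


@dataclass(frozen=True)
class ImpactEstimate:
    """ITT effect size in SD units with its 95% CI; SE derived from the CI."""

    outcome: str
    arm: str
    effect: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.effect <= self.ci_high:
            raise CEAError(
                f"{self.outcome}/{self.arm}: effect {self.effect} outside "
                f"CI ({self.ci_low}, {self.ci_high})"
            )

    @property
    def se(self) -> float:
        return ci_to_se(self.ci_low, self.ci_high)


@dataclass(frozen=True)
class ICERResult:
    outcome: str
    arm: str
    perspective: str
    sd_per_100usd: float
    se: float
    cost_per_child_used: float


def icer(
    impact: ImpactEstimate, breakdown: CostBreakdown, perspective: str = "societal"
) -> ICERResult:
    """Effect and SE per US$100 of per-child cost under the given perspective."""
    cost = breakdown.per_child(perspective)
    if cost <= 0:
        raise CEAError(f"per-child cost must be positive, got {cost}")
    hundreds = cost / 100.0
    return ICERResult(
        outcome=impact.outcome,
        arm=impact.arm,
        perspective=perspective,
        sd_per_100usd=impact.effect / hundreds,
        se=impact.se / hundreds,
        cost_per_child_used=cost,
    )


def icer_table(
    impacts: Iterable[ImpactEstimate],
    breakdowns: Mapping[str, CostBreakdown],
    perspectives: Sequence[str] = ("provider", "societal"),
    rounded: bool = False,
) -> pd.DataFrame:
    """ICERs for every impact x perspective, one row each.

    With ``rounded`` the point estimate is half-up rounded to 2 decimals and
    the SE to 3, the precision used in printed cost-effectiveness tables.
    """
    impacts = list(impacts)
    rows = []
    for persp in perspectives:
        for imp in impacts:
            res = icer(imp, breakdowns[imp.arm], persp)
            rows.append(
                {
                    "perspective": persp,
                    "outcome": res.outcome,
                    "arm": res.arm,
                    "sd_per_100usd": (
                        round_half_up(res.sd_per_100usd, 2)
                        if rounded
                        else res.sd_per_100usd
                    ),
                    "se": round_half_up(res.se, 3) if rounded else res.se,
                    "cost_per_child": res.cost_per_child_used,
                }
            )
    return pd.DataFrame(rows)
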