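"""Benefit-cost ratios and government return on investment, with Monte Carlo
uncertainty in the returns-to-cognition parameters.

Benefits are the per-child gain in survival-adjusted discounted lifetime
earnings; costs add the PDV of future schooling attendance to the
present-period per-child cost. The government's ROI counts only the tax share
of the earnings gain: roi = (tax * gains - cost) / cost = tax * bcr - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ledger import CostBreakdown
from .lifecycle import (
    EconAssumptions,
    LifeTable,
    ReturnsModel,
    WageProfile,
    pdv_lifetime_earnings,
    schooling_cost,
    schooling_impact,
    wage_impact,
)


class BCAError(ValueError):
    """Invalid benefit-cost input."""


def lifetime_gains(pdv: float, wage_impact: float) -> float:
    """Per-child earnings gain: PDV of lifetime earnings times the
    proportional wage impact."""
    if pdv < 0:
        raise BCAError("PDV must be non-negative")
    return pdv * wage_impact


def benefit_cost_ratio(gains: float, total_longterm_cost: float) -> float:
    """Monetised lifetime benefits per dollar of total long-term cost."""
    if total_longterm_cost <= 0:
        raise BCAError("total long-term cost must be positive")
    return gains / total_longterm_cost


def return_on_investment(
    gains: float, total_longterm_cost: float, tax_rate: float
) -> float:
    """Government net return: (tax revenue from gains - cost) / cost."""
    if not 0.0 <= tax_rate <= 1.0:
        raise BCAError("tax rate must lie in [0, 1]")
    return (tax_rate * gains - total_longterm_cost) / total_longterm_cost


@dataclass(frozen=True)
class BCAResult:
    """Point estimates and simulation SEs for one arm, with the assumption
    set that produced them."""

    arm: str
    pdv_earnings: float
    wage_impact: float
    gains_per_child: float
    present_cost_per_child: float
    future_schooling_cost: float
    total_longterm_cost: float
    bcr: float
    roi: float
    bcr_se: float
    roi_se: float
    n_draws: int
    seed: int | None
    assumptions: EconAssumptions = field(repr=False, default=EconAssumptions())


def monte_carlo_uncertainty(
    pdv: float,
    effect: float,
    present_cost_per_child: float,
    returns: ReturnsModel,
    assumptions: EconAssumptions,
    n_draws: int = 1000,
    seed: int | None = None,
    return_draws: bool = False,
):
    """Simulation SEs for BCR and ROI.

    Draws the wage return and the schooling return independently from normal
    distributions centred on their point estimates with their estimated SEs
    (ITT impacts and present-period costs held fixed), recomputes BCR and ROI
    per draw, and returns the sample standard deviations. Negative draws are
    kept: a negative wage-return draw yields negative gains by design.
    """
    if n_draws < 2:
        raise BCAError("need at least two Monte Carlo draws")
    rng = np.random.default_rng(seed)
    rho_w = rng.normal(returns.wage_return_per_sd, returns.wage_return_se, n_draws)
    rho_s = rng.normal(
        returns.schooling_return_per_sd, returns.schooling_return_se, n_draws
    )
    gains = pdv * effect * rho_w
    school_unit = schooling_cost(1.0, assumptions)  # cost per extra year
    costs = present_cost_per_child + effect * rho_s * school_unit
    bcr = gains / costs
    roi = assumptions.tax_rate * bcr - 1.0
    bcr_se = float(np.std(bcr, ddof=1))
    roi_se = float(np.std(roi, ddof=1))
    if return_draws:
        return bcr_se, roi_se, bcr, roi
    return bcr_se, roi_se


def evaluate_arm(
    breakdown: CostBreakdown,
    cognition_effect: float,
    profile: WageProfile,
    lifetable: LifeTable,
    returns: ReturnsModel,
    assumptions: EconAssumptions,
    n_draws: int = 1000,
    seed: int | None = 1,
) -> BCAResult:
    """Full benefit-cost chain for one arm from its cost breakdown and
    cognition impact."""
    pdv = pdv_lifetime_earnings(
        profile, lifetable, assumptions.discount_rate, assumptions.anchor_age
    )
    wi = wage_impact(cognition_effect, returns)
    gains = lifetime_gains(pdv, wi)
    school = schooling_cost(schooling_impact(cognition_effect, returns), assumptions)
    present = breakdown.per_child_total
    total_lt = present + school
    bcr = benefit_cost_ratio(gains, total_lt)
    roi = return_on_investment(gains, total_lt, assumptions.tax_rate)
    bcr_se, roi_se = monte_carlo_uncertainty(
        pdv, cognition_effect, present, returns, assumptions, n_draws, seed
    )
    return BCAResult(
        arm=breakdown.arm,
        pdv_earnings=pdv,
        wage_impact=wi,
        gains_per_child=gains,
        present_cost_per_child=present,
        future_schooling_cost=school,
        total_longterm_cost=total_lt,
        bcr=bcr,
        roi=roi,
        bcr_se=bcr_se,
        roi_se=roi_se,
        n_draws=n_draws,
        seed=seed,
        assumptions=assumptions,
    )
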