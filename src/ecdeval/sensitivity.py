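"""One-way threshold ("extreme value") sensitivity analysis.

For each input parameter in turn, holding every other parameter at its
benchmark value, find the value at which the evaluation flips from
favourable to unfavourable: BCR = 1 or ROI = 0. Thresholds are located with
a bracketing root-finder after verifying the criterion is monotone over the
search bounds; parameters the criterion does not respond to (e.g. the tax
rate, which cancels out of the BCR) yield an explicit no-threshold marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bca import benefit_cost_ratio, lifetime_gains, return_on_investment
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

PARAMETERS = (
    "discount_rate",
    "provider_cost_per_child",
    "tax_rate",
    "wage_return",
    "schooling_cost_share",
    "cognition_effect",
)
CRITERIA = ("bcr_below_1", "roi_below_0")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "discount_rate": (0.0, 1.0),
    "provider_cost_per_child": (1e-6, 10_000.0),
    "tax_rate": (0.0, 1.0),
    "wage_return": (0.0, 1.0),
    "schooling_cost_share": (0.0, 50.0),
    "cognition_effect": (0.0, 1.0),
}

NO_THRESHOLD = "-"


class SensitivityError(ValueError):
    """Invalid threshold query or model input."""


@dataclass(frozen=True)
class ThresholdQuery:
    parameter: str
    criterion: str
    arm: str
    search_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise SensitivityError(f"unknown parameter {self.parameter!r}")
        if self.criterion not in CRITERIA:
            raise SensitivityError(f"unknown criterion {self.criterion!r}")
        if self.search_bounds is not None:
            lo, hi = self.search_bounds
            if not lo < hi:
                raise SensitivityError("search bounds require lo < hi")

    @property
    def bounds(self) -> tuple[float, float]:
        return self.search_bounds or DEFAULT_BOUNDS[self.parameter]


@dataclass(frozen=True)
class ThresholdResult:
    query: ThresholdQuery
    threshold_value: float | None
    criterion_value_at_threshold: float | None
    bracket_evaluations: int
    converged: bool
    note: str = ""


@dataclass(frozen=True)
class BenchmarkInputs:
    """Everything the one-way analysis perturbs: per-arm cost breakdowns and
    cognition effects, the wage profile and life table, returns estimates and
    economic assumptions."""

    breakdowns: Mapping[str, CostBreakdown]
    cognition_effects: Mapping[str, float]
    profile: WageProfile
    lifetable: LifeTable
    returns: ReturnsModel
    assumptions: EconAssumptions
    # scale future schooling costs with the cognition effect when it is the
    # varied parameter (fade-out rescales both pathways); switchable because
    # the threshold is insensitive to the choice at printed precision
    fadeout_rescales_schooling: bool = True


def evaluate_criterion(
    value: float, query: ThresholdQuery, inputs: BenchmarkInputs
) -> float:
    """BCR - 1 or ROI with one parameter overridden at ``value``.

    Rebuilds the full lifecycle -> benefit-cost chain, so overrides of the
    discount rate propagate to both the earnings PDV and the schooling-cost
    discounting.
    """
    a = inputs.assumptions
    breakdown = inputs.breakdowns[query.arm]
    effect = inputs.cognition_effects[query.arm]
    returns = inputs.returns
    present = breakdown.per_child_total
    p = query.parameter

    if p == "discount_rate":
        if value < 0:
            raise SensitivityError("discount rate must be non-negative")
        a = a.with_(discount_rate=value)
    elif p == "tax_rate":
        if not 0.0 <= value <= 1.0:
            raise SensitivityError("tax rate must lie in [0, 1]")
        a = a.with_(tax_rate=value)
    elif p == "schooling_cost_share":
        if value < 0:
            raise SensitivityError("schooling cost share must be non-negative")
        a = a.with_(schooling_cost_share=value)
    elif p == "wage_return":
        returns = ReturnsModel(
            wage_return_per_sd=value,
            wage_return_se=returns.wage_return_se,
            schooling_return_per_sd=returns.schooling_return_per_sd,
            schooling_return_se=returns.schooling_return_se,
        )
    elif p == "cognition_effect":
        effect = value
    elif p == "provider_cost_per_child":
        if value <= 0:
            raise SensitivityError("provider cost per child must be positive")
        present = value + breakdown.per_child_societal

    pdv = pdv_lifetime_earnings(
        inputs.profile, inputs.lifetable, a.discount_rate, a.anchor_age
    )
    gains = lifetime_gains(pdv, wage_impact(effect, returns))
    school_effect = effect
    if p == "cognition_effect" and not inputs.fadeout_rescales_schooling:
        school_effect = inputs.cognition_effects[query.arm]
    school = schooling_cost(schooling_impact(school_effect, returns), a)
    total = present + school
    if query.criterion == "bcr_below_1":
        return benefit_cost_ratio(gains, total) - 1.0
    return return_on_investment(gains, total, a.tax_rate)


def solve_threshold(
    query: ThresholdQuery,
    inputs: BenchmarkInputs,
    tolerance: float = 1e-6,
    scan_points: int = 33,
) -> ThresholdResult:
    """Locate the break-even value of one parameter by bracketed root finding.

    The criterion is first scanned over the bounds to verify monotonicity;
    non-monotone responses are reported rather than silently bisected, and a
    criterion that never changes sign yields a no-threshold result.
    """
    lo, hi = query.bounds
    grid = np.linspace(lo, hi, scan_points)
    values = np.array([evaluate_criterion(g, query, inputs) for g in grid])
    evals = scan_points
    diffs = np.diff(values)
    if np.any(diffs > tolerance) and np.any(diffs < -tolerance):
        return ThresholdResult(
            query, None, None, evals, False, note="criterion not monotone over bounds"
        )
    f_lo, f_hi = values[0], values[-1]
    if f_lo == 0.0:
        return ThresholdResult(query, lo, 0.0, evals, True)
    if f_hi == 0.0:
        return ThresholdResult(query, hi, 0.0, evals, True)
    if np.sign(f_lo) == np.sign(f_hi):
        return ThresholdResult(
            query, None, None, evals, False, note="no threshold in range"
        )

    count = [0]

    def f(x: float) -> float:
        count[0] += 1
        return evaluate_criterion(x, query, inputs)

    root = float(brentq(f, lo, hi, xtol=tolerance))
    return ThresholdResult(
        query,
        root,
        evaluate_criterion(root, query, inputs),
        evals + count[0] + 1,
        True,
    )


def default_queries(arm: str) -> list[ThresholdQuery]:
    """The full one-way grid for one arm: six parameters x two criteria."""
    return [
        ThresholdQuery(parameter=p, criterion=c, arm=arm)
        for p in PARAMETERS
        for c in CRITERIA
    ]


def one_way_table(
    queries: Sequence[ThresholdQuery] | None,
    inputs: BenchmarkInputs,
    arms: Sequence[str] = ("group_only", "mixed"),
) -> pd.DataFrame:
    """Threshold table over a query grid (default: all parameters and
    criteria for each arm), one row per parameter with a column per
    arm x criterion; unreachable cells carry the no-threshold marker."""
    if queries is None:
        queries = [q for arm in arms for q in default_queries(arm)]
    rows: dict[str, dict[str, object]] = {}
    for q in queries:
        res = solve_threshold(q, inputs)
        col = f"{q.arm}:{q.criterion}"
        cell = res.threshold_value if res.converged else NO_THRESHOLD
        rows.setdefault(q.parameter, {"parameter": q.parameter})[col] = cell
    return pd.DataFrame(list(rows.values()))
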