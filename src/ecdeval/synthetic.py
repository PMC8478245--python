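"""Synthetic inputs with the statistical structure the evaluation assumes.

The published analysis draws on household-survey wage microdata (ages 16-64,
at-least-halftime workers), a national life table, and a longitudinal panel
linking adult schooling and wages to age-standardised cognition. None of
those microdata are redistributable, so this module generates stand-ins:

* a Mincer-style concave age-earnings profile (optionally worker-level
  microdata around it), with a calibration mode that rescales the level so
  the survival-adjusted PDV at the benchmark discount rate equals the
  published US$13,219 per child;
* a piecewise-constant-hazard survival curve shaped like a high-mortality-
  decline setting;
* a returns panel in which one SD of cognition truly causes 1.79 extra years
  of schooling and a 39.7% wage gain, with correlated covariates so the
  adjusted regressions are genuinely exercised;
* the packaged cost-ledger and ITT-impact fixtures.

Every generator is a pure function of its config (all randomness flows
through ``config.seed``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cea import ImpactEstimate
from .ledger import CostLine, read_ledger
from .lifecycle import LifeTable, WageProfile, pdv_lifetime_earnings

#: Published per-child PDV of survival-adjusted discounted lifetime earnings
#: (2020 USD, 5% discount rate) that the calibration mode targets.
TARGET_PDV = 13_219.0


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    # wage profile
    n_workers_per_age: int = 200
    wage_level: float = 1_000.0  # annual USD at the start of working life
    wage_growth: float = 0.08  # Mincer experience slope (log points/year)
    wage_curvature: float = 0.00138  # quadratic experience term
    wage_dispersion_sd: float = 0.6  # worker-level log-wage spread
    work_start_age: int = 16
    work_end_age: int = 64
    calibrate_pdv: float | None = TARGET_PDV
    # survival curve (piecewise-constant hazards by age band)
    infant_mortality: float = 0.035
    child_hazard: float = 0.003
    adult_hazard: float = 0.004
    old_hazard: float = 0.015
    oldest_hazard_growth: float = 1.09  # annual multiplier beyond age 65
    max_age: int = 100
    anchor_age: int = 2
    discount_rate: float = 0.05
    # returns panel
    panel_n: int = 5_000
    true_wage_return: float = 0.397
    true_schooling_return: float = 1.79
    wage_noise_sd: float = 0.65
    schooling_noise_sd: float = 2.0
    parent_ed_cognition_slope: float = 1.0  # confounding: parental education
    parent_ed_wage_effect: float = 0.04
    parent_ed_schooling_effect: float = 0.15
    female_wage_effect: float = -0.25
    female_schooling_effect: float = -0.3

    def __post_init__(self) -> None:
        if min(self.n_workers_per_age, self.panel_n) <= 0:
            raise ValueError("counts must be positive")
        if min(self.wage_noise_sd, self.schooling_noise_sd, self.wage_dispersion_sd) < 0:
            raise ValueError("noise SDs must be non-negative")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def gen_lifetable(config: SyntheticConfig = SyntheticConfig()) -> LifeTable:
    """Survival curve from piecewise-constant hazards, conditional on the
    anchor age (S(anchor) = 1)."""
    ages = np.arange(0, config.max_age + 1)
    qx = np.empty_like(ages, dtype=float)
    qx[0] = config.infant_mortality
    qx[(ages >= 1) & (ages <= 4)] = config.child_hazard
    qx[(ages >= 5) & (ages <= 14)] = config.child_hazard / 3.0
    qx[(ages >= 15) & (ages <= 49)] = config.adult_hazard
    qx[(ages >= 50) & (ages <= 64)] = config.old_hazard
    old = ages >= 65
    qx[old] = np.minimum(
        1.0, config.old_hazard * config.oldest_hazard_growth ** (ages[old] - 64)
    )
    return LifeTable.from_qx(ages, qx, anchor_age=config.anchor_age)


def _mean_wage_curve(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    ages = np.arange(config.work_start_age, config.work_end_age + 1)
    exp = ages - config.work_start_age
    log_w = (
        np.log(config.wage_level)
        + config.wage_growth * exp
        - config.wage_curvature * exp**2
    )
    return ages, np.exp(log_w)


def gen_wage_profile(
    config: SyntheticConfig = SyntheticConfig(),
    lifetable: LifeTable | None = None,
    return_microdata: bool = False,
):
    """Concave age-earnings profile over the working window.

    The profile is the age-wise mean over simulated lognormal worker wages
    around a Mincer curve (deterministic in the seed). With
    ``config.calibrate_pdv`` set, the level is rescaled so the
    survival-adjusted PDV at the config's discount rate and anchor age equals
    that target; the calibration leaves the profile's shape untouched.
    """
    ages = np.arange(config.work_start_age, config.work_end_age + 1)
    if config.wage_level == 0:
        micro = np.zeros((config.n_workers_per_age, ages.size))
    else:
        _, curve = _mean_wage_curve(config)
        rng = np.random.default_rng(config.seed)
        noise = rng.normal(
            0.0, config.wage_dispersion_sd, (config.n_workers_per_age, ages.size)
        )
        micro = curve[None, :] * np.exp(noise - config.wage_dispersion_sd**2 / 2.0)
    means = micro.mean(axis=0)
    profile = WageProfile(ages, means)
    if config.calibrate_pdv is not None and config.wage_level != 0:
        lt = lifetable if lifetable is not None else gen_lifetable(config)
        pdv = pdv_lifetime_earnings(
            profile, lt, config.discount_rate, config.anchor_age
        )
        profile = profile.scaled(config.calibrate_pdv / pdv)
        if return_microdata:
            micro = micro * (config.calibrate_pdv / pdv)
    if return_microdata:
        frame = pd.DataFrame(
            {
                "age": np.repeat(ages, config.n_workers_per_age),
                "annual_wage_usd": micro.T.ravel(),
            }
        )
        return profile, frame
    return profile


def gen_returns_panel(config: SyntheticConfig = SyntheticConfig()) -> pd.DataFrame:
    """Panel of adult outcomes with known returns to cognition.

    Cognition is standard normal; parental education is correlated with it
    (so the unadjusted regressions are biased and covariate adjustment
    matters); sex, survey wave, interview month, and baseline grade enter
    both outcome equations as in the adjusted specification.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.panel_n
    cog = rng.normal(0.0, 1.0, n)
    parent_ed = 8.0 + config.parent_ed_cognition_slope * cog + rng.normal(0, 2.5, n)
    female = rng.integers(0, 2, n).astype(float)
    wave = rng.integers(1, 5, n)
    month = rng.integers(1, 13, n)
    grade = rng.integers(1, 9, n)
    wave_eff = 0.05 * wave
    grade_eff = 0.25 * grade
    month_eff = 0.01 * month
    schooling = (
        6.0
        + config.true_schooling_return * cog
        + config.parent_ed_schooling_effect * parent_ed
        + config.female_schooling_effect * female
        + wave_eff
        + grade_eff
        + month_eff
        + rng.normal(0.0, config.schooling_noise_sd, n)
    )
    log_wage = (
        5.5
        + config.true_wage_return * cog
        + config.parent_ed_wage_effect * parent_ed
        + config.female_wage_effect * female
        + 0.8 * wave_eff
        + 0.4 * grade_eff
        + month_eff
        + rng.normal(0.0, config.wage_noise_sd, n)
    )
    return pd.DataFrame(
        {
            "cognition_sd": cog,
            "years_schooling": schooling,
            "log_wage": log_wage,
            "parental_education": parent_ed,
            "female": female,
            "wave": wave,
            "interview_month": month,
            "baseline_grade": grade,
        }
    )


def _data_path(name: str) -> Path:
    return Path(resources.files("ecdeval.data") / name)


def gen_cost_ledger(arm: str | None = None) -> list[CostLine]:
    """Packaged cost-ledger fixture (both arms; optionally filtered).

    Line amounts carry the published arm-level accounts directly; see the
    methods note for the one-dollar reconciliation on the group-arm travel
    line.
    """
    lines = read_ledger(_data_path("cost_ledger.csv"))
    if arm is not None:
        lines = [ln for ln in lines if ln.arm in (arm, "both")]
    return lines


def gen_impacts() -> list[ImpactEstimate]:
    """Packaged ITT impact fixture: all six outcome x arm effect sizes."""
    with open(_data_path("impacts.yaml")) as fh:
        records = yaml.safe_load(fh)
    return [ImpactEstimate(**rec) for rec in records]


def write_fixtures(outdir: str | Path, config: SyntheticConfig = SyntheticConfig()) -> dict[str, Path]:
    """Write every synthetic input (ledger CSV, impacts YAML, wage-profile and
    life-table CSVs, returns-panel CSV) into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ledger_path = outdir / "cost_ledger.csv"
    ledger_path.write_text(_data_path("cost_ledger.csv").read_text())
    paths["ledger"] = ledger_path

    impacts_path = outdir / "impacts.yaml"
    impacts_path.write_text(_data_path("impacts.yaml").read_text())
    paths["impacts"] = impacts_path

    lt = gen_lifetable(config)
    lt_path = outdir / "lifetable.csv"
    pd.DataFrame({"age": lt.ages, "survival": lt.survival}).to_csv(
        lt_path, index=False
    )
    paths["lifetable"] = lt_path

    profile = gen_wage_profile(config, lifetable=lt)
    prof_path = outdir / "wage_profile.csv"
    pd.DataFrame(
        {"age": profile.ages, "mean_annual_wage_usd": profile.mean_wage}
    ).to_csv(prof_path, index=False)
    paths["profile"] = prof_path

    panel_path = outdir / "returns_panel.csv"
    gen_returns_panel(config).to_csv(panel_path, index=False)
    paths["panel"] = panel_path
    return paths
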