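"""Lifetime productivity losses from newborn iodine deficiency.

The chain runs: newborns with clinical IDDs -> labor-force participation
-> annual earnings (GNI per capita x wage share) -> a lifelong
productivity deficit fraction -> discounted over the working years to a
net present value at the reference year.

The deficit fraction rests on three published coefficients: an 8.18%
IQ improvement attributable to iodized-salt exposure, a 1.18% earnings
deficit per lost IQ point, and a 0.64 correlation between early
cognitive scores and workforce-age IQ.  Their literal product is
6.177%; the published chain carries 6.12%, which is kept as the default
so results line up with the published accounting.  Use
:func:`derive_deficit_fraction` for sensitivity analysis with the
literal product.

Discounting is discrete and annual at rate r (default 3%), with a
cohort born in the reference year (2019) entering work ``delay`` = 11
years later (2030).  Losses accrue at the end of each working year by
default, so the annuity factor is sum over t = delay .. delay+W-1 of
(1+r)**-t with a fractional final year prorated; a payments-at-start
variant shifts every term one year earlier.
"""

from __future__ import annotations

import dataclasses
import math

from pydantic import BaseModel, Field


class EconParams(BaseModel):
    """Economic constants of the productivity-loss chain."""

    discount_rate: float = Field(default=0.03, ge=0, lt=1)
    iq_gain_percent: float = Field(default=8.18, ge=0)
    earnings_per_iq_point_percent: float = Field(default=1.18, ge=0)
    cognition_iq_correlation: float = Field(default=0.64, ge=0, le=1)
    productivity_deficit_fraction: float = Field(default=0.0612, ge=0, le=1)
    work_start_age_years: int = Field(default=15, ge=0)
    workforce_entry_delay_years: int = Field(default=11, ge=0)
    reference_year: int = 2019
    payments_at_start: bool = False

    def deficit(self, derived: bool = False) -> float:
        """Deficit fraction: the configured default, or the literal product."""
        if derived:
            return derive_deficit_fraction(
                self.iq_gain_percent,
                self.earnings_per_iq_point_percent,
                self.cognition_iq_correlation,
            )
        return self.productivity_deficit_fraction


@dataclasses.dataclass(frozen=True)
class NPVLoss:
    """Discounted lifetime productivity loss for one scope (thousands USD)."""

    scope: str
    newborns_with_idd_thousands: float
    labor_participation_fraction: float
    annual_income_usd: float
    work_life_years: float
    annuity_factor: float
    deficit_fraction: float
    npv_loss_usd_thousands: float


def derive_deficit_fraction(
    iq_gain_percent: float,
    earnings_per_iq_point_percent: float,
    cognition_iq_correlation: float,
) -> float:
    """Productivity deficit as the product of the three coefficients.

    (8.18, 1.18, 0.64) -> 0.0618 (to three significant figures); the
    published chain rounds this to 0.0612.
    """
    if min(iq_gain_percent, earnings_per_iq_point_percent, cognition_iq_correlation) < 0:
        raise ValueError("all deficit-chain inputs must be nonnegative")
    # IQ-points lost x percent earnings per point x correlation gives a
    # percent of earnings; divide once to return a fraction.
    return (
        iq_gain_percent * earnings_per_iq_point_percent * cognition_iq_correlation
    ) / 100.0


def annual_earnings(gni_per_capita_usd: float, wage_share_fraction: float) -> float:
    """Annual labor earnings: GNI per capita times the wage share."""
    if gni_per_capita_usd < 0 or wage_share_fraction < 0:
        raise ValueError("earnings inputs must be nonnegative")
    return gni_per_capita_usd * wage_share_fraction


def work_life_years(hale_years: float, work_start_age_years: float = 15.0) -> float:
    """Working years: healthy life expectancy minus the work-start age."""
    if hale_years <= work_start_age_years:
        raise ValueError(
            f"healthy life expectancy ({hale_years}) must exceed the "
            f"work-start age ({work_start_age_years})"
        )
    return hale_years - work_start_age_years


def annuity_factor(
    discount_rate: float,
    delay_years: float,
    work_life_years: float,
    payments_at_start: bool = False,
) -> float:
    """Sum of per-year discount factors over the working years.

    With end-of-year accrual the t-th working year (t counted from the
    reference year, starting at ``delay_years``) contributes
    (1+r)**-t; a fractional final working year contributes its fraction
    of the next term.  At r = 0 this is exactly the work-life length.
    """
    if discount_rate < 0 or delay_years < 0 or work_life_years < 0:
        raise ValueError("annuity inputs must be nonnegative")
    r = discount_rate
    offset = delay_years - 1 if payments_at_start else delay_years
    whole = math.floor(work_life_years)
    frac = work_life_years - whole
    total = sum((1.0 + r) ** -(offset + t) for t in range(whole))
    if frac > 0:
        total += frac * (1.0 + r) ** -(offset + whole)
    return total


def npv_loss(
    newborns_thousands: float,
    participation_fraction: float,
    income_usd_per_year: float,
    deficit_fraction: float,
    annuity: float,
    scope: str = "",
    work_life: float = float("nan"),
) -> NPVLoss:
    """Discounted lifetime loss, linear in every factor.

    loss ('000 USD) = newborns ('000) x participation x annual income
    (USD) x deficit fraction x annuity factor.
    """
    factors = (newborns_thousands, participation_fraction, income_usd_per_year,
               deficit_fraction, annuity)
    if any(f < 0 for f in factors):
        raise ValueError("all npv_loss factors must be nonnegative")
    loss = math.prod(factors)
    return NPVLoss(
        scope=scope,
        newborns_with_idd_thousands=newborns_thousands,
        labor_participation_fraction=participation_fraction,
        annual_income_usd=income_usd_per_year,
        work_life_years=work_life,
        annuity_factor=annuity,
        deficit_fraction=deficit_fraction,
        npv_loss_usd_thousands=loss,
    )


def cohort_npv_loss(
    newborns_thousands: float,
    gni_per_capita_usd: float,
    wage_share_fraction: float,
    labor_participation_fraction: float,
    hale_years: float,
    params: EconParams,
    scope: str = "",
    derived_deficit: bool = False,
) -> NPVLoss:
    """Full chain from covariates to NPV loss for one birth cohort."""
    income = annual_earnings(gni_per_capita_usd, wage_share_fraction)
    wl = work_life_years(hale_years, params.work_start_age_years)
    ann = annuity_factor(
        params.discount_rate,
        params.workforce_entry_delay_years,
        wl,
        payments_at_start=params.payments_at_start,
    )
    return npv_loss(
        newborns_thousands,
        labor_participation_fraction,
        income,
        params.deficit(derived=derived_deficit),
        ann,
        scope=scope,
        work_life=wl,
    )
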