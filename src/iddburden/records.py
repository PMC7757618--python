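"""Core domain records for country-level iodine surveillance data.

The analysis operates on country-year rows that carry demographics
(population and live births, both in thousands), one or both iodine
indicators (total goiter rate, TGR, in percent; median urinary iodine
concentration, MUIC, in ug/L), and the economic covariates needed for
productivity-loss accounting (GNI per capita, wage share, labor-force
participation, healthy life expectancy).
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

#: The six WHO regions used to aggregate country estimates.
WHO_REGIONS: tuple[str, ...] = (
    "Africa",
    "Americas",
    "Eastern Mediterranean",
    "Europe",
    "South Asia",
    "East Asia and Pacific",
)


class CountryRecord(BaseModel):
    """One country-year row of surveillance and economic covariates.

    Counts (population, births) are in thousands; fractions (wage share,
    labor participation) are on [0, 1]; money is current USD.  Either
    ``tgr_percent`` or ``muic_ug_per_l`` must be present for the record
    to be usable in burden estimation; which one is present normally
    depends on the survey era (goiter surveys at baseline, urinary
    iodine surveys at endpoint).
    """

    country_id: str = Field(min_length=1)
    name: str = ""
    region: str
    year: int
    population_thousands: float = Field(ge=0)
    births_thousands: float = Field(ge=0)
    tgr_percent: Optional[float] = Field(default=None, ge=0, le=100)
    muic_ug_per_l: Optional[float] = Field(default=None, gt=0)
    gni_per_capita_usd: Optional[float] = Field(default=None, ge=0)
    wage_share_fraction: Optional[float] = Field(default=None, gt=0, le=1)
    labor_participation_fraction: Optional[float] = Field(default=None, gt=0, le=1)
    hale_years: Optional[float] = Field(default=None, gt=15)

    @field_validator("region")
    @classmethod
    def _region_in_vocabulary(cls, v: str) -> str:
        if v not in WHO_REGIONS:
            raise ValueError(
                f"region {v!r} is not one of the six WHO regions {WHO_REGIONS}"
            )
        return v

    def has_iodine_indicator(self) -> bool:
        """True when at least one of TGR / MUIC is present."""
        return self.tgr_percent is not None or self.muic_ug_per_l is not None

    def require(self, *fields: str) -> None:
        """Fail fast when a downstream stage needs fields this record lacks."""
        missing = [f for f in fields if getattr(self, f) is None]
        if missing:
            raise ValueError(
                f"record {self.country_id!r} ({self.year}) is missing "
                f"required field(s): {', '.join(missing)}"
            )


class SurveyPoint(BaseModel):
    """One paired (MUIC, TGR) observation used to fit the dose-response.

    Both coordinates must be strictly positive because fitting happens
    on natural-log scale.
    """

    muic_ug_per_l: float = Field(gt=0)
    tgr_percent: float = Field(gt=0)
    label: Optional[str] = None


class RegionTable(BaseModel):
    """An ordered collection of country records under one scenario tag.

    Keys (country_id, year, scenario) must be unique.  Iteration yields
    the records in insertion order; :meth:`sorted_records` gives the
    canonical (region, country_id) order used for deterministic output.
    """

    scenario: str = ""
    records: list[CountryRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _no_duplicate_keys(self) -> "RegionTable":
        seen: set[tuple[str, int]] = set()
        for rec in self.records:
            key = (rec.country_id, rec.year)
            if key in seen:
                raise ValueError(
                    f"duplicate (country_id, year) key {key} in scenario "
                    f"{self.scenario!r}"
                )
            seen.add(key)
        return self

    def __iter__(self) -> Iterator[CountryRecord]:  # type: ignore[override]
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def sorted_records(self) -> list[CountryRecord]:
        """Records ordered by (region, country_id) — the canonical CSV order."""
        return sorted(self.records, key=lambda r: (r.region, r.country_id))

    def by_id(self) -> dict[str, CountryRecord]:
        return {r.country_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        """Render as a pandas DataFrame, one column per field."""
        cols = list(CountryRecord.model_fields)
        rows = [{c: getattr(r, c) for c in cols} for r in self.sorted_records()]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_records(
        cls, records: Iterable[CountryRecord], scenario: str = ""
    ) -> "RegionTable":
        return cls(scenario=scenario, records=list(records))
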