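import numpy as np
import pytest

from iddburden import CountryRecord, RegionTable, SurveyPoint

ALPHA_REF = 11049.0
BETA_REF = -1.63


@pytest.fixture
def curve_points() -> list[SurveyPoint]:
    """24 noise-free points exactly on TGR = 11049 * MUIC**-1.63."""
    muic = np.linspace(20.0, 300.0, 24)
    return [
        SurveyPoint(muic_ug_per_l=float(m), tgr_percent=float(ALPHA_REF * m**BETA_REF))
        for m in muic
    ]


def make_record(cid="C001", region="Africa", year=2019, pop=1000.0, births=20.0, **kw):
    return CountryRecord(
        country_id=cid,
        name=cid,
        region=region,
        year=year,
        population_thousands=pop,
        births_thousands=births,
        **kw,
    )


@pytest.fixture
def three_region_tables() -> tuple[RegionTable, RegionTable]:
    """Three-country baseline/endpoint pair spanning two regions.

    C003 is present only at baseline, to exercise join policies.
    """
    baseline = RegionTable.from_records(
        [
            make_record("C001", "Africa", 1993, pop=800.0, births=30.0, tgr_percent=20.0),
            make_record("C002", "Europe", 1993, pop=500.0, births=10.0, tgr_percent=10.0),
            make_record("C003", "Africa", 1993, pop=200.0, births=8.0, tgr_percent=30.0),
        ],
        scenario="baseline_1993",
    )
    endpoint = RegionTable.from_records(
        [
            make_record(
                "C001", "Africa", 2019, pop=1200.0, births=36.0,
                muic_ug_per_l=150.0, gni_per_capita_usd=2000.0,
                wage_share_fraction=0.5, labor_participation_fraction=0.6,
                hale_years=60.0,
            ),
            make_record(
                "C002", "Europe", 2019, pop=550.0, births=9.0,
                muic_ug_per_l=220.0, gni_per_capita_usd=30000.0,
                wage_share_fraction=0.6, labor_participation_fraction=0.55,
                hale_years=68.0,
            ),
        ],
        scenario="endpoint_2019",
    )
    return baseline, endpoint
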