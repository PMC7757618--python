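"""Bundled regional reference tables for the global salt-iodization era.

These are region-level summary estimates for the six WHO regions,
covering the pre-iodization baseline (goiter-survey era, 1993) and the
current endpoint (urinary-iodine era, 2019): population and live births
(thousands), total goiter rate (%, modeled from MUIC at the endpoint),
the doing-nothing counterfactual caseload, and the economic covariates
and discounted productivity losses of the newborn cohorts.

They serve as fixed inputs for the headline global accounting — summing
regions to the globe, differencing the counterfactual against the
endpoint, and totalling discounted losses.  Country-level detail
underlying these rows is not bundled; country tables come from user
CSVs or from :mod:`iddburden.synthetic`.

Note the counterfactual birth cohort (173,963k births) is larger than
the endpoint cohort (136,149k): the two scenarios rest on different
country sets and eras, so newborn rows are compared as published rather
than recomputed from a single denominator.
"""

from __future__ import annotations

import pandas as pd

from .burden import BurdenEstimate, DenominatorKind, ScenarioTag

# region: (population_thousands, tgr_percent, affected_thousands) per era,
# plus the doing-nothing caseload (baseline rates, endpoint-era population).
_REGIONAL_STATUS = [
    # region, pop_1993, tgr_1993, cases_1993, pop_2019, tgr_2019, cases_2019, doing_nothing
    ("Africa", 543_705, 15.6, 85_029, 929_856, 4.8, 44_716, 145_419),
    ("Americas", 691_115, 11.0, 75_832, 970_166, 1.7, 16_931, 106_451),
    ("Eastern Mediterranean", 383_635, 24.2, 93_004, 577_938, 3.9, 22_808, 140_109),
    ("Europe", 782_151, 12.8, 100_152, 907_895, 5.1, 46_099, 116_253),
    ("South Asia", 1_331_968, 13.0, 172_505, 1_878_262, 2.8, 51_829, 243_256),
    ("East Asia and Pacific", 1_403_931, 10.5, 147_028, 1_853_008, 2.3, 42_978, 194_058),
]

# Newborn cohorts: births (thousands), TGR applied, newborns with IDDs.
_NEWBORN_ENDPOINT = [
    ("Africa", 33_681, 4.8, 1_740),
    ("Americas", 15_074, 1.7, 272),
    ("Eastern Mediterranean", 15_406, 3.9, 636),
    ("Europe", 11_119, 5.1, 559),
    ("South Asia", 36_518, 2.8, 1_010),
    ("East Asia and Pacific", 24_350, 3.1, 609),
]
_NEWBORN_DOING_NOTHING = [
    ("Africa", 38_898, 15.6, 6_341),
    ("Americas", 20_181, 11.0, 2_511),
    ("Eastern Mediterranean", 17_773, 24.2, 4_307),
    ("Europe", 10_445, 12.8, 1_748),
    ("South Asia", 53_128, 13.0, 6_589),
    ("East Asia and Pacific", 33_538, 10.5, 3_793),
]

# Economic rows: newborns with IDDs (thousands), labor participation (%),
# wage-share-adjusted annual income (USD), NPV loss at 3% (thousands USD).
_ECON_ENDPOINT = [
    ("Africa", 1_740, 71.8, 1_146, 838_880),
    ("Americas", 272, 65.1, 5_722, 3_246_795),
    ("Eastern Mediterranean", 636, 55.1, 8_100, 794_755),
    ("Europe", 559, 59.3, 18_596, 4_683_995),
    ("South Asia", 1_010, 69.4, 1_479, 433_285),
    ("East Asia and Pacific", 609, 64.0, 6_372, 2_485_492),
]
_ECON_DOING_NOTHING = [
    ("Africa", 6_341, 70.2, 1_146, 1_326_288),
    ("Americas", 2_511, 62.4, 5_722, 14_736_522),
    ("Eastern Mediterranean", 4_307, 52.8, 8_435, 3_463_865),
    ("Europe", 1_748, 59.3, 18_596, 8_247_588),
    ("South Asia", 6_589, 68.3, 1_479, 3_092_915),
    ("East Asia and Pacific", 3_793, 67.4, 6_372, 14_353_332),
]


def regional_status_frame() -> pd.DataFrame:
    """Regional population, goiter rate and caseload for both eras."""
    return pd.DataFrame(
        _REGIONAL_STATUS,
        columns=[
            "region",
            "population_1993_thousands",
            "tgr_1993_percent",
            "cases_1993_thousands",
            "population_2019_thousands",
            "tgr_2019_percent",
            "cases_2019_thousands",
            "doing_nothing_cases_thousands",
        ],
    )


def regional_burden(scenario: ScenarioTag) -> list[BurdenEstimate]:
    """Region-level population burden estimates for one scenario."""
    tag = ScenarioTag(scenario)
    out = []
    for region, p93, t93, c93, p19, t19, c19, dn in _REGIONAL_STATUS:
        if tag is ScenarioTag.BASELINE:
            denom, tgr, cases = p93, t93, c93
        elif tag is ScenarioTag.ENDPOINT:
            denom, tgr, cases = p19, t19, c19
        else:
            denom, tgr, cases = p19, t93, dn
        out.append(
            BurdenEstimate(
                scope=region,
                scenario=tag.value,
                denominator_thousands=float(denom),
                tgr_percent=float(tgr),
                cases_thousands=float(cases),
                denominator_kind=DenominatorKind.POPULATION.value,
            )
        )
    return out


def newborn_burden(scenario: ScenarioTag) -> list[BurdenEstimate]:
    """Region-level newborn burden estimates for one scenario."""
    tag = ScenarioTag(scenario)
    if tag is ScenarioTag.ENDPOINT:
        rows = _NEWBORN_ENDPOINT
    elif tag is ScenarioTag.DOING_NOTHING:
        rows = _NEWBORN_DOING_NOTHING
    else:
        raise ValueError("newborn reference rows exist for endpoint and counterfactual")
    return [
        BurdenEstimate(
            scope=region,
            scenario=tag.value,
            denominator_thousands=float(births),
            tgr_percent=float(tgr),
            cases_thousands=float(cases),
            denominator_kind=DenominatorKind.BIRTHS.value,
        )
        for region, births, tgr, cases in rows
    ]


def econ_frame(scenario: ScenarioTag) -> pd.DataFrame:
    """Regional newborn-cohort economics for one scenario."""
    tag = ScenarioTag(scenario)
    if tag is ScenarioTag.ENDPOINT:
        rows = _ECON_ENDPOINT
    elif tag is ScenarioTag.DOING_NOTHING:
        rows = _ECON_DOING_NOTHING
    else:
        raise ValueError("economic reference rows exist for endpoint and counterfactual")
    return pd.DataFrame(
        rows,
        columns=[
            "region",
            "newborns_with_idd_thousands",
            "labor_participation_percent",
            "annual_income_usd",
            "npv_loss_usd_thousands",
        ],
    )
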