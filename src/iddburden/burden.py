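"""Clinical IDD burden accounting: scenarios, counterfactuals, aggregation.

Cases of clinical iodine deficiency disorders (IDDs) are estimated as
denominator x TGR / 100, where the denominator is either total
population or annual live births (both in thousands) and TGR is the
total goiter rate used as a surrogate prevalence of clinical IDDs.

Three scenarios are tracked:

* ``baseline_1993`` — surveyed goiter rates of the pre-iodization era;
* ``endpoint_2019`` — current burden, with TGR modeled from MUIC via the
  dose-response where no direct goiter survey exists;
* ``doing_nothing`` — the counterfactual pairing baseline TGR with a
  later-era denominator: the burden had iodine status never improved.

Products are always taken at country level and at full precision;
regional and global rates are recomputed as 100 * sum(cases) /
sum(denominator) after summation.  Multiplying a rounded regional rate
by a regional denominator gives visibly different numbers — an
aggregation-order effect worth keeping in mind when comparing against
rounded published tables.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from enum import Enum
from typing import Optional

from .dose_response import PowerFit, predict_tgr
from .records import CountryRecord, RegionTable

GLOBAL_SCOPE = "global"


class ScenarioTag(str, Enum):
    BASELINE = "baseline_1993"
    ENDPOINT = "endpoint_2019"
    DOING_NOTHING = "doing_nothing"


class DenominatorKind(str, Enum):
    POPULATION = "population"
    BIRTHS = "births"


class JoinPolicy(str, Enum):
    """How the counterfactual pairs baseline rates with denominators.

    ``ENDPOINT_DENOMINATORS`` applies each country's baseline TGR to its
    endpoint-era denominator, falling back to the baseline denominator
    (and flagging the row) for countries absent from the endpoint table.
    ``BASELINE_DENOMINATORS`` evaluates the counterfactual over the
    baseline country set with baseline-era denominators throughout.
    ``STRICT`` uses only countries present in both tables and errors if
    the intersection is empty.
    """

    ENDPOINT_DENOMINATORS = "endpoint-denominators"
    BASELINE_DENOMINATORS = "baseline-denominators"
    STRICT = "strict"


@dataclasses.dataclass(frozen=True)
class BurdenEstimate:
    """Cases of clinical IDDs for one scope under one scenario.

    ``scope`` is a country_id, a WHO region label, or ``"global"``.  The
    identity cases = denominator * tgr / 100 holds exactly at country
    level; aggregates carry summed cases and denominators with the rate
    recomputed from those sums.
    """

    scope: str
    scenario: str
    denominator_thousands: float
    tgr_percent: float
    cases_thousands: float
    denominator_kind: str = DenominatorKind.POPULATION.value
    flagged: bool = False  # e.g. a counterfactual row with a fallback denominator


@dataclasses.dataclass(frozen=True)
class BenefitSummary:
    """Prevented cases and prevalence reduction for one scope."""

    scope: str
    doing_nothing_cases_thousands: float
    endpoint_cases_thousands: float
    prevented_cases_thousands: float
    prevalence_reduction_percent: float


def estimate_cases(denominator_thousands: float, tgr_percent: float) -> float:
    """Cases (thousands) = denominator (thousands) x TGR / 100, unrounded."""
    if denominator_thousands < 0:
        raise ValueError("denominator must be nonnegative")
    if not 0.0 <= tgr_percent <= 100.0:
        raise ValueError(f"tgr_percent must be in [0, 100], got {tgr_percent}")
    return denominator_thousands * tgr_percent / 100.0


def record_tgr(
    record: CountryRecord,
    fit: Optional[PowerFit] = None,
    prefer_measured: bool = False,
) -> float:
    """TGR (%) for a record, modeled from MUIC when required.

    By default a record carrying MUIC uses the modeled TGR even when a
    measured goiter rate is also present, so baseline and endpoint rest
    on a single comparable scale; set ``prefer_measured`` to use the
    surveyed value whenever one exists.
    """
    if prefer_measured and record.tgr_percent is not None:
        return record.tgr_percent
    if record.muic_ug_per_l is not None:
        if fit is None:
            raise ValueError(
                f"record {record.country_id!r} needs MUIC->TGR conversion but "
                "no dose-response model was supplied"
            )
        return predict_tgr(fit, record.muic_ug_per_l)
    if record.tgr_percent is not None:
        return record.tgr_percent
    raise ValueError(f"record {record.country_id!r} carries no iodine indicator")


def _denominator(record: CountryRecord, kind: DenominatorKind) -> float:
    if kind is DenominatorKind.POPULATION:
        return record.population_thousands
    return record.births_thousands


def country_burden(
    table: RegionTable,
    scenario: ScenarioTag,
    denominator_kind: DenominatorKind = DenominatorKind.POPULATION,
    fit: Optional[PowerFit] = None,
    prefer_measured: bool = False,
) -> list[BurdenEstimate]:
    """Per-country burden estimates for one table under one scenario."""
    kind = DenominatorKind(denominator_kind)
    out = []
    for rec in table.sorted_records():
        tgr = record_tgr(rec, fit=fit, prefer_measured=prefer_measured)
        denom = _denominator(rec, kind)
        out.append(
            BurdenEstimate(
                scope=rec.country_id,
                scenario=ScenarioTag(scenario).value,
                denominator_thousands=denom,
                tgr_percent=tgr,
                cases_thousands=estimate_cases(denom, tgr),
                denominator_kind=kind.value,
            )
        )
    return out


def doing_nothing_scenario(
    baseline: RegionTable,
    endpoint: RegionTable,
    denominator_kind: DenominatorKind = DenominatorKind.POPULATION,
    policy: JoinPolicy = JoinPolicy.ENDPOINT_DENOMINATORS,
) -> list[BurdenEstimate]:
    """Counterfactual burden: baseline goiter rates, later denominators.

    Every baseline record must carry a surveyed ``tgr_percent``.  The
    join ``policy`` controls which denominator each country contributes
    (see :class:`JoinPolicy`); rows that had to fall back to a baseline
    denominator are returned with ``flagged=True``.
    """
    kind = DenominatorKind(denominator_kind)
    policy = JoinPolicy(policy)
    endpoint_by_id = endpoint.by_id()
    out = []
    for rec in baseline.sorted_records():
        rec.require("tgr_percent")
        tgr = rec.tgr_percent
        assert tgr is not None
        if policy is JoinPolicy.BASELINE_DENOMINATORS:
            denom, flagged = _denominator(rec, kind), False
        else:
            match = endpoint_by_id.get(rec.country_id)
            if match is not None:
                denom, flagged = _denominator(match, kind), False
            elif policy is JoinPolicy.STRICT:
                continue
            else:
                denom, flagged = _denominator(rec, kind), True
        out.append(
            BurdenEstimate(
                scope=rec.country_id,
                scenario=ScenarioTag.DOING_NOTHING.value,
                denominator_thousands=denom,
                tgr_percent=tgr,
                cases_thousands=estimate_cases(denom, tgr),
                denominator_kind=kind.value,
                flagged=flagged,
            )
        )
    if policy is JoinPolicy.STRICT and not out:
        raise ValueError("strict join policy: no countries in common")
    return out


def prevented_cases(
    doing_nothing: BurdenEstimate, endpoint: BurdenEstimate
) -> BenefitSummary:
    """Prevented cases = counterfactual minus endpoint, same scope.

    The prevalence reduction is 100 * prevented / counterfactual when
    the counterfactual burden is positive, else 0.  Negative prevented
    cases (status worsened) are reported as-is, never clipped.
    """
    if doing_nothing.scope != endpoint.scope:
        raise ValueError(
            f"scope mismatch: {doing_nothing.scope!r} vs {endpoint.scope!r}"
        )
    if doing_nothing.denominator_kind != endpoint.denominator_kind:
        raise ValueError("denominator kinds differ between scenarios")
    prevented = doing_nothing.cases_thousands - endpoint.cases_thousands
    dn = doing_nothing.cases_thousands
    reduction = 100.0 * prevented / dn if dn > 0 else 0.0
    return BenefitSummary(
        scope=doing_nothing.scope,
        doing_nothing_cases_thousands=dn,
        endpoint_cases_thousands=endpoint.cases_thousands,
        prevented_cases_thousands=prevented,
        prevalence_reduction_percent=reduction,
    )


def aggregate(
    estimates: Sequence[BurdenEstimate],
    groups: Optional[dict[str, str]] = None,
) -> list[BurdenEstimate]:
    """Sum burden estimates into regional (or global) aggregates.

    ``groups`` maps each member scope to its aggregate scope (e.g.
    country_id -> region label); when omitted, everything collapses into
    a single ``"global"`` row.  Cases and denominators are summed and
    the aggregate TGR recomputed as 100 * sum(cases) / sum(denominator).
    Mixing denominator kinds or scenarios is an error.
    """
    if not estimates:
        return []
    kinds = {e.denominator_kind for e in estimates}
    if len(kinds) > 1:
        raise ValueError(f"mixed denominator kinds: {sorted(kinds)}")
    scenarios = {e.scenario for e in estimates}
    if len(scenarios) > 1:
        raise ValueError(f"mixed scenarios: {sorted(scenarios)}")

    buckets: dict[str, list[BurdenEstimate]] = {}
    for e in estimates:
        target = groups.get(e.scope, GLOBAL_SCOPE) if groups else GLOBAL_SCOPE
        buckets.setdefault(target, []).append(e)

    out = []
    for scope in sorted(buckets):
        members = buckets[scope]
        denom = sum(m.denominator_thousands for m in members)
        cases = sum(m.cases_thousands for m in members)
        out.append(
            BurdenEstimate(
                scope=scope,
                scenario=members[0].scenario,
                denominator_thousands=denom,
                tgr_percent=100.0 * cases / denom if denom > 0 else 0.0,
                cases_thousands=cases,
                denominator_kind=members[0].denominator_kind,
                flagged=any(m.flagged for m in members),
            )
        )
    return out


def benefit_by_scope(
    doing_nothing: Iterable[BurdenEstimate],
    endpoint: Iterable[BurdenEstimate],
) -> list[BenefitSummary]:
    """Pair counterfactual and endpoint estimates scope-by-scope."""
    endpoint_by_scope = {e.scope: e for e in endpoint}
    out = []
    for dn in doing_nothing:
        if dn.scope in endpoint_by_scope:
            out.append(prevented_cases(dn, endpoint_by_scope[dn.scope]))
    return out
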