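"""End-to-end estimation pipeline and report rendering.

One call runs the whole chain on a pair of country tables: convert
endpoint MUIC to modeled goiter rates, estimate country-level burdens
under the endpoint and doing-nothing scenarios, aggregate to WHO
regions and the globe, attach newborn-cohort productivity losses, and
render four CSV reports:

* ``table2.csv`` — regional population, goiter rates, caseloads,
  counterfactual, prevented cases and prevalence reduction;
* ``table3.csv`` — newborn cohorts and newborn IDD cases per scenario;
* ``table4.csv`` — NPV productivity losses of the newborn cohorts;
* ``status_counts.csv`` — countries per iodine-status class per region.

Every report carries a Total row equal to the sum of its regional rows,
and a plain-text run log records every parameter and policy, enough to
replay the run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as iddio
from .burden import (
    BenefitSummary,
    BurdenEstimate,
    DenominatorKind,
    JoinPolicy,
    ScenarioTag,
    aggregate,
    benefit_by_scope,
    country_burden,
    doing_nothing_scenario,
)
from .dose_response import (
    DEFAULT_THRESHOLDS,
    REFERENCE_MODEL,
    IodineStatusClass,
    PowerFit,
    classify_iodine_status,
    fit_power_model,
)
from .economics import EconParams, cohort_npv_loss
from .records import WHO_REGIONS, RegionTable
from .synthetic import GeneratorConfig, generate_country_tables, generate_survey_points

TOTAL_LABEL = "Total"
_CSV_FLOAT_FMT = "%.6g"


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    Exactly one source of country tables (CSV paths or a generator
    config) and exactly one source of the dose-response model (a survey
    CSV to fit, a generator-drawn survey, or the packaged reference
    coefficients) must be chosen.
    """

    baseline_path: Optional[str] = None
    endpoint_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None

    survey_path: Optional[str] = None
    fit_from_generator: bool = False
    use_reference_model: bool = True

    econ: EconParams = Field(default_factory=EconParams)
    population_join_policy: JoinPolicy = JoinPolicy.ENDPOINT_DENOMINATORS
    births_join_policy: JoinPolicy = JoinPolicy.BASELINE_DENOMINATORS
    deficit: str = Field(default="printed", pattern="^(printed|derived)$")
    prefer_measured_tgr: bool = False
    status_thresholds: tuple[float, float] = DEFAULT_THRESHOLDS

    out_dir: str = "results"
    verbosity: int = 1

    @model_validator(mode="after")
    def _one_source_each(self) -> "RunConfig":
        have_paths = self.baseline_path is not None and self.endpoint_path is not None
        if have_paths == (self.generator is not None):
            raise ValueError(
                "choose exactly one table source: baseline_path+endpoint_path "
                "or a generator config"
            )
        model_sources = sum(
            [self.survey_path is not None, self.fit_from_generator,
             self.use_reference_model]
        )
        if model_sources != 1:
            raise ValueError(
                "choose exactly one dose-response source: survey_path, "
                "fit_from_generator, or use_reference_model"
            )
        if self.fit_from_generator and self.generator is None:
            raise ValueError("fit_from_generator requires a generator config")
        return self


@dataclasses.dataclass
class ReportBundle:
    """All artifacts of one pipeline run, in memory."""

    model: PowerFit
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    status_counts: pd.DataFrame
    benefits: list[BenefitSummary]
    log: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (
            ("table2", self.table2),
            ("table3", self.table3),
            ("table4", self.table4),
            ("status_counts", self.status_counts),
        ):
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False, float_format=_CSV_FLOAT_FMT, encoding="utf-8")
            paths[name] = p
        self.model.to_json(out / "model.json")
        paths["model"] = out / "model.json"
        log_path = out / "run_log.json"
        with open(log_path, "w", encoding="utf-8") as fh:
            json.dump(self.log, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["log"] = log_path
        return paths


def count_status(
    endpoint: RegionTable,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Countries per iodine-status class, by region with a global Total.

    Records without MUIC are not classifiable and are counted in an
    ``unclassified`` column; an error is raised when no record at all
    carries MUIC.
    """
    classes = [c.value for c in IodineStatusClass]
    counts: dict[str, dict[str, int]] = {
        r: {c: 0 for c in classes} | {"unclassified": 0} for r in WHO_REGIONS
    }
    n_classified = 0
    for rec in endpoint:
        if rec.muic_ug_per_l is None:
            counts[rec.region]["unclassified"] += 1
            continue
        label = classify_iodine_status(rec.muic_ug_per_l, thresholds).value
        counts[rec.region][label] += 1
        n_classified += 1
    if n_classified == 0:
        raise ValueError("no records carry MUIC: nothing to classify")
    rows = [{"region": r, **counts[r]} for r in WHO_REGIONS]
    total = {"region": TOTAL_LABEL}
    for c in [*classes, "unclassified"]:
        total[c] = sum(row[c] for row in rows)
    return pd.DataFrame([*rows, total])


def _with_total(frame: pd.DataFrame, rate_cols: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Append a Total row: sums everywhere, rates recomputed from sums.

    ``rate_cols`` maps a rate column to its (cases, denominator) pair.
    """
    total: dict[str, object] = {"region": TOTAL_LABEL}
    for col in frame.columns:
        if col == "region":
            continue
        if col in rate_cols:
            continue
        total[col] = frame[col].sum()
    for rate, (cases, denom) in rate_cols.items():
        d = frame[denom].sum()
        total[rate] = 100.0 * frame[cases].sum() / d if d else 0.0
    return pd.concat([frame, pd.DataFrame([total])], ignore_index=True)


def _resolve_model(config: RunConfig) -> PowerFit:
    if config.survey_path is not None:
        return fit_power_model(iddio.read_survey_points(config.survey_path))
    if config.fit_from_generator:
        assert config.generator is not None
        return fit_power_model(generate_survey_points(config.generator))
    return REFERENCE_MODEL


def _load_tables(config: RunConfig) -> tuple[RegionTable, RegionTable]:
    if config.generator is not None:
        return generate_country_tables(config.generator)
    assert config.baseline_path and config.endpoint_path
    baseline = iddio.read_country_table(
        config.baseline_path, scenario=ScenarioTag.BASELINE.value
    ).raise_on_rejections()
    endpoint = iddio.read_country_table(
        config.endpoint_path, scenario=ScenarioTag.ENDPOINT.value
    ).raise_on_rejections()
    return baseline, endpoint


def _regional(
    estimates: list[BurdenEstimate], groups: dict[str, str]
) -> list[BurdenEstimate]:
    by_region = aggregate(estimates, groups)
    order = {r: i for i, r in enumerate(WHO_REGIONS)}
    return sorted(by_region, key=lambda e: order.get(e.scope, 99))


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full estimation chain under one configuration."""

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    model = stage("dose_response", _resolve_model, config)
    baseline, endpoint = stage("load_tables", _load_tables, config)
    groups = {r.country_id: r.region for t in (baseline, endpoint) for r in t}

    # --- population burden (table 2) -------------------------------------
    base_c = stage(
        "baseline_burden", country_burden, baseline, ScenarioTag.BASELINE,
        DenominatorKind.POPULATION, model, config.prefer_measured_tgr,
    )
    end_c = stage(
        "endpoint_burden", country_burden, endpoint, ScenarioTag.ENDPOINT,
        DenominatorKind.POPULATION, model, config.prefer_measured_tgr,
    )
    dn_c = stage(
        "doing_nothing", doing_nothing_scenario, baseline, endpoint,
        DenominatorKind.POPULATION, config.population_join_policy,
    )
    base_r = _regional(base_c, groups)
    end_r = _regional(end_c, groups)
    dn_r = _regional(dn_c, groups)
    benefits = benefit_by_scope(dn_r, end_r)
    ben = {b.scope: b for b in benefits}

    end_by = {e.scope: e for e in end_r}
    dn_by = {d.scope: d for d in dn_r}
    table2 = pd.DataFrame(
        [
            {
                "region": b.scope,
                "population_1993_thousands": b.denominator_thousands,
                "tgr_1993_percent": b.tgr_percent,
                "cases_1993_thousands": b.cases_thousands,
                "population_2019_thousands": end_by[b.scope].denominator_thousands,
                "tgr_2019_percent": end_by[b.scope].tgr_percent,
                "cases_2019_thousands": end_by[b.scope].cases_thousands,
                "doing_nothing_cases_thousands": dn_by[b.scope].cases_thousands,
                "prevented_cases_thousands": ben[b.scope].prevented_cases_thousands,
                "prevalence_reduction_percent": ben[
                    b.scope
                ].prevalence_reduction_percent,
            }
            for b in base_r
            if b.scope in end_by and b.scope in dn_by
        ]
    )
    table2 = _with_total(
        table2,
        {
            "tgr_1993_percent": ("cases_1993_thousands", "population_1993_thousands"),
            "tgr_2019_percent": ("cases_2019_thousands", "population_2019_thousands"),
        },
    )
    # Total-row reduction recomputed from summed cases, not summed over rows
    dn_total = table2.loc[
        table2.region == TOTAL_LABEL, "doing_nothing_cases_thousands"
    ].iloc[0]
    prev_total = table2.loc[
        table2.region == TOTAL_LABEL, "prevented_cases_thousands"
    ].iloc[0]
    table2.loc[table2.region == TOTAL_LABEL, "prevalence_reduction_percent"] = (
        100.0 * prev_total / dn_total if dn_total else 0.0
    )

    # --- newborn burden (table 3) ----------------------------------------
    end_b = stage(
        "endpoint_newborns", country_burden, endpoint, ScenarioTag.ENDPOINT,
        DenominatorKind.BIRTHS, model, config.prefer_measured_tgr,
    )
    dn_b = stage(
        "doing_nothing_newborns", doing_nothing_scenario, baseline, endpoint,
        DenominatorKind.BIRTHS, config.births_join_policy,
    )
    end_br = _regional(end_b, groups)
    dn_br = _regional(dn_b, groups)
    t3_rows = []
    for scen_label, ests in (
        (ScenarioTag.ENDPOINT.value, end_br),
        (ScenarioTag.DOING_NOTHING.value, dn_br),
    ):
        for e in ests:
            t3_rows.append(
                {
                    "scenario": scen_label,
                    "region": e.scope,
                    "births_thousands": e.denominator_thousands,
                    "tgr_percent": e.tgr_percent,
                    "newborns_with_idd_thousands": e.cases_thousands,
                }
            )
    table3 = pd.concat(
        [
            _with_total(
                pd.DataFrame([r for r in t3_rows if r["scenario"] == s]),
                {"tgr_percent": ("newborns_with_idd_thousands", "births_thousands")},
            ).assign(scenario=s)
            for s in (ScenarioTag.ENDPOINT.value, ScenarioTag.DOING_NOTHING.value)
        ],
        ignore_index=True,
    )[["scenario", "region", "births_thousands", "tgr_percent",
       "newborns_with_idd_thousands"]]

    # --- newborn-cohort economics (table 4) -------------------------------
    econ_cov = _regional_econ_covariates(endpoint, groups)
    t4_frames = []
    for scen_label, ests in (
        (ScenarioTag.ENDPOINT.value, end_br),
        (ScenarioTag.DOING_NOTHING.value, dn_br),
    ):
        rows = []
        for e in ests:
            cov = econ_cov[e.scope]
            loss = cohort_npv_loss(
                newborns_thousands=e.cases_thousands,
                gni_per_capita_usd=cov["gni"],
                wage_share_fraction=cov["wage"],
                labor_participation_fraction=cov["part"],
                hale_years=cov["hale"],
                params=config.econ,
                scope=e.scope,
                derived_deficit=config.deficit == "derived",
            )
            rows.append(
                {
                    "scenario": scen_label,
                    "region": e.scope,
                    "newborns_with_idd_thousands": loss.newborns_with_idd_thousands,
                    "labor_participation_percent": 100.0
                    * loss.labor_participation_fraction,
                    "annual_income_usd": loss.annual_income_usd,
                    "work_life_years": loss.work_life_years,
                    "annuity_factor": loss.annuity_factor,
                    "npv_loss_usd_thousands": loss.npv_loss_usd_thousands,
                }
            )
        frame = pd.DataFrame(rows)
        total = {
            "scenario": scen_label,
            "region": TOTAL_LABEL,
            "newborns_with_idd_thousands": frame[
                "newborns_with_idd_thousands"
            ].sum(),
            "npv_loss_usd_thousands": frame["npv_loss_usd_thousands"].sum(),
        }
        t4_frames.append(
            pd.concat([frame, pd.DataFrame([total])], ignore_index=True)
        )
    table4 = pd.concat(t4_frames, ignore_index=True)

    status_counts = stage(
        "status_counts", count_status, endpoint, config.status_thresholds
    )

    log = {
        "config": json.loads(config.model_dump_json()),
        "model": dataclasses.asdict(model),
        "n_baseline_countries": len(baseline),
        "n_endpoint_countries": len(endpoint),
        "flagged_doing_nothing_rows": sorted(
            e.scope for e in dn_c + dn_b if e.flagged
        ),
    }
    return ReportBundle(
        model=model,
        table2=table2,
        table3=table3,
        table4=table4,
        status_counts=status_counts,
        benefits=benefits,
        log=log,
    )


def _regional_econ_covariates(
    endpoint: RegionTable, groups: dict[str, str]
) -> dict[str, dict[str, float]]:
    """Birth-weighted regional means of the economic covariates.

    Regional cohorts mix countries, so covariates are averaged with
    live-birth weights; records missing a covariate fail fast.
    """
    acc: dict[str, dict[str, float]] = {}
    for rec in endpoint:
        rec.require(
            "gni_per_capita_usd",
            "wage_share_fraction",
            "labor_participation_fraction",
            "hale_years",
        )
        w = rec.births_thousands
        slot = acc.setdefault(
            groups[rec.country_id],
            {"w": 0.0, "gni": 0.0, "wage": 0.0, "part": 0.0, "hale": 0.0},
        )
        slot["w"] += w
        slot["gni"] += w * rec.gni_per_capita_usd
        slot["wage"] += w * rec.wage_share_fraction
        slot["part"] += w * rec.labor_participation_fraction
        slot["hale"] += w * rec.hale_years
    out = {}
    for region, slot in acc.items():
        w = slot.pop("w")
        out[region] = {k: v / w for k, v in slot.items()} if w > 0 else slot
    return out


def replay_log(log: dict) -> ReportBundle:
    """Re-run a pipeline from its own run log (reproducibility check)."""
    return run_pipeline(RunConfig.model_validate(log["config"]))
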