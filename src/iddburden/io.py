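"""CSV input/output for country tables and paired survey points.

Dialect: UTF-8, comma-separated, ``.`` decimal, mandatory header row.
Rows that fail validation are not silently dropped — every read returns
the rejected rows with their 1-based data row number and the reason, so
a caller can log or surface them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import ValidationError

from .records import CountryRecord, RegionTable, SurveyPoint

#: Canonical column order of a country-table CSV.
COUNTRY_COLUMNS: tuple[str, ...] = tuple(CountryRecord.model_fields)

#: Columns that must be present (possibly after renaming) in any input file.
REQUIRED_COLUMNS: tuple[str, ...] = (
    "country_id",
    "region",
    "year",
    "population_thousands",
    "births_thousands",
)

#: Float formatting used on write; 6 significant digits round-trip losslessly
#: through this format for the magnitudes the tables carry.
_FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class RowRejection:
    """A single input row that failed validation."""

    row_number: int  # 1-based, counting data rows (header excluded)
    reason: str
    raw: dict


@dataclasses.dataclass
class ReadReport:
    table: RegionTable
    rejections: list[RowRejection]

    def raise_on_rejections(self) -> RegionTable:
        if self.rejections:
            first = self.rejections[0]
            raise ValueError(
                f"{len(self.rejections)} row(s) failed validation; first: "
                f"row {first.row_number}: {first.reason}"
            )
        return self.table


def read_country_table(
    path: str | Path,
    schema: Optional[dict[str, str]] = None,
    scenario: str = "",
) -> ReadReport:
    """Read a country-table CSV into a validated :class:`RegionTable`.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Optional mapping from file column names to canonical field names,
        for files whose headers differ from :data:`COUNTRY_COLUMNS`.
    scenario:
        Tag stored on the returned table (e.g. ``baseline_1993``).

    Returns a :class:`ReadReport` carrying the validated records and a
    rejection entry (row number + reason) for every invalid row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"country table not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        frame = frame.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s) in {path}: {', '.join(missing)}")

    records: list[CountryRecord] = []
    rejections: list[RowRejection] = []
    known = [c for c in COUNTRY_COLUMNS if c in frame.columns]
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw = {c: getattr(row, c) for c in known}
        payload = {k: (None if v == "" else v) for k, v in raw.items()}
        try:
            records.append(CountryRecord.model_validate(payload))
        except ValidationError as err:
            reasons = "; ".join(
                f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                for e in err.errors()
            )
            rejections.append(RowRejection(row_number=i, reason=reasons, raw=raw))
    table = RegionTable.from_records(records, scenario=scenario)
    return ReadReport(table=table, rejections=rejections)


def write_country_table(table: RegionTable, path: str | Path) -> None:
    """Write a validated table as UTF-8 CSV with the canonical header.

    Rows are sorted by (region, country_id), so the same table always
    produces a byte-identical file.
    """
    frame = table.to_frame()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def read_survey_points(path: str | Path) -> list[SurveyPoint]:
    """Read paired (MUIC, TGR) observations from a CSV.

    Expects columns ``muic_ug_per_l`` and ``tgr_percent``; an optional
    ``label`` column is carried through.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey-point file not found: {path}")
    frame = pd.read_csv(path)
    for col in ("muic_ug_per_l", "tgr_percent"):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    points = []
    for row in frame.itertuples(index=False):
        label = getattr(row, "label", None)
        points.append(
            SurveyPoint(
                muic_ug_per_l=row.muic_ug_per_l,
                tgr_percent=row.tgr_percent,
                label=None if label is None or pd.isna(label) else str(label),
            )
        )
    return points


def write_survey_points(points: list[SurveyPoint], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "muic_ug_per_l": p.muic_ug_per_l,
                "tgr_percent": p.tgr_percent,
                "label": p.label or "",
            }
            for p in points
        ],
        columns=["muic_ug_per_l", "tgr_percent", "label"],
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def read_region_mapping(path: str | Path) -> dict[str, str]:
    """Read a YAML/JSON mapping of country_id -> WHO region label.

    Region membership is configuration, not code: published regional
    summaries give only country counts per region, so the assignment of
    individual countries must be supplied by the user.
    """
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError(f"region mapping in {path} must be a mapping")
    return {str(k): str(v) for k, v in mapping.items()}
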