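"""Comparison-record schema, CSV I/O, exclusion filters and summary conversions.

A :class:`ComparisonRecord` holds one paired urban/non-urban summary (per
trait, per breeding season or pooled across seasons) with per-arm mean, SD and
sample size. Literature-extracted tables are messy, so reading is tolerant of
missing cells ("", "NA", "NaN") and column reordering; filtering then removes
records that cannot enter a meta-analysis (missing n or SD, n == 1, SD == 0)
and logs exactly why each record was dropped.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

TRAITS = ("laying_date", "clutch_size", "n_fledglings")

POOLED = "pooled"

#: CSV schema, in canonical column order.
COLUMNS = (
    "record_id",
    "study_id",
    "population_pair_id",
    "species",
    "trait",
    "season",
    "n_seasons",
    "mean_urban",
    "sd_urban",
    "n_urban",
    "mean_nonurban",
    "sd_nonurban",
    "n_nonurban",
    "lat_urban",
    "lon_urban",
    "lat_nonurban",
    "lon_nonurban",
    "publication_year",
)

_NUMERIC = {
    "mean_urban",
    "sd_urban",
    "n_urban",
    "mean_nonurban",
    "sd_nonurban",
    "n_nonurban",
    "lat_urban",
    "lon_urban",
    "lat_nonurban",
    "lon_nonurban",
}

_MISSING_TOKENS = {"", "na", "nan", "none", "null"}


class SchemaError(ValueError):
    """Input table does not match the comparison-record schema."""


@dataclass
class ComparisonRecord:
    """One paired urban/non-urban summary for a single trait and season.

    ``season`` is an integer year or the string ``"pooled"`` for estimates
    combined over ``n_seasons`` breeding seasons. Laying-date means are in
    days since 1 January (Jan 1 = 1); the other traits are counts, so their
    means must be positive. Missing numeric values are ``nan``.
    """

    record_id: str
    study_id: str
    population_pair_id: str
    species: str
    trait: str
    season: int | str
    mean_urban: float
    sd_urban: float
    n_urban: float
    mean_nonurban: float
    sd_nonurban: float
    n_nonurban: float
    n_seasons: int = 1
    lat_urban: float = math.nan
    lon_urban: float = math.nan
    lat_nonurban: float = math.nan
    lon_nonurban: float = math.nan
    publication_year: int = 2000


@dataclass
class ExclusionLog:
    """Per-rule removal counts plus the identity of every removed record.

    Rules are applied in a fixed order (missing n, missing SD, n == 1,
    SD == 0) and each removed record is tallied under the first rule that
    matches it, so the counts are unambiguous even for multiply-flawed rows.
    """

    missing_n: int = 0
    missing_sd: int = 0
    n_equals_one: int = 0
    sd_equals_zero: int = 0
    removed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def counts(self) -> dict[str, int]:
        return {
            "missing_n": self.missing_n,
            "missing_sd": self.missing_sd,
            "n_equals_one": self.n_equals_one,
            "sd_equals_zero": self.sd_equals_zero,
        }

    def to_json(self, path) -> None:
        payload = self.counts()
        payload["removed"] = [{"record_id": r, "rule": rule} for r, rule in self.removed]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    if isinstance(x, str) and x.strip().lower() in _MISSING_TOKENS:
        return True
    return False


def _parse_number(value, row: int, column: str) -> float:
    if _is_missing(value):
        return math.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"row {row}: column '{column}' is not numeric (got {value!r})"
        ) from None


def _parse_season(value, row: int):
    if _is_missing(value):
        raise SchemaError(f"row {row}: column 'season' is required")
    s = str(value).strip().lower()
    if s == POOLED:
        return POOLED
    try:
        return int(float(s))
    except ValueError:
        raise SchemaError(
            f"row {row}: season must be an integer year or 'pooled' (got {value!r})"
        ) from None


def read_comparisons(path) -> list[ComparisonRecord]:
    """Read paired urban/non-urban comparison summaries from CSV.

    Headers are matched case-insensitively and may appear in any order.
    Missing cells ("", "NA", "NaN") become ``nan`` — records are *not*
    filtered here; see :func:`apply_exclusions`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns and c not in
               ("lat_urban", "lon_urban", "lat_nonurban", "lon_nonurban",
                "n_seasons", "publication_year")]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    records = []
    for idx, row in enumerate(df.to_dict("records"), start=1):
        trait = str(row["trait"]).strip()
        if trait not in TRAITS:
            raise SchemaError(f"row {idx}: unknown trait label {trait!r}")
        kwargs = {
            "record_id": str(row["record_id"]).strip(),
            "study_id": str(row["study_id"]).strip(),
            "population_pair_id": str(row["population_pair_id"]).strip(),
            "species": str(row["species"]).strip(),
            "trait": trait,
            "season": _parse_season(row["season"], idx),
        }
        for col in _NUMERIC:
            if col in df.columns:
                kwargs[col] = _parse_number(row.get(col), idx, col)
        if "n_seasons" in df.columns and not _is_missing(row.get("n_seasons")):
            kwargs["n_seasons"] = int(float(row["n_seasons"]))
        if "publication_year" in df.columns and not _is_missing(row.get("publication_year")):
            kwargs["publication_year"] = int(float(row["publication_year"]))
        records.append(ComparisonRecord(**kwargs))
    return records


def write_comparisons(records: Iterable[ComparisonRecord], path) -> None:
    """Write records back to CSV in canonical column order (full precision)."""
    rows = []
    for r in records:
        d = asdict(r)
        rows.append({c: d[c] for c in COLUMNS})
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, index=False, float_format="%.17g")


def to_frame(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=list(COLUMNS))


_RULES = ("missing_n", "missing_sd", "n_equals_one", "sd_equals_zero")


def _first_violation(r: ComparisonRecord) -> str | None:
    if math.isnan(r.n_urban) or math.isnan(r.n_nonurban):
        return "missing_n"
    if math.isnan(r.sd_urban) or math.isnan(r.sd_nonurban):
        return "missing_sd"
    if r.n_urban == 1 or r.n_nonurban == 1:
        return "n_equals_one"
    if r.sd_urban == 0 or r.sd_nonurban == 0:
        return "sd_equals_zero"
    return None


def apply_exclusions(
    records: Sequence[ComparisonRecord],
) -> tuple[list[ComparisonRecord], ExclusionLog]:
    """Drop records unusable for effect-size computation, logging each removal.

    Rules, in order: any missing sample size; any missing SD; any n == 1
    (mean and SD undefined); any SD == 0. A record failing several rules is
    counted once, under the first rule that applies.
    """
    kept: list[ComparisonRecord] = []
    log = ExclusionLog()
    for r in records:
        rule = _first_violation(r)
        if rule is None:
            kept.append(r)
        else:
            setattr(log, rule, getattr(log, rule) + 1)
            log.removed.append((r.record_id, rule))
    return kept, log


def sd_from_se(se: float, n: int) -> float:
    """Convert a standard error to a standard deviation: SD = SE * sqrt(n)."""
    if se <= 0:
        raise ValueError(f"se must be positive (got {se})")
    if n < 2:
        raise ValueError(f"n must be at least 2 (got {n})")
    return se * math.sqrt(n)


def summary_from_quartiles(
    median: float, q1: float, q3: float, n: int
) -> tuple[float, float]:
    """Estimate (mean, SD) from a three-number summary {q1, median, q3}.

    Mean uses the optimally weighted estimator

        mean ~= (0.7 + 0.39/n) * (q1 + q3)/2 + (0.3 - 0.39/n) * median

    and SD the quantile-matching IQR estimator

        sd ~= (q3 - q1) / (2 * z[(0.75 n - 0.125) / (n + 0.25)])

    where z is the standard normal quantile function. Both assume an
    approximately normal underlying sample. A degenerate summary
    (q1 == median == q3) yields sd == 0, which the exclusion filter will
    later remove.
    """
    if n < 2:
        raise ValueError(f"n must be at least 2 (got {n})")
    if q1 > q3:
        raise ValueError(f"q1 ({q1}) exceeds q3 ({q3})")
    if not (q1 <= median <= q3):
        raise ValueError("median must lie between q1 and q3")
    w = 0.7 + 0.39 / n
    mean = w * (q1 + q3) / 2.0 + (1.0 - w) * median
    z = stats.norm.ppf((0.75 * n - 0.125) / (n + 0.25))
    sd = (q3 - q1) / (2.0 * z)
    return mean, sd


def standardize_lay_date(value, year: int | None = None) -> int:
    """Standardise a laying date to day-of-year, with 1 January = 1.

    Accepts a ``datetime.date``, an ISO date string, or an already-coded
    integer day number (passed through after range validation; the upper
    bound 366 allows leap years).
    """
    if isinstance(value, _dt.datetime):
        value = value.date()
    if isinstance(value, _dt.date):
        return value.timetuple().tm_yday
    if isinstance(value, str):
        return _dt.date.fromisoformat(value).timetuple().tm_yday
    day = int(value)
    if day < 1 or day > 366:
        raise ValueError(f"day-of-year {day} outside [1, 366]")
    return day
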