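"""Pooling of per-breeding-season summaries into among-season summaries.

When a study reports (mean, SD, n) per breeding season, the among-season mean
is the sample-size-weighted average of the per-season means and the
among-season variance is the weighted sum of within-season variances plus the
weighted variance of season means around the pooled mean:

    x_among = sum_i (n_i / N) * x_i,                 N = sum_i n_i
    S2_among = sum_i (n_i / N) * s2_i
             + sum_i (n_i / N) * (x_i - x_among)^2

With population variances (denominator n_i) this reproduces the variance of
the concatenated raw samples exactly; with the sample variances reported in
the literature it is the standard close approximation.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Sequence

from urbanvar.data_model import ComparisonRecord, POOLED

logger = logging.getLogger(__name__)


@dataclass
class SeasonSummary:
    """Mean, variance and sample size of one trait in one breeding season."""

    season: int
    mean: float
    var: float
    n: int


@dataclass
class PooledSummary:
    """Among-season mean and variance of a multi-season series."""

    mean: float
    var: float
    n_total: int
    n_seasons: int


def pool_seasons(seasons: Sequence[SeasonSummary]) -> PooledSummary:
    """Pool per-season summaries into an among-season mean and variance."""
    if not seasons:
        raise ValueError("cannot pool an empty list of season summaries")
    for s in seasons:
        if s.n < 2:
            raise ValueError(f"season {s.season}: n must be at least 2 (got {s.n})")
        if s.var < 0:
            raise ValueError(f"season {s.season}: negative variance {s.var}")
    N = sum(s.n for s in seasons)
    mean = sum(s.mean * s.n for s in seasons) / N
    within = sum((s.n / N) * s.var for s in seasons)
    between = sum((s.n / N) * (s.mean - mean) ** 2 for s in seasons)
    return PooledSummary(mean=mean, var=within + between, n_total=N,
                         n_seasons=len(seasons))


def split_intra_annual(records: Sequence[ComparisonRecord]) -> list[ComparisonRecord]:
    """Return only the single-season comparisons (season != 'pooled')."""
    return [r for r in records if r.season != POOLED]


def _pooled_record(group: list[ComparisonRecord]) -> ComparisonRecord:
    group = sorted(group, key=lambda r: r.season)
    urban = pool_seasons(
        [SeasonSummary(r.season, r.mean_urban, r.sd_urban**2, int(r.n_urban))
         for r in group]
    )
    nonurban = pool_seasons(
        [SeasonSummary(r.season, r.mean_nonurban, r.sd_nonurban**2, int(r.n_nonurban))
         for r in group]
    )
    first = group[0]
    return dataclasses.replace(
        first,
        record_id=f"{first.record_id}::pooled",
        season=POOLED,
        n_seasons=len(group),
        mean_urban=urban.mean,
        sd_urban=math.sqrt(urban.var),
        n_urban=urban.n_total,
        mean_nonurban=nonurban.mean,
        sd_nonurban=math.sqrt(nonurban.var),
        n_nonurban=nonurban.n_total,
    )


def build_interannual_dataset(
    records: Sequence[ComparisonRecord],
) -> list[ComparisonRecord]:
    """Build the inter-annual (among-breeding-season) comparison dataset.

    Single-season records from the same (study, population pair, trait) are
    pooled per arm via :func:`pool_seasons` when the group spans two or more
    breeding seasons; records already reported as multi-season estimates pass
    through unchanged. Groups observed in a single season only are not
    among-season comparisons and are dropped. Because both arms of a
    ComparisonRecord describe the same seasons by construction, season
    coverage always matches within a record; a group with duplicated seasons
    (which would make coverage ambiguous) is skipped with a warning.
    """
    out: list[ComparisonRecord] = []
    groups: dict[tuple, list[ComparisonRecord]] = {}
    for r in records:
        if r.season == POOLED:
            out.append(r)  # already an among-season estimate
            continue
        key = (r.study_id, r.population_pair_id, r.trait)
        groups.setdefault(key, []).append(r)
    for key, group in groups.items():
        if len(group) < 2:
            continue
        seasons = [r.season for r in group]
        if len(set(seasons)) != len(seasons):
            logger.warning(
                "group %s has duplicated seasons %s; skipped", key, seasons
            )
            continue
        out.append(_pooled_record(group))
    return out
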