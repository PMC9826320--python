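"""Effect sizes for paired urban/non-urban comparisons.

Computes, from per-arm (mean, SD, n) summaries, the log response ratio
(lnRR; difference in means), the log coefficient-of-variation ratio (lnCVR;
difference in relative variability, accounting for the mean-variance
relationship), the log total variation ratio (lnVR; difference in SDs), and
a heteroscedastic standardized mean difference (SMDH), each with its
sampling variance. Also emits per-arm (lnSD, lnMean) rows for arm-based
models of phenotypic variation. The urban arm is always the numerator, so
positive values mean a higher estimate in the urban population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import pandas as pd

from urbanvar.data_model import ComparisonRecord

MEASURES = ("lnRR", "lnCVR", "lnVR", "SMDH")


@dataclass
class EffectSize:
    """A computed comparison statistic with sampling variance and grouping IDs."""

    record_id: str
    study_id: str
    population_pair_id: str
    species: str
    trait: str
    season: int | str
    measure: str
    yi: float
    vi: float
    effective_n: float
    publication_year: int


@dataclass
class ArmRow:
    """Per-habitat (lnSD, lnMean) observation for the arm-based lnSD model."""

    record_id: str
    study_id: str
    population_pair_id: str
    species: str
    trait: str
    habitat: str  # "urban" | "nonurban"
    ln_sd: float
    ln_mean: float
    v_ln_sd: float
    n: int


def effective_sample_size(n1: float, n2: float) -> float:
    """Two-group effective sample size, 4*n1*n2/(n1 + n2)."""
    return 4.0 * n1 * n2 / (n1 + n2)


def _check(record: ComparisonRecord, need_means: bool, need_sds: bool, need_n2: bool):
    if need_means and (record.mean_urban <= 0 or record.mean_nonurban <= 0):
        raise ValueError(
            f"record {record.record_id}: non-positive mean "
            f"({record.mean_urban}, {record.mean_nonurban})"
        )
    if need_sds and (record.sd_urban <= 0 or record.sd_nonurban <= 0):
        raise ValueError(
            f"record {record.record_id}: non-positive SD "
            f"({record.sd_urban}, {record.sd_nonurban})"
        )
    if need_n2 and (record.n_urban < 2 or record.n_nonurban < 2):
        raise ValueError(f"record {record.record_id}: sample size below 2")


def _make(record: ComparisonRecord, measure: str, yi: float, vi: float) -> EffectSize:
    return EffectSize(
        record_id=record.record_id,
        study_id=record.study_id,
        population_pair_id=record.population_pair_id,
        species=record.species,
        trait=record.trait,
        season=record.season,
        measure=measure,
        yi=yi,
        vi=vi,
        effective_n=effective_sample_size(record.n_urban, record.n_nonurban),
        publication_year=record.publication_year,
    )


def compute_lnRR(record: ComparisonRecord) -> EffectSize:
    """Log response ratio ln(mean_urban / mean_nonurban).

    The plain (uncorrected) log-ratio is used; its sampling variance is the
    delta-method form sd_u^2/(n_u mean_u^2) + sd_n^2/(n_n mean_n^2).
    """
    _check(record, need_means=True, need_sds=False, need_n2=False)
    mu, mn = record.mean_urban, record.mean_nonurban
    yi = math.log(mu / mn)
    vi = (
        record.sd_urban**2 / (record.n_urban * mu**2)
        + record.sd_nonurban**2 / (record.n_nonurban * mn**2)
    )
    return _make(record, "lnRR", yi, vi)


def compute_lnCVR(record: ComparisonRecord) -> EffectSize:
    """Log coefficient-of-variation ratio, with small-sample bias correction.

    yi = ln(CV_u / CV_n) + 1/(2(n_u - 1)) - 1/(2(n_n - 1)), where CV = SD/mean;
    vi sums the delta-method mean terms and the log-SD sampling terms. The
    mean-variance sampling correlation is treated as zero.
    """
    _check(record, need_means=True, need_sds=True, need_n2=True)
    mu, mn = record.mean_urban, record.mean_nonurban
    su, sn = record.sd_urban, record.sd_nonurban
    nu, nn = record.n_urban, record.n_nonurban
    yi = (
        math.log((su / mu) / (sn / mn))
        + 1.0 / (2.0 * (nu - 1))
        - 1.0 / (2.0 * (nn - 1))
    )
    vi = (
        su**2 / (nu * mu**2)
        + 1.0 / (2.0 * (nu - 1))
        + sn**2 / (nn * mn**2)
        + 1.0 / (2.0 * (nn - 1))
    )
    return _make(record, "lnCVR", yi, vi)


def compute_lnVR(record: ComparisonRecord) -> EffectSize:
    """Log total variation ratio ln(sd_urban / sd_nonurban), bias-corrected."""
    _check(record, need_means=False, need_sds=True, need_n2=True)
    su, sn = record.sd_urban, record.sd_nonurban
    nu, nn = record.n_urban, record.n_nonurban
    yi = math.log(su / sn) + 1.0 / (2.0 * (nu - 1)) - 1.0 / (2.0 * (nn - 1))
    vi = 1.0 / (2.0 * (nu - 1)) + 1.0 / (2.0 * (nn - 1))
    return _make(record, "lnVR", yi, vi)


def compute_SMDH(record: ComparisonRecord) -> EffectSize:
    """Standardized mean difference allowing heteroscedastic arm variances.

    d = (mean_u - mean_n) / s with s^2 = (sd_u^2 + sd_n^2)/2, multiplied by
    the exact small-sample correction
    c(m) = Gamma(m/2) / (sqrt(m/2) Gamma((m-1)/2)), m = n_u + n_n - 2,
    with the matching large-sample heteroscedastic sampling variance.
    """
    from scipy.special import gammaln

    _check(record, need_means=False, need_sds=True, need_n2=True)
    mu, mn = record.mean_urban, record.mean_nonurban
    su, sn = record.sd_urban, record.sd_nonurban
    nu, nn = record.n_urban, record.n_nonurban
    sp2 = (su**2 + sn**2) / 2.0
    sp = math.sqrt(sp2)
    m = nu + nn - 2
    cm = math.exp(gammaln(m / 2.0) - gammaln((m - 1) / 2.0)) / math.sqrt(m / 2.0)
    yi = cm * (mu - mn) / sp
    vi = (
        yi**2 * (su**4 / (nu - 1) + sn**4 / (nn - 1)) / (8.0 * sp2**2)
        + (su**2 / (nu - 1) + sn**2 / (nn - 1)) / sp2
    )
    return _make(record, "SMDH", yi, vi)


_COMPUTE = {
    "lnRR": compute_lnRR,
    "lnCVR": compute_lnCVR,
    "lnVR": compute_lnVR,
    "SMDH": compute_SMDH,
}


def compute_effects(
    records: Iterable[ComparisonRecord], measure: str
) -> list[EffectSize]:
    """Vector version of the per-record effect-size computations."""
    if measure not in _COMPUTE:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    fn = _COMPUTE[measure]
    return [fn(r) for r in records]


def arm_rows(record: ComparisonRecord) -> tuple[ArmRow, ArmRow]:
    """Per-arm (lnSD, lnMean) rows; sampling variance of lnSD is 1/(2(n-1))."""
    _check(record, need_means=True, need_sds=True, need_n2=True)
    out = []
    for habitat, mean, sd, n in (
        ("urban", record.mean_urban, record.sd_urban, record.n_urban),
        ("nonurban", record.mean_nonurban, record.sd_nonurban, record.n_nonurban),
    ):
        out.append(
            ArmRow(
                record_id=record.record_id,
                study_id=record.study_id,
                population_pair_id=record.population_pair_id,
                species=record.species,
                trait=record.trait,
                habitat=habitat,
                ln_sd=math.log(sd),
                ln_mean=math.log(mean),
                v_ln_sd=1.0 / (2.0 * (n - 1)),
                n=int(n),
            )
        )
    return out[0], out[1]


def percent_difference(yi: float) -> float:
    """Back-transform a log-ratio to a percent difference in magnitude.

    Returns 100 * (exp(|yi|) - 1): the percent by which the larger arm
    exceeds the smaller one. The direction is carried by the sign of ``yi``
    itself (positive = urban larger); use :func:`math.copysign` if a signed
    percent is needed.
    """
    if not math.isfinite(yi):
        raise ValueError(f"yi must be finite (got {yi})")
    return 100.0 * (math.exp(abs(yi)) - 1.0)


def effects_to_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in effects])


def write_effects(effects: Sequence[EffectSize], path) -> None:
    effects_to_frame(effects).to_csv(path, index=False, float_format="%.17g")
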