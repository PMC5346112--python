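"""Interlaboratory variability metrics.

The comparability metric of the scheme is the per-collective coefficient of
variation (CV), computed on the linear kU/L scale with the n-1 sample
standard deviation, and judged against a 20 % quality mark.  Saturation
censoring (results piled up at a device's highest calibration point)
mechanically collapses the CV toward 0, so the saturated fraction is
reported alongside each CV.

Also here: dilution-linearity recovery, per-manufacturer timelines across
surveys, and a geometric-mean estimator of each manufacturer's relative
bias against the all-participant consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import OTHER_CODE, form_collectives

__all__ = [
    "DispersionError",
    "DispersionRecord",
    "compute_cv",
    "flag_quality",
    "saturated_fraction",
    "dilution_recovery",
    "dispersion_table",
    "build_timeline",
    "recover_bias",
    "QUALITY_MARK_PCT",
]

#: Critical interlaboratory-comparability quality mark, in percent CV.
QUALITY_MARK_PCT = 20.0


class DispersionError(ValueError):
    """Raised for undefined dispersion statistics."""


@dataclass
class DispersionRecord:
    """Per-collective dispersion summary for one survey/analyte/sample."""

    survey_id: str
    analyte: str
    sample_id: str
    manufacturer_code: str
    n: int
    cv_pct: float
    saturated_fraction: float
    exceeds_quality_mark: bool


def compute_cv(values: Sequence[float] | pd.Series) -> float:
    """Coefficient of variation in percent, on the linear kU/L scale.

    ``100 * sd / mean`` with the n-1 (sample) standard deviation and the
    arithmetic mean.  Constant inputs give exactly 0; values above 100 %
    are reported as-is.

    Raises
    ------
    DispersionError
        If fewer than two values are given, or the mean is zero.
    """
    arr = np.asarray(pd.Series(values, dtype=float).dropna(), dtype=float)
    if arr.size < 2:
        raise DispersionError(f"CV needs at least 2 values, got {arr.size}")
    mean = float(np.mean(arr))
    if mean == 0.0:
        raise DispersionError("CV undefined: mean is zero")
    return 100.0 * float(np.std(arr, ddof=1)) / mean


def flag_quality(cv_pct: float, mark: float = QUALITY_MARK_PCT) -> bool:
    """True iff the CV strictly exceeds the quality mark (20 % keeps)."""
    return bool(cv_pct > mark)


def saturated_fraction(
    values: Sequence[float] | pd.Series,
    top_calibration: float,
    rel_tol: float = 1e-9,
) -> float:
    """Fraction of values at (within ``rel_tol``) or above the saturation point."""
    if top_calibration <= 0:
        raise DispersionError(
            f"top_calibration must be positive, got {top_calibration}"
        )
    arr = np.asarray(pd.Series(values, dtype=float).dropna(), dtype=float)
    if arr.size == 0:
        return 0.0
    at_top = arr >= top_calibration * (1.0 - rel_tol)
    return float(np.count_nonzero(at_top)) / float(arr.size)


def dilution_recovery(
    concentrated_median: float, diluted_median: float, dilution_factor: float
) -> float:
    """Linearity diagnostic for a (parent, dilution) sample pair.

    ``recovery = diluted_median * dilution_factor / concentrated_median``;
    1.0 means the diluted sample recovers the parent exactly.  Recovery
    above 1 is the signature of a saturation-censored parent.
    """
    for name, v in (
        ("concentrated_median", concentrated_median),
        ("diluted_median", diluted_median),
        ("dilution_factor", dilution_factor),
    ):
        if not v > 0:
            raise DispersionError(f"{name} must be positive, got {v}")
    return diluted_median * dilution_factor / concentrated_median


def dispersion_table(
    results: pd.DataFrame,
    device_profiles: Optional[dict] = None,
    *,
    min_size: int = 4,
    mark: float = QUALITY_MARK_PCT,
) -> pd.DataFrame:
    """Per-collective CV table across one or many surveys.

    Forms collectives per (survey, analyte, sample) from already
    outlier-filtered concentration results and reports n, CV %, saturated
    fraction (0 when no device profile is supplied for the code) and the
    quality flag.  Collectives too small for a CV get ``cv_pct = NaN``.
    """
    rows = []
    with_conc = results[results["concentration_ku_l"].notna()]
    for survey_id, survey_group in with_conc.groupby("survey_id", sort=True):
        for coll in form_collectives(survey_group, min_size=min_size):
            vals = coll.members["concentration_ku_l"]
            try:
                cv = compute_cv(vals)
            except DispersionError:
                cv = np.nan
            sat = 0.0
            if device_profiles is not None and coll.manufacturer_code in device_profiles:
                sat = saturated_fraction(
                    vals, device_profiles[coll.manufacturer_code].top_calibration
                )
            rows.append(
                {
                    "survey_id": survey_id,
                    "analyte": coll.analyte,
                    "sample_id": coll.sample_id,
                    "manufacturer_code": coll.manufacturer_code,
                    "n": coll.n,
                    "cv_pct": cv,
                    "saturated_fraction": sat,
                    "exceeds_quality_mark": bool(np.nan_to_num(cv) > mark)
                    if pd.notna(cv)
                    else False,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "survey_id",
            "analyte",
            "sample_id",
            "manufacturer_code",
            "n",
            "cv_pct",
            "saturated_fraction",
            "exceeds_quality_mark",
        ],
    )


def build_timeline(
    records: pd.DataFrame,
    survey_dates: dict[str, str],
) -> pd.DataFrame:
    """Chronological series per (manufacturer, analyte, sample).

    ``records`` needs columns survey_id / analyte / sample_id /
    manufacturer_code plus the per-survey statistics to carry along
    (e.g. ``consensus_median``, ``cv_pct``).  ``survey_dates`` maps survey
    id to an ISO "YYYY-MM" month used for ordering.  Surveys a manufacturer
    missed are simply absent - gaps are never interpolated.

    Raises
    ------
    DispersionError
        If a (manufacturer, analyte, sample, survey) combination occurs
        twice (the series would be ambiguous), or a survey has no date.
    """
    missing = set(records["survey_id"]) - set(survey_dates)
    if missing:
        raise DispersionError(
            "no date for survey id(s): " + ", ".join(sorted(map(str, missing)))
        )
    keys = ["manufacturer_code", "analyte", "sample_id", "survey_id"]
    dup = records.duplicated(subset=keys)
    if dup.any():
        first = records.loc[dup, keys].iloc[0].to_dict()
        raise DispersionError(f"duplicate timeline entry: {first}")
    out = records.copy()
    out["date"] = out["survey_id"].map(survey_dates)
    out = out.sort_values(
        ["manufacturer_code", "analyte", "sample_id", "date", "survey_id"],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def recover_bias(
    timeline: pd.DataFrame,
    *,
    reference: str = "pooled",
) -> pd.DataFrame:
    """Estimate each manufacturer's relative bias from its timeline.

    For every survey shared with the all-participant pooled consensus, the
    ratio ``collective_median / pooled_median`` is formed; the bias
    estimate is the geometric mean of those per-survey ratios and the
    constancy statistic is the CV (in %) of the ratios - small when a
    manufacturer's offset is stable over time.

    ``timeline`` needs columns manufacturer_code / analyte / sample_id /
    survey_id / consensus_median, with the pooled all-participant series
    under ``manufacturer_code == reference``.

    Raises
    ------
    DispersionError
        If a manufacturer shares fewer than two surveys with the pooled
        reference series.
    """
    pooled = timeline[timeline["manufacturer_code"] == reference]
    if pooled.empty:
        raise DispersionError(f"no reference series {reference!r} in timeline")
    pooled_idx = pooled.set_index(["analyte", "sample_id", "survey_id"])[
        "consensus_median"
    ]
    rows = []
    others = timeline[timeline["manufacturer_code"] != reference]
    for (code, analyte, sample_id), sub in others.groupby(
        ["manufacturer_code", "analyte", "sample_id"], sort=True
    ):
        ratios = []
        for _, r in sub.iterrows():
            key = (analyte, sample_id, r["survey_id"])
            if key in pooled_idx.index:
                denom = pooled_idx.loc[key]
                if pd.notna(denom) and denom > 0 and pd.notna(r["consensus_median"]):
                    ratios.append(float(r["consensus_median"]) / float(denom))
        if len(ratios) < 2:
            raise DispersionError(
                f"insufficient overlap for {code!r}/{analyte!r}/{sample_id!r}: "
                f"{len(ratios)} shared survey(s), need >= 2"
            )
        ratios_arr = np.asarray(ratios)
        rows.append(
            {
                "manufacturer_code": code,
                "analyte": analyte,
                "sample_id": sample_id,
                "n_surveys": len(ratios),
                "bias_estimate": float(np.exp(np.mean(np.log(ratios_arr)))),
                "constancy_cv_pct": compute_cv(ratios_arr),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "manufacturer_code",
            "analyte",
            "sample_id",
            "n_surveys",
            "bias_estimate",
            "constancy_cv_pct",
        ],
    )
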