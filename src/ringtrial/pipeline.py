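"""End-to-end evaluation pipeline over a tidy participant-result table.

Glues the stages together in the order the scheme prescribes - outlier
exclusion, collective formation, consensus-median scoring on both scales,
certificates, per-collective dispersion, consensus timelines and bias
recovery - and returns every intermediate table so drivers, tests and
reports all see the same objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .dispersion import build_timeline, dispersion_table, recover_bias
from .evaluation import (
    certificates,
    consensus_median,
    evaluate_class_results,
    evaluate_concentrations,
    filter_outliers,
    form_collectives,
    pass_rate,
)
from .panel_model import DeviceProfile

__all__ = ["EvaluationRun", "run_evaluation", "consensus_timeline_records"]

#: Reference code used for the all-participant pooled series in timelines.
POOLED_CODE = "pooled"


@dataclass
class EvaluationRun:
    """All tables produced by one pipeline run."""

    included: pd.DataFrame
    excluded: pd.DataFrame
    outcomes_concentration: pd.DataFrame
    outcomes_class: pd.DataFrame
    certificates: pd.DataFrame
    dispersion: pd.DataFrame

    @property
    def outcomes(self) -> pd.DataFrame:
        frames = [self.outcomes_concentration, self.outcomes_class]
        frames = [f for f in frames if not f.empty]
        if not frames:
            return self.outcomes_concentration
        return pd.concat(frames, ignore_index=True)

    def pass_rate(self, scale: Optional[str] = None) -> float:
        out = self.outcomes
        if scale is not None:
            out = out[out["scale"] == scale]
        return pass_rate(out)


def run_evaluation(
    results: pd.DataFrame,
    device_profiles: Mapping[str, DeviceProfile],
    *,
    min_size: int = 4,
    band: float = 0.25,
    quality_mark: float = 20.0,
    relevance_ranges: Optional[Mapping[tuple[str, str], tuple[float, float]]] = None,
) -> EvaluationRun:
    """Run the full scoring pipeline on one or many surveys at once."""
    included, excluded = filter_outliers(results, device_profiles)

    conc_frames, class_frames = [], []
    if not included.empty:
        for _, survey_group in included.groupby("survey_id", sort=True):
            conc_frames.append(
                evaluate_concentrations(
                    survey_group,
                    min_size=min_size,
                    band=band,
                    relevance_ranges=relevance_ranges,
                )
            )
            class_frames.append(
                evaluate_class_results(survey_group, min_size=min_size, band=band)
            )
    from .evaluation import OUTCOME_COLUMNS

    conc = (
        pd.concat(conc_frames, ignore_index=True)
        if conc_frames
        else pd.DataFrame(columns=OUTCOME_COLUMNS)
    )
    cls = (
        pd.concat(class_frames, ignore_index=True)
        if class_frames
        else pd.DataFrame(columns=OUTCOME_COLUMNS)
    )
    all_outcomes = (
        pd.concat([f for f in (conc, cls) if not f.empty], ignore_index=True)
        if not (conc.empty and cls.empty)
        else conc
    )
    certs = (
        certificates(all_outcomes)
        if not all_outcomes.empty
        else pd.DataFrame(
            columns=["survey_id", "participant_id", "n_evaluable", "n_passed", "overall"]
        )
    )
    disp = dispersion_table(
        included, dict(device_profiles), min_size=min_size, mark=quality_mark
    )
    return EvaluationRun(
        included=included,
        excluded=excluded,
        outcomes_concentration=conc,
        outcomes_class=cls,
        certificates=certs,
        dispersion=disp,
    )


def consensus_timeline_records(
    included: pd.DataFrame,
    survey_dates: Mapping[str, str],
    *,
    min_size: int = 4,
) -> pd.DataFrame:
    """Per-survey consensus medians per collective plus the pooled series.

    For every (survey, analyte, sample): one row per manufacturer
    collective with its consensus median and CV, and one ``"pooled"`` row
    holding the median over ALL included participants - the reference
    series :func:`ringtrial.dispersion.recover_bias` divides by.
    Chronologically ordered via :func:`ringtrial.dispersion.build_timeline`.
    """
    rows = []
    with_conc = included[included["concentration_ku_l"].notna()]
    for survey_id, survey_group in with_conc.groupby("survey_id", sort=True):
        for (analyte, sample_id), group in survey_group.groupby(
            ["analyte", "sample_id"], sort=True
        ):
            pooled_vals = group["concentration_ku_l"]
            rows.append(
                {
                    "survey_id": survey_id,
                    "analyte": analyte,
                    "sample_id": sample_id,
                    "manufacturer_code": POOLED_CODE,
                    "n": len(pooled_vals),
                    "consensus_median": consensus_median(pooled_vals),
                    "cv_pct": _safe_cv(pooled_vals),
                }
            )
            for coll in form_collectives(group, min_size=min_size):
                vals = coll.members["concentration_ku_l"]
                rows.append(
                    {
                        "survey_id": survey_id,
                        "analyte": analyte,
                        "sample_id": sample_id,
                        "manufacturer_code": coll.manufacturer_code,
                        "n": coll.n,
                        "consensus_median": consensus_median(vals),
                        "cv_pct": _safe_cv(vals),
                    }
                )
    records = pd.DataFrame(
        rows,
        columns=[
            "survey_id",
            "analyte",
            "sample_id",
            "manufacturer_code",
            "n",
            "consensus_median",
            "cv_pct",
        ],
    )
    return build_timeline(records, dict(survey_dates))


def _safe_cv(values) -> float:
    from .dispersion import DispersionError, compute_cv

    try:
        return compute_cv(values)
    except DispersionError:
        return float("nan")
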