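"""Human-readable run summary: pass rates, CV tables, exclusions, roster."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .evaluation import EvaluationError, pass_rate
from .pipeline import EvaluationRun

__all__ = ["render_report", "cv_wide_table"]


def cv_wide_table(dispersion: pd.DataFrame, *, mark: float = 20.0) -> pd.DataFrame:
    """Pivot the dispersion table: rows = surveys, columns = manufacturer x sample.

    CVs that exceed the quality mark carry a ``*`` marker in a plain-text
    annotation (e.g. ``"35.2*"``), mirroring the bold highlighting used in
    printed CV tables.
    """
    if dispersion.empty:
        return pd.DataFrame()
    d = dispersion.copy()
    d["cell"] = d["cv_pct"].map(
        lambda v: "" if pd.isna(v) else f"{v:.1f}" + ("*" if v > mark else "")
    )
    wide = d.pivot_table(
        index="survey_id",
        columns=["analyte", "manufacturer_code", "sample_id"],
        values="cell",
        aggfunc="first",
    )
    return wide.sort_index()


def render_report(run: EvaluationRun, *, mark: float = 20.0) -> str:
    """Assemble the full text report for one evaluation run."""
    lines: list[str] = []
    push = lines.append
    push("=== Ring-trial evaluation report ===")
    push("")

    outcomes = run.outcomes
    n_results = len(run.included) + len(run.excluded)
    push(f"results read:      {n_results}")
    push(f"included:          {len(run.included)}")
    push(f"excluded outliers: {len(run.excluded)}")
    push("")

    if outcomes.empty or not outcomes["evaluable"].any():
        push("zero evaluable results — no pass rates to report")
        push("")
    else:
        push("--- pass rates ---")
        for scale, sub in outcomes.groupby("scale", sort=True):
            try:
                push(f"overall [{scale}]: {pass_rate(sub):.1f} %")
            except EvaluationError:
                push(f"overall [{scale}]: unevaluable")
        for survey_id, sub in outcomes.groupby("survey_id", sort=True):
            try:
                push(f"survey {survey_id}: {pass_rate(sub):.1f} %")
            except EvaluationError:
                push(f"survey {survey_id}: unevaluable")
        push("")

    if not run.dispersion.empty:
        push(f"--- per-collective CV [%] ('*' = above the {mark:g} % quality mark) ---")
        push(cv_wide_table(run.dispersion, mark=mark).to_string())
        flagged = run.dispersion[run.dispersion["exceeds_quality_mark"]]
        push(f"collectives above the quality mark: {len(flagged)} of {len(run.dispersion)}")
        push("")

    push("--- exclusion log ---")
    if run.excluded.empty:
        push("no exclusions")
    else:
        cols = [
            "survey_id", "participant_id", "manufacturer_code", "analyte",
            "sample_id", "exclusion_reason",
        ]
        push(run.excluded[cols].to_string(index=False))
    push("")

    push("--- certificate roster ---")
    if run.certificates.empty:
        push("no certificates (nothing evaluable)")
    else:
        counts = run.certificates["overall"].value_counts().to_dict()
        push(
            "participants: "
            + ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
        )
        push(run.certificates.to_string(index=False))
    push("")
    return "\n".join(lines)
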