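"""Consensus-median scoring of ring-trial results.

The evaluation scheme, per survey / analyte / sample:

1. Exclude transfer-error outliers: a concentration more than 20 % above
   the reporting device's highest calibration point, or a class more than
   0.5 above its class ceiling.
2. Sort the remaining participants into manufacturer "collectives"; any
   manufacturer with fewer than four participants goes into a pooled
   "other" collective.
3. Each collective is scored against its own consensus median: a
   participant passes when the reported value lies within +/-25 % of that
   median (boundary inclusive).
4. Allergen-class results are by default scored against one pooled median
   over ALL participants; only a collective whose results lie in a
   completely different range receives its own class median.
5. A participant passing every evaluable analyte/sample receives a
   certificate for the survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panel_model import DeviceProfile

__all__ = [
    "OTHER_CODE",
    "Collective",
    "EvaluationError",
    "EmptyCollectiveError",
    "DegenerateConsensusError",
    "filter_outliers",
    "form_collectives",
    "consensus_median",
    "score_participant",
    "score_collective",
    "evaluate_concentrations",
    "evaluate_class_results",
    "default_divergence_rule",
    "certificate",
    "certificates",
    "pass_rate",
]

#: Label of the pooled collective for manufacturers below the size threshold.
OTHER_CODE = "other"

OUTCOME_COLUMNS = [
    "survey_id",
    "participant_id",
    "manufacturer_code",
    "analyte",
    "sample_id",
    "scale",
    "collective_code",
    "value",
    "consensus_median",
    "deviation_pct",
    "included",
    "evaluable",
    "passed",
]


class EvaluationError(ValueError):
    """Base class for scoring-stage errors."""


class EmptyCollectiveError(EvaluationError):
    """A consensus median was requested from a collective with no usable values."""


class DegenerateConsensusError(EvaluationError):
    """The consensus median is non-positive; relative scoring is undefined."""


@dataclass
class Collective:
    """A per-manufacturer evaluation group for one (analyte, sample).

    ``members`` holds the included result rows; the consensus median and the
    +/-25 % pass band are filled in by :func:`score_collective`.
    """

    manufacturer_code: str
    analyte: str
    sample_id: str
    members: pd.DataFrame
    consensus_median: Optional[float] = None
    pass_band: Optional[tuple[float, float]] = None

    @property
    def n(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Stage 1: outlier exclusion
# ---------------------------------------------------------------------------

def filter_outliers(
    results: pd.DataFrame,
    device_profiles: Mapping[str, DeviceProfile],
    *,
    concentration_margin: float = 0.20,
    class_margin: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split results into (included, excluded) by the transfer-error rule.

    A row is excluded when its concentration exceeds the device's highest
    calibration point by MORE than ``concentration_margin`` (strict: exactly
    +20 % is kept), or its reported class exceeds the class ceiling by more
    than ``class_margin`` classes.  Excluded rows get an ``exclusion_reason``
    column; included rows pass through unchanged.

    Raises
    ------
    KeyError
        If a manufacturer code in ``results`` has no device profile.
    """
    if results.empty:
        empty = results.copy()
        excluded = results.copy()
        excluded["exclusion_reason"] = pd.Series(dtype=str)
        return empty, excluded

    missing = set(results["manufacturer_code"]) - set(device_profiles)
    if missing:
        raise KeyError(
            "no DeviceProfile for manufacturer code(s): "
            + ", ".join(sorted(map(str, missing)))
        )

    top_cal = results["manufacturer_code"].map(
        {c: p.top_calibration for c, p in device_profiles.items()}
    )
    top_class = results["manufacturer_code"].map(
        {c: p.top_class for c, p in device_profiles.items()}
    )

    conc = results["concentration_ku_l"]
    cls = results["allergen_class"]
    conc_out = conc.notna() & (conc > (1.0 + concentration_margin) * top_cal)
    class_out = cls.notna() & (cls > top_class + class_margin)

    mask = conc_out | class_out
    reasons = []
    for idx in results.index[mask]:
        parts = []
        if conc_out.loc[idx]:
            parts.append(
                f"concentration {conc.loc[idx]:g} kU/L exceeds top calibration "
                f"{top_cal.loc[idx]:g} kU/L by more than {concentration_margin:.0%}"
            )
        if class_out.loc[idx]:
            parts.append(
                f"class {cls.loc[idx]:g} exceeds class ceiling "
                f"{top_class.loc[idx]:g} by more than {class_margin:g}"
            )
        reasons.append("; ".join(parts))
    included = results.loc[~mask].copy()
    excluded = results.loc[mask].copy()
    excluded["exclusion_reason"] = reasons
    return included, excluded


# ---------------------------------------------------------------------------
# Stage 2: collective formation
# ---------------------------------------------------------------------------

def form_collectives(
    results: pd.DataFrame, min_size: int = 4
) -> list[Collective]:
    """Group outlier-filtered results into manufacturer collectives.

    Within each (analyte, sample_id) group, every manufacturer with at
    least ``min_size`` participants forms its own collective; all smaller
    manufacturer groups are pooled into a single ``"other"`` collective.
    Every input row lands in exactly one collective.
    """
    collectives: list[Collective] = []
    if results.empty:
        return collectives
    for (analyte, sample_id), group in results.groupby(
        ["analyte", "sample_id"], sort=True
    ):
        small_parts: list[pd.DataFrame] = []
        for code, sub in group.groupby("manufacturer_code", sort=True):
            if len(sub) >= min_size:
                collectives.append(
                    Collective(str(code), str(analyte), str(sample_id), sub.copy())
                )
            else:
                small_parts.append(sub)
        if small_parts:
            pooled = pd.concat(small_parts)
            collectives.append(
                Collective(OTHER_CODE, str(analyte), str(sample_id), pooled.copy())
            )
    return collectives


# ---------------------------------------------------------------------------
# Stage 3: consensus median and pass/fail
# ---------------------------------------------------------------------------

def consensus_median(
    values: Sequence[float] | pd.Series,
    relevance_range: Optional[tuple[float, float]] = None,
) -> float:
    """Median of a collective's concentrations, optionally range-restricted.

    ``relevance_range`` is an explicit, evaluator-supplied [lo, hi]
    clinically-relevant window (both ends inclusive); values outside it do
    not enter the median.  Even counts use the midpoint of the two central
    values.

    Raises
    ------
    EmptyCollectiveError
        If no usable (non-NaN, in-range) value remains.
    """
    arr = np.asarray(pd.Series(values, dtype=float).dropna(), dtype=float)
    if relevance_range is not None:
        lo, hi = relevance_range
        arr = arr[(arr >= lo) & (arr <= hi)]
    if arr.size == 0:
        raise EmptyCollectiveError("no usable values to form a consensus median")
    return float(np.median(arr))


def score_participant(
    value: float, consensus: float, band: float = 0.25
) -> tuple[float, bool]:
    """Score one reported value against a consensus median.

    Returns ``(deviation_pct, passed)`` with
    ``deviation_pct = 100 * (value - consensus) / consensus`` and
    ``passed`` true iff ``|deviation_pct| <= 100 * band`` (exactly +/-25 %
    still passes).

    Raises
    ------
    DegenerateConsensusError
        If ``consensus`` is not positive (relative deviation undefined).
    """
    if not consensus > 0:
        raise DegenerateConsensusError(
            f"consensus median must be positive for relative scoring, got {consensus}"
        )
    deviation_pct = 100.0 * (float(value) - consensus) / consensus
    return deviation_pct, bool(abs(deviation_pct) <= 100.0 * band + 1e-12)


def score_collective(
    collective: Collective,
    *,
    value_column: str = "concentration_ku_l",
    scale_label: str = "kU/L",
    band: float = 0.25,
    relevance_range: Optional[tuple[float, float]] = None,
    consensus: Optional[float] = None,
    collective_code: Optional[str] = None,
) -> pd.DataFrame:
    """Score every member of a collective; returns outcome rows.

    When ``consensus`` is given (class evaluation against a pooled median)
    it overrides the collective's own median.  A non-positive or missing
    consensus marks all members unevaluable rather than failing them.
    """
    members = collective.members
    values = members[value_column]
    code = collective_code if collective_code is not None else collective.manufacturer_code

    try:
        med = (
            consensus
            if consensus is not None
            else consensus_median(values, relevance_range)
        )
        if not med > 0:
            raise DegenerateConsensusError(str(med))
        evaluable = True
    except (EmptyCollectiveError, DegenerateConsensusError):
        med = np.nan
        evaluable = False

    collective.consensus_median = None if not evaluable else float(med)
    collective.pass_band = (
        None if not evaluable else (0.75 * float(med), 1.25 * float(med))
    )

    rows = []
    for _, r in members.iterrows():
        v = r[value_column]
        if evaluable and pd.notna(v):
            dev, ok = score_participant(float(v), float(med), band)
            row_eval = True
        else:
            dev, ok, row_eval = np.nan, False, False
        rows.append(
            {
                "survey_id": r["survey_id"],
                "participant_id": r["participant_id"],
                "manufacturer_code": r["manufacturer_code"],
                "analyte": collective.analyte,
                "sample_id": collective.sample_id,
                "scale": scale_label,
                "collective_code": code,
                "value": v,
                "consensus_median": med,
                "deviation_pct": dev,
                "included": True,
                "evaluable": row_eval,
                "passed": ok,
            }
        )
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


def evaluate_concentrations(
    results: pd.DataFrame,
    *,
    min_size: int = 4,
    band: float = 0.25,
    relevance_ranges: Optional[Mapping[tuple[str, str], tuple[float, float]]] = None,
) -> pd.DataFrame:
    """Concentration (kU/L) scoring: per-collective medians, +/-25 % band.

    ``relevance_ranges`` maps (analyte, sample_id) to an explicit
    clinically-relevant [lo, hi] window; the default applies none.
    Returns one outcome row per included result with a concentration.
    """
    frames = []
    with_conc = results[results["concentration_ku_l"].notna()]
    for coll in form_collectives(with_conc, min_size=min_size):
        rng = None
        if relevance_ranges is not None:
            rng = relevance_ranges.get((coll.analyte, coll.sample_id))
        frames.append(
            score_collective(coll, band=band, relevance_range=rng)
        )
    if not frames:
        return pd.DataFrame(columns=OUTCOME_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Stage 4: class evaluation with the separate-median rule
# ---------------------------------------------------------------------------

def default_divergence_rule(
    collective_classes: np.ndarray,
    other_classes: np.ndarray,
    *,
    min_gap: float = 2.0,
    percentiles: tuple[float, float] = (10.0, 90.0),
) -> bool:
    """Is a collective's class range "completely different" from the rest?

    True when the collective's class median differs from the median of all
    OTHER participants by at least ``min_gap`` classes AND the two 10-90
    percentile ranges do not overlap AND the collective is the minority
    side (the majority of participants defines the "general" range a
    collective can diverge from).  Conservative on purpose: class results
    are normally comparable across manufacturers, so a separate median is
    the exception.
    """
    if collective_classes.size == 0 or other_classes.size == 0:
        return False
    if collective_classes.size >= other_classes.size:
        return False
    gap = abs(np.median(collective_classes) - np.median(other_classes))
    if gap < min_gap:
        return False
    lo, hi = percentiles
    c_lo, c_hi = np.percentile(collective_classes, [lo, hi])
    o_lo, o_hi = np.percentile(other_classes, [lo, hi])
    return bool(c_hi < o_lo or o_hi < c_lo)


def evaluate_class_results(
    results: pd.DataFrame,
    *,
    min_size: int = 4,
    band: float = 0.25,
    divergence_rule: Callable[[np.ndarray, np.ndarray], bool] = default_divergence_rule,
) -> pd.DataFrame:
    """Allergen-class scoring with one pooled median over all participants.

    Per (analyte, sample): by default every participant is scored against
    the pooled class median of the whole survey group.  A manufacturer
    collective flagged by ``divergence_rule`` (its results lie in a
    completely different range) is instead scored against its own class
    median.  Scoring itself is the same relative +/-25 % band on the class
    scale; a zero pooled median makes the group unevaluable.
    """
    frames = []
    with_cls = results[results["allergen_class"].notna()]
    if with_cls.empty:
        return pd.DataFrame(columns=OUTCOME_COLUMNS)
    for (analyte, sample_id), group in with_cls.groupby(
        ["analyte", "sample_id"], sort=True
    ):
        all_cls = group["allergen_class"].to_numpy(dtype=float)
        collectives = form_collectives(group, min_size=min_size)
        divergent: set[str] = set()
        for coll in collectives:
            if coll.manufacturer_code == OTHER_CODE:
                continue
            mine = coll.members["allergen_class"].to_numpy(dtype=float)
            rest = group.loc[
                group["manufacturer_code"] != coll.manufacturer_code,
                "allergen_class",
            ].to_numpy(dtype=float)
            if divergence_rule(mine, rest):
                divergent.add(coll.manufacturer_code)

        pooled_values = group.loc[
            ~group["manufacturer_code"].isin(divergent), "allergen_class"
        ]
        try:
            pooled = consensus_median(pooled_values)
        except EmptyCollectiveError:
            pooled = np.nan

        for coll in collectives:
            if coll.manufacturer_code in divergent:
                frames.append(
                    score_collective(
                        coll,
                        value_column="allergen_class",
                        scale_label="class",
                        band=band,
                    )
                )
            else:
                frames.append(
                    score_collective(
                        coll,
                        value_column="allergen_class",
                        scale_label="class",
                        band=band,
                        consensus=pooled,
                        collective_code="pooled",
                    )
                )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Stage 5: certificates and pass rates
# ---------------------------------------------------------------------------

def certificate(outcomes: pd.DataFrame, *, policy: str = "all") -> dict:
    """Pass/fail summary for ONE participant in one survey.

    Returns per-analyte flags plus an overall verdict.  Under the default
    ``"all"`` policy the participant passes when every evaluable outcome
    passed; with no evaluable outcome the certificate is ``"unevaluable"``
    rather than a failure.
    """
    if policy not in ("all",):
        raise ValueError(f"unknown certificate policy {policy!r}")
    evaluable = outcomes[outcomes["evaluable"]]
    per_analyte = {}
    for analyte, sub in evaluable.groupby("analyte", sort=True):
        per_analyte[str(analyte)] = {
            "n_evaluable": int(len(sub)),
            "n_passed": int(sub["passed"].sum()),
            "passed": bool(sub["passed"].all()),
        }
    if evaluable.empty:
        overall = "unevaluable"
    else:
        overall = "pass" if bool(evaluable["passed"].all()) else "fail"
    return {"per_analyte": per_analyte, "overall": overall}


def certificates(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Certificate roster: one row per (survey, participant)."""
    rows = []
    for (survey_id, pid), sub in outcomes.groupby(
        ["survey_id", "participant_id"], sort=True
    ):
        cert = certificate(sub)
        rows.append(
            {
                "survey_id": survey_id,
                "participant_id": pid,
                "n_evaluable": int(sub["evaluable"].sum()),
                "n_passed": int(sub.loc[sub["evaluable"], "passed"].sum()),
                "overall": cert["overall"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["survey_id", "participant_id", "n_evaluable", "n_passed", "overall"],
    )


def pass_rate(outcomes: pd.DataFrame) -> float:
    """Percentage of evaluable outcomes that passed.

    Raises
    ------
    EvaluationError
        If there is no evaluable outcome (the rate is undefined).
    """
    evaluable = outcomes[outcomes["evaluable"]]
    if evaluable.empty:
        raise EvaluationError("pass rate undefined: no evaluable outcomes")
    return 100.0 * float(evaluable["passed"].sum()) / float(len(evaluable))
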