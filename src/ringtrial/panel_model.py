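"""Core domain model for a ring-trial serum panel.

A survey (one ring-trial instance) distributes a small panel of lyophilized
serum samples to every participating laboratory.  In the default
configuration a panel holds five samples: three undiluted sera with high
specific-IgE (sIgE) levels, and two dilutions prepared from two of those
sera.  One sample role is reserved for total IgE, which this package does
not evaluate.

Concentrations are reported in kU/L.  Alongside the semiquantitative
concentration, laboratories report an ordinal allergen (RAST) class 0-6;
class 0 (< 0.35 kU/L) is the conventional negative / non-sensitized result.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "SampleRole",
    "SampleSpec",
    "SurveyPanel",
    "DeviceProfile",
    "ClassScale",
    "DEFAULT_CLASS_SCALE",
    "to_allergen_class",
    "validate_panel",
    "RESULT_COLUMNS",
]

#: Column contract for a tidy participant-result table (CSV header order).
RESULT_COLUMNS = [
    "survey_id",
    "participant_id",
    "manufacturer_code",
    "analyte",
    "sample_id",
    "concentration_ku_l",
    "allergen_class",
]


class SampleRole:
    """Sample roles within a panel (plain string constants)."""

    HIGH = "high"
    DILUTION = "dilution"
    TOTAL_IGE = "total_ige"

    ALL = (HIGH, DILUTION, TOTAL_IGE)


@dataclass(frozen=True)
class SampleSpec:
    """One physical serum sample within a panel.

    Parameters
    ----------
    sample_id:
        Opaque label, unique within the panel.
    role:
        ``"high"`` (undiluted high-level serum), ``"dilution"`` (prepared by
        diluting a parent sample), or ``"total_ige"``.
    parent_id:
        For dilutions, the ``sample_id`` of the serum that was diluted.
    dilution_factor:
        Unitless factor > 1 by which the parent was diluted.
    """

    sample_id: str
    role: str = SampleRole.HIGH
    parent_id: Optional[str] = None
    dilution_factor: Optional[float] = None


@dataclass(frozen=True)
class SurveyPanel:
    """One ring-trial instance: a survey id, a date, and its samples."""

    survey_id: str
    date: str  # ISO "YYYY-MM" calendar month
    samples: tuple[SampleSpec, ...] = ()

    def sample(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"no sample {sample_id!r} in panel {self.survey_id!r}")


@dataclass(frozen=True)
class DeviceProfile:
    """Measurement limits of one manufacturer's detection system.

    ``top_calibration`` is the highest calibration point in kU/L (commonly
    100); results pile up ("saturate") there.  ``top_class`` is the highest
    reportable allergen class, 6 by default.
    """

    manufacturer_code: str
    top_calibration: float = 100.0
    top_class: float = 6.0

    def __post_init__(self) -> None:
        if self.top_calibration <= 0:
            raise ValueError(
                f"top_calibration must be positive, got {self.top_calibration}"
            )


@dataclass(frozen=True)
class ClassScale:
    """Concentration cut points mapping kU/L to allergen classes 0..6.

    ``boundaries[k]`` is the lower edge of class ``k + 1``; membership is
    lower-inclusive, so a concentration exactly at a boundary belongs to the
    class above it.  The first boundary is the 0.35 kU/L negativity cutoff
    (class 0 = negative).
    """

    boundaries: tuple[float, ...] = (0.35, 0.7, 3.5, 17.5, 50.0, 100.0)

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) == 0:
            raise ValueError("ClassScale needs at least one boundary")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"boundaries must be strictly increasing: {b}")
        if b[0] <= 0:
            raise ValueError("first boundary must be positive")

    @property
    def n_classes(self) -> int:
        """Highest class index (0..n_classes)."""
        return len(self.boundaries)


#: Conventional CAP ladder; only the 0.35 kU/L negativity cutoff is fixed
#: by the evaluation scheme, the rest is the field's standard default.
DEFAULT_CLASS_SCALE = ClassScale()


def to_allergen_class(
    concentration: float, scale: ClassScale = DEFAULT_CLASS_SCALE
) -> int:
    """Convert a concentration in kU/L to an integer allergen class.

    Lower-inclusive banding: ``boundaries[k-1] <= c < boundaries[k]`` maps
    to class ``k``; anything below the first boundary is class 0 and
    anything at or above the last boundary is the top class.

    Raises
    ------
    ValueError
        If ``concentration`` is negative or not finite.
    """
    c = float(concentration)
    if not np.isfinite(c) or c < 0:
        raise ValueError(f"concentration must be a finite value >= 0, got {concentration}")
    # bisect_right places a value exactly at a boundary into the class above
    return bisect.bisect_right(scale.boundaries, c)


def validate_panel(
    panel: SurveyPanel, expected_samples: int = 5, expected_dilutions: int = 2
) -> list[str]:
    """Check a panel against the default study layout; report, never throw.

    Returns a list of human-readable violations (empty when the panel is
    well formed): exactly ``expected_samples`` samples, exactly
    ``expected_dilutions`` dilution samples, each dilution referencing a
    distinct existing parent with ``dilution_factor > 1``.
    """
    violations: list[str] = []
    samples = panel.samples
    if len(samples) != expected_samples:
        violations.append(
            f"panel {panel.survey_id!r}: expected {expected_samples} samples, "
            f"found {len(samples)}"
        )
    ids = [s.sample_id for s in samples]
    for dup in sorted({i for i in ids if ids.count(i) > 1}):
        violations.append(f"sample id {dup!r} is duplicated")

    dilutions = [s for s in samples if s.role == SampleRole.DILUTION]
    if len(dilutions) != expected_dilutions:
        violations.append(
            f"expected {expected_dilutions} dilution samples, found {len(dilutions)}"
        )
    seen_parents: set[str] = set()
    for s in samples:
        if s.role == SampleRole.DILUTION:
            if s.parent_id is None:
                violations.append(f"dilution sample {s.sample_id!r} has no parent_id")
            elif s.parent_id not in ids:
                violations.append(
                    f"dilution sample {s.sample_id!r} references unknown parent "
                    f"{s.parent_id!r}"
                )
            elif s.parent_id in seen_parents:
                violations.append(
                    f"dilution sample {s.sample_id!r} shares its parent "
                    f"{s.parent_id!r} with another dilution"
                )
            else:
                seen_parents.add(s.parent_id)
            if s.dilution_factor is None or s.dilution_factor <= 1:
                violations.append(
                    f"dilution sample {s.sample_id!r} needs dilution_factor > 1, "
                    f"got {s.dilution_factor}"
                )
        else:
            if s.parent_id is not None or s.dilution_factor is not None:
                violations.append(
                    f"non-dilution sample {s.sample_id!r} must not set "
                    "parent_id/dilution_factor"
                )
        if s.role not in SampleRole.ALL:
            violations.append(f"sample {s.sample_id!r} has unknown role {s.role!r}")
    return violations
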