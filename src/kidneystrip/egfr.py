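"""MDRD eGFR computation and CKD severity classification.

The estimated glomerular filtration rate (eGFR, mL/min/1.73 m^2) is computed
from serum creatinine concentration ``S_Cr`` (mg/dL) and subject metadata with
the four-variable MDRD equation

    eGFR = 175 * S_Cr^-1.154 * age^-0.203 * (0.742 if female)
                                          * (1.212 if African born)

and mapped to a three-level CKD severity (healthy / intermediate / critical)
by thresholding: CKD is indicated below 60 mL/min/1.73 m^2, and 15 is the
conventional kidney-failure boundary. Both thresholds are configurable since
clinical staging conventions vary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "Subject",
    "SeverityThresholds",
    "EGFRResult",
    "compute_egfr",
    "classify_severity",
    "evaluate_subject",
    "severity_table",
    "CREATININE_FLOOR",
]

Severity = Literal["healthy", "intermediate", "critical"]

#: Lowest nonzero creatinine dilution in the assay design; used as the
#: flooring value for blank (0 mg/dL) samples when flooring is enabled.
CREATININE_FLOOR: float = 0.1


@dataclass(frozen=True)
class Subject:
    """Demographic metadata entering the MDRD equation."""

    age: int
    sex: Literal["male", "female"]
    african_born: bool

    def __post_init__(self) -> None:
        if self.age < 0:
            raise DomainError(f"age must be >= 0, got {self.age}")
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class SeverityThresholds:
    """eGFR boundaries separating the three CKD severity classes.

    ``healthy_min`` is the lower edge of the healthy class (closed: an eGFR
    exactly at the boundary is healthy); ``critical_max`` is the upper edge of
    the critical class (open: an eGFR exactly at the boundary is
    intermediate). Units: mL/min/1.73 m^2.
    """

    healthy_min: float = 60.0
    critical_max: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.critical_max < self.healthy_min):
            raise DomainError(
                "thresholds must satisfy 0 < critical_max < healthy_min, got "
                f"critical_max={self.critical_max}, healthy_min={self.healthy_min}"
            )


@dataclass(frozen=True)
class EGFRResult:
    egfr: float
    severity: Severity


def compute_egfr(s_cr: float, subject: Subject, *, floor: bool = False) -> float:
    """Evaluate the MDRD equation for one subject.

    Parameters
    ----------
    s_cr
        Serum creatinine concentration in mg/dL. Must be positive unless
        ``floor`` is set, in which case non-positive values are raised to
        :data:`CREATININE_FLOOR` (intended for blank samples).
    subject
        Age (>= 1 year), sex, and African-born flag.
    """
    if floor and s_cr < CREATININE_FLOOR:
        s_cr = CREATININE_FLOOR
    if s_cr <= 0:
        raise DomainError(f"s_cr must be > 0 mg/dL, got {s_cr}")
    if subject.age < 1:
        raise DomainError(f"MDRD requires age >= 1 year, got {subject.age}")
    egfr = 175.0 * s_cr ** -1.154 * float(subject.age) ** -0.203
    if subject.sex == "female":
        egfr *= 0.742
    if subject.african_born:
        egfr *= 1.212
    return egfr


def classify_severity(
    egfr_value: float, thresholds: SeverityThresholds | None = None
) -> Severity:
    """Map an eGFR value to healthy / intermediate / critical."""
    if egfr_value <= 0:
        raise DomainError(f"eGFR must be > 0, got {egfr_value}")
    t = thresholds or SeverityThresholds()
    if egfr_value >= t.healthy_min:
        return "healthy"
    if egfr_value < t.critical_max:
        return "critical"
    return "intermediate"


def evaluate_subject(
    s_cr: float,
    subject: Subject,
    thresholds: SeverityThresholds | None = None,
    *,
    floor: bool = False,
) -> EGFRResult:
    """Compute eGFR and its severity class in one step."""
    egfr = compute_egfr(s_cr, subject, floor=floor)
    return EGFRResult(egfr=egfr, severity=classify_severity(egfr, thresholds))


def severity_table(
    frame: pd.DataFrame,
    thresholds: SeverityThresholds | None = None,
    *,
    floor: bool = False,
) -> pd.DataFrame:
    """Batch eGFR/severity for a DataFrame with columns
    ``s_cr, age, sex, african_born``; returns a copy with ``egfr`` and
    ``severity`` columns appended. Backs the batch CLI.
    """
    required = {"s_cr", "age", "sex", "african_born"}
    missing = required - set(frame.columns)
    if missing:
        raise DomainError(f"missing columns: {sorted(missing)}")
    out = frame.copy()
    egfrs = np.empty(len(frame), dtype=float)
    sev = []
    for i, row in enumerate(frame.itertuples(index=False)):
        subj = Subject(age=int(row.age), sex=row.sex, african_born=bool(row.african_born))
        res = evaluate_subject(float(row.s_cr), subj, thresholds, floor=floor)
        egfrs[i] = res.egfr
        sev.append(res.severity)
    out["egfr"] = egfrs
    out["severity"] = sev
    return out
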