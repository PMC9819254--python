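"""Stage-1 screening: blood sugar and heart rate -> health-state score.

The rule base maps the 4 x 3 combinations of blood-sugar and heart-rate
terms to a health state; only Normal blood sugar with Normal heart rate is
Healthy.  The crisp score lives on a 0-100 scale with Unhealthy anchored
below 40 and Healthy above 60; a score strictly between the anchors is
labeled ``borderline`` — the narrative case of a patient who has not fully
fallen into an unhealthy state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from functools import lru_cache
from pathlib import Path

import pandas as pd

from .config import load_packaged_system
from .errors import DomainError
from .fuzzy import DefuzzConfig, FiredRule, FuzzySystem

__all__ = [
    "HEALTHY_THRESHOLD",
    "UNHEALTHY_THRESHOLD",
    "VitalsReading",
    "DiagnosisResult",
    "build_diagnosis_system",
    "diagnose",
    "diagnose_values",
    "diagnose_batch",
]

UNHEALTHY_THRESHOLD = 40.0
HEALTHY_THRESHOLD = 60.0

CSV_COLUMNS = ["timestamp", "patient_id", "blood_sugar_mmol_l", "heart_rate_bpm"]


@dataclass(frozen=True)
class VitalsReading:
    """One timestamped sensor sample of blood sugar and heart rate."""

    timestamp: datetime
    patient_id: str
    blood_sugar: float  # mmol/L
    heart_rate: float  # BPM

    def __post_init__(self) -> None:
        if not self.blood_sugar > 0:
            raise DomainError(f"blood_sugar must be positive, got {self.blood_sugar}")
        if not self.heart_rate > 0:
            raise DomainError(f"heart_rate must be positive, got {self.heart_rate}")


@dataclass(frozen=True)
class DiagnosisResult:
    """Crisp health-state score with its label and rule trace."""

    score: float
    label: str  # healthy | borderline | unhealthy
    trace: tuple[FiredRule, ...]
    method: str
    grades: dict[str, dict[str, float]] = field(default_factory=dict)


def classify_score(score: float) -> str:
    """Three-way label: unhealthy <= 40 < borderline < 60 <= healthy."""
    if score <= UNHEALTHY_THRESHOLD:
        return "unhealthy"
    if score >= HEALTHY_THRESHOLD:
        return "healthy"
    return "borderline"


@lru_cache(maxsize=1)
def _packaged_system() -> FuzzySystem:
    return load_packaged_system("diagnosis")


def build_diagnosis_system() -> FuzzySystem:
    """The configured two-input screening system (packaged definition)."""
    return _packaged_system()


def diagnose_values(
    blood_sugar: float,
    heart_rate: float,
    config: DefuzzConfig | None = None,
    clamp_tolerance: float = 0.0,
    system: FuzzySystem | None = None,
) -> DiagnosisResult:
    """Diagnose from bare crisp vitals (no timestamp required)."""
    sys_ = system if system is not None else build_diagnosis_system()
    if config is None:
        config = sys_.default_config()
    score, fired, grades = sys_.infer(
        {"blood_sugar": blood_sugar, "heart_rate": heart_rate},
        config,
        clamp_tolerance,
    )
    return DiagnosisResult(
        score=score,
        label=classify_score(score),
        trace=tuple(fired),
        method=config.method,
        grades=grades,
    )


def diagnose(
    reading: VitalsReading,
    config: DefuzzConfig | None = None,
    clamp_tolerance: float = 0.0,
) -> DiagnosisResult:
    """Diagnose one vitals reading."""
    return diagnose_values(
        reading.blood_sugar, reading.heart_rate, config, clamp_tolerance
    )


def diagnose_batch(
    readings: pd.DataFrame | str | Path,
    config: DefuzzConfig | None = None,
    clamp_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Diagnose every row of a vitals table.

    Accepts a DataFrame or a CSV path with columns ``timestamp``,
    ``patient_id``, ``blood_sugar_mmol_l``, ``heart_rate_bpm``; returns a
    copy with ``score`` and ``label`` columns appended.
    """
    if not isinstance(readings, pd.DataFrame):
        readings = pd.read_csv(readings)
    missing = set(CSV_COLUMNS) - set(readings.columns)
    if missing:
        raise DomainError(f"vitals table missing columns: {sorted(missing)}")
    system = build_diagnosis_system()
    if config is None:
        config = system.default_config()
    scores, labels = [], []
    for row in readings.itertuples(index=False):
        result = diagnose_values(
            float(row.blood_sugar_mmol_l),
            float(row.heart_rate_bpm),
            config,
            clamp_tolerance,
            system=system,
        )
        scores.append(result.score)
        labels.append(result.label)
    out = readings.copy()
    out["score"] = scores
    out["label"] = labels
    return out
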