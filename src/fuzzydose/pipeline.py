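"""End-to-end pipeline: screen each reading, dose when indicated.

Stage-2 dosing runs for a reading when the stage-1 score retains Unhealthy
membership (score < 60) *and* the glucose is in the diabetic range
(> 7.0 mmol/L); otherwise the dose columns are left empty.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .diagnosis import VitalsReading, diagnose
from .dosing import DoseInputs, PatientProfile, compute_dose
from .fuzzy import DefuzzConfig

__all__ = ["DIABETIC_GLUCOSE", "run_pipeline"]

DIABETIC_GLUCOSE = 7.0  # mmol/L; dosing applies strictly above this


def run_pipeline(
    readings: Sequence[VitalsReading],
    profile: PatientProfile,
    diag_config: DefuzzConfig | None = None,
    dose_config: DefuzzConfig | None = None,
    clamp_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Diagnose every reading and compute a dose where applicable.

    Returns one row per reading with columns ``timestamp``, ``patient_id``,
    ``blood_sugar_mmol_l``, ``heart_rate_bpm``, ``score``, ``label``,
    ``dose_units``, ``dose_label`` (the last two NA when dosing does not
    apply).
    """
    rows = []
    for r in readings:
        diag = diagnose(r, diag_config, clamp_tolerance)
        dose_units: float | None = None
        dose_label: str | None = None
        if diag.score < 60.0 and r.blood_sugar > DIABETIC_GLUCOSE:
            result = compute_dose(
                DoseInputs(
                    health_score=diag.score,
                    diabetic_level=r.blood_sugar,
                    weight=profile.weight,
                    carbohydrate=profile.daily_carbohydrate,
                ),
                dose_config,
                clamp_tolerance,
            )
            dose_units = result.dose
            dose_label = result.label
        rows.append(
            {
                "timestamp": r.timestamp.isoformat(),
                "patient_id": r.patient_id,
                "blood_sugar_mmol_l": r.blood_sugar,
                "heart_rate_bpm": r.heart_rate,
                "score": diag.score,
                "label": diag.label,
                "dose_units": dose_units,
                "dose_label": dose_label,
            }
        )
    return pd.DataFrame(rows)
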