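"""Stage-2 insulin dosing: the four-input fuzzy system and the clinical
bolus formula.

The fuzzy system combines the stage-1 health-state score with the diabetic
glucose level, body weight, and daily carbohydrate intake through 27 rules,
every one gated on the patient being (at least partly) Unhealthy.  The
deterministic clinical calculator provides the standard bolus arithmetic
the rule table was derived from:

    TDI = 0.55 * weight_kg                 total daily insulin, units
    CCR = 500 / TDI                        grams covered per insulin unit
    CHO dose = carbs_g / CCR               mealtime carbohydrate dose
    correction = (BG_mgdl - 120) * TDI/1800   toward the 120 mg/dL baseline

with the correction floored at zero below the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .errors import DomainError, NotApplicableError
from .fuzzy import DefuzzConfig, FiredRule, FuzzySystem, aggregate_strengths
from .config import load_packaged_system

__all__ = [
    "PatientProfile",
    "DoseInputs",
    "DoseResult",
    "ClinicalDose",
    "ClinicalConstants",
    "build_dosing_system",
    "compute_dose",
    "clinical_formula_dose",
    "mmol_to_mgdl",
]


@dataclass(frozen=True)
class PatientProfile:
    """Static per-patient attributes used by stage-2 dosing."""

    patient_id: str
    weight: float  # kg
    daily_carbohydrate: float  # g

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise DomainError(f"weight must be positive, got {self.weight}")
        if self.daily_carbohydrate < 0:
            raise DomainError(
                f"daily_carbohydrate must be non-negative, got {self.daily_carbohydrate}"
            )


@dataclass(frozen=True)
class DoseInputs:
    """Crisp inputs to the stage-2 fuzzy system."""

    health_score: float  # stage-1 output, 0-100
    diabetic_level: float  # mmol/L, > 7.0 for dosing to apply
    weight: float  # kg
    carbohydrate: float  # g


@dataclass(frozen=True)
class DoseResult:
    """Crisp insulin dose with the winning label and rule trace."""

    dose: float  # insulin units
    label: str  # Low | Medium | High | Very High
    trace: tuple[FiredRule, ...]
    method: str
    grades: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class ClinicalConstants:
    """Constants of the standard bolus arithmetic."""

    tdi_factor: float = 0.55  # units per kg body weight
    ccr_numerator: float = 500.0  # the "500 rule" for carb coverage
    baseline_bg: float = 120.0  # mg/dL pre-meal target
    correction_divisor: float = 1800.0  # the "1800 rule" denominator
    correction_factor: float = 50.0  # mg/dL lowered per insulin unit
    mmol_to_mgdl: float = 18.0

    def __post_init__(self) -> None:
        for name in (
            "tdi_factor", "ccr_numerator", "baseline_bg",
            "correction_divisor", "correction_factor", "mmol_to_mgdl",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")


@dataclass(frozen=True)
class ClinicalDose:
    """Formula-based dose breakdown."""

    tdi: float  # insulin units / day
    ccr: float  # g carbohydrate per insulin unit
    cho_dose: float  # insulin units
    correction_dose: float  # insulin units
    total: float  # insulin units


_LABEL_ORDER = ("Low", "Medium", "High", "Very High")


@lru_cache(maxsize=1)
def _packaged_system() -> FuzzySystem:
    return load_packaged_system("dosing")


def build_dosing_system() -> FuzzySystem:
    """The configured four-input dosing system (packaged definition)."""
    return _packaged_system()


def _winning_label(fired: tuple[FiredRule, ...]) -> str:
    # Maximal aggregated strength; ties broken toward the lower dose label.
    agg = aggregate_strengths(fired)
    best = max(agg.values())
    for label in _LABEL_ORDER:
        if agg.get(label, 0.0) == best:
            return label
    raise AssertionError("unreachable: fired set has a maximal label")


def compute_dose(
    inputs: DoseInputs,
    config: DefuzzConfig | None = None,
    clamp_tolerance: float = 0.0,
) -> DoseResult:
    """Run the stage-2 fuzzy system on crisp inputs.

    Raises :class:`NotApplicableError` when the health score carries no
    Unhealthy membership (score >= 60): the rule base prescribes insulin
    only to patients the screening stage did not classify healthy.
    """
    system = build_dosing_system()
    if config is None:
        config = system.default_config()
    values = {
        "health_state": inputs.health_score,
        "diabetic_level": inputs.diabetic_level,
        "weight": inputs.weight,
        "carbohydrate": inputs.carbohydrate,
    }
    fuzzified = system.fuzzify_inputs(values, clamp_tolerance)
    if fuzzified["health_state"]["Unhealthy"] == 0.0:
        raise NotApplicableError(
            f"not applicable — patient not classified unhealthy "
            f"(health score {inputs.health_score})"
        )
    dose, fired, grades = system.infer(values, config, clamp_tolerance)
    return DoseResult(
        dose=dose,
        label=_winning_label(tuple(fired)),
        trace=tuple(fired),
        method=config.method,
        grades=grades,
    )


def mmol_to_mgdl(x: float, factor: float = 18.0) -> float:
    """Convert a glucose concentration from mmol/L to mg/dL."""
    if x < 0:
        raise DomainError(f"glucose must be non-negative, got {x}")
    return factor * x


def clinical_formula_dose(
    weight: float,
    carbohydrate: float,
    blood_sugar: float,
    constants: ClinicalConstants | None = None,
) -> ClinicalDose:
    """Deterministic bolus calculation (500/1800 rules).

    ``blood_sugar`` is in mmol/L; the correction term works in mg/dL and is
    floored at zero when glucose is below the 120 mg/dL baseline.
    """
    if constants is None:
        constants = ClinicalConstants()
    if not weight > 0:
        raise DomainError(f"weight must be positive, got {weight}")
    if not blood_sugar > 0:
        raise DomainError(f"blood_sugar must be positive, got {blood_sugar}")
    tdi = constants.tdi_factor * weight
    ccr = constants.ccr_numerator / tdi
    cho_dose = carbohydrate / ccr
    bg_mgdl = mmol_to_mgdl(blood_sugar, constants.mmol_to_mgdl)
    correction = (bg_mgdl - constants.baseline_bg) * tdi / constants.correction_divisor
    correction = max(correction, 0.0)
    return ClinicalDose(
        tdi=tdi,
        ccr=ccr,
        cho_dose=cho_dose,
        correction_dose=correction,
        total=cho_dose + correction,
    )
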