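"""Generic Mamdani fuzzy-inference machinery.

This module implements the primitives shared by both clinical rule bases:
piecewise-linear (trapezoid / open-shoulder) membership functions,
linguistic variables, min-AND rule firing, and two defuzzification
strategies — the strength-weighted representative average used in hand
calculations, and the full Mamdani clip/max-aggregate/centroid variant
computed on a uniform grid.

Nothing here knows about blood sugar or insulin; the clinical systems are
configured on top of these types (see :mod:`fuzzydose.diagnosis` and
:mod:`fuzzydose.dosing`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, NoApplicableRuleError

__all__ = [
    "MembershipFunction",
    "LinguisticVariable",
    "FuzzyRule",
    "FiredRule",
    "DefuzzConfig",
    "FuzzySystem",
    "membership_degree",
    "fuzzify",
    "fire_rules",
    "defuzzify_weighted",
    "defuzzify_centroid",
]

WEIGHTED = "weighted_representative"
CENTROID = "mamdani_centroid"


@dataclass(frozen=True)
class MembershipFunction:
    """A trapezoidal membership grade function.

    The grade rises linearly from ``a`` to ``b``, is 1 on the plateau
    ``[b, c]``, and falls linearly from ``c`` to ``d``.  An *open* shoulder
    extends the plateau to infinity on that side: with ``open_left`` the
    grade is 1 for every ``x <= b`` (``a`` is ignored), with ``open_right``
    it is 1 for every ``x >= c`` (``d`` is ignored).
    """

    label: str
    a: float
    b: float
    c: float
    d: float
    open_left: bool = False
    open_right: bool = False

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigurationError(
                f"term {self.label!r}: breakpoints must satisfy a <= b <= c <= d, "
                f"got ({self.a}, {self.b}, {self.c}, {self.d})"
            )

    def __call__(self, x: float) -> float:
        return membership_degree(self, x)

    @property
    def support(self) -> tuple[float, float]:
        """Interval outside which the grade is zero (infinite for open shoulders)."""
        lo = -math.inf if self.open_left else self.a
        hi = math.inf if self.open_right else self.d
        return lo, hi


def membership_degree(mf: MembershipFunction, x: float) -> float:
    """Evaluate the trapezoid ``mf`` at a crisp point ``x``.

    Exact at breakpoints: grade 1 on the plateau ``[b, c]`` (closed), 0 at
    ``a`` and ``d`` on closed sides.
    """
    if not math.isfinite(x):
        raise DomainError(f"membership argument must be finite, got {x!r}")
    if mf.open_left and x <= mf.b:
        return 1.0
    if mf.open_right and x >= mf.c:
        return 1.0
    if x <= mf.a or x >= mf.d:
        # a == b (or c == d) means a vertical edge; the plateau test below
        # still claims its closed endpoint first.
        if mf.b <= x <= mf.c:
            return 1.0
        return 0.0
    if mf.b <= x <= mf.c:
        return 1.0
    if x < mf.b:
        return (x - mf.a) / (mf.b - mf.a)
    return (mf.d - x) / (mf.d - mf.c)


@dataclass(frozen=True)
class LinguisticVariable:
    """A named crisp quantity partitioned into labeled fuzzy terms.

    Terms are kept in increasing order along the universe.  Adjacent terms
    in the clinical configurations overlap only on single linear crossover
    segments where their grades sum to one.
    """

    name: str
    units: str
    universe_lo: float
    universe_hi: float
    terms: tuple[MembershipFunction, ...]

    def __post_init__(self) -> None:
        if self.universe_lo >= self.universe_hi:
            raise ConfigurationError(
                f"variable {self.name!r}: empty universe "
                f"[{self.universe_lo}, {self.universe_hi}]"
            )
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"variable {self.name!r}: duplicate term labels")
        for t in self.terms:
            lo, hi = t.support
            if hi < self.universe_lo or lo > self.universe_hi:
                raise ConfigurationError(
                    f"variable {self.name!r}: term {t.label!r} lies outside the "
                    f"universe [{self.universe_lo}, {self.universe_hi}]"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    def term(self, label: str) -> MembershipFunction:
        for t in self.terms:
            if t.label == label:
                return t
        raise ConfigurationError(f"variable {self.name!r} has no term {label!r}")

    def clamp(self, x: float, tolerance: float = 0.0) -> float:
        """Clamp ``x`` to the universe if within ``tolerance`` of a bound.

        Raises :class:`DomainError` for values further out.
        """
        if not math.isfinite(x):
            raise DomainError(f"{self.name}: value must be finite, got {x!r}")
        if x < self.universe_lo - tolerance or x > self.universe_hi + tolerance:
            raise DomainError(
                f"{self.name}: value {x} {self.units} outside universe "
                f"[{self.universe_lo}, {self.universe_hi}] {self.units}"
            )
        return min(max(x, self.universe_lo), self.universe_hi)

    def fuzzify(self, x: float, clamp_tolerance: float = 0.0) -> dict[str, float]:
        x = self.clamp(x, clamp_tolerance)
        return {t.label: membership_degree(t, x) for t in self.terms}

    def crossover_segments(self) -> list[tuple[str, str, float, float]]:
        """Open intervals where two consecutive terms overlap.

        Returns ``(left_label, right_label, lo, hi)`` for each pair of
        consecutive terms whose supports intersect; on these segments the
        clinical configurations satisfy partition of unity.
        """
        segments = []
        for left, right in zip(self.terms, self.terms[1:]):
            lo, hi = right.a, left.d
            if right.open_left or left.open_right:
                continue
            if lo < hi:
                segments.append((left.label, right.label, lo, hi))
        return segments


@dataclass(frozen=True)
class FuzzyRule:
    """IF <conjunction of variable == term> THEN <output term>."""

    rule_id: int
    antecedents: Mapping[str, str]
    consequent: str

    def __post_init__(self) -> None:
        if not self.antecedents:
            raise ConfigurationError(f"rule {self.rule_id}: empty antecedent")


@dataclass(frozen=True)
class FiredRule:
    """A rule together with its firing strength (min over antecedent grades)."""

    rule_id: int
    strength: float
    consequent: str


@dataclass(frozen=True)
class DefuzzConfig:
    """Defuzzification strategy and its parameters.

    ``weighted_representative`` reproduces the hand calculation: each output
    label contributes a single crisp representative value weighted by firing
    strength.  ``mamdani_centroid`` clips each consequent trapezoid at its
    aggregated strength, takes the pointwise max on a uniform grid over the
    output universe, and returns the grid centroid.
    """

    method: str = WEIGHTED
    representatives: Mapping[str, float] = field(default_factory=dict)
    grid_step: float = 0.01

    def __post_init__(self) -> None:
        if self.method not in (WEIGHTED, CENTROID):
            raise ConfigurationError(f"unknown defuzzification method {self.method!r}")
        if self.grid_step <= 0:
            raise ConfigurationError("grid_step must be positive")


def fuzzify(
    variable: LinguisticVariable, x: float, clamp_tolerance: float = 0.0
) -> dict[str, float]:
    """Map a crisp value to a grade for every term of ``variable``."""
    return variable.fuzzify(x, clamp_tolerance)


def fire_rules(
    rulebase: Iterable[FuzzyRule],
    fuzzified: Mapping[str, Mapping[str, float]],
) -> list[FiredRule]:
    """Fire every rule with min-AND; rules at strength 0 are dropped."""
    fired: list[FiredRule] = []
    for rule in rulebase:
        strength = 1.0
        for var_name, term_label in rule.antecedents.items():
            if var_name not in fuzzified:
                raise ConfigurationError(
                    f"rule {rule.rule_id}: unknown variable {var_name!r}"
                )
            grades = fuzzified[var_name]
            if term_label not in grades:
                raise ConfigurationError(
                    f"rule {rule.rule_id}: variable {var_name!r} has no term "
                    f"{term_label!r}"
                )
            strength = min(strength, grades[term_label])
        if strength > 0.0:
            fired.append(FiredRule(rule.rule_id, strength, rule.consequent))
    return fired


def defuzzify_weighted(
    fired: Sequence[FiredRule], config: DefuzzConfig
) -> float:
    """Strength-weighted average of one representative value per output label."""
    if not fired:
        raise NoApplicableRuleError("no applicable rule: empty fired set")
    num = 0.0
    den = 0.0
    for fr in fired:
        if fr.consequent not in config.representatives:
            raise ConfigurationError(
                f"no representative value configured for output term {fr.consequent!r}"
            )
        num += fr.strength * config.representatives[fr.consequent]
        den += fr.strength
    if den == 0.0:
        raise NoApplicableRuleError("no applicable rule: total firing strength is 0")
    return num / den


def aggregate_strengths(fired: Sequence[FiredRule]) -> dict[str, float]:
    """Max firing strength per consequent label (standard Mamdani aggregation)."""
    agg: dict[str, float] = {}
    for fr in fired:
        agg[fr.consequent] = max(agg.get(fr.consequent, 0.0), fr.strength)
    return agg


def defuzzify_centroid(
    fired: Sequence[FiredRule],
    output_var: LinguisticVariable,
    config: DefuzzConfig,
) -> float:
    """Mamdani clip / max-aggregate / grid centroid defuzzification.

    Open shoulders are truncated at the output universe bounds: the grid
    covers exactly ``[universe_lo, universe_hi]``.
    """
    if not fired:
        raise NoApplicableRuleError("no applicable rule: empty fired set")
    agg = aggregate_strengths(fired)
    for label in agg:
        output_var.term(label)  # raises ConfigurationError on unknown labels
    step = config.grid_step
    n = int(round((output_var.universe_hi - output_var.universe_lo) / step))
    grid = np.linspace(output_var.universe_lo, output_var.universe_hi, n + 1)
    mu = np.zeros_like(grid)
    for label, strength in agg.items():
        if strength <= 0.0:
            continue
        term = output_var.term(label)
        grades = np.fromiter((membership_degree(term, x) for x in grid), float, len(grid))
        np.maximum(mu, np.minimum(grades, strength), out=mu)
    area = float(np.trapezoid(mu, grid))
    if area == 0.0:
        raise NoApplicableRuleError("no applicable rule: aggregated output has zero area")
    return float(np.trapezoid(grid * mu, grid) / area)


@dataclass(frozen=True)
class FuzzySystem:
    """A complete single-output Mamdani system: inputs, output, rule base."""

    name: str
    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: tuple[FuzzyRule, ...]
    representatives: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_name = {v.name: v for v in self.inputs}
        if len(by_name) != len(self.inputs):
            raise ConfigurationError(f"system {self.name!r}: duplicate input names")
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"system {self.name!r}: duplicate rule ids")
        for rule in self.rules:
            for var_name, term_label in rule.antecedents.items():
                if var_name not in by_name:
                    raise ConfigurationError(
                        f"system {self.name!r} rule {rule.rule_id}: "
                        f"unknown input {var_name!r}"
                    )
                by_name[var_name].term(term_label)
            self.output.term(rule.consequent)
        for label in self.representatives:
            self.output.term(label)

    def input(self, name: str) -> LinguisticVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise ConfigurationError(f"system {self.name!r} has no input {name!r}")

    def fuzzify_inputs(
        self, values: Mapping[str, float], clamp_tolerance: float = 0.0
    ) -> dict[str, dict[str, float]]:
        missing = {v.name for v in self.inputs} - set(values)
        if missing:
            raise DomainError(f"missing input values: {sorted(missing)}")
        return {
            v.name: v.fuzzify(values[v.name], clamp_tolerance) for v in self.inputs
        }

    def default_config(self, method: str = WEIGHTED) -> DefuzzConfig:
        return DefuzzConfig(method=method, representatives=dict(self.representatives))

    def infer(
        self,
        values: Mapping[str, float],
        config: DefuzzConfig | None = None,
        clamp_tolerance: float = 0.0,
    ) -> tuple[float, list[FiredRule], dict[str, dict[str, float]]]:
        """Fuzzify, fire, defuzzify; returns (crisp output, trace, grades)."""
        if config is None:
            config = self.default_config()
        fuzzified = self.fuzzify_inputs(values, clamp_tolerance)
        fired = fire_rules(self.rules, fuzzified)
        if config.method == WEIGHTED:
            crisp = defuzzify_weighted(fired, config)
        else:
            crisp = defuzzify_centroid(fired, self.output, config)
        return crisp, fired, fuzzified
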