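"""YAML (de)serialization of fuzzy system definitions.

The two clinical systems ship as packaged YAML files under
``fuzzydose/data/``; :func:`load_packaged_system` reads them.  The same
format can be used to supply a modified system from a user file.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError
from .fuzzy import FuzzyRule, FuzzySystem, LinguisticVariable, MembershipFunction

_TERM_KEYS = {"label", "points", "open_left", "open_right"}
_VAR_KEYS = {"name", "units", "universe", "terms"}
_SYSTEM_KEYS = {"name", "inputs", "output", "rules", "representatives"}


def _term_from_dict(d: dict[str, Any]) -> MembershipFunction:
    unknown = set(d) - _TERM_KEYS
    if unknown:
        raise ConfigurationError(f"unknown term keys: {sorted(unknown)}")
    a, b, c, dd = (float(v) for v in d["points"])
    return MembershipFunction(
        label=str(d["label"]),
        a=a, b=b, c=c, d=dd,
        open_left=bool(d.get("open_left", False)),
        open_right=bool(d.get("open_right", False)),
    )


def _variable_from_dict(d: dict[str, Any]) -> LinguisticVariable:
    unknown = set(d) - _VAR_KEYS
    if unknown:
        raise ConfigurationError(f"unknown variable keys: {sorted(unknown)}")
    lo, hi = (float(v) for v in d["universe"])
    return LinguisticVariable(
        name=str(d["name"]),
        units=str(d["units"]),
        universe_lo=lo,
        universe_hi=hi,
        terms=tuple(_term_from_dict(t) for t in d["terms"]),
    )


def system_from_dict(d: dict[str, Any]) -> FuzzySystem:
    unknown = set(d) - _SYSTEM_KEYS
    if unknown:
        raise ConfigurationError(f"unknown system keys: {sorted(unknown)}")
    rules = tuple(
        FuzzyRule(
            rule_id=int(r["id"]),
            antecedents={str(k): str(v) for k, v in r["if"].items()},
            consequent=str(r["then"]),
        )
        for r in d["rules"]
    )
    return FuzzySystem(
        name=str(d["name"]),
        inputs=tuple(_variable_from_dict(v) for v in d["inputs"]),
        output=_variable_from_dict(d["output"]),
        rules=rules,
        representatives={str(k): float(v) for k, v in d.get("representatives", {}).items()},
    )


def _term_to_dict(t: MembershipFunction) -> dict[str, Any]:
    d: dict[str, Any] = {"label": t.label, "points": [t.a, t.b, t.c, t.d]}
    if t.open_left:
        d["open_left"] = True
    if t.open_right:
        d["open_right"] = True
    return d


def _variable_to_dict(v: LinguisticVariable) -> dict[str, Any]:
    return {
        "name": v.name,
        "units": v.units,
        "universe": [v.universe_lo, v.universe_hi],
        "terms": [_term_to_dict(t) for t in v.terms],
    }


def system_to_dict(system: FuzzySystem) -> dict[str, Any]:
    return {
        "name": system.name,
        "inputs": [_variable_to_dict(v) for v in system.inputs],
        "output": _variable_to_dict(system.output),
        "rules": [
            {"id": r.rule_id, "if": dict(r.antecedents), "then": r.consequent}
            for r in system.rules
        ],
        "representatives": dict(system.representatives),
    }


def load_system(path: str | Path) -> FuzzySystem:
    """Load a fuzzy system definition from a YAML file."""
    with open(path) as fh:
        return system_from_dict(yaml.safe_load(fh))


def dump_system(system: FuzzySystem, path: str | Path) -> None:
    """Write a fuzzy system definition to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=False)


def dumps_system(system: FuzzySystem) -> str:
    return yaml.safe_dump(system_to_dict(system), sort_keys=False)


def load_packaged_system(name: str) -> FuzzySystem:
    """Load one of the shipped system definitions (``diagnosis`` or ``dosing``)."""
    ref = resources.files("fuzzydose").joinpath(f"data/{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ConfigurationError(f"no packaged system named {name!r}") from None
    return system_from_dict(yaml.safe_load(text))
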