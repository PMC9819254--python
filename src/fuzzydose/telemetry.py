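"""Synthetic vitals-stream generation and stream I/O.

This module emulates the patient-side sensing hardware: a wearable that
samples blood sugar and heart rate every eight hours and ships the readings
upstream.  Streams are plain CSV or JSON-lines files so the full two-stage
pipeline can be exercised end to end without any device.

Readings are drawn from truncated normal distributions per patient
archetype; truncation bounds keep every sample inside the fuzzy variables'
universes (and, for the diabetic archetype, strictly inside the diabetic
glucose range so stage-2 dosing always applies).
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .diagnosis import CSV_COLUMNS, VitalsReading
from .errors import DomainError, StreamFormatError

__all__ = [
    "ArchetypeSpec",
    "ARCHETYPES",
    "generate_stream",
    "read_stream",
    "write_stream",
]

DEFAULT_START = datetime(2023, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Distribution of a simulated patient's vitals.

    Blood sugar ~ TruncNormal(bg_mean, bg_sd) on [bg_lo, bg_hi] (mmol/L),
    heart rate ~ TruncNormal(hr_mean, hr_sd) on [hr_lo, hr_hi] (BPM),
    sampled every ``sampling_interval`` hours.
    """

    name: str
    bg_mean: float
    bg_sd: float
    hr_mean: float
    hr_sd: float
    bg_lo: float = 0.5
    bg_hi: float = 12.0
    hr_lo: float = 30.0
    hr_hi: float = 180.0
    sampling_interval: float = 8.0  # hours

    def __post_init__(self) -> None:
        if self.bg_sd < 0 or self.hr_sd < 0:
            raise DomainError("standard deviations must be non-negative")
        if self.sampling_interval <= 0:
            raise DomainError("sampling_interval must be positive")
        if not (self.bg_lo < self.bg_hi and self.hr_lo < self.hr_hi):
            raise DomainError("truncation bounds must be ordered")


#: Default archetypes, centered on the plateaus of the corresponding
#: stage-1 terms.  The diabetic archetype truncates glucose above 7.0
#: mmol/L so every reading is in the diabetic range.
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "healthy": ArchetypeSpec("healthy", bg_mean=4.7, bg_sd=0.3, hr_mean=80.0, hr_sd=8.0),
    "prediabetic": ArchetypeSpec("prediabetic", bg_mean=6.2, bg_sd=0.3, hr_mean=80.0, hr_sd=8.0),
    "diabetic": ArchetypeSpec(
        "diabetic", bg_mean=8.6, bg_sd=0.5, hr_mean=80.0, hr_sd=8.0, bg_lo=7.05
    ),
    "bradycardic": ArchetypeSpec("bradycardic", bg_mean=4.7, bg_sd=0.3, hr_mean=50.0, hr_sd=4.0),
    "tachycardic": ArchetypeSpec("tachycardic", bg_mean=4.7, bg_sd=0.3, hr_mean=112.0, hr_sd=5.0),
}


def get_archetype(name: str, **overrides) -> ArchetypeSpec:
    try:
        spec = ARCHETYPES[name]
    except KeyError:
        raise DomainError(
            f"unknown archetype {name!r}; choose from {sorted(ARCHETYPES)}"
        ) from None
    return replace(spec, **overrides) if overrides else spec


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, min(max(mean, lo), hi))
    # Rejection sampling; the archetype bounds are several sd wide, so a
    # handful of rounds suffices.
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_stream(
    spec: ArchetypeSpec | str,
    n: int,
    seed: int,
    patient_id: str | None = None,
    start: datetime = DEFAULT_START,
) -> list[VitalsReading]:
    """Generate ``n`` readings at the archetype's sampling interval."""
    if isinstance(spec, str):
        spec = get_archetype(spec)
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    bg = _truncated_normal(rng, spec.bg_mean, spec.bg_sd, spec.bg_lo, spec.bg_hi, n)
    hr = _truncated_normal(rng, spec.hr_mean, spec.hr_sd, spec.hr_lo, spec.hr_hi, n)
    pid = patient_id if patient_id is not None else f"{spec.name}-{seed}"
    step = timedelta(hours=spec.sampling_interval)
    return [
        VitalsReading(
            timestamp=start + i * step,
            patient_id=pid,
            blood_sugar=float(bg[i]),
            heart_rate=float(hr[i]),
        )
        for i in range(n)
    ]


def _check_monotone(readings: Sequence[VitalsReading]) -> None:
    for prev, cur in zip(readings, readings[1:]):
        if cur.timestamp <= prev.timestamp:
            warnings.warn(
                f"non-monotone timestamps: {cur.timestamp.isoformat()} follows "
                f"{prev.timestamp.isoformat()}",
                stacklevel=3,
            )
            return


def _parse_row(
    ts: str, pid: str, bg: str, hr: str, line: int
) -> VitalsReading:
    try:
        timestamp = datetime.fromisoformat(ts)
    except ValueError:
        raise StreamFormatError(f"invalid ISO-8601 timestamp {ts!r}", line) from None
    try:
        blood_sugar = float(bg)
        heart_rate = float(hr)
    except ValueError:
        raise StreamFormatError(
            f"non-numeric vitals (blood_sugar={bg!r}, heart_rate={hr!r})", line
        ) from None
    if not (math.isfinite(blood_sugar) and math.isfinite(heart_rate)):
        raise StreamFormatError("non-finite vitals", line)
    try:
        return VitalsReading(timestamp, pid, blood_sugar, heart_rate)
    except DomainError as exc:
        raise StreamFormatError(str(exc), line) from None


def read_stream(path: str | Path) -> list[VitalsReading]:
    """Read a vitals stream from CSV or JSON-lines (by file extension)."""
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson", ".json"):
        readings = _read_jsonl(path)
    else:
        readings = _read_csv(path)
    _check_monotone(readings)
    return readings


def _read_csv(path: Path) -> list[VitalsReading]:
    readings = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return []
        if header != CSV_COLUMNS:
            raise StreamFormatError(
                f"expected header {CSV_COLUMNS}, got {header}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise StreamFormatError(f"expected 4 fields, got {len(row)}", lineno)
            readings.append(_parse_row(*row, line=lineno))
    return readings


def _read_jsonl(path: Path) -> list[VitalsReading]:
    readings = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamFormatError(f"invalid JSON: {exc}", lineno) from None
            try:
                readings.append(
                    _parse_row(
                        str(obj["timestamp"]),
                        str(obj["patient_id"]),
                        str(obj["blood_sugar_mmol_l"]),
                        str(obj["heart_rate_bpm"]),
                        lineno,
                    )
                )
            except KeyError as exc:
                raise StreamFormatError(f"missing key {exc}", lineno) from None
    return readings


def write_stream(
    readings: Iterable[VitalsReading], path: str | Path, fmt: str | None = None
) -> None:
    """Write a vitals stream as CSV or JSON-lines.

    ``fmt`` is ``csv`` or ``jsonl``; inferred from the extension when
    omitted.  Floats are written with full repr precision so write/read
    round-trips are exact.
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix in (".jsonl", ".ndjson", ".json") else "csv"
    if fmt not in ("csv", "jsonl"):
        raise DomainError(f"unknown stream format {fmt!r}")
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for r in readings:
                writer.writerow(
                    [r.timestamp.isoformat(), r.patient_id,
                     repr(r.blood_sugar), repr(r.heart_rate)]
                )
    else:
        with open(path, "w") as fh:
            for r in readings:
                fh.write(
                    json.dumps(
                        {
                            "timestamp": r.timestamp.isoformat(),
                            "patient_id": r.patient_id,
                            "blood_sugar_mmol_l": r.blood_sugar,
                            "heart_rate_bpm": r.heart_rate,
                        }
                    )
                    + "\n"
                )
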