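"""Craniofacial distance measurements from named 3-D landmarks.

Twelve measures (ids I-XI plus palatal width) are straight-line chord
distances between two landmarks, the digital counterpart of sliding-caliper
measurement.  Landmarks are in millimetres; results are reported in
centimetres.  A measurement whose defining landmarks are absent is reported
as missing rather than raising, so partially measurable subjects survive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "LandmarkSet",
    "AnthropometryResult",
    "MEASUREMENT_DEFINITIONS",
    "MEASUREMENT_NAMES",
    "measure_all",
    "palatal_width",
    "repeat_measurements",
]

RECOGNIZED_NAMES = frozenset(
    {
        "vertex",
        "gnathion",
        "glabella",
        "subnasale",
        "chelion_left",
        "chelion_right",
        "tragus",
        "ext_auditory_meatus_left",
        "ext_auditory_meatus_right",
        "upper_lip",
        "lower_lip",
        "back_of_head",
        "molar_16",
        "molar_26",
        "ridge_16",
        "ridge_26",
        "pterygoid_hamulus_left",
        "pterygoid_hamulus_right",
    }
)

#: measurement id -> (landmark_a, landmark_b)
MEASUREMENT_DEFINITIONS: dict[str, tuple[str, str]] = {
    "I": ("vertex", "gnathion"),
    "II": ("ext_auditory_meatus_right", "ext_auditory_meatus_left"),
    "III": ("back_of_head", "glabella"),
    "IV": ("glabella", "gnathion"),
    "V": ("subnasale", "gnathion"),
    "VI": ("glabella", "subnasale"),
    "VII": ("chelion_right", "chelion_left"),
    "VIII": ("glabella", "upper_lip"),
    "IX": ("subnasale", "upper_lip"),
    "X": ("gnathion", "lower_lip"),
    "XI": ("tragus", "gnathion"),
}

MEASUREMENT_NAMES: dict[str, str] = {
    "I": "length of the head",
    "II": "width of the head",
    "III": "depth of the head",
    "IV": "face height",
    "V": "lower face height",
    "VI": "nose height",
    "VII": "width of the mouth",
    "VIII": "upper face height",
    "IX": "upper lip height",
    "X": "mandible height",
    "XI": "mandibular length",
    "palatal_width": "palatal width",
}

ALL_MEASUREMENT_IDS = tuple(MEASUREMENT_DEFINITIONS) + ("palatal_width",)


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical points in world millimetres."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        cleaned = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=np.float64).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            cleaned[str(name)] = arr
        object.__setattr__(self, "points", cleaned)

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def get(self, name: str):
        return self.points.get(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    def transformed(self, rotation=None, translation=None, scale: float = 1.0) -> "LandmarkSet":
        rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        shift = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return LandmarkSet({k: scale * (rot @ v) + shift for k, v in self.points.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: list(map(float, v)) for k, v in self.points.items()}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        return cls(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class AnthropometryResult:
    """Measurement id -> distance in cm (None when not measurable)."""

    values: dict[str, float | None]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, measurement_id: str) -> float | None:
        return self.values[measurement_id]

    def present(self) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if v is not None}


def _distance_cm(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b)) / 10.0


def palatal_width(lm: LandmarkSet) -> tuple[float | None, str]:
    """Inter-first-molar distance in cm, with provenance.

    Uses the molar landmarks when both are present; falls back to the
    alveolar-ridge estimates of the molar positions (flagged as
    ``"ridge-estimate"``) when one or both molars were extracted.
    """
    if "molar_16" in lm and "molar_26" in lm:
        return _distance_cm(lm["molar_16"], lm["molar_26"]), "molars"
    if "ridge_16" in lm and "ridge_26" in lm:
        return _distance_cm(lm["ridge_16"], lm["ridge_26"]), "ridge-estimate"
    return None, "missing"


def measure_all(lm: LandmarkSet) -> AnthropometryResult:
    """All twelve measurements; undefined pairs become None."""
    if not lm.points:
        raise ValueError("empty landmark set")
    values: dict[str, float | None] = {}
    provenance: dict[str, str] = {}
    for mid, (a, b) in MEASUREMENT_DEFINITIONS.items():
        if a in lm and b in lm:
            values[mid] = _distance_cm(lm[a], lm[b])
        else:
            values[mid] = None
            provenance[mid] = "missing"
    pw, pw_prov = palatal_width(lm)
    values["palatal_width"] = pw
    provenance["palatal_width"] = pw_prov
    if all(v is None for v in values.values()):
        raise ValueError("no measurement is definable from the given landmarks")
    return AnthropometryResult(values, provenance)


def _quantize(value: float | None, step_cm: float) -> float | None:
    if value is None:
        return None
    return round(value / step_cm) * step_cm


def repeat_measurements(
    session_a: Mapping[str, LandmarkSet],
    session_b: Mapping[str, LandmarkSet],
    quantize_step_cm: float | None = None,
):
    """Two measurement sessions -> per-measurement two-column tables.

    ``session_a`` and ``session_b`` map subject ids to landmark sets and
    must cover the same subjects.  Optional quantization to ``step`` cm
    (0.05 cm emulates a 0.5 mm caliper resolution).  Returns a dict
    measurement id -> :class:`~oralsurf.stats.MeasurementTable`.
    """
    from .stats import MeasurementTable

    if set(session_a) != set(session_b):
        raise ValueError("the two sessions must cover the same subjects")
    subjects = sorted(session_a)
    results_a = {s: measure_all(session_a[s]) for s in subjects}
    results_b = {s: measure_all(session_b[s]) for s in subjects}
    tables = {}
    for mid in ALL_MEASUREMENT_IDS:
        rows = []
        for s in subjects:
            va, vb = results_a[s].values[mid], results_b[s].values[mid]
            if quantize_step_cm:
                va = _quantize(va, quantize_step_cm)
                vb = _quantize(vb, quantize_step_cm)
            rows.append([np.nan if va is None else va, np.nan if vb is None else vb])
        tables[mid] = MeasurementTable(
            values=np.asarray(rows, dtype=float),
            subject_ids=tuple(subjects),
            column_kind="repeat",
        )
    return tables


def results_to_rows(results: Mapping[str, AnthropometryResult]) -> Iterable[dict]:
    """Flatten per-subject results for CSV export."""
    for subject, res in results.items():
        for mid in ALL_MEASUREMENT_IDS:
            yield {
                "subject": subject,
                "measurement": mid,
                "name": MEASUREMENT_NAMES[mid],
                "value_cm": res.values[mid],
                "provenance": res.provenance.get(mid, ""),
            }
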