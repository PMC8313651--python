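"""Bronchial landmark scoring: the registration-quality score D.

An expert marks 25 bronchial landmarks (Boyden nomenclature) in the
diagnostic CT and checks their position in the registered low-dose CT.  For
the large airways (trachea, main bronchi) the centre-to-centre distance is
measured in mm and converted to a distance-type quantity 1 / 0.5 / 0 by
comparison with 10% and 20% of the bronchial diameter; for every smaller
bronchus an in-lumen indicator 1/0 is recorded directly.  D is the weighted
sum of the 25 quantities with weights 16 (trachea), 7 (main bronchi),
3 (lobar) and 1 (segmental), roughly proportional to bronchial cross
section, for a maximum of 62.

Missing measurements carry two distinct codes — ``NA`` (not identifiable in
the low-dose CT) and ``NULL`` (absent or obscured in the diagnostic CT) —
both of which contribute 0 to D but are preserved in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InputShapeError, ValidationError

__all__ = [
    "Landmark", "ScoreResult", "LANDMARKS", "LANDMARK_ORDER", "MAX_SCORE",
    "NA", "NULL", "MISSING_CODES", "convert_measurement", "compute_score",
    "score_table", "read_landmark_table", "write_landmark_table",
    "write_score_table",
]

NA = "NA"
NULL = "NULL"
MISSING_CODES = (NA, NULL)

MeasurementValue = Union[float, int, str]


@dataclass(frozen=True)
class Landmark:
    """One of the 25 scored bronchial landmarks."""

    code: str
    category: str              # trachea | main-bronchus | lobar | segmental
    weight: int
    reference_diameter_mm: float | None = None  # trachea / main bronchi only

    @property
    def is_distance(self) -> bool:
        """True if measured as a mm distance (trachea and main bronchi)."""
        return self.reference_diameter_mm is not None

    @property
    def threshold_10pct(self) -> float:
        return 0.1 * self.reference_diameter_mm

    @property
    def threshold_20pct(self) -> float:
        return 0.2 * self.reference_diameter_mm


def _default_landmarks() -> Mapping[str, Landmark]:
    # Reference diameters chosen so that 10%/20% reproduce the published
    # thresholds: trachea 1.8/3.6 mm, main bronchi 1.22/2.44 mm.
    lms = [Landmark("TB", "trachea", 16, 18.0)]
    lms += [Landmark(c, "main-bronchus", 7, 12.2) for c in ("RMB", "LMB")]
    lms += [Landmark(c, "lobar", 3) for c in ("RULB", "RMLB", "RLLB")]
    lms += [Landmark(c, "segmental", 1)
            for c in ("RB1", "RB2", "RB3", "RB4", "RB5", "RB6",
                      "RB8", "RB9", "RB10")]
    lms += [Landmark(c, "lobar", 3) for c in ("LULB", "LLLB")]
    lms += [Landmark(c, "segmental", 1)
            for c in ("LB1/2", "LB3", "LB4", "LB5", "LB6",
                      "LB8", "LB9", "LB10")]
    return MappingProxyType({lm.code: lm for lm in lms})


#: The 25 landmarks with the published weights and diameter thresholds,
#: in the column order of the measurement tables.
LANDMARKS: Mapping[str, Landmark] = _default_landmarks()
LANDMARK_ORDER: tuple[str, ...] = tuple(LANDMARKS)
MAX_SCORE: int = sum(lm.weight for lm in LANDMARKS.values())

assert len(LANDMARK_ORDER) == 25 and MAX_SCORE == 62


def _is_missing(value: MeasurementValue) -> bool:
    return isinstance(value, str) and value.strip().upper() in MISSING_CODES


def convert_measurement(landmark: Landmark, value: MeasurementValue) -> float | None:
    """Convert one raw measurement into a distance-type quantity.

    Returns 1, 0.5 or 0 for distance landmarks (closed upper bound on each
    class: d <= 10% of diameter -> 1, 10% < d <= 20% -> 0.5, d > 20% -> 0),
    the 0/1 indicator itself for the remaining bronchi, and ``None`` for the
    missing codes NA/NULL.
    """
    if _is_missing(value):
        return None
    if isinstance(value, str):
        try:
            value = float(value)
        except ValueError:
            raise ValidationError(
                f"{landmark.code}: non-numeric measurement {value!r}") from None
    value = float(value)
    if landmark.is_distance:
        if value < 0:
            raise ValidationError(
                f"{landmark.code}: negative distance {value} mm")
        if value <= landmark.threshold_10pct:
            return 1.0
        if value <= landmark.threshold_20pct:
            return 0.5
        return 0.0
    if value not in (0.0, 1.0):
        raise InputShapeError(
            f"{landmark.code} takes a 0/1 in-lumen indicator, got {value}")
    return value


@dataclass(frozen=True)
class ScoreResult:
    """Per-patient distance-type quantities and the weighted score D."""

    patient: str
    quantities: Mapping[str, float | None]   # per landmark; None = missing
    weighted: Mapping[str, float | None]     # weight x quantity; None = missing
    score_D: float

    def __post_init__(self):
        if not (0.0 <= self.score_D <= MAX_SCORE):
            raise ValidationError(
                f"score D={self.score_D} outside [0, {MAX_SCORE}]")


def compute_score(row: Mapping[str, MeasurementValue],
                  patient: str = "",
                  landmarks: Mapping[str, Landmark] = LANDMARKS) -> ScoreResult:
    """Score one patient's complete set of landmark measurements.

    ``row`` must contain a measurement for every landmark code.  Missing
    measurements (NA/NULL) contribute 0; the per-landmark weighted
    contributions are retained so a score table can be regenerated cell by
    cell.
    """
    absent = [code for code in landmarks if code not in row]
    if absent:
        raise ValidationError(
            f"incomplete row for {patient or '<patient>'}: missing {absent}")
    quantities: dict[str, float | None] = {}
    weighted: dict[str, float | None] = {}
    total = 0.0
    for code, lm in landmarks.items():
        q = convert_measurement(lm, row[code])
        quantities[code] = q
        weighted[code] = None if q is None else lm.weight * q
        if q is not None:
            total += lm.weight * q
    return ScoreResult(patient=patient, quantities=quantities,
                       weighted=weighted, score_D=total)


def score_table(table: pd.DataFrame,
                landmarks: Mapping[str, Landmark] = LANDMARKS) -> pd.DataFrame:
    """Score every row of a landmark table.

    Returns a frame indexed like the input with one column per landmark
    (weighted contribution; NaN where the measurement was missing) and a
    final ``score`` column.
    """
    results = [compute_score(table.loc[pat].to_dict(), str(pat), landmarks)
               for pat in table.index]
    out = pd.DataFrame(
        [{**{c: (np.nan if r.weighted[c] is None else r.weighted[c])
             for c in landmarks}, "score": r.score_D} for r in results],
        index=table.index)
    return out


# ---------------------------------------------------------------------------
# CSV I/O.  One row per patient, columns in the published order, tokens
# NA/NULL recognised case-insensitively and preserved on write.

def _parse_cell(code: str, raw: str) -> MeasurementValue:
    token = str(raw).strip()
    if token.upper() in MISSING_CODES:
        return token.upper()
    try:
        return float(token)
    except ValueError:
        raise ValidationError(
            f"column {code}: non-numeric cell {raw!r} (expected a number, "
            f"NA or NULL)") from None


def read_landmark_table(path,
                        landmarks: Mapping[str, Landmark] = LANDMARKS) -> pd.DataFrame:
    """Read a landmark measurement CSV into a patient-indexed DataFrame.

    Cells are floats or the strings ``"NA"`` / ``"NULL"``.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty landmark table") from None
    if "patient" not in raw.columns:
        raise ValidationError(f"{path}: missing 'patient' column")
    unknown = [c for c in raw.columns if c not in landmarks and c != "patient"]
    if unknown:
        raise ValidationError(f"{path}: unknown landmark column(s) {unknown}")
    absent = [c for c in landmarks if c not in raw.columns]
    if absent:
        raise ValidationError(f"{path}: missing landmark column(s) {absent}")
    if raw["patient"].duplicated().any():
        dupes = raw.loc[raw["patient"].duplicated(), "patient"].tolist()
        raise ValidationError(f"{path}: duplicate patient id(s) {dupes}")
    if len(raw) == 0:
        raise ValidationError(f"{path}: no patient rows")
    table = raw.set_index("patient")[list(landmarks)]
    return table.apply(lambda col: [_parse_cell(col.name, v) for v in col])


def write_landmark_table(table: pd.DataFrame, path) -> None:
    out = table.copy()

    def fmt(v):
        if isinstance(v, str):
            return v
        f = float(v)
        return str(int(f)) if f == int(f) else repr(f)

    out = out.map(fmt)
    out.index.name = "patient"
    out.to_csv(path)


def write_score_table(scores: pd.DataFrame, path) -> None:
    """Write a score table; missing contributions are written as ``NA``."""
    out = scores.copy()

    def fmt(v):
        if pd.isna(v):
            return NA
        f = float(v)
        return str(int(f)) if f == int(f) else repr(f)

    out = out.map(fmt)
    out.index.name = "patient"
    out.to_csv(path)
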