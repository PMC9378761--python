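"""Facial landmark records and interocular-normalized distance phenotypes.

A face record carries 19 named planar landmark points plus the two iris
centers.  Every distance phenotype is the Euclidean distance between a
landmark pair divided by the interocular distance (left iris center to
right iris center), so the interocular distance itself always maps to 1
and the output is invariant under translation, rotation and uniform
scaling of the photograph.

The default measurement table defines 10 horizontal (H1-H10) and 11
vertical (V1-V11) pairs over standard anthropometric landmarks.  The
pair definitions are configurable: users with a different measurement
protocol can load their own table from a config mapping.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LANDMARK_NAMES",
    "IRIS_LEFT",
    "IRIS_RIGHT",
    "LandmarkSet",
    "Measurement",
    "MeasurementTable",
    "PhenotypeVector",
    "read_landmarks",
    "compute_phenotypes",
    "phenotypes_to_frame",
]

#: The 19 named landmark points required on every face record.
#: Abbreviations follow standard facial anthropometry: en/ex = endo-/
#: exocanthion (inner/outer eye corner), n = nasion, prn = pronasale,
#: sn = subnasale, al = alare, ch = cheilion (mouth corner), ls/li =
#: labiale superius/inferius, sto = stomion, gn = gnathion (chin),
#: zy = zygion, go = gonion.  _l/_r denote the subject's left/right.
LANDMARK_NAMES: tuple[str, ...] = (
    "en_l", "en_r",
    "ex_l", "ex_r",
    "n",
    "prn",
    "sn",
    "al_l", "al_r",
    "ch_l", "ch_r",
    "ls",
    "sto",
    "li",
    "gn",
    "zy_l", "zy_r",
    "go_l", "go_r",
)

IRIS_LEFT = "iris_L"
IRIS_RIGHT = "iris_R"

#: Maximum plausible current age (years); guards obvious data entry errors.
DEFAULT_MAX_AGE = 25.0


@dataclass(frozen=True)
class LandmarkSet:
    """One photo's 19 landmark points, iris centers and age metadata."""

    person_id: str
    photo_id: str
    age: float
    current_age: float
    points: Mapping[str, tuple[float, float]]
    iris_left: tuple[float, float]
    iris_right: tuple[float, float]

    def validate(self, max_age: float = DEFAULT_MAX_AGE) -> None:
        missing = [nm for nm in LANDMARK_NAMES if nm not in self.points]
        if missing:
            raise ValueError(f"missing landmark(s): {', '.join(missing)}")
        extra = [nm for nm in self.points if nm not in LANDMARK_NAMES]
        if extra:
            raise ValueError(f"unknown landmark(s): {', '.join(extra)}")
        if self.interocular_distance() == 0.0:
            raise ValueError("degenerate interocular distance")
        if not (0 < self.age <= self.current_age <= max_age):
            raise ValueError(
                f"ages violate 0 < age ({self.age}) <= current_age "
                f"({self.current_age}) <= {max_age}"
            )

    def interocular_distance(self) -> float:
        return math.dist(self.iris_left, self.iris_right)

    def coordinate(self, name: str) -> tuple[float, float]:
        """Resolve a point name; iris centers are addressable like landmarks."""
        if name == IRIS_LEFT:
            return self.iris_left
        if name == IRIS_RIGHT:
            return self.iris_right
        try:
            return self.points[name]
        except KeyError:
            raise KeyError(f"unknown landmark name {name!r}") from None


@dataclass(frozen=True)
class Measurement:
    name: str
    point_a: str
    point_b: str
    axis: str  # "horizontal" | "vertical"


class MeasurementTable:
    """An ordered set of named landmark-pair measurements.

    The default table has exactly 10 horizontal and 11 vertical entries.
    Custom tables (e.g. loaded from config) may have any composition but
    names must be unique and axes valid.
    """

    def __init__(self, entries: Sequence[Measurement], *, strict_default_shape: bool = False):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("measurement names must be unique")
        for e in entries:
            if e.axis not in ("horizontal", "vertical"):
                raise ValueError(f"{e.name}: axis must be horizontal|vertical, got {e.axis!r}")
            for pt in (e.point_a, e.point_b):
                if pt not in LANDMARK_NAMES and pt not in (IRIS_LEFT, IRIS_RIGHT):
                    raise ValueError(f"{e.name}: unknown landmark {pt!r}")
        if strict_default_shape:
            n_h = sum(e.axis == "horizontal" for e in entries)
            n_v = sum(e.axis == "vertical" for e in entries)
            if (n_h, n_v) != (10, 11):
                raise ValueError(f"expected 10 horizontal + 11 vertical, got {n_h} + {n_v}")
        self.entries: tuple[Measurement, ...] = tuple(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @classmethod
    def default(cls) -> "MeasurementTable":
        h = [
            ("H1", "ex_l", "ex_r"),   # outer eye-corner width
            ("H2", "en_l", "en_r"),   # inner eye-corner width
            ("H3", "zy_l", "zy_r"),   # upper facial width
            ("H4", "go_l", "go_r"),   # lower facial width
            ("H5", "al_l", "al_r"),   # nose width
            ("H6", "ch_l", "ch_r"),   # mouth width
            ("H7", "en_l", "ex_l"),   # left eye width
            ("H8", "en_r", "ex_r"),   # right eye width
            ("H9", "al_l", "ch_l"),   # left nose-mouth diagonal
            ("H10", "al_r", "ch_r"),  # right nose-mouth diagonal
        ]
        v = [
            ("V1", "n", "gn"),    # facial height
            ("V2", "n", "sn"),    # nose height
            ("V3", "sn", "gn"),   # lower face height
            ("V4", "n", "prn"),   # nasal bridge length
            ("V5", "prn", "sn"),  # nose tip to base
            ("V6", "sn", "ls"),   # philtrum
            ("V7", "ls", "sto"),  # upper lip
            ("V8", "sto", "li"),  # lower lip
            ("V9", "li", "gn"),   # lip to chin
            ("V10", "n", "sto"),  # nasion to mouth
            ("V11", "sn", "sto"), # subnasale to mouth
        ]
        entries = [Measurement(nm, a, b, "horizontal") for nm, a, b in h]
        entries += [Measurement(nm, a, b, "vertical") for nm, a, b in v]
        return cls(entries, strict_default_shape=True)

    @classmethod
    def from_config(cls, items: Iterable[Mapping[str, str]]) -> "MeasurementTable":
        """Build a table from config entries with keys name/point_a/point_b/axis."""
        entries = []
        for item in items:
            try:
                entries.append(
                    Measurement(item["name"], item["point_a"], item["point_b"], item["axis"])
                )
            except KeyError as exc:
                raise ValueError(f"measurement entry missing key {exc}") from None
        return cls(entries)

    def to_config(self) -> list[dict[str, str]]:
        return [
            {"name": e.name, "point_a": e.point_a, "point_b": e.point_b, "axis": e.axis}
            for e in self.entries
        ]


@dataclass(frozen=True)
class PhenotypeVector:
    """Normalized distances for one photo, in units of interocular distances."""

    person_id: str
    photo_id: str
    age: float
    current_age: float
    values: Mapping[str, float] = field(default_factory=dict)


def _landmark_columns() -> list[str]:
    cols = ["person_id", "photo_id", "age", "current_age",
            "iris_L_x", "iris_L_y", "iris_R_x", "iris_R_y"]
    for nm in LANDMARK_NAMES:
        cols += [f"{nm}_x", f"{nm}_y"]
    return cols


LANDMARK_CSV_COLUMNS = _landmark_columns()


def read_landmarks(path, *, max_age: float = DEFAULT_MAX_AGE) -> list[LandmarkSet]:
    """Read a landmark CSV into validated :class:`LandmarkSet` records.

    Rows that violate the schema or record invariants raise ``ValueError``
    with the 1-based data row number in the message.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in LANDMARK_CSV_COLUMNS if c not in header]
        if missing_cols:
            raise ValueError(f"{path}: missing column(s): {', '.join(missing_cols)}")
        out: list[LandmarkSet] = []
        seen: set[tuple[str, str]] = set()
        for i, row in enumerate(reader, start=1):
            try:
                lm = _parse_row(row)
                lm.validate(max_age=max_age)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from None
            key = (lm.person_id, lm.photo_id)
            if key in seen:
                raise ValueError(f"{path}: row {i}: duplicate (person_id, photo_id) {key}")
            seen.add(key)
            out.append(lm)
    return out


def _parse_row(row: Mapping[str, str]) -> LandmarkSet:
    def num(col: str) -> float:
        raw = row[col]
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric value {raw!r} in column {col!r}") from None

    points = {nm: (num(f"{nm}_x"), num(f"{nm}_y")) for nm in LANDMARK_NAMES}
    return LandmarkSet(
        person_id=str(row["person_id"]),
        photo_id=str(row["photo_id"]),
        age=num("age"),
        current_age=num("current_age"),
        points=points,
        iris_left=(num("iris_L_x"), num("iris_L_y")),
        iris_right=(num("iris_R_x"), num("iris_R_y")),
    )


def compute_phenotypes(lm: LandmarkSet, table: MeasurementTable | None = None) -> PhenotypeVector:
    """Compute every table measurement as an interocular-normalized distance."""
    if table is None:
        table = MeasurementTable.default()
    iod = lm.interocular_distance()
    if iod == 0.0:
        raise ValueError("degenerate interocular distance")
    values = {
        e.name: math.dist(lm.coordinate(e.point_a), lm.coordinate(e.point_b)) / iod
        for e in table
    }
    return PhenotypeVector(lm.person_id, lm.photo_id, lm.age, lm.current_age, values)


def phenotypes_to_frame(vectors: Iterable[PhenotypeVector]) -> pd.DataFrame:
    """Long-format phenotype table: one row per (photo, phenotype)."""
    records = [
        (v.person_id, v.photo_id, v.age, v.current_age, name, value)
        for v in vectors
        for name, value in v.values.items()
    ]
    return pd.DataFrame(
        records,
        columns=["person_id", "photo_id", "age", "current_age", "phenotype", "value"],
    )
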