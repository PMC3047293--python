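"""Domain types, 24-2 grid geometry, and cohort I/O.

The atomic analysis unit is the :class:`EyeRecord`: one eye's same-day pairing
of a Humphrey 24-2 visual field (pointwise Total Deviation, in dB) and an HRT
optic-disc scan (measured and Moorfields-predicted rim area per sector, in
mm^2), plus a diagnosis label.

Coordinate convention (both eyes): ``x`` positive rightward in field space,
``y`` positive superior.  Stored data are never mirrored between lateralities;
laterality differences are absorbed by per-laterality reference models.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

log = logging.getLogger("sfindex")

LATERALITIES = ("right", "left")

#: The six HRT disc sectors, in canonical order.
SECTORS = (
    "temporal",
    "superotemporal",
    "superonasal",
    "nasal",
    "inferonasal",
    "inferotemporal",
)

#: Angular arc [start, end) of each sector on the disc circumference, degrees.
#: Anatomical convention for both eyes: 0 deg = temporal pole, 90 deg =
#: superior, 180 deg = nasal, 270 deg = inferior.  The temporal arc wraps
#: through 0 and is stored as [315, 405).  The six arcs partition the circle.
SECTOR_ARCS = {
    "temporal": (315.0, 405.0),
    "superotemporal": (45.0, 90.0),
    "superonasal": (90.0, 135.0),
    "nasal": (135.0, 225.0),
    "inferonasal": (225.0, 270.0),
    "inferotemporal": (270.0, 315.0),
}

GROUP_LABELS = ("reference", "suspect", "glaucoma")

GHT_CATEGORIES = (
    "within_normal_limits",
    "borderline",
    "outside_normal_limits",
    "other",
)
MFC_CATEGORIES = ("within_normal_limits", "borderline", "outside_normal_limits")


class SchemaError(ValueError):
    """A cohort file does not conform to the documented schema."""


class ValidationError(ValueError):
    """A record violates a type invariant."""


class FieldLocation(NamedTuple):
    """A 24-2 test location in degrees of eccentricity."""

    x: int
    y: int


def _check_laterality(laterality: str) -> str:
    if laterality not in LATERALITIES:
        raise ValidationError(f"invalid laterality {laterality!r}")
    return laterality


# ---------------------------------------------------------------------------
# 24-2 grid geometry
# ---------------------------------------------------------------------------

# Row layout of the standard 24-2 lattice: y -> base x offsets.  The rows at
# y = +/-3 additionally carry one nasal-extension point at 27 deg eccentricity
# on the nasal side (x = -27 for right eyes, +27 for left eyes).
_ROW_X = {
    21: (-9, -3, 3, 9),
    15: (-15, -9, -3, 3, 9, 15),
    9: (-21, -15, -9, -3, 3, 9, 15, 21),
    3: (-21, -15, -9, -3, 3, 9, 15, 21),
}


def blind_spot(laterality: str) -> tuple[FieldLocation, FieldLocation]:
    """The two 24-2 locations overlying the optic-nerve head (never scored)."""
    _check_laterality(laterality)
    bx = 15 if laterality == "right" else -15
    return (FieldLocation(bx, 3), FieldLocation(bx, -3))


def full_grid_24_2(laterality: str) -> list[FieldLocation]:
    """All 54 locations of the 24-2 pattern, blind spot included.

    Order: rows superior to inferior, x ascending within each row.
    """
    _check_laterality(laterality)
    ext = -27 if laterality == "right" else 27
    points: list[FieldLocation] = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        xs = list(_ROW_X[abs(y)])
        if abs(y) == 3:
            xs.append(ext)
        for x in sorted(xs):
            points.append(FieldLocation(x, y))
    return points


def grid_24_2(laterality: str) -> list[FieldLocation]:
    """The 52 scored 24-2 locations (blind spot excluded), deterministic order."""
    bs = set(blind_spot(laterality))
    return [p for p in full_grid_24_2(laterality) if p not in bs]


def mirror_location(point: FieldLocation) -> FieldLocation:
    """Reflect a field location through the vertical meridian (x -> -x)."""
    return FieldLocation(-point.x, point.y)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VisualField:
    """A reliable 24-2 field: Total Deviation per scored point plus MD/PSD."""

    laterality: str
    total_deviation: dict[FieldLocation, float]
    md: float
    psd: float
    reliable: bool = True
    ght_category: Optional[str] = None

    def validate(self) -> None:
        _check_laterality(self.laterality)
        expected = set(grid_24_2(self.laterality))
        got = set(self.total_deviation)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValidationError(
                f"total deviation keys do not match the {self.laterality}-eye "
                f"24-2 grid (missing {missing[:4]}..., extra {extra[:4]}...)"
                if missing or extra
                else "bad total deviation keys"
            )
        for p, v in self.total_deviation.items():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite TD at {p}")
        if not (math.isfinite(self.md) and math.isfinite(self.psd)):
            raise ValidationError("MD/PSD must be finite")
        if self.ght_category is not None and self.ght_category not in GHT_CATEGORIES:
            raise ValidationError(f"invalid GHT category {self.ght_category!r}")


@dataclass
class OpticDiscScan:
    """One HRT scan: measured and Moorfields-predicted rim area per sector.

    The Moorfields-predicted rim area (which normalises for disc area and age)
    is a required input; this package does not compute the regression itself.
    """

    laterality: str
    measured_rim_area: dict[str, float]
    predicted_rim_area: dict[str, float]
    quality_acceptable: bool = True
    mfc_category: Optional[str] = None

    def validate(self) -> None:
        _check_laterality(self.laterality)
        for name, mapping in (
            ("measured_rim_area", self.measured_rim_area),
            ("predicted_rim_area", self.predicted_rim_area),
        ):
            if set(mapping) != set(SECTORS):
                raise ValidationError(f"{name} must cover all six sectors")
            for s, v in mapping.items():
                if not (isinstance(v, (int, float)) and v == v and v >= 0):
                    raise ValidationError(f"{name}[{s}] must be >= 0, got {v!r}")
        if self.mfc_category is not None and self.mfc_category not in MFC_CATEGORIES:
            raise ValidationError(f"invalid MFC category {self.mfc_category!r}")


@dataclass
class EyeRecord:
    """One eye's paired same-day field and disc measurements plus labels."""

    subject_id: str
    laterality: str
    field: VisualField
    disc: OpticDiscScan
    group_label: str

    def validate(self) -> None:
        _check_laterality(self.laterality)
        if self.group_label not in GROUP_LABELS:
            raise ValidationError(f"invalid group label {self.group_label!r}")
        if not (self.field.laterality == self.disc.laterality == self.laterality):
            raise ValidationError("laterality mismatch between record, field and disc")
        self.field.validate()
        self.disc.validate()


# ---------------------------------------------------------------------------
# Cohort serialization (delimited text)
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = [
    "subject_id",
    "laterality",
    "group_label",
    "md",
    "psd",
    "reliable",
    "ght_category",
    "quality_acceptable",
    "mfc_category",
]


def _td_column(p: FieldLocation) -> str:
    return f"td_{p.x}_{p.y}"


def _all_td_columns() -> list[str]:
    # Union over lateralities so mixed cohorts share one header.
    cols: list[str] = []
    seen = set()
    for lat in LATERALITIES:
        for p in grid_24_2(lat):
            c = _td_column(p)
            if c not in seen:
                seen.add(c)
                cols.append(c)
    return cols


def cohort_columns() -> list[str]:
    """The full ordered column set of the cohort CSV schema."""
    cols = list(_FIXED_COLUMNS) + _all_td_columns()
    cols += [f"rim_measured_{s}" for s in SECTORS]
    cols += [f"rim_predicted_{s}" for s in SECTORS]
    return cols


def _record_to_row(rec: EyeRecord) -> dict[str, str]:
    row = {
        "subject_id": rec.subject_id,
        "laterality": rec.laterality,
        "group_label": rec.group_label,
        "md": repr(float(rec.field.md)),
        "psd": repr(float(rec.field.psd)),
        "reliable": "1" if rec.field.reliable else "0",
        "ght_category": rec.field.ght_category or "",
        "quality_acceptable": "1" if rec.disc.quality_acceptable else "0",
        "mfc_category": rec.disc.mfc_category or "",
    }
    for p, v in rec.field.total_deviation.items():
        row[_td_column(p)] = repr(float(v))
    for s in SECTORS:
        row[f"rim_measured_{s}"] = repr(float(rec.disc.measured_rim_area[s]))
        row[f"rim_predicted_{s}"] = repr(float(rec.disc.predicted_rim_area[s]))
    return row


def _row_to_record(row: dict[str, str]) -> EyeRecord:
    laterality = _check_laterality(row["laterality"].strip())
    td = {}
    for p in grid_24_2(laterality):
        col = _td_column(p)
        raw = row.get(col, "")
        if raw is None or raw.strip() == "":
            raise ValidationError(f"missing TD value in column {col}")
        td[p] = float(raw)
    vf = VisualField(
        laterality=laterality,
        total_deviation=td,
        md=float(row["md"]),
        psd=float(row["psd"]),
        reliable=row.get("reliable", "1").strip() in ("1", "true", "True"),
        ght_category=(row.get("ght_category") or "").strip() or None,
    )
    measured = {}
    predicted = {}
    for s in SECTORS:
        for prefix, target in (("rim_measured_", measured), ("rim_predicted_", predicted)):
            raw = row.get(prefix + s, "")
            if raw is None or raw.strip() == "":
                raise ValidationError(f"missing rim area in column {prefix + s}")
            target[s] = float(raw)
    disc = OpticDiscScan(
        laterality=laterality,
        measured_rim_area=measured,
        predicted_rim_area=predicted,
        quality_acceptable=row.get("quality_acceptable", "1").strip()
        in ("1", "true", "True"),
        mfc_category=(row.get("mfc_category") or "").strip() or None,
    )
    rec = EyeRecord(
        subject_id=row["subject_id"].strip(),
        laterality=laterality,
        field=vf,
        disc=disc,
        group_label=row["group_label"].strip(),
    )
    rec.validate()
    return rec


def write_cohort(records: Iterable[EyeRecord], path) -> None:
    """Write records as a comma-delimited cohort file (lossless round-trip).

    Numeric values are serialized at full ``repr`` precision so that
    ``read_cohort(write_cohort(x))`` reproduces ``x`` bitwise.
    """
    records = list(records)
    for rec in records:
        rec.validate()
    cols = cohort_columns()
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, restval="")
        writer.writeheader()
        for rec in records:
            writer.writerow(_record_to_row(rec))


def read_cohort(path, errors: Optional[list] = None) -> list[EyeRecord]:
    """Read a cohort file; invalid rows are reported and skipped.

    Parameters
    ----------
    path
        Comma-delimited cohort file produced by :func:`write_cohort` (or
        conforming to the same schema).
    errors
        Optional list; ``(row_number, reason)`` tuples for rejected rows are
        appended to it.  Rejections are also logged as warnings.

    Raises
    ------
    SchemaError
        If a mandatory (non-TD) column is absent from the header.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _FIXED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"cohort file is missing mandatory columns {missing}")
        out: list[EyeRecord] = []
        for i, row in enumerate(reader, start=2):  # 1-based, header is line 1
            try:
                out.append(_row_to_record(row))
            except (ValidationError, ValueError, KeyError) as exc:
                log.warning("cohort row %d rejected: %s", i, exc)
                if errors is not None:
                    errors.append((i, str(exc)))
    return out


# ---------------------------------------------------------------------------
# Record selection
# ---------------------------------------------------------------------------


def select_worse_eye(records: Sequence[EyeRecord]) -> list[EyeRecord]:
    """Keep at most one eye per subject: the one with the worse (lower) MD.

    On an exact MD tie the right eye is retained (documented tie-break).
    Order of first appearance of each subject is preserved.
    """
    by_subject: dict[str, list[EyeRecord]] = {}
    order: list[str] = []
    seen_pairs = set()
    for rec in records:
        key = (rec.subject_id, rec.laterality)
        if key in seen_pairs:
            raise ValidationError(f"duplicate (subject, laterality) pair {key}")
        seen_pairs.add(key)
        if not math.isfinite(rec.field.md):
            raise ValidationError(f"non-finite MD for subject {rec.subject_id}")
        if rec.subject_id not in by_subject:
            order.append(rec.subject_id)
        by_subject.setdefault(rec.subject_id, []).append(rec)
    out = []
    for sid in order:
        eyes = by_subject[sid]
        if len(eyes) == 1:
            out.append(eyes[0])
        else:
            worst_md = min(e.field.md for e in eyes)
            worst = [e for e in eyes if e.field.md == worst_md]
            right = [e for e in worst if e.laterality == "right"]
            out.append(right[0] if right else worst[0])
    return out
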