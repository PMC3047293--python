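"""The pointwise Structure Function Index.

For one eye and one field location the index fuses three probabilities:

* ``P(field)`` — probability that the location's Total Deviation is abnormal
  (one minus its reference-CPF value);
* ``P(sector)`` — probability that a disc sector's rim-area difference is
  abnormal (one minus its reference-CPF value);
* ``P(anatomy)`` — probability that the location's nerve fiber bundle inserts
  in that sector.

The index is ``P(field) * sum_sectors P(sector) * P(anatomy)``: the joint
probability of a structure-function abnormality at that location, summed
over the possible anatomical routes.  Abnormalities in field and disc only
raise the index when the anatomy makes them compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import SectorLinkage
from .io_model import SECTORS, EyeRecord, FieldLocation, ValidationError, grid_24_2
from .reference import ReferenceModel, rim_area_difference

#: Anatomy probabilities below this contribute only zero terms and are skipped.
ANATOMY_EPS = 1e-6

#: Tolerance on the normalization of the anatomy vector.
ANATOMY_SUM_TOL = 1e-6


@dataclass
class SFIResult:
    """Pointwise index values for one eye, with provenance."""

    laterality: str
    values: dict[FieldLocation, float]  # 52 entries, each in [0, 1]
    subject_id: str = ""
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.values) != set(grid_24_2(self.laterality)):
            raise ValidationError("index values do not cover the 24-2 grid")
        for p, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"index at {p} outside [0, 1]: {v}")


def sfi_point(
    p_field_abn: float,
    p_sector_abn: np.ndarray,
    p_anatomy: np.ndarray,
) -> float:
    """Fuse the three probabilities at a single field location.

    Parameters
    ----------
    p_field_abn
        Probability that the field location is abnormal, in [0, 1].
    p_sector_abn
        6-vector of per-sector abnormality probabilities, each in [0, 1],
        ordered as :data:`sfindex.io_model.SECTORS`.
    p_anatomy
        6-vector of anatomical linkage probabilities; must sum to 1.
    """
    p_sector_abn = np.asarray(p_sector_abn, dtype=float)
    p_anatomy = np.asarray(p_anatomy, dtype=float)
    if p_sector_abn.shape != (6,) or p_anatomy.shape != (6,):
        raise ValueError("sector and anatomy vectors must have length 6")
    if not 0.0 <= p_field_abn <= 1.0:
        raise ValueError(f"p_field_abn outside [0, 1]: {p_field_abn}")
    if np.any(p_sector_abn < 0) or np.any(p_sector_abn > 1):
        raise ValueError("sector abnormality probabilities outside [0, 1]")
    if np.any(p_anatomy < 0) or abs(p_anatomy.sum() - 1.0) > ANATOMY_SUM_TOL:
        raise ValueError(
            f"anatomy vector must be non-negative and sum to 1 "
            f"(sum = {p_anatomy.sum():.9f})"
        )
    mask = p_anatomy >= ANATOMY_EPS
    return float(p_field_abn * np.sum(p_sector_abn[mask] * p_anatomy[mask]))


def score_eye(
    record: EyeRecord,
    model: ReferenceModel,
    linkage: SectorLinkage,
) -> SFIResult:
    """Compute the pointwise index for every scored location of one eye.

    The record, reference model and anatomical linkage must share one
    laterality.  Deterministic: rescoring the same record is bitwise
    identical.
    """
    record.validate()
    model.validate()
    if not (record.laterality == model.laterality == linkage.laterality):
        raise ValidationError(
            "record, reference model and linkage lateralities disagree"
        )
    diffs = rim_area_difference(record.disc)
    p_sector_abn = np.array(
        [1.0 - model.sector_cpfs[s].evaluate(diffs[s]) for s in SECTORS]
    )
    values: dict[FieldLocation, float] = {}
    for p in grid_24_2(record.laterality):
        if p not in model.field_cpfs:
            raise ValidationError(f"reference model lacks a CPF for {p}")
        if p not in linkage.probabilities:
            raise ValidationError(f"linkage lacks probabilities for {p}")
        p_field_abn = 1.0 - model.field_cpfs[p].evaluate(
            record.field.total_deviation[p]
        )
        values[p] = sfi_point(p_field_abn, p_sector_abn, linkage.vector(p))
    return SFIResult(
        laterality=record.laterality,
        values=values,
        subject_id=record.subject_id,
        provenance={"n_reference_eyes": model.n_eyes},
    )


def mean_sfi(result: SFIResult) -> float:
    """Arithmetic mean of the 52 pointwise index values (per-eye summary)."""
    result.validate()
    return float(np.mean(list(result.values.values())))
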