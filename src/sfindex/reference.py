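"""Empirical cumulative probability functions (CPFs) and the reference model.

The diagnostic index rests on *continuous* probabilities of abnormality
rather than the device's sparse categorical cutoffs.  For every 24-2 field
location the reference cohort's Total Deviation values define an empirical
cumulative probability function; likewise for every disc sector the
measured-minus-Moorfields-predicted rim-area differences.  Evaluating a CPF
at an observed value returns the probability that the value is *normal*
(low values of TD or rim difference sit low on the curve); the probability
of abnormality is one minus that.

Evaluation uses Hazen plotting positions, ``(i - 0.5) / n`` at the i-th
order statistic, with linear interpolation between order statistics and
clamping to ``[1/(2n), 1 - 1/(2n)]`` so that neither probability ever reaches
exactly 0 or 1 (the hemifield region score diverges as the index approaches
1, so the clamp keeps downstream scores finite).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_model import (
    SECTORS,
    EyeRecord,
    FieldLocation,
    OpticDiscScan,
    ValidationError,
    grid_24_2,
)

MODEL_FORMAT_VERSION = 1

#: Minimum reference sample size for fitting a CPF.
DEFAULT_MIN_N = 20


class FitError(ValueError):
    """Raised when a CPF or reference model cannot be fitted."""


def rim_area_difference(disc: OpticDiscScan) -> dict[str, float]:
    """Per-sector measured minus Moorfields-predicted rim area (mm^2).

    Negative values mean less rim than predicted for the eye's disc area and
    age, i.e. the direction of glaucomatous loss.
    """
    disc.validate()
    return {
        s: disc.measured_rim_area[s] - disc.predicted_rim_area[s] for s in SECTORS
    }


@dataclass
class EmpiricalCPF:
    """A sorted reference sample with a plotting-position evaluation rule."""

    sample: np.ndarray  # sorted ascending
    clamp_lo: float
    clamp_hi: float

    @property
    def n(self) -> int:
        return len(self.sample)

    def evaluate(self, x) -> np.ndarray | float:
        """Probability of normality of ``x`` in ``(0, 1)``.

        Non-decreasing in ``x`` and bounded by the clamps.  Accepts scalars
        or arrays.
        """
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("CPF evaluated at non-finite value")
        n = self.n
        positions = (np.arange(1, n + 1) - 0.5) / n
        p = np.interp(x, self.sample, positions)
        p = np.clip(p, self.clamp_lo, self.clamp_hi)
        return float(p) if p.ndim == 0 else p

    __call__ = evaluate


def fit_cpf(
    values: Iterable[float],
    min_n: int = DEFAULT_MIN_N,
    clamp: Optional[tuple[float, float]] = None,
    name: str = "",
) -> EmpiricalCPF:
    """Fit an empirical CPF on a reference sample.

    Parameters
    ----------
    values
        Finite reference values (dB for field points, mm^2 for sector
        rim-area differences).
    min_n
        Minimum admissible sample size.
    clamp
        Probability bounds; defaults to ``(1/(2n), 1 - 1/(2n))``, the Hazen
        positions of the extreme order statistics.
    name
        Optional label used in error messages (e.g. the field location).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < max(min_n, 2) or not np.all(np.isfinite(arr)):
        what = f" for {name}" if name else ""
        raise FitError(
            f"need at least {max(min_n, 2)} finite reference values{what}, "
            f"got {arr.size}"
        )
    arr = np.sort(arr)
    n = arr.size
    if clamp is None:
        clamp = (1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    lo, hi = clamp
    if not (0.0 < lo < hi < 1.0):
        raise FitError(f"invalid clamp bounds {clamp}")
    return EmpiricalCPF(sample=arr, clamp_lo=float(lo), clamp_hi=float(hi))


def cpf_eval(cpf: EmpiricalCPF, x) -> float:
    """Functional alias for :meth:`EmpiricalCPF.evaluate`."""
    return cpf.evaluate(x)


# ---------------------------------------------------------------------------
# Hemifield-test reference distributions (populated by the hemifield module)
# ---------------------------------------------------------------------------


@dataclass
class HTReference:
    """Reference distributions for the hemifield summary test.

    Five signed paired-difference samples (superior minus inferior region
    score, regions 1-5) and one region-score-sum sample, each wrapped as an
    :class:`EmpiricalCPF` with ``r/(n+1)``-style bounding so abnormality
    probabilities never reach exactly 1.
    """

    diffs: list[EmpiricalCPF]  # length 5, region order 1..5
    total: EmpiricalCPF

    def validate(self) -> None:
        if len(self.diffs) != 5:
            raise ValidationError("hemifield reference needs 5 difference samples")


@dataclass
class ReferenceModel:
    """Per-laterality bundle of fitted reference distributions."""

    laterality: str
    field_cpfs: dict[FieldLocation, EmpiricalCPF]
    sector_cpfs: dict[str, EmpiricalCPF]
    ht_reference: Optional[HTReference] = None
    n_eyes: int = 0

    def validate(self) -> None:
        expected = set(grid_24_2(self.laterality))
        if set(self.field_cpfs) != expected:
            raise ValidationError("field CPFs do not cover the 24-2 grid")
        if set(self.sector_cpfs) != set(SECTORS):
            raise ValidationError("sector CPFs do not cover all six sectors")
        if self.ht_reference is not None:
            self.ht_reference.validate()


def fit_reference_model(
    records: Sequence[EyeRecord],
    laterality: str,
    min_n: int = DEFAULT_MIN_N,
) -> ReferenceModel:
    """Fit all 52 field CPFs and 6 sector CPFs from a reference cohort.

    All records must carry ``group_label == "reference"`` and the requested
    laterality.  Total Deviation (already age-corrected) is the field input;
    measured minus predicted rim area (already age- and disc-area-normalised)
    is the structural input.  Fitting is deterministic and invariant to the
    order of the records.
    """
    recs = list(records)
    for rec in recs:
        rec.validate()
        if rec.group_label != "reference":
            raise FitError(
                f"record {rec.subject_id} has group {rec.group_label!r}; "
                "reference models are fitted on reference eyes only"
            )
        if rec.laterality != laterality:
            raise FitError(
                f"record {rec.subject_id} is a {rec.laterality} eye; "
                f"expected {laterality}"
            )
    if len(recs) < min_n:
        raise FitError(
            f"need at least {min_n} reference eyes, got {len(recs)}"
        )
    field_cpfs = {}
    for p in grid_24_2(laterality):
        field_cpfs[p] = fit_cpf(
            (r.field.total_deviation[p] for r in recs),
            min_n=min_n,
            name=f"field point {p}",
        )
    diffs = [rim_area_difference(r.disc) for r in recs]
    sector_cpfs = {
        s: fit_cpf((d[s] for d in diffs), min_n=min_n, name=f"sector {s}")
        for s in SECTORS
    }
    model = ReferenceModel(
        laterality=laterality,
        field_cpfs=field_cpfs,
        sector_cpfs=sector_cpfs,
        n_eyes=len(recs),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _cpf_to_json(cpf: EmpiricalCPF) -> dict:
    return {
        "sample": [float(v) for v in cpf.sample],
        "clamp_lo": cpf.clamp_lo,
        "clamp_hi": cpf.clamp_hi,
    }


def _cpf_from_json(obj: dict) -> EmpiricalCPF:
    return EmpiricalCPF(
        sample=np.asarray(obj["sample"], dtype=float),
        clamp_lo=float(obj["clamp_lo"]),
        clamp_hi=float(obj["clamp_hi"]),
    )


def save_model(model: ReferenceModel, path) -> None:
    """Serialize a reference model to a JSON file (lossless round-trip)."""
    model.validate()
    doc = {
        "format": "sfindex-reference-model",
        "version": MODEL_FORMAT_VERSION,
        "laterality": model.laterality,
        "n_eyes": model.n_eyes,
        "field_cpfs": {
            f"{p.x}_{p.y}": _cpf_to_json(c) for p, c in model.field_cpfs.items()
        },
        "sector_cpfs": {s: _cpf_to_json(c) for s, c in model.sector_cpfs.items()},
        "ht_reference": None
        if model.ht_reference is None
        else {
            "diffs": [_cpf_to_json(c) for c in model.ht_reference.diffs],
            "total": _cpf_to_json(model.ht_reference.total),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ReferenceModel:
    """Load a reference model written by :func:`save_model`."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt reference-model file {path}: {exc}") from exc
    if doc.get("format") != "sfindex-reference-model":
        raise ValueError(f"{path} is not a reference-model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"reference-model version {doc.get('version')!r} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    field_cpfs = {}
    for key, obj in doc["field_cpfs"].items():
        x, y = key.split("_")
        field_cpfs[FieldLocation(int(x), int(y))] = _cpf_from_json(obj)
    model = ReferenceModel(
        laterality=doc["laterality"],
        field_cpfs=field_cpfs,
        sector_cpfs={s: _cpf_from_json(o) for s, o in doc["sector_cpfs"].items()},
        n_eyes=int(doc["n_eyes"]),
    )
    ht = doc.get("ht_reference")
    if ht is not None:
        model.ht_reference = HTReference(
            diffs=[_cpf_from_json(o) for o in ht["diffs"]],
            total=_cpf_from_json(ht["total"]),
        )
    model.validate()
    return model
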