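"""The hemifield summary test for the pointwise index (SFI-HT).

Glaucoma tends to damage one hemifield first because nerve fiber bundles
respect the horizontal raphe, so — following the logic of the device's
Glaucoma Hemifield Test — the 52 pointwise index values are grouped into
ten bundle-shaped clusters (regions 1-5 superior and their mirror images
inferiorly).  Each region receives the score

    region score = sum over points of min(1 / (10 * (1 - SFI)), 100)

which grows without bound as pointwise values approach 1, hence the
per-point cap of 100 (reached at an index of 99.9%).  A region's score
therefore ranges from 0.1 per point up to 100 per point — 300 maximum for
the 3-point region 1 and 600 for the 6-point region 4.

Five signed superior-minus-inferior score differences detect asymmetric
loss; the sum of all ten region scores catches diffuse loss that leaves the
hemifields balanced.  Each of those six statistics is referred to its
empirical distribution in the reference cohort, and the eye is summarised by
the single largest probability of abnormality among the six (a value in
[0, 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import FieldLocation, ValidationError, mirror_location
from .reference import EmpiricalCPF, HTReference, fit_cpf
from .sfi_core import SFIResult

#: Per-point score cap; binds for index values >= 0.999.
POINT_SCORE_CAP = 100.0

REGION_IDS = (1, 2, 3, 4, 5)
HEMIFIELDS = ("superior", "inferior")

#: Superior-hemifield clusters for a right eye, shaped after the published
#: hemifield-test layout: region 1 is the 3-point nasal step, regions 2-4
#: follow the arcuate bundles from nasal periphery to the temporal side, and
#: region 5 holds the central/temporal points next to the horizontal.  The
#: ten clusters partition all 52 scored locations.  Overridable.
_RIGHT_SUPERIOR_REGIONS: dict[int, tuple[tuple[int, int], ...]] = {
    1: ((-27, 3), (-21, 3), (-15, 3)),
    2: ((-21, 9), (-15, 9), (-15, 15), (-9, 15), (-9, 21)),
    3: ((-9, 9), (-3, 9), (-3, 15), (3, 15), (-3, 21), (3, 21)),
    4: ((3, 9), (9, 9), (15, 9), (9, 15), (15, 15), (9, 21)),
    5: ((-9, 3), (-3, 3), (3, 3), (9, 3), (21, 3), (21, 9)),
}


@dataclass
class RegionMap:
    """Ten mirror-paired clusters of field locations."""

    laterality: str
    regions: dict[tuple[int, str], tuple[FieldLocation, ...]]

    def points(self, region: int, hemifield: str) -> tuple[FieldLocation, ...]:
        return self.regions[(region, hemifield)]

    def validate(self) -> None:
        keys = {(r, h) for r in REGION_IDS for h in HEMIFIELDS}
        if set(self.regions) != keys:
            raise ValidationError("region map must define regions 1-5 x 2 hemifields")
        seen: set[FieldLocation] = set()
        for (r, h), pts in self.regions.items():
            if not 3 <= len(pts) <= 6:
                raise ValidationError(f"region {r} {h} has {len(pts)} points")
            if seen & set(pts):
                raise ValidationError("region clusters overlap")
            seen |= set(pts)
        for r in REGION_IDS:
            sup = {FieldLocation(p.x, -p.y) for p in self.regions[(r, "superior")]}
            if sup != set(self.regions[(r, "inferior")]):
                raise ValidationError(f"region {r} is not mirror-paired")


def default_regions(laterality: str) -> RegionMap:
    """The packaged region map; left-eye clusters are the x-mirror."""
    regions: dict[tuple[int, str], tuple[FieldLocation, ...]] = {}
    for r, pts in _RIGHT_SUPERIOR_REGIONS.items():
        sup = tuple(FieldLocation(x, y) for x, y in pts)
        if laterality == "left":
            sup = tuple(mirror_location(p) for p in sup)
        elif laterality != "right":
            raise ValidationError(f"invalid laterality {laterality!r}")
        inf = tuple(FieldLocation(p.x, -p.y) for p in sup)
        regions[(r, "superior")] = sup
        regions[(r, "inferior")] = inf
    rmap = RegionMap(laterality=laterality, regions=regions)
    rmap.validate()
    return rmap


def point_score(sfi: float) -> float:
    """Per-point region-score term: ``min(1 / (10 (1 - SFI)), 100)``."""
    if not 0.0 <= sfi <= 1.0:
        raise ValueError(f"index value outside [0, 1]: {sfi}")
    if sfi >= 0.999:  # the cap binds from an index of 99.9% upward
        return POINT_SCORE_CAP
    return min(1.0 / (10.0 * (1.0 - sfi)), POINT_SCORE_CAP)


def region_score(sfi_result: SFIResult, points) -> float:
    """Sum of per-point scores over one region's points."""
    total = 0.0
    for p in points:
        if p not in sfi_result.values:
            raise ValidationError(f"region point {p} missing from index result")
        total += point_score(sfi_result.values[p])
    return total


def region_scores(
    sfi_result: SFIResult, region_map: RegionMap
) -> dict[tuple[int, str], float]:
    """Scores for all ten regions."""
    if sfi_result.laterality != region_map.laterality:
        raise ValidationError("index result and region map lateralities disagree")
    return {
        key: region_score(sfi_result, pts) for key, pts in region_map.regions.items()
    }


def ht_statistics(
    sfi_result: SFIResult, region_map: RegionMap
) -> tuple[np.ndarray, float]:
    """Five signed paired differences (superior minus inferior) and the total."""
    scores = region_scores(sfi_result, region_map)
    diffs = np.array(
        [scores[(r, "superior")] - scores[(r, "inferior")] for r in REGION_IDS]
    )
    total = float(sum(scores.values()))
    return diffs, total


def fit_ht_reference(
    sfi_results,
    region_map: RegionMap,
    min_n: int = 20,
) -> HTReference:
    """Empirical reference distributions of the six summary statistics.

    Fitted on the pointwise index results of the reference cohort (scored
    with the same reference model and anatomy map that will be used for test
    eyes).  Samples are wrapped as CPFs with ``r/(n+1)``-style bounding so
    downstream abnormality probabilities never reach exactly 1.
    """
    diffs_all = []
    totals = []
    for res in sfi_results:
        d, t = ht_statistics(res, region_map)
        diffs_all.append(d)
        totals.append(t)
    n = len(totals)
    if n < min_n:
        raise ValidationError(f"need at least {min_n} reference eyes, got {n}")
    diffs_arr = np.asarray(diffs_all)
    clamp = (1.0 / (n + 1), n / (n + 1.0))
    ref = HTReference(
        diffs=[
            fit_cpf(diffs_arr[:, k], min_n=min_n, clamp=clamp, name=f"region {k + 1}")
            for k in range(5)
        ],
        total=fit_cpf(totals, min_n=min_n, clamp=clamp, name="region-score sum"),
    )
    ref.validate()
    return ref


@dataclass
class SFIHTResult:
    """Hemifield summary for one eye."""

    region_scores: dict[tuple[int, str], float]
    paired_diffs: np.ndarray  # length 5, superior minus inferior
    total: float
    abnormality_probs: dict[str, float]  # diff_1..diff_5, total
    summary: float  # max of the six probabilities
    argmax_statistic: str  # which statistic attained the max

    subject_id: str = ""


def ht_summary(
    diffs: np.ndarray,
    total: float,
    ht_reference: HTReference,
    two_sided: bool = True,
    region_score_values: dict | None = None,
    subject_id: str = "",
) -> SFIHTResult:
    """Refer the six statistics to their reference distributions.

    Each signed difference is scored by two-sided extremity,
    ``2 * max(F(d), 1 - F(d)) - 1`` under the reference ECDF F (either
    hemifield may be the damaged one); with ``two_sided=False`` the upper
    tail alone is used.  The total is one-sided (large totals are abnormal):
    its abnormality probability is ``F_total(t)``.  The eye's summary is the
    largest of the six probabilities, and the statistic attaining it is
    reported.
    """
    ht_reference.validate()
    diffs = np.asarray(diffs, dtype=float)
    if diffs.shape != (5,):
        raise ValueError("expected 5 paired differences")
    probs: dict[str, float] = {}
    for k in range(5):
        F = ht_reference.diffs[k].evaluate(diffs[k])
        if two_sided:
            probs[f"diff_{k + 1}"] = 2.0 * max(F, 1.0 - F) - 1.0
        else:
            probs[f"diff_{k + 1}"] = F
    probs["total"] = float(ht_reference.total.evaluate(total))
    argmax = max(probs, key=lambda k: (probs[k], k))
    return SFIHTResult(
        region_scores=dict(region_score_values or {}),
        paired_diffs=diffs,
        total=float(total),
        abnormality_probs=probs,
        summary=probs[argmax],
        argmax_statistic=argmax,
        subject_id=subject_id,
    )


def score_eye_ht(
    sfi_result: SFIResult,
    region_map: RegionMap,
    ht_reference: HTReference,
    two_sided: bool = True,
) -> SFIHTResult:
    """Convenience wrapper: region scores, statistics and summary for one eye."""
    scores = region_scores(sfi_result, region_map)
    diffs, total = ht_statistics(sfi_result, region_map)
    return ht_summary(
        diffs,
        total,
        ht_reference,
        two_sided=two_sided,
        region_score_values=scores,
        subject_id=sfi_result.subject_id,
    )
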