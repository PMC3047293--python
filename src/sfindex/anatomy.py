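"""Probabilistic map from 24-2 field locations to optic-disc sectors.

Each retinal nerve fiber bundle serving a visual-field location inserts into
the optic-nerve head at a characteristic angle; across eyes that angle
varies, so the link between a field point and a disc sector is probabilistic.
Here each field point carries a normal distribution of insertion angle
(mean, SD in degrees on the disc circumference, wrapped on the circle), and
the probability that the point is linked to a sector is the mass of that
distribution falling within the sector's angular arc.

Angle convention (both eyes, anatomical): 0 deg = temporal pole of the disc,
90 deg = superior, 180 deg = nasal, 270 deg = inferior; angles increase
counterclockwise for a right disc as conventionally displayed.  Because the
retinal image is inverted, superior field locations insert on the *inferior*
disc circumference and vice versa.

The default per-point mean angles are packaged configuration data in the
style of the red-free-photograph structure-function map: central points just
off the horizontal feed the papillomacular bundle near the temporal pole;
peripheral nasal points feed wide arcuate bundles entering near the vertical
poles; temporal field points insert nasally.  The per-point SDs used by the
map's originators are unpublished, so a uniform default SD (15 deg) is
applied; both means and SDs can be overridden from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .io_model import (
    SECTOR_ARCS,
    SECTORS,
    FieldLocation,
    ValidationError,
    grid_24_2,
    mirror_location,
)

#: Uniform default SD of the insertion angle, degrees.
DEFAULT_SD_DEG = 15.0

#: Mean disc-insertion angle (degrees) for the superior-field points of a
#: right eye.  Inferior-field points are the reflection a -> 360 - a at
#: (x, -y) (raphe symmetry); left-eye entries equal the right-eye entries at
#: the x-mirrored location (anatomical angle convention is shared).
#: The (3, 15) entry is placed so that with SD 15 deg the inferotemporal /
#: inferonasal split is 0.74 / 0.26, the published calibration example for
#: this map.
_RIGHT_SUPERIOR_MEAN_ANGLE: dict[tuple[int, int], float] = {
    # y = 21: superior periphery -> inferior disc around the vertical pole
    (-9, 21): 258.0,
    (-3, 21): 264.0,
    (3, 21): 271.0,
    (9, 21): 278.0,
    # y = 15
    (-15, 15): 250.0,
    (-9, 15): 257.0,
    (-3, 15): 265.0,
    (3, 15): 279.64,
    (9, 15): 284.0,
    (15, 15): 271.0,
    # y = 9: arcuate bundles; (21, 9) is nasal retina inserting directly
    (-21, 9): 263.0,
    (-15, 9): 269.0,
    (-9, 9): 276.0,
    (-3, 9): 287.0,
    (3, 9): 299.0,
    (9, 9): 310.0,
    (15, 9): 269.0,
    (21, 9): 229.0,
    # y = 3: papillomacular bundle centrally, nasal step peripherally,
    # temporal field (21, 3) inserting in the nasal sector
    (-27, 3): 290.0,
    (-21, 3): 300.0,
    (-15, 3): 315.0,
    (-9, 3): 328.0,
    (-3, 3): 336.0,
    (3, 3): 341.0,
    (9, 3): 345.0,
    (21, 3): 190.0,
}


@dataclass
class InsertionAngleModel:
    """Per-point normal distribution of disc insertion angle."""

    laterality: str
    mean_angle: dict[FieldLocation, float]  # degrees in [0, 360)
    sd_angle: dict[FieldLocation, float]  # degrees > 0

    def validate(self) -> None:
        expected = set(grid_24_2(self.laterality))
        if set(self.mean_angle) != expected or set(self.sd_angle) != expected:
            raise ValidationError("insertion-angle map must cover all 52 points")
        for p in expected:
            if not 0.0 <= self.mean_angle[p] < 360.0:
                raise ValidationError(f"mean angle at {p} outside [0, 360)")
            if not self.sd_angle[p] > 0.0:
                raise ValidationError(f"sd angle at {p} must be > 0")


@dataclass
class SectorLinkage:
    """Cached 6-vectors of sector linkage probabilities per field point."""

    laterality: str
    probabilities: dict[FieldLocation, np.ndarray]  # each length 6, sums to 1

    def vector(self, point: FieldLocation) -> np.ndarray:
        return self.probabilities[point]


def default_map(laterality: str, sd: float = DEFAULT_SD_DEG) -> InsertionAngleModel:
    """The packaged insertion-angle map for one laterality.

    The left-eye map is the mirror of the right-eye map: the entry for a left
    eye at ``(x, y)`` equals the right-eye entry at ``(-x, y)``, the insertion
    angle being expressed in the shared anatomical convention.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    mean: dict[FieldLocation, float] = {}
    for (x, y), a in _RIGHT_SUPERIOR_MEAN_ANGLE.items():
        mean[FieldLocation(x, y)] = a % 360.0
        mean[FieldLocation(x, -y)] = (360.0 - a) % 360.0
    if laterality == "left":
        mean = {mirror_location(p): a for p, a in mean.items()}
    elif laterality != "right":
        raise ValidationError(f"invalid laterality {laterality!r}")
    model = InsertionAngleModel(
        laterality=laterality,
        mean_angle=mean,
        sd_angle={p: float(sd) for p in mean},
    )
    model.validate()
    return model


def load_map(path) -> InsertionAngleModel:
    """Load an insertion-angle map override from a YAML file.

    Expected layout::

        laterality: right
        points:
          - {x: 3, y: 15, mean_angle: 279.6, sd_angle: 15.0}
          ...
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    mean = {}
    sd = {}
    for row in doc["points"]:
        p = FieldLocation(int(row["x"]), int(row["y"]))
        mean[p] = float(row["mean_angle"]) % 360.0
        sd[p] = float(row["sd_angle"])
    model = InsertionAngleModel(
        laterality=doc["laterality"], mean_angle=mean, sd_angle=sd
    )
    model.validate()
    return model


def wrapped_normal_arc_mass(
    mean: float, sd: float, start: float, end: float, periods: int = 2
) -> float:
    """Mass of a wrapped normal(mean, sd) on the circular arc [start, end).

    ``end`` may exceed 360 for arcs wrapping through zero.  The wrapped
    density is summed over ``+/- periods`` extra circle periods of the plain
    normal CDF; for sd <= 60 deg and two periods the truncation error is
    below 1e-12.
    """
    return float(wrapped_arc_mass_vec(mean, sd, start, end, periods=periods))


def wrapped_arc_mass_vec(
    means, sds, start: float, end: float, periods: int = 2
) -> np.ndarray:
    """Vectorized :func:`wrapped_normal_arc_mass` over arrays of (mean, sd)."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.any(sds <= 0):
        raise ValueError("sd must be > 0")
    if not 0.0 <= end - start <= 360.0:
        raise ValueError("arc must span between 0 and 360 degrees")
    total = np.zeros(np.broadcast(means, sds).shape)
    for k in range(-periods, periods + 1):
        shift = 360.0 * k
        total = total + (
            norm.cdf(end + shift, loc=means, scale=sds)
            - norm.cdf(start + shift, loc=means, scale=sds)
        )
    return total


def sector_probabilities(
    model: InsertionAngleModel,
    point: FieldLocation,
    sector_arcs: dict[str, tuple[float, float]] = SECTOR_ARCS,
) -> np.ndarray:
    """6-vector of sector linkage probabilities for one field point.

    Entry order follows :data:`sfindex.io_model.SECTORS`.  The vector is the
    wrapped-normal mass in each sector arc and sums to 1 (the arcs partition
    the circle).
    """
    if point not in model.mean_angle:
        raise KeyError(f"point {point} not in insertion-angle map")
    mu = model.mean_angle[point]
    sd = model.sd_angle[point]
    probs = np.array(
        [
            wrapped_normal_arc_mass(mu, sd, *sector_arcs[s])
            for s in SECTORS
        ]
    )
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"sector arcs do not partition the circle (mass {probs.sum():.12f})"
        )
    return probs


def build_linkage(
    model: InsertionAngleModel,
    sector_arcs: dict[str, tuple[float, float]] = SECTOR_ARCS,
) -> SectorLinkage:
    """Cache sector probabilities for all 52 points of the map's laterality."""
    model.validate()
    probs = {
        p: sector_probabilities(model, p, sector_arcs)
        for p in grid_24_2(model.laterality)
    }
    return SectorLinkage(laterality=model.laterality, probabilities=probs)
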