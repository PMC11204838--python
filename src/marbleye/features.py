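"""Connected-component fleck analysis and the six marbling features.

Flecks are connected components of the binary fat mask.  Each fleck's area
in mm² follows from its pixel count and the image calibration.  Flecks are
partitioned by area into three classes:

* discarded — below ``small_min`` (default 1 mm²), treated as noise;
* small — between ``small_min`` and ``small_max`` inclusive (default 1-50 mm²);
* large — above ``small_max``.

From the partition and the beef area the six predictors are:

* SMN, SMA — number and total area (mm²) of small flecks;
* TMN, TMA — number and total area of all retained flecks (small + large);
* MR = TMA / beef area (fraction of the steak face that is fat);
* F = SMN / beef area (fineness: density of small flecks per mm²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure

from .errors import InvalidConfigError, InvalidInputError
from .segmentation import BeefMask, FleckMask

__all__ = [
    "Fleck",
    "FleckPartition",
    "MarblingFeatureVector",
    "FEATURE_NAMES",
    "label_flecks",
    "partition_flecks",
    "compute_features",
]

FEATURE_NAMES = ("SMN", "SMA", "TMN", "TMA", "MR", "F")


@dataclass(frozen=True)
class Fleck:
    """One connected fat fleck."""

    label: int
    pixel_count: int
    area_mm2: float
    centroid: tuple[float, float]


@dataclass
class FleckPartition:
    """Flecks split by area class; the classes are disjoint and exhaustive."""

    discarded: list[Fleck]
    small: list[Fleck]
    large: list[Fleck]
    small_min: float = 1.0
    small_max: float = 50.0

    def all_flecks(self) -> list[Fleck]:
        return self.discarded + self.small + self.large


@dataclass(frozen=True)
class MarblingFeatureVector:
    SMN: int
    SMA: float
    TMN: int
    TMA: float
    MR: float
    F: float
    beef_area_mm2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "SMN": self.SMN,
            "SMA": self.SMA,
            "TMN": self.TMN,
            "TMA": self.TMA,
            "MR": self.MR,
            "F": self.F,
            "beef_area_mm2": self.beef_area_mm2,
        }


def label_flecks(
    flecks: FleckMask, px_per_mm: float, connectivity: int = 8
) -> list[Fleck]:
    """Identify individual flecks as connected components of the fat mask.

    ``connectivity`` 8 (default) merges diagonally touching fat streaks into
    one fleck; 4 keeps them separate.  Components touching the image border
    are retained.
    """
    if connectivity not in (4, 8):
        raise InvalidConfigError(f"connectivity must be 4 or 8, got {connectivity}")
    if not px_per_mm > 0:
        raise InvalidInputError("px_per_mm must be positive")
    mask = np.asarray(flecks.mask, bool)
    if mask.size == 0 or not mask.any():
        return []
    labels = skmeasure.label(mask, connectivity=1 if connectivity == 4 else 2)
    out: list[Fleck] = []
    for region in skmeasure.regionprops(labels):
        out.append(
            Fleck(
                label=int(region.label),
                pixel_count=int(region.area),
                area_mm2=float(region.area) / px_per_mm**2,
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
            )
        )
    return out


def partition_flecks(
    flecks: list[Fleck], small_min: float = 1.0, small_max: float = 50.0
) -> FleckPartition:
    """Classify flecks by area: < small_min discarded, [small_min, small_max]
    small (bounds inclusive), > small_max large."""
    if not (0 < small_min < small_max):
        raise InvalidConfigError(
            f"need 0 < small_min < small_max, got ({small_min}, {small_max})"
        )
    part = FleckPartition([], [], [], small_min=small_min, small_max=small_max)
    for f in flecks:
        if f.area_mm2 < small_min:
            part.discarded.append(f)
        elif f.area_mm2 <= small_max:
            part.small.append(f)
        else:
            part.large.append(f)
    return part


def compute_features(
    partition: FleckPartition, beef: BeefMask | float
) -> MarblingFeatureVector:
    """Compute the six marbling predictors from a fleck partition.

    ``beef`` may be a :class:`BeefMask` or the beef area in mm² directly.
    Discarded (sub-``small_min``) flecks are excluded from TMN/TMA so that
    TMN = SMN + large count and TMA = SMA + large area hold exactly.
    """
    area = beef.area_mm2 if isinstance(beef, BeefMask) else float(beef)
    if not area > 0:
        raise InvalidInputError(
            "beef area must be positive to form the ratio features MR and F"
        )
    smn = len(partition.small)
    sma = float(sum(f.area_mm2 for f in partition.small))
    lmn = len(partition.large)
    lma = float(sum(f.area_mm2 for f in partition.large))
    tma = sma + lma
    return MarblingFeatureVector(
        SMN=smn,
        SMA=sma,
        TMN=smn + lmn,
        TMA=tma,
        MR=tma / area,
        F=smn / area,
        beef_area_mm2=area,
    )
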