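"""Background removal and marbling-fleck binarization for rib-eye photographs.

The processing chain mirrors the standard ImageJ-style workflow used for
digital marbling assessment: the photograph is standardized to a square
working resolution, converted to the 8-bit Lab* representation (L* scaled by
2.55, a* and b* offset by +128 so every channel lives on 0-255), and the
uniform gray presentation board is removed by a Lab* box threshold.  A pixel
is *background* when all three of its Lab255 channels fall inside the
threshold ranges; the beef region of interest is the complement, cleaned up
to its largest connected component with interior holes filled.  Marbling
candidates are then obtained by automatic-threshold binarization of the
luminance image restricted to the beef region, the bright phase being
intramuscular fat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import measure as skmeasure
from skimage import transform as sktransform

from .errors import InvalidConfigError, InvalidInputError, NoRegionOfInterestError

__all__ = [
    "RibEyeImage",
    "LabThresholdSpec",
    "BeefMask",
    "FleckMask",
    "DEFAULT_BACKGROUND_SPEC",
    "resize_standard",
    "rgb_to_lab255",
    "segment_beef",
    "binarize_flecks",
]


@dataclass
class RibEyeImage:
    """An RGB photograph of one meat-sample face plus its spatial calibration.

    Parameters
    ----------
    pixels:
        ``H x W x 3`` uint8 array of channel intensities in [0, 255].
    px_per_mm:
        Pixels per millimetre along one axis (assumed isotropic).
    sample_id, side, duplicate_index:
        Provenance: which meat sample, which face (``"A"``/``"B"``) and which
        of the duplicate shots of that face this image is.
    """

    pixels: np.ndarray
    px_per_mm: float
    sample_id: str = ""
    side: str = "A"
    duplicate_index: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidInputError(
                f"expected an H x W x 3 RGB array, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise InvalidInputError("image has no pixels")
        if self.pixels.dtype != np.uint8:
            arr = np.asarray(self.pixels)
            if arr.min() < 0 or arr.max() > 255:
                raise InvalidInputError("channel values must lie in [0, 255]")
            self.pixels = arr.astype(np.uint8)
        if not self.px_per_mm > 0:
            raise InvalidInputError(f"px_per_mm must be positive, got {self.px_per_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class LabThresholdSpec:
    """Inclusive per-channel box on the 0-255 Lab scale selecting *background*.

    Defaults reproduce the thresholds used for a neutral gray board:
    L 0-255, a 0-255, b 0-129.  Neutral gray sits at b255 = 128 and is
    selected; reddish lean meat (b255 well above 129) is not.
    """

    l_range: tuple[float, float] = (0.0, 255.0)
    a_range: tuple[float, float] = (0.0, 255.0)
    b_range: tuple[float, float] = (0.0, 129.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("l_range", self.l_range),
            ("a_range", self.a_range),
            ("b_range", self.b_range),
        ):
            if not (0.0 <= lo <= hi <= 255.0):
                raise InvalidConfigError(
                    f"{name} must satisfy 0 <= lo <= hi <= 255, got ({lo}, {hi})"
                )


DEFAULT_BACKGROUND_SPEC = LabThresholdSpec()


@dataclass
class BeefMask:
    """Boolean beef region of interest and its calibrated area."""

    mask: np.ndarray
    area_mm2: float

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class FleckMask:
    """Boolean mask of candidate marbling (fat) pixels; a subset of the beef mask."""

    mask: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), bool))

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def resize_standard(image: RibEyeImage, target_px: int = 500) -> RibEyeImage:
    """Resize to the square ``target_px`` working resolution.

    Intensities are bilinearly interpolated.  The calibration is rescaled by
    the per-axis factor; when the input is not square the two factors differ
    and their geometric mean is used (with a warning), since a single
    isotropic calibration cannot represent an anisotropic rescale exactly.
    """
    if target_px < 8:
        raise InvalidInputError(f"target_px must be >= 8, got {target_px}")
    h, w = image.shape
    if (h, w) == (target_px, target_px):
        return replace(image, pixels=image.pixels.copy())
    fy = target_px / h
    fx = target_px / w
    if h != w:
        warnings.warn(
            f"anisotropic resize {h}x{w} -> {target_px}x{target_px}: "
            "px_per_mm rescaled by the geometric mean of the axis factors",
            stacklevel=2,
        )
    out = sktransform.resize(
        image.pixels.astype(np.float64),
        (target_px, target_px, 3),
        order=1,
        mode="edge",
        anti_aliasing=(fy < 1 or fx < 1),
        preserve_range=True,
    )
    return replace(
        image,
        pixels=np.clip(np.rint(out), 0, 255).astype(np.uint8),
        px_per_mm=image.px_per_mm * float(np.sqrt(fy * fx)),
    )


def rgb_to_lab255(image: RibEyeImage) -> np.ndarray:
    """Convert to CIELAB and rescale each channel onto 0-255.

    Uses the 8-bit convention ``L255 = L* * 2.55``, ``a255 = a* + 128``,
    ``b255 = b* + 128`` (D65 white), so thresholds quoted on the 8-bit scale
    apply directly.
    """
    lab = skcolor.rgb2lab(image.pixels)
    out = np.empty_like(lab)
    out[..., 0] = lab[..., 0] * 2.55
    out[..., 1] = lab[..., 1] + 128.0
    out[..., 2] = lab[..., 2] + 128.0
    return out


def segment_beef(
    image: RibEyeImage, spec: LabThresholdSpec = DEFAULT_BACKGROUND_SPEC
) -> BeefMask:
    """Remove the presentation board and return the beef region of interest.

    A pixel is background iff all three Lab255 channels fall inside ``spec``.
    The complement is cleaned to its largest 8-connected component and
    interior holes (e.g. bright fat whose b channel strays into the
    background box) are filled before the area is measured.
    """
    lab = rgb_to_lab255(image)
    bg = (
        (lab[..., 0] >= spec.l_range[0])
        & (lab[..., 0] <= spec.l_range[1])
        & (lab[..., 1] >= spec.a_range[0])
        & (lab[..., 1] <= spec.a_range[1])
        & (lab[..., 2] >= spec.b_range[0])
        & (lab[..., 2] <= spec.b_range[1])
    )
    fg = ~bg
    if not fg.any():
        raise NoRegionOfInterestError(
            "no region of interest: every pixel matches the background thresholds"
        )
    labels = skmeasure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        raise NoRegionOfInterestError("no region of interest after cleanup")
    area = float(mask.sum()) / image.px_per_mm**2
    return BeefMask(mask=mask, area_mm2=area)


_LUMA = np.array([0.2125, 0.7154, 0.0721])


def binarize_flecks(
    image: RibEyeImage,
    beef: BeefMask,
    method: str = "isodata",
    min_contrast: float = 10.0,
    edge_exclusion_px: int = 2,
) -> FleckMask:
    """Binarize the beef-region luminance; bright (fat) phase becomes True.

    ``method`` is ``"isodata"`` (the classic make-binary default) or
    ``"otsu"``.  The threshold is computed from beef-region pixels only, so
    the board cannot bias it.  Two guards keep the automatic threshold from
    manufacturing flecks where there are none: a thin
    ``edge_exclusion_px``-wide margin just inside the beef boundary is
    excluded (those pixels mix meat and board colors), and when the
    separation between the two luminance classes falls below
    ``min_contrast`` — a uniform or noise-only lean region — an empty mask
    is returned with a warning rather than speckle.
    """
    if not beef.mask.any():
        raise InvalidInputError("beef mask is empty")
    gray = image.pixels.astype(np.float64) @ _LUMA
    interior = beef.mask
    if edge_exclusion_px > 0:
        # border_value=1: only the meat/board boundary is eroded, not the
        # image frame, so full-frame masks pass through unchanged
        interior = ndi.binary_erosion(
            beef.mask, iterations=edge_exclusion_px, border_value=1
        )
        if not interior.any():
            interior = beef.mask
    vals = gray[interior]
    if float(vals.max() - vals.min()) < 1.0:
        warnings.warn(
            "beef region is uniform; returning an empty fleck mask", stacklevel=2
        )
        return FleckMask(mask=np.zeros_like(beef.mask))
    from skimage.filters import threshold_isodata, threshold_otsu

    if method == "isodata":
        thr = threshold_isodata(vals)
    elif method == "otsu":
        thr = threshold_otsu(vals)
    else:
        raise InvalidConfigError(f"unknown binarization method {method!r}")
    above = vals > thr
    if not above.any() or float(vals[above].mean() - vals[~above].mean()) < min_contrast:
        warnings.warn(
            "no fat phase distinguishable from the lean background; "
            "returning an empty fleck mask",
            stacklevel=2,
        )
        return FleckMask(mask=np.zeros_like(beef.mask))
    return FleckMask(mask=(gray > thr) & interior)
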