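"""Visual feature extraction from whole-fruit and middle-cut images.

Implements the 46-feature inventory: whole-fruit color means (RGB, HSV,
CIELAB) and morphology (area, roundness, aspect ratio), middle-cut section
morphology, per-tissue color means for the outer pericarp, red locule and
pale core, the locule area rate, and core morphology.

Segmentation follows the classical recipe for this kind of scene: grayscale
Otsu thresholding plus morphological opening for the whole fruit; hue-channel
Otsu for the cut section; and a two-stage split of the excess-green index
ExG = 2G - R - B within the section to separate outer pericarp (strongly
positive ExG), core (near zero) and locule (strongly negative, obtained by
subtraction so the three tissue masks tile the section exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure, morphology
from skimage.filters import threshold_multiotsu, threshold_otsu

from kiwifuse.errors import SegmentationError

__all__ = [
    "BinaryMask",
    "RegionMasks",
    "MorphFeatures",
    "ColorMeans",
    "ImageFeatureVector",
    "FEATURE_NAMES",
    "crop_center",
    "segment_whole_fruit",
    "compute_morphology",
    "apply_mask",
    "compute_color_means",
    "exg_transform",
    "segment_middle_cut",
    "locule_area_rate",
    "extract_image_features",
]

#: A binary mask is simply a 2-D boolean array matching its source image.
BinaryMask = np.ndarray

#: Opening structuring-element radius at the reference 1600 px image scale.
OPENING_RADIUS_AT_1600 = 5

#: Minimum region size, as a fraction of the section, below which a tissue
#: mask is treated as a segmentation failure rather than a real region.
_MIN_REGION_FRACTION = 0.005

_COLOR_KEYS = ("r", "g", "b", "h", "s", "v", "l_star", "a_star", "b_star")
_MORPH_KEYS = ("area", "roundness", "aspect_ratio")

#: Fixed order of the 46 extracted features.
FEATURE_NAMES = tuple(
    [f"whole_{k}" for k in _COLOR_KEYS]
    + [f"whole_{k}" for k in _MORPH_KEYS]
    + [f"section_{k}" for k in _MORPH_KEYS]
    + [f"outer_{k}" for k in _COLOR_KEYS]
    + [f"locule_{k}" for k in _COLOR_KEYS]
    + ["locule_area_rate"]
    + [f"core_{k}" for k in _COLOR_KEYS]
    + [f"core_{k}" for k in _MORPH_KEYS]
)
assert len(FEATURE_NAMES) == 46


@dataclass(frozen=True)
class RegionMasks:
    """The four binary masks of a middle-cut image.

    ``outer``, ``core`` and ``locule`` are pairwise disjoint and their union
    equals ``section``.
    """

    section: BinaryMask
    outer: BinaryMask
    core: BinaryMask
    locule: BinaryMask

    def __post_init__(self):
        if (np.any(self.outer & self.core) or np.any(self.outer & self.locule)
                or np.any(self.core & self.locule)):
            raise ValueError("tissue masks must be pairwise disjoint")
        if not np.array_equal(self.outer | self.core | self.locule, self.section):
            raise ValueError("tissue masks must tile the section exactly")


@dataclass(frozen=True)
class MorphFeatures:
    """Area (px), roundness 4*pi*A/P^2, and moment-ellipse aspect ratio."""

    area: float
    roundness: float
    aspect_ratio: float


@dataclass(frozen=True)
class ColorMeans:
    """Mean color over mask pixels: RGB on [0, 255], HSV on [0, 1], CIELAB
    in native units (L* in [0, 100], a*/b* roughly [-128, 127])."""

    r: float
    g: float
    b: float
    h: float
    s: float
    v: float
    l_star: float
    a_star: float
    b_star: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _COLOR_KEYS])


@dataclass(frozen=True)
class ImageFeatureVector:
    """The ordered 46-element visual feature vector."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (46,):
            raise ValueError("an image feature vector has exactly 46 entries")
        if not np.all(np.isfinite(v)):
            raise ValueError("image features must be finite")

    @property
    def names(self) -> tuple:
        return FEATURE_NAMES

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, np.asarray(self.values, dtype=float)))

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def crop_center(image: np.ndarray, size: int) -> np.ndarray:
    """Return the centered ``size x size`` block (floor split of odd margins)."""
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than crop size {size}")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return image[r0:r0 + size, c0:c0 + size]


def _opening_radius(shape) -> int:
    return max(1, round(OPENING_RADIUS_AT_1600 * min(shape[:2]) / 1600))


def _cleanup(mask: BinaryMask, radius: int) -> BinaryMask:
    """Opening with a disk, keep the largest component, fill holes."""
    mask = morphology.opening(mask, morphology.disk(radius))
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    largest = np.argmax(ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))) + 1
    return ndimage.binary_fill_holes(labels == largest)


def segment_whole_fruit(image: np.ndarray) -> BinaryMask:
    """Segment the fruit from a whole-fruit image.

    Grayscale conversion, Otsu threshold (fruit darker than background),
    opening with a disk, largest connected component, hole filling.
    """
    gray = skcolor.rgb2gray(image)
    if gray.min() == gray.max():
        raise SegmentationError("fruit", "uniform image: no fruit found")
    t = threshold_otsu(gray)
    mask = gray < t
    mask = _cleanup(mask, _opening_radius(image.shape))
    if not mask.any():
        raise SegmentationError("fruit", "empty foreground after cleanup")
    return mask


def compute_morphology(mask: BinaryMask) -> MorphFeatures:
    """Area, roundness and aspect ratio of a binary region.

    Roundness is 4*pi*A/P^2 with the perimeter measured as the polyline
    length of the outer boundary contour, subsampled every 5th vertex to
    suppress the pixel-staircase overestimate (a raw digital contour inflates
    a circle's perimeter by ~5%, pushing its roundness down to ~0.90);
    aspect ratio is the axis ratio of the moment-equivalent ellipse (>= 1).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    area = float(mask.sum())
    # pad so boundary regions still yield a closed contour
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    outer = max(contours, key=lambda c: len(c))
    sub = outer[::5]
    if not np.array_equal(sub[-1], outer[-1]):
        sub = np.vstack([sub, outer[-1]])     # keep the loop closed
    perimeter = float(np.sum(np.linalg.norm(np.diff(sub, axis=0), axis=1)))
    roundness = 4.0 * np.pi * area / perimeter ** 2
    props = measure.regionprops(mask.astype(np.uint8))[0]
    minor = props.axis_minor_length
    aspect = float(props.axis_major_length / minor) if minor > 0 else np.inf
    return MorphFeatures(area=area, roundness=float(roundness), aspect_ratio=aspect)


def apply_mask(image: np.ndarray, mask: BinaryMask) -> np.ndarray:
    """Zero the background, keep foreground pixels byte-identical."""
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    return image * np.asarray(mask, dtype=image.dtype)[..., None]


def compute_color_means(image: np.ndarray, mask: BinaryMask) -> ColorMeans:
    """Mean R, G, B, H, S, V, L*, a*, b* over the mask pixels only.

    HSV is the standard hexcone conversion on [0, 1] channels; CIELAB is
    sRGB -> CIEXYZ (D65) -> CIELAB.
    """
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    px = image[mask].astype(float)           # (n, 3) masked pixels only
    pxf = px / 255.0
    hsv = skcolor.rgb2hsv(pxf)
    lab = skcolor.rgb2lab(pxf)
    rgb_mean = px.mean(axis=0)
    hsv_mean = hsv.mean(axis=0)
    lab_mean = lab.mean(axis=0)
    return ColorMeans(
        r=float(rgb_mean[0]), g=float(rgb_mean[1]), b=float(rgb_mean[2]),
        h=float(hsv_mean[0]), s=float(hsv_mean[1]), v=float(hsv_mean[2]),
        l_star=float(lab_mean[0]), a_star=float(lab_mean[1]),
        b_star=float(lab_mean[2]),
    )


def exg_transform(image: np.ndarray) -> np.ndarray:
    """Per-pixel excess green 2G - R - B on raw [0, 255] channels."""
    img = np.asarray(image, dtype=float)
    return 2.0 * img[..., 1] - img[..., 0] - img[..., 2]


# ---------------------------------------------------------------------------
# middle-cut segmentation
# ---------------------------------------------------------------------------

def segment_middle_cut(image: np.ndarray) -> RegionMasks:
    """Segment a middle-cut image into section, outer, core and locule masks.

    1. Section: Otsu on the hue channel (rotated by 0.5 so red and
       near-zero hues form one mode), then opening, largest component and
       hole filling.  The fruit side of the threshold is the side with the
       higher mean saturation (tissue is chromatic, background near-white).
    2. Outer pericarp: within the section, two-threshold multi-Otsu on the
       ExG image; the highest-ExG class is the outer pericarp.
    3. Core: Otsu split of the remainder; the class whose mean ExG is
       nearest zero is the core (cleaned by opening + largest component).
    4. Locule: section minus outer minus core, so the partition is exact.
    """
    hsv = skcolor.rgb2hsv(np.asarray(image, dtype=float) / 255.0)
    hue = (hsv[..., 0] + 0.5) % 1.0
    sat = hsv[..., 1]
    if hue.min() == hue.max():
        raise SegmentationError("section", "uniform hue: no cut section found")
    t = threshold_otsu(hue)
    side = hue > t
    # fruit tissue is the more saturated side
    fg = side if sat[side].mean() >= sat[~side].mean() else ~side
    radius = _opening_radius(image.shape)
    section = _cleanup(fg, radius)
    if not section.any():
        raise SegmentationError("section")

    exg = exg_transform(image)
    sec_vals = exg[section]
    thresholds = threshold_multiotsu(sec_vals, classes=3)
    outer = section & (exg > thresholds[1])
    if not outer.any():
        raise SegmentationError("outer")

    remainder = section & ~outer
    rem_vals = exg[remainder]
    if rem_vals.size == 0 or rem_vals.min() == rem_vals.max():
        raise SegmentationError("core", "no ExG contrast left for the core split")
    tc = threshold_otsu(rem_vals)
    upper = remainder & (exg > tc)
    lower = remainder & ~upper
    # the near-zero-ExG class is the core; the other remains locule candidate
    if abs(exg[upper].mean()) <= abs(exg[lower].mean()):
        core_cand = upper
    else:
        core_cand = lower
    core = _cleanup(core_cand, radius)
    core &= section & ~outer
    min_px = _MIN_REGION_FRACTION * section.sum()
    if core.sum() < min_px:
        raise SegmentationError("core")

    locule = section & ~outer & ~core
    if locule.sum() < min_px:
        raise SegmentationError("locule")
    # coherence check: a real locule is a solid ring, not salt-and-pepper
    # residue left by splitting a scene that has no third tissue class
    coherent = morphology.opening(locule, morphology.disk(radius))
    if coherent.sum() < 0.5 * locule.sum():
        raise SegmentationError(
            "locule", "locule residue is incoherent: no distinct locule ring")
    return RegionMasks(section=section, outer=outer, core=core, locule=locule)


def locule_area_rate(masks: RegionMasks) -> float:
    """Locule area as a fraction of the cut-section area, in [0, 1)."""
    section_area = masks.section.sum()
    if section_area == 0:
        raise ValueError("empty section mask")
    return float(masks.locule.sum() / section_area)


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract_image_features(whole_image: np.ndarray,
                           cut_image: np.ndarray,
                           crop_size: int | None = None) -> ImageFeatureVector:
    """Run crop -> segment -> measure on both images; return the 46 features.

    ``crop_size`` defaults to 1600 px, shrunk to the image if the input is
    smaller (so already-tight renders pass through unchanged).
    """
    feats = []
    for stage, image in (("whole", whole_image), ("cut", cut_image)):
        size = crop_size or min(image.shape[0], image.shape[1], 1600)
        try:
            img = crop_center(image, size)
            if stage == "whole":
                mask = segment_whole_fruit(img)
                feats.extend(compute_color_means(img, mask).as_array())
                m = compute_morphology(mask)
                feats.extend([m.area, m.roundness, m.aspect_ratio])
            else:
                masks = segment_middle_cut(img)
                m = compute_morphology(masks.section)
                feats.extend([m.area, m.roundness, m.aspect_ratio])
                feats.extend(compute_color_means(img, masks.outer).as_array())
                feats.extend(compute_color_means(img, masks.locule).as_array())
                feats.append(locule_area_rate(masks))
                feats.extend(compute_color_means(img, masks.core).as_array())
                mc = compute_morphology(masks.core)
                feats.extend([mc.area, mc.roundness, mc.aspect_ratio])
        except SegmentationError as err:
            raise SegmentationError(
                err.region, f"{stage}-image stage: {err}") from err
    return ImageFeatureVector(values=np.asarray(feats, dtype=float))
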