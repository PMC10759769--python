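"""Synthetic kiwifruit study generator.

Produces labeled samples — whole-fruit and middle-cut RGB images with exact
ground-truth masks, 13-channel MOS gas-sensor voltage curves over a 220 s
acquisition (120 s baseline, 40 s headspace injection, 60 s recovery), and
per-fruit physicochemical records — with the between-region structure of the
three Guilan growing regions (Talesh, Langarud, Rasht).

The generator is the study stand-in: every downstream stage (segmentation,
feature extraction, normalization, fusion modeling) is testable against the
ground truth it emits.  Two dials control difficulty:

``separation``
    scales between-region differences; 1.0 reproduces the published regional
    means, 0.0 collapses all regions onto the grand mean.
``noise_scale``
    scales all within-region variability (physicochemical CVs, pixel noise,
    sensor noise and drift); 0.0 is the noiseless limit used by closed-form
    tests.

Aroma carries genuine predictive signal for fruit quality: each sensor's
response amplitude is ``gain_s * (1 + KAPPA * z)`` where ``z`` is the
sample's standardized soluble-solids content (SSC), so e-nose features are
informative for the physicochemical targets and not only for region identity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from kiwifuse.imgfeat import RegionMasks

__all__ = [
    "RegionLabel",
    "PhysChemRecord",
    "RegionProfile",
    "SceneSpec",
    "SensorCurve",
    "EnoseSample",
    "SyntheticSample",
    "DatasetConfig",
    "PHYSCHEM_ATTRIBUTES",
    "SENSOR_IDS",
    "make_region_profiles",
    "sample_physchem",
    "render_whole_fruit",
    "render_middle_cut",
    "simulate_enose_sample",
    "generate_dataset",
    "default_scene",
]


class RegionLabel(enum.IntEnum):
    """The three growing regions, with stable integer codes 1..3."""

    Talesh = 1
    Langarud = 2
    Rasht = 3


#: Physicochemical attributes in canonical order.  ``bar`` (Brix-acid ratio)
#: is always recomputed as ssc / ta, never sampled independently.
PHYSCHEM_ATTRIBUTES = (
    "firmness", "ssc", "ta", "bar", "ph", "vitamin_c", "tp", "tac",
    "dpph", "frap", "sucrose", "glucose", "fructose",
)

_SAMPLED_ATTRIBUTES = tuple(a for a in PHYSCHEM_ATTRIBUTES if a != "bar")

# Published per-region means: firmness kg/cm^2, SSC degBrix, TA % citric acid,
# pH, vitamin C mg/100 g, TP mg GAE/100 g, TAC mg CGE/100 g, DPPH %,
# FRAP umol/g, sugars %.
_REGION_MEANS = {
    RegionLabel.Talesh: dict(
        firmness=0.76, ssc=18.63, ta=0.58, ph=3.83, vitamin_c=84.84,
        tp=93.18, tac=3.27, dpph=60.84, frap=9.38,
        sucrose=0.76, glucose=1.30, fructose=0.94,
    ),
    RegionLabel.Langarud: dict(
        firmness=0.63, ssc=20.96, ta=0.55, ph=3.75, vitamin_c=94.19,
        tp=104.91, tac=3.49, dpph=67.12, frap=10.68,
        sucrose=0.79, glucose=1.32, fructose=0.98,
    ),
    RegionLabel.Rasht: dict(
        firmness=1.20, ssc=17.40, ta=0.63, ph=3.71, vitamin_c=74.07,
        tp=88.37, tac=2.64, dpph=57.25, frap=8.48,
        sucrose=0.74, glucose=1.38, fructose=0.91,
    ),
}

#: Default within-region coefficient of variation (fraction of the mean) for
#: every sampled attribute, scaled multiplicatively by ``noise_scale``.
BASE_CV = 0.05

#: Sensor channel labels (8 MQ + 5 TGS); configurable, order is canonical.
SENSOR_IDS = (
    "MQ2", "MQ3", "MQ4", "MQ5", "MQ6", "MQ8", "MQ9", "MQ135",
    "TGS813", "TGS822", "TGS2600", "TGS2602", "TGS2610",
)

# Per-sensor baseline voltage (V), rise time constant (s) and base amplitude
# gain.  Values span the spread a mixed MQ/TGS array shows in practice.
_SENSOR_V0 = np.array(
    [1.20, 1.50, 1.10, 1.40, 1.30, 1.60, 1.20, 1.50, 2.00, 1.80, 1.70, 1.90, 1.40])
_SENSOR_TAU = np.array(
    [5.0, 6.0, 7.0, 8.0, 5.5, 6.5, 7.5, 8.5, 6.0, 7.0, 5.0, 8.0, 6.5])
_SENSOR_TAU_RECOVERY = np.array(
    [18.0, 20.0, 22.0, 19.0, 17.0, 21.0, 18.5, 20.5, 19.5, 22.5, 17.5, 21.5, 18.0])
_BASE_GAIN = np.array(
    [1.80, 1.20, 1.50, 1.00, 1.10, 0.90, 1.60, 1.40, 1.30, 1.70, 1.00, 1.20, 1.50])

# Per-region, per-sensor fractional gain offsets at separation = 1.  The
# Langarud offsets exceed the other two regions on every channel, matching
# the observed radar-plot ordering of mean MSR values.
_GAIN_DELTA = {
    RegionLabel.Talesh: np.array(
        [0.06, 0.02, 0.08, 0.04, 0.00, 0.05, 0.02, 0.07, 0.03, 0.05, 0.01, 0.04, 0.06]),
    RegionLabel.Langarud: np.array(
        [0.40, 0.28, 0.35, 0.30, 0.26, 0.33, 0.38, 0.42, 0.27, 0.36, 0.29, 0.31, 0.39]),
    RegionLabel.Rasht: np.array(
        [-0.10, -0.05, -0.12, -0.08, -0.04, -0.09, -0.11, -0.06, -0.07, -0.13, -0.05, -0.08, -0.10]),
}

#: Latent coupling: amplitude factor per unit of standardized SSC.
KAPPA = 0.3
#: Reference SSC (grand mean over the three regions) and standardization scale.
SSC_REF = (18.63 + 20.96 + 17.40) / 3.0
SSC_SCALE = 1.5

# Acquisition protocol (seconds): baseline, injection, recovery; 1 Hz.
BASELINE_END = 120.0
INJECTION_END = 160.0
PROTOCOL_END = 220.0

# Base palette, 8-bit RGB.  The background is a faintly cool white: a truly
# achromatic background has numerically unstable hue under pixel noise, which
# would defeat hue-channel thresholding of the cut section.
BACKGROUND_RGB = (238, 243, 250)
SKIN_RGB = (139, 110, 72)
OUTER_RGB = (150, 200, 60)
LOCULE_RGB = (200, 40, 60)
CORE_RGB = (235, 225, 205)

# Signed RGB offsets added to the locule base color, per region, at
# separation = 1.  Region identity expresses itself visually mainly through
# locule pigmentation (anthocyanin-driven); the three shifts are chosen
# non-collinear — regions differ in pigment composition (hue direction),
# not merely in the amount of one pigment.
_LOCULE_SHIFT = {
    RegionLabel.Talesh: np.array([5.0, 16.0, -14.0]),     # warmer, orange-red
    RegionLabel.Langarud: np.array([22.0, -12.0, -6.0]),  # deep saturated red
    RegionLabel.Rasht: np.array([-18.0, 10.0, 10.0]),     # paler pink
}

# Milder region shifts for the remaining tissues: skin, pericarp and core
# pigmentation also track the growing climate, but far more weakly than the
# anthocyanin-rich locule — whole-fruit appearance alone separates regions
# poorly, the cut face well.
_TISSUE_SHIFT = {
    "skin": {
        RegionLabel.Talesh: np.array([5.0, 3.0, -4.0]),
        RegionLabel.Langarud: np.array([-5.0, 5.0, -5.0]),
        RegionLabel.Rasht: np.array([4.0, -6.0, 4.0]),
    },
    "outer": {
        RegionLabel.Talesh: np.array([-4.0, 6.0, -5.0]),
        RegionLabel.Langarud: np.array([6.0, 4.0, -6.0]),
        RegionLabel.Rasht: np.array([3.0, -7.0, 6.0]),
    },
    "core": {
        RegionLabel.Talesh: np.array([4.0, -3.0, 2.0]),
        RegionLabel.Langarud: np.array([-4.0, 4.0, -4.0]),
        RegionLabel.Rasht: np.array([2.0, 3.0, 4.0]),
    },
}


@dataclass(frozen=True)
class PhysChemRecord:
    """One fruit's laboratory quality record.

    Units: firmness kg/cm^2; ssc degBrix; ta % citric acid; bar = ssc/ta
    (dimensionless); ph pH units; vitamin_c mg/100 g; tp mg GAE/100 g;
    tac mg CGE/100 g; dpph %; frap umol/g; sugars %.
    """

    firmness: float
    ssc: float
    ta: float
    bar: float
    ph: float
    vitamin_c: float
    tp: float
    tac: float
    dpph: float
    frap: float
    sucrose: float
    glucose: float
    fructose: float

    def __post_init__(self):
        for attr in PHYSCHEM_ATTRIBUTES:
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if abs(self.bar - self.ssc / self.ta) > 1e-9:
            raise ValueError("bar must equal ssc / ta")
        if not 2.0 <= self.ph <= 7.0:
            raise ValueError("ph must lie in [2, 7]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, a) for a in PHYSCHEM_ATTRIBUTES])

    def as_dict(self) -> dict:
        return {a: getattr(self, a) for a in PHYSCHEM_ATTRIBUTES}


@dataclass(frozen=True)
class RegionProfile:
    """Generative parameters for one growing region."""

    label: RegionLabel
    physchem_means: PhysChemRecord
    physchem_cv: dict           # attribute -> effective CV (already noise-scaled)
    sensor_gain: np.ndarray     # 13 positive amplitude multipliers
    locule_color_shift: np.ndarray  # signed RGB offsets for the locule base color
    shape_jitter: float         # fractional axis-length variation
    noise_scale: float = 1.0

    def __post_init__(self):
        if np.any(self.sensor_gain <= 0):
            raise ValueError("sensor_gain entries must be > 0")
        for attr, cv in self.physchem_cv.items():
            if not 0.0 <= cv < 0.5:
                raise ValueError(f"physchem_cv[{attr}] must lie in [0, 0.5)")


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and palette of a rendered scene (square image).

    ``fruit_axes`` and ``core_axes`` are (semi-major, semi-minor) in pixels;
    ``locule_outer_fraction`` scales the fruit axes to the ellipse bounding
    the red locule ring.  ``base_colors`` maps region names (background, skin,
    outer, locule, core) to RGB triplets in [0, 255].
    """

    image_size: int = 1600
    fruit_axes: tuple = (520.0, 470.0)
    core_axes: tuple = (118.0, 96.0)
    locule_outer_fraction: float = 0.52
    base_colors: dict = field(default_factory=lambda: {
        "background": BACKGROUND_RGB,
        "skin": SKIN_RGB,
        "outer": OUTER_RGB,
        "locule": LOCULE_RGB,
        "core": CORE_RGB,
    })
    noise_sd: float = 2.5

    def __post_init__(self):
        a, b = self.fruit_axes
        ca, cb = self.core_axes
        la, lb = self.locule_bound_axes
        if not (ca < la < a and cb < lb < b):
            raise ValueError(
                "geometry must nest: core_axes < locule bound < fruit_axes")
        if self.image_size < 2 * a:
            raise ValueError("image_size must be at least 2 x fruit semi-major")
        for name, rgb in self.base_colors.items():
            if np.any(np.asarray(rgb) < 0) or np.any(np.asarray(rgb) > 255):
                raise ValueError(f"color {name} outside [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def locule_bound_axes(self) -> tuple:
        return (self.fruit_axes[0] * self.locule_outer_fraction,
                self.fruit_axes[1] * self.locule_outer_fraction)

    def scaled(self, image_size: int) -> "SceneSpec":
        """Rescale all geometry to a new square image size."""
        f = image_size / self.image_size
        return replace(
            self,
            image_size=image_size,
            fruit_axes=(self.fruit_axes[0] * f, self.fruit_axes[1] * f),
            core_axes=(self.core_axes[0] * f, self.core_axes[1] * f),
        )


def default_scene(image_size: int = 1600, noise_sd: float = 2.5) -> SceneSpec:
    """Default scene geometry at the requested image size."""
    return replace(SceneSpec(noise_sd=noise_sd).scaled(image_size))


@dataclass(frozen=True)
class SensorCurve:
    """Raw response of one gas sensor over the 220 s protocol."""

    sensor_id: str
    times: np.ndarray
    voltages: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and voltages must have the same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("voltages must be > 0")


@dataclass(frozen=True)
class EnoseSample:
    """One fruit's 13 sensor curves on a shared time base."""

    curves: tuple

    def __post_init__(self):
        if len(self.curves) != 13:
            raise ValueError("an e-nose sample holds exactly 13 curves")
        t0 = self.curves[0].times
        for c in self.curves[1:]:
            if not np.array_equal(c.times, t0):
                raise ValueError("all curves must share one time base")

    @property
    def sensor_ids(self) -> tuple:
        return tuple(c.sensor_id for c in self.curves)


@dataclass(frozen=True)
class SyntheticSample:
    """A fully labeled synthetic fruit: images, truth masks, curves, record."""

    sample_id: str
    label: RegionLabel
    whole_image: np.ndarray
    cut_image: np.ndarray
    truth_masks: RegionMasks
    enose: EnoseSample
    physchem: PhysChemRecord


@dataclass(frozen=True)
class DatasetConfig:
    """Reproducible dataset recipe: everything derives from these fields."""

    n_per_region: int = 15
    seed: int = 0
    separation: float = 1.0
    noise_scale: float = 1.0
    image_size: int = 1600

    def __post_init__(self):
        if self.n_per_region < 3:
            raise ValueError("n_per_region must be >= 3 (needed for splits)")
        if self.separation < 0 or self.noise_scale < 0:
            raise ValueError("separation and noise_scale must be >= 0")


# ---------------------------------------------------------------------------
# profiles and physicochemical sampling
# ---------------------------------------------------------------------------

def make_region_profiles(separation: float = 1.0,
                         noise_scale: float = 1.0) -> dict:
    """Build the three region profiles.

    At ``separation = 1`` the physicochemical means equal the published
    regional means; at 0 all three regions share the grand mean.  Sensor
    gains interpolate the same way, keeping Langarud highest on every channel
    whenever ``separation > 0``.
    """
    if separation < 0 or noise_scale < 0:
        raise ValueError("separation and noise_scale must be >= 0")
    grand = {a: np.mean([_REGION_MEANS[r][a] for r in RegionLabel])
             for a in _SAMPLED_ATTRIBUTES}
    profiles = {}
    for region in RegionLabel:
        means = {a: grand[a] + separation * (_REGION_MEANS[region][a] - grand[a])
                 for a in _SAMPLED_ATTRIBUTES}
        means["bar"] = means["ssc"] / means["ta"]
        record = PhysChemRecord(**means)
        gain = _BASE_GAIN * (1.0 + separation * _GAIN_DELTA[region])
        profiles[region] = RegionProfile(
            label=region,
            physchem_means=record,
            physchem_cv={a: BASE_CV * noise_scale for a in _SAMPLED_ATTRIBUTES},
            sensor_gain=gain,
            locule_color_shift=_LOCULE_SHIFT[region] * separation,
            shape_jitter=0.04,
            noise_scale=noise_scale,
        )
    return profiles


def sample_physchem(profile: RegionProfile, rng: np.random.Generator) -> PhysChemRecord:
    """Draw one physicochemical record from a region profile.

    Each attribute is a truncated normal draw with the profile mean and
    sd = mean x cv, bounded below at 10% of the mean (pH also bounded above
    at 7.0).  BAR is recomputed as ssc / ta after sampling.
    """
    values = {}
    for attr in _SAMPLED_ATTRIBUTES:
        mean = getattr(profile.physchem_means, attr)
        sd = mean * profile.physchem_cv[attr]
        if sd == 0.0:
            values[attr] = mean
            continue
        lo = 0.1 * mean
        hi = 7.0 if attr == "ph" else np.inf
        a, b = (lo - mean) / sd, (hi - mean) / sd
        values[attr] = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                                 random_state=rng))
    values["bar"] = values["ssc"] / values["ta"]
    return PhysChemRecord(**values)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(size: int, axes: tuple) -> np.ndarray:
    c = (size - 1) / 2.0
    u = (np.arange(size, dtype=np.float64) - c)
    a, b = axes
    return (u / a)[None, :] ** 2 + (u / b)[:, None] ** 2 <= 1.0


def _finalize(img: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_whole_fruit(scene: SceneSpec, rng: np.random.Generator):
    """Render a whole fruit: a skin-colored ellipse on the uniform background.

    Returns ``(rgb_image, fruit_mask)`` where the mask is the exact rendered
    ellipse.
    """
    size = scene.image_size
    mask = _ellipse_mask(size, scene.fruit_axes)
    img = np.empty((size, size, 3), dtype=float)
    img[:] = scene.base_colors["background"]
    img[mask] = scene.base_colors["skin"]
    return _finalize(img, scene.noise_sd, rng), mask


def render_middle_cut(scene: SceneSpec, rng: np.random.Generator):
    """Render an equatorial cut face and its exact region masks.

    Concentric layout: outer pericarp annulus (green-yellow, strongly
    positive excess-green index ExG = 2G - R - B), red locule ring (strongly
    negative ExG) with radial streak texture, pale core ellipse (ExG near
    zero).  The cut face fills the fruit ellipse edge-to-edge: at render
    resolution the ~1 mm skin rim of a real cut is sub-pixel and is omitted.
    """
    size = scene.image_size
    section = _ellipse_mask(size, scene.fruit_axes)
    locule_bound = _ellipse_mask(size, scene.locule_bound_axes)
    core = _ellipse_mask(size, scene.core_axes)
    locule = locule_bound & ~core
    outer = section & ~locule_bound

    img = np.empty((size, size, 3), dtype=float)
    img[:] = scene.base_colors["background"]
    img[outer] = scene.base_colors["outer"]
    img[core] = scene.base_colors["core"]
    # radial streaks: multiplicative brightness ripple along the angle
    c = (size - 1) / 2.0
    yy, xx = np.nonzero(locule)
    theta = np.arctan2(yy - c, xx - c)
    ripple = 1.0 + 0.08 * np.sin(40.0 * theta)
    img[locule] = np.asarray(scene.base_colors["locule"]) * ripple[:, None]

    masks = RegionMasks(section=section, outer=outer, core=core, locule=locule)
    return _finalize(img, scene.noise_sd, rng), masks


# ---------------------------------------------------------------------------
# e-nose simulation
# ---------------------------------------------------------------------------

def simulate_enose_sample(profile: RegionProfile,
                          physchem: PhysChemRecord,
                          rng: np.random.Generator) -> EnoseSample:
    """Simulate the 13 sensor curves for one fruit.

    Per sensor s, on the 1 Hz grid t = 1..220 s:

    * baseline (t <= 120):  V0_s plus a small linear drift and noise;
    * injection (120 < t <= 160):  saturating rise
      ``V0_s * (1 + A_s * (1 - exp(-(t - 120)/tau_s)))``;
    * recovery (t > 160):  exponential return toward V0_s.

    The amplitude is ``A_s = gain_s * (1 + KAPPA * z)`` with z the sample's
    standardized SSC, so aroma amplitude is coupled to fruit quality.  Drift
    and noise scale with the profile's ``noise_scale``; at 0 the curves match
    the closed forms exactly.
    """
    t = np.arange(1.0, PROTOCOL_END + 1.0)
    z = (physchem.ssc - SSC_REF) / SSC_SCALE
    amp = profile.sensor_gain * (1.0 + KAPPA * z)
    amp = np.maximum(amp, 0.01)
    ns = profile.noise_scale

    curves = []
    for i, sid in enumerate(SENSOR_IDS):
        v0, tau, tau_r = _SENSOR_V0[i], _SENSOR_TAU[i], _SENSOR_TAU_RECOVERY[i]
        shape = np.full_like(t, v0)
        rise = (t > BASELINE_END) & (t <= INJECTION_END)
        shape[rise] = v0 * (1.0 + amp[i] * (1.0 - np.exp(-(t[rise] - BASELINE_END) / tau)))
        peak = amp[i] * (1.0 - np.exp(-(INJECTION_END - BASELINE_END) / tau))
        rec = t > INJECTION_END
        shape[rec] = v0 * (1.0 + peak * np.exp(-(t[rec] - INJECTION_END) / tau_r))
        if ns > 0:
            drift = v0 * 0.002 * ns * rng.uniform(-1.0, 1.0) * (t / PROTOCOL_END)
            noise = rng.normal(0.0, 0.004 * v0 * ns, t.shape)
            shape = shape + drift + noise
        shape = np.maximum(shape, 1e-6)
        curves.append(SensorCurve(sensor_id=sid, times=t, voltages=shape))
    return EnoseSample(curves=tuple(curves))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def generate_dataset(config: DatasetConfig, out_dir=None) -> list:
    """Generate 3 x n_per_region labeled samples, reproducibly from the seed.

    If ``out_dir`` is given, images (PNG), curves and records (CSV) are also
    written there in the package's on-disk conventions.
    """
    profiles = make_region_profiles(config.separation, config.noise_scale)
    base_scene = default_scene(config.image_size,
                               noise_sd=2.5 * config.noise_scale)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(3 * config.n_per_region)

    samples = []
    k = 0
    for region in RegionLabel:
        profile = profiles[region]
        for i in range(config.n_per_region):
            rng = np.random.default_rng(children[k])
            k += 1
            physchem = sample_physchem(profile, rng)

            jit = profile.shape_jitter
            fa = base_scene.fruit_axes
            ca = base_scene.core_axes
            jf = 1.0 + jit * rng.uniform(-1.0, 1.0, 2)
            jc = 1.0 + jit * rng.uniform(-1.0, 1.0, 2)
            frac = base_scene.locule_outer_fraction + 0.02 * rng.uniform(-1.0, 1.0)
            # per-fruit color variability: pigment jitter per tissue plus a
            # common illumination factor (fruit tissue only, not background)
            gain = 1.0 + 0.015 * config.noise_scale * rng.normal()
            colors = dict(base_scene.base_colors)
            locule_rgb = (np.asarray(LOCULE_RGB, dtype=float)
                          + profile.locule_color_shift
                          + rng.normal(0.0, 3.0 * config.noise_scale, 3))
            colors["locule"] = tuple(np.clip(locule_rgb * gain, 0, 255))
            for tissue in ("skin", "outer", "core"):
                rgb = (np.asarray(base_scene.base_colors[tissue], dtype=float)
                       + _TISSUE_SHIFT[tissue][region] * config.separation
                       + rng.normal(0.0, 2.5 * config.noise_scale, 3))
                colors[tissue] = tuple(np.clip(rgb * gain, 0, 255))
            scene = replace(base_scene,
                            fruit_axes=(fa[0] * jf[0], fa[1] * jf[1]),
                            core_axes=(ca[0] * jc[0], ca[1] * jc[1]),
                            locule_outer_fraction=frac,
                            base_colors=colors)

            whole_img, _ = render_whole_fruit(scene, rng)
            cut_img, masks = render_middle_cut(scene, rng)
            enose = simulate_enose_sample(profile, physchem, rng)
            samples.append(SyntheticSample(
                sample_id=f"{region.name.lower()}-{i:03d}",
                label=region,
                whole_image=whole_img,
                cut_image=cut_img,
                truth_masks=masks,
                enose=enose,
                physchem=physchem,
            ))

    if out_dir is not None:
        from kiwifuse import io as kio
        kio.write_dataset(samples, out_dir)
    return samples
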