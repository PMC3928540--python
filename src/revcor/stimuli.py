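"""Stimulus rendering, display geometry, contrast-energy bookkeeping and noise.

The detection stimulus is a dark central disk optionally surrounded by a ring
of context ("inducer") disks, rasterized as a square contrast image
(``(L_pixel - L_bg) / L_bg`` per pixel).  Inducer pixels are always rendered at
the display's maximum negative contrast and are kept noise-free; all other
pixels receive truncated Gaussian contrast noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "Condition",
    "DisplaySpec",
    "StimulusSpec",
    "ContrastImage",
    "NoiseField",
    "pixels_to_degrees",
    "pixel_area_deg2",
    "contrast_energy",
    "render_stimulus",
    "scale_to_energy",
    "sample_noise_field",
    "compose_trial_image",
    "window_center",
    "SMALL_INDUCERS",
    "LARGE_INDUCERS",
    "NO_INDUCERS",
]


class Condition(str, Enum):
    """Inducer context of the detection stimulus."""

    SMALL = "small_inducers"
    LARGE = "large_inducers"
    NONE = "none"


class ConfigurationError(ValueError):
    """Invalid display or stimulus configuration."""


@dataclass(frozen=True)
class DisplaySpec:
    """Physical display geometry fixing the pixel<->degree conversion.

    Defaults reproduce a 38.25 cm wide, 1024x768 CRT viewed at 130 cm.
    """

    width_cm: float = 38.25
    width_px: int = 1024
    height_px: int = 768
    viewing_distance_cm: float = 130.0
    refresh_hz: float = 85.0
    background_luminance_cdm2: float = 85.0
    max_neg_contrast: float = -0.87

    def __post_init__(self) -> None:
        for name in ("width_cm", "width_px", "height_px", "viewing_distance_cm",
                     "refresh_hz", "background_luminance_cdm2"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"display field {name!r} must be > 0")
        if abs(self.max_neg_contrast) > 1:
            raise ConfigurationError("|max_neg_contrast| must be <= 1")


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of the central-dot + inducer-ring figure."""

    condition: Condition
    central_diameter_px: int = 45
    inducer_diameter_px: int = 15
    n_inducers: int = 12
    center_to_center_px: float = 45.0
    window_px: int = 200
    target_contrast: float = -0.87

    def __post_init__(self) -> None:
        if self.condition is Condition.NONE and self.n_inducers != 0:
            raise ConfigurationError("condition 'none' requires n_inducers == 0")
        if self.window_px <= 0 or self.central_diameter_px < 0:
            raise ConfigurationError("window and diameters must be positive")
        if self.target_contrast > 0:
            raise ConfigurationError("target_contrast must be <= 0 (dark target)")
        if self.n_inducers > 0:
            reach = self.center_to_center_px + self.inducer_diameter_px / 2.0
            if reach > self.window_px / 2.0:
                raise ConfigurationError(
                    "inducer disks would overlap the analysis-window border "
                    f"(reach {reach} px > half-window {self.window_px / 2.0} px)"
                )


# Canonical stimulus geometries.
SMALL_INDUCERS = StimulusSpec(
    condition=Condition.SMALL, inducer_diameter_px=15, n_inducers=12,
    center_to_center_px=45.0)
LARGE_INDUCERS = StimulusSpec(
    condition=Condition.LARGE, inducer_diameter_px=55, n_inducers=5,
    center_to_center_px=60.0)
NO_INDUCERS = StimulusSpec(
    condition=Condition.NONE, inducer_diameter_px=0, n_inducers=0,
    center_to_center_px=0.0)


@dataclass
class ContrastImage:
    """A rasterized contrast map plus the mask of noise-free inducer pixels."""

    values: np.ndarray
    inducer_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    origin: str = "zero_based_geometric_center"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("contrast image must be 2-D")
        if self.inducer_mask is None:
            self.inducer_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.inducer_mask = np.asarray(self.inducer_mask, dtype=bool)
        if self.inducer_mask.shape != self.values.shape:
            raise ValueError("inducer_mask shape must match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ContrastImage":
        return ContrastImage(self.values.copy(), self.inducer_mask.copy(),
                             self.origin)


@dataclass
class NoiseField:
    """Truncated Gaussian contrast noise; zero on inducer-mask pixels."""

    values: np.ndarray
    sigma2: float
    truncation_sd: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def pixels_to_degrees(px: float, display: DisplaySpec) -> float:
    """Visual angle (degrees) spanned by ``px`` pixels.

    The full display subtense ``2 atan(width / (2 distance))`` is divided
    uniformly over the horizontal pixel count, giving a constant angular
    pixel pitch.  This convention reproduces every printed disk size of the
    reference display (0.25, 0.74, 0.9, 0.98, 1.11 and 3.27 deg) at its
    quoted precision, which the plain small-angle form does not.
    """
    if px < 0:
        raise ValueError("pixel count must be >= 0")
    subtense = 2.0 * math.atan(display.width_cm
                               / (2.0 * display.viewing_distance_cm))
    return math.degrees(subtense) * px / display.width_px


def pixel_area_deg2(display: DisplaySpec) -> float:
    """Area of one pixel in squared degrees of visual angle."""
    return pixels_to_degrees(1.0, display) ** 2


def contrast_energy(image: ContrastImage, display: DisplaySpec) -> float:
    """Sum of squared pixel contrasts times per-pixel area (deg^2)."""
    vals = image.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("image contains non-finite contrasts")
    return float(np.sum(vals * vals)) * pixel_area_deg2(display)


def window_center(window_px: int) -> tuple[float, float]:
    """Geometric center of an N x N window in 0-based pixel coordinates."""
    c = (window_px - 1) / 2.0
    return c, c


def _disk_mask(window_px: int, cx: float, cy: float, diameter_px: float) -> np.ndarray:
    yy, xx = np.mgrid[0:window_px, 0:window_px]
    r = diameter_px / 2.0
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def render_stimulus(spec: StimulusSpec, display: DisplaySpec,
                    present: bool) -> ContrastImage:
    """Rasterize the figure onto the analysis window.

    The central disk is drawn at ``spec.target_contrast`` iff ``present``;
    inducer disks are drawn at the display's maximum negative contrast,
    equally spaced in angle (first inducer at the top) at the configured
    center-to-center radius.  A pixel belongs to a disk iff its center lies
    within ``diameter/2`` of the disk center (no anti-aliasing).
    """
    n = spec.window_px
    cx, cy = window_center(n)
    values = np.zeros((n, n), dtype=float)
    mask = np.zeros((n, n), dtype=bool)

    if present and spec.central_diameter_px > 0:
        values[_disk_mask(n, cx, cy, spec.central_diameter_px)] = spec.target_contrast

    if spec.condition is not Condition.NONE:
        for k in range(spec.n_inducers):
            theta = math.pi / 2.0 + 2.0 * math.pi * k / spec.n_inducers
            ix = cx + spec.center_to_center_px * math.cos(theta)
            iy = cy - spec.center_to_center_px * math.sin(theta)  # row axis points down
            mask |= _disk_mask(n, ix, iy, spec.inducer_diameter_px)
        values[mask] = display.max_neg_contrast

    return ContrastImage(values, mask)


def scale_to_energy(image: ContrastImage, target_energy: float,
                    display: DisplaySpec) -> ContrastImage:
    """Rescale the non-inducer region to a prescribed contrast energy.

    Inducer pixels are left untouched; every other pixel is multiplied by the
    single factor that brings the energy of the scalable region to
    ``target_energy``.
    """
    if target_energy < 0:
        raise ValueError("target energy must be >= 0")
    free = ~image.inducer_mask
    current = float(np.sum(image.values[free] ** 2)) * pixel_area_deg2(display)
    if current <= 0.0:
        raise ValueError("scalable region has zero contrast energy")
    factor = math.sqrt(target_energy / current)
    out = image.copy()
    out.values[free] *= factor
    return out


def sample_noise_field(sigma2: float, window_px: int,
                       inducer_mask: np.ndarray | None = None,
                       rng: np.random.Generator | int | None = None) -> NoiseField:
    """Draw a truncated Gaussian white-noise field.

    Zero-mean deviates of variance ``sigma2`` are rejection-resampled until
    every sample satisfies ``|x| <= 2 * sqrt(sigma2)``; pixels under
    ``inducer_mask`` are forced to zero.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    values = np.zeros((window_px, window_px), dtype=float)
    if sigma2 > 0:
        sd = math.sqrt(sigma2)
        values = gen.normal(0.0, sd, size=(window_px, window_px))
        bad = np.abs(values) > 2.0 * sd
        while bad.any():
            values[bad] = gen.normal(0.0, sd, size=int(bad.sum()))
            bad = np.abs(values) > 2.0 * sd
    if inducer_mask is not None:
        values[np.asarray(inducer_mask, dtype=bool)] = 0.0
    return NoiseField(values, sigma2)


def truncated_variance_factor(truncation_sd: float = 2.0) -> float:
    """Variance of a +-k-sd truncated standard normal relative to sigma^2."""
    from scipy.stats import norm
    k = truncation_sd
    z = norm.cdf(k) - norm.cdf(-k)
    return 1.0 - 2.0 * k * norm.pdf(k) / z


def compose_trial_image(stimulus: ContrastImage, noise: NoiseField) -> ContrastImage:
    """Pixel-wise sum of stimulus and noise outside the inducer mask.

    Inducer pixels keep the stimulus value exactly (they are noise-free).
    """
    if stimulus.values.shape != noise.values.shape:
        raise ValueError("stimulus and noise shapes differ")
    out = stimulus.values + noise.values
    out[stimulus.inducer_mask] = stimulus.values[stimulus.inducer_mask]
    return ContrastImage(out, stimulus.inducer_mask.copy())


def spec_for(condition: Condition | str,
             target_contrast: float = -0.87) -> StimulusSpec:
    """Canonical StimulusSpec for a named condition."""
    cond = Condition(condition)
    base = {Condition.SMALL: SMALL_INDUCERS,
            Condition.LARGE: LARGE_INDUCERS,
            Condition.NONE: NO_INDUCERS}[cond]
    return replace(base, target_contrast=target_contrast)
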