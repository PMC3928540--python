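"""Simulated deciders for the yes/no detection task.

Three observer models are provided:

* ``IdealObserver`` — the likelihood-ratio decision rule for a known additive
  target in white Gaussian noise (maximum-posterior under equal priors).
* ``CSFIdealObserver`` — the same rule after both the noise-free stimulus and
  the decision template have been passed through a contrast-sensitivity
  function (CSF) in the frequency domain; the noise itself is unfiltered.
* ``TemplateObserver`` — a linear-template matcher with internal Gaussian
  noise and a fixed criterion, used as a configurable human stand-in.

All observers decide on the pixels outside the inducer mask; the inducer
disks are identical under both hypotheses and carry no information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stimuli import (Condition, ContrastImage, DisplaySpec, StimulusSpec,
                      pixels_to_degrees, render_stimulus, window_center)

__all__ = [
    "CSFSpec",
    "default_csf",
    "csf_filter",
    "ideal_decide",
    "csf_ideal_decide",
    "template_observer_decide",
    "IdealObserver",
    "CSFIdealObserver",
    "TemplateObserver",
    "center_surround_template",
    "make_observer",
]


# ---------------------------------------------------------------------------
# Contrast sensitivity function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSFSpec:
    """Truncated log-parabola contrast sensitivity curve.

    ``S(f) = peak_sensitivity * exp(-(log2(f / peak_frequency))^2 /
    (2 * high_frequency_rolloff^2))``, clipped below the peak so that it never
    falls under ``peak_sensitivity * (1 - low_frequency_attenuation)`` — a
    standard band-pass parameterization of adult foveal sensitivity.
    """

    peak_sensitivity: float = 250.0
    peak_frequency_cdeg: float = 4.0
    low_frequency_attenuation: float = 0.8
    high_frequency_rolloff: float = 1.0  # log2-octave width of the falloff

    def __post_init__(self) -> None:
        if (self.peak_sensitivity <= 0 or self.peak_frequency_cdeg <= 0
                or self.high_frequency_rolloff <= 0):
            raise ValueError("CSF parameters must be positive")
        if not 0.0 <= self.low_frequency_attenuation <= 1.0:
            raise ValueError("low_frequency_attenuation must lie in [0, 1]")

    def __call__(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        out = np.zeros_like(f)
        pos = f > 0
        x = np.log2(f[pos] / self.peak_frequency_cdeg)
        out[pos] = np.exp(-x * x / (2.0 * self.high_frequency_rolloff ** 2))
        floor = 1.0 - self.low_frequency_attenuation
        low = f < self.peak_frequency_cdeg
        out[low] = np.maximum(out[low], floor)
        out[f == 0] = floor
        return self.peak_sensitivity * out


class FlatCSF:
    """Frequency-flat sensitivity; reduces the CSF-limited rule to the ideal."""

    peak_sensitivity = 1.0

    def __call__(self, f) -> np.ndarray:
        return np.ones_like(np.asarray(f, dtype=float))


def flat_csf() -> FlatCSF:
    return FlatCSF()


def default_csf(peak_sensitivity: float = 250.0,
                peak_frequency_cdeg: float = 4.0,
                low_frequency_attenuation: float = 0.8,
                high_frequency_rolloff: float = 1.0) -> CSFSpec:
    """Band-pass CSF approximating adult foveal sensitivity (peak ~4 c/deg)."""
    return CSFSpec(peak_sensitivity, peak_frequency_cdeg,
                   low_frequency_attenuation, high_frequency_rolloff)


def csf_filter(image: ContrastImage, csf: CSFSpec,
               display: DisplaySpec) -> ContrastImage:
    """Filter an image by the CSF in the frequency domain.

    The 2-D Fourier amplitude at radial frequency ``f`` (cycles/degree, fixed
    by the pixel pitch) is multiplied by ``S(f) / max S`` so the filter never
    amplifies; the real part of the inverse transform is returned.  The
    operation is linear and shift-covariant.
    """
    vals = image.values
    if vals.shape[0] != vals.shape[1]:
        raise ValueError("csf_filter requires a square image")
    n = vals.shape[0]
    pitch = pixels_to_degrees(1.0, display)  # degrees per pixel
    fx = np.fft.fftfreq(n, d=pitch)
    fr = np.hypot(fx[None, :], fx[:, None])
    # normalize so the passband peak has unit gain (filtering never amplifies)
    gain = np.asarray(csf(fr), dtype=float)
    gain = gain / gain.max()
    out = np.fft.ifft2(np.fft.fft2(vals) * gain).real
    return ContrastImage(out, image.inducer_mask.copy(), image.origin)


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------

def _log_likelihood_ratio(x: np.ndarray, s: np.ndarray, sigma2: float) -> float:
    # lambda = (<x, s> - ||s||^2 / 2) / sigma^2
    return (float(np.dot(x, s)) - 0.5 * float(np.dot(s, s))) / sigma2


def ideal_decide(observation: ContrastImage, signal_template: ContrastImage,
                 sigma2: float) -> bool:
    """Likelihood-ratio decision for a known target in white Gaussian noise.

    Returns True ("present") iff the log-likelihood ratio
    ``(<x, s> - ||s||^2 / 2) / sigma^2`` is strictly positive, with both
    ``x`` and ``s`` restricted to non-inducer pixels.  Ties go to "absent".
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    free = ~observation.inducer_mask
    x = observation.values[free]
    s = signal_template.values[free]
    return _log_likelihood_ratio(x, s, sigma2) > 0.0


def csf_ideal_decide(observation: ContrastImage, condition: Condition | str,
                     csf: CSFSpec, display: DisplaySpec, sigma2: float,
                     *, _registry: dict | None = None) -> bool:
    """CSF-limited likelihood decision for a canonical condition.

    Convenience wrapper around :class:`CSFIdealObserver` for one-off calls;
    the observation must have been built as ``csf_filter(noise-free signal
    with inducers) + raw noise``.
    """
    from .stimuli import spec_for
    cond = Condition(condition)
    if cond is Condition.NONE:
        raise ValueError("no registered templates for condition 'none'")
    obs = CSFIdealObserver(spec_for(cond), display, sigma2, csf)
    return obs.respond(observation)


def template_observer_decide(observation: ContrastImage, template: ContrastImage,
                             internal_sigma2: float, criterion: float,
                             rng: np.random.Generator) -> bool:
    """Linear template match plus internal noise against a fixed criterion."""
    free = ~observation.inducer_mask
    drive = float(np.dot(observation.values[free], template.values[free]))
    if internal_sigma2 > 0:
        drive += rng.normal(0.0, math.sqrt(internal_sigma2))
    return drive > criterion


# ---------------------------------------------------------------------------
# Observer classes (stateful, used by the trial loop)
# ---------------------------------------------------------------------------

class ObserverModel:
    """Contract: map a composed trial image to a present/absent decision."""

    #: whether the noise-free stimulus must be pre-filtered before adding noise
    filters_stimulus = False

    def transform_stimulus(self, stimulus: ContrastImage) -> ContrastImage:
        return stimulus

    def respond(self, observation: ContrastImage) -> bool:
        raise NotImplementedError

    def reseed(self, rng: np.random.Generator) -> None:
        """Install the per-run random stream (no-op for deterministic rules)."""


class IdealObserver(ObserverModel):
    """Maximum-posterior rule: template = the noise-free central dot."""

    def __init__(self, spec: StimulusSpec, display: DisplaySpec, sigma2: float):
        if sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        self.sigma2 = sigma2
        # dot-only template; inducers cancel between hypotheses
        from .stimuli import NO_INDUCERS
        from dataclasses import replace
        dot_spec = replace(NO_INDUCERS, window_px=spec.window_px,
                           central_diameter_px=spec.central_diameter_px,
                           target_contrast=spec.target_contrast)
        dot = render_stimulus(dot_spec, display, present=True)
        self._template = dot.values
        self._mask = render_stimulus(spec, display, present=False).inducer_mask

    def set_template_scale(self, factor: float) -> None:
        """Match the template to the current staircase contrast scaling."""
        self._scale = factor

    _scale = 1.0

    def respond(self, observation: ContrastImage) -> bool:
        free = ~observation.inducer_mask
        s = self._template[free] * self._scale
        x = observation.values[free]
        return _log_likelihood_ratio(x, s, self.sigma2) > 0.0


class CSFIdealObserver(ObserverModel):
    """Ideal rule operating on CSF-filtered signal and templates.

    The noise-free stimulus (inducers included) is filtered through the CSF
    before unfiltered noise is added; decisions use the filtered dot-only
    template and subtract the filtered inducer background.
    """

    filters_stimulus = True

    def __init__(self, spec: StimulusSpec, display: DisplaySpec, sigma2: float,
                 csf: CSFSpec | None = None):
        if sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        self.sigma2 = sigma2
        self.csf = csf if csf is not None else default_csf()
        self.display = display
        self._mask = render_stimulus(spec, display, present=False).inducer_mask

        from .stimuli import NO_INDUCERS
        from dataclasses import replace
        dot_spec = replace(NO_INDUCERS, window_px=spec.window_px,
                           central_diameter_px=spec.central_diameter_px,
                           target_contrast=spec.target_contrast)
        dot = render_stimulus(dot_spec, display, present=True)
        background = render_stimulus(spec, display, present=False)
        self._filtered_dot = csf_filter(
            ContrastImage(dot.values), self.csf, display).values
        self._filtered_background = csf_filter(
            ContrastImage(background.values), self.csf, display).values

    _scale = 1.0

    def set_template_scale(self, factor: float) -> None:
        self._scale = factor

    def transform_stimulus(self, stimulus: ContrastImage) -> ContrastImage:
        filtered = csf_filter(ContrastImage(stimulus.values), self.csf,
                              self.display)
        return ContrastImage(filtered.values, stimulus.inducer_mask.copy())

    def respond(self, observation: ContrastImage) -> bool:
        free = ~observation.inducer_mask
        s = self._filtered_dot[free] * self._scale
        x = observation.values[free] - self._filtered_background[free]
        return _log_likelihood_ratio(x, s, self.sigma2) > 0.0


class TemplateObserver(ObserverModel):
    """Linear matcher with internal noise; the synthetic human stand-in."""

    def __init__(self, template: ContrastImage, internal_sigma2: float = 0.0,
                 criterion: float = 0.0,
                 rng: np.random.Generator | int | None = None):
        t = np.asarray(template.values, dtype=float)
        norm = math.sqrt(float(np.sum(t * t)))
        if norm == 0:
            raise ValueError("template must be non-zero")
        self.template = ContrastImage(t / norm, template.inducer_mask.copy())
        self.internal_sigma2 = float(internal_sigma2)
        self.criterion = float(criterion)
        self.rng = (rng if isinstance(rng, np.random.Generator)
                    else np.random.default_rng(rng))

    def reseed(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def respond(self, observation: ContrastImage) -> bool:
        return template_observer_decide(observation, self.template,
                                        self.internal_sigma2, self.criterion,
                                        self.rng)


def center_surround_template(spec: StimulusSpec, display: DisplaySpec,
                             surround_width_px: float = 12.0,
                             surround_gain: float = 0.5) -> ContrastImage:
    """Antagonistic template: negative central disk, positive annulus.

    Mimics the qualitative human strategy of weighing the dot region against
    the ring just outside it; normalized to unit energy.
    """
    n = spec.window_px
    cx, cy = window_center(n)
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(xx - cx, yy - cy)
    r_dot = spec.central_diameter_px / 2.0
    t = np.zeros((n, n), dtype=float)
    t[r <= r_dot] = -1.0
    ann = (r > r_dot) & (r <= r_dot + surround_width_px)
    t[ann] = surround_gain
    mask = render_stimulus(spec, display, present=False).inducer_mask
    t[mask] = 0.0
    t /= math.sqrt(float(np.sum(t * t)))
    return ContrastImage(t, mask)


def make_observer(kind: str, spec: StimulusSpec, display: DisplaySpec,
                  sigma2: float, *, csf: CSFSpec | None = None,
                  internal_sigma2: float | None = None,
                  criterion: float | None = None,
                  rng: np.random.Generator | int | None = None) -> ObserverModel:
    """Factory for the three observer kinds from plain configuration."""
    if kind == "ideal":
        return IdealObserver(spec, display, sigma2)
    if kind == "csf_ideal":
        return CSFIdealObserver(spec, display, sigma2, csf)
    if kind == "template":
        from .stimuli import truncated_variance_factor
        template = center_surround_template(spec, display)
        sigma_eff2 = sigma2 * truncated_variance_factor()
        if internal_sigma2 is None:
            internal_sigma2 = sigma_eff2  # roughly halves efficiency
        if criterion is None:
            # bias-free-ish default: ~0.67 sd of the decision variable
            from scipy.stats import norm
            sd = math.sqrt(sigma_eff2 + internal_sigma2)
            criterion = norm.ppf(0.75) * sd
        return TemplateObserver(template, internal_sigma2, criterion, rng)
    raise ValueError(f"unknown observer kind {kind!r}")
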