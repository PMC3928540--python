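"""Trial loop and threshold pipeline.

A 2-down/1-up staircase drives the contrast energy of the central dot while a
simulated observer performs the yes/no detection task in truncated Gaussian
pixel noise.  Thresholds are obtained by maximum-likelihood Weibull fits to
the staircase data, interpolated at 71% correct, with bootstrap standard
deviations; efficiency is the ratio of ideal to observer threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .archive import RunArchive, TrialRecord
from .observers import ObserverModel
from .stimuli import (ContrastImage, DisplaySpec, StimulusSpec,
                      pixel_area_deg2, render_stimulus,
                      truncated_variance_factor)

__all__ = [
    "TrialRecord",
    "StaircaseState",
    "PsychometricFit",
    "ThresholdEstimate",
    "run_staircase",
    "fit_weibull",
    "threshold_at",
    "bootstrap_threshold",
    "ideal_threshold_mc",
    "efficiency",
    "pilot_ideal_energy",
    "default_staircase",
    "FitError",
]

TARGET_PROPORTION = 0.71  # interpolation criterion; 2-down/1-up -> sqrt(.5)


class FitError(RuntimeError):
    """Psychometric fit failed or the data are degenerate."""


@dataclass
class StaircaseState:
    """2-down/1-up multiplicative staircase over contrast energy (deg^2)."""

    level: float
    step_down: float = 10.0 ** -0.1  # -1 dB after two consecutive correct
    step_up: float = 10.0 ** 0.1     # +1 dB after each error
    consecutive_correct: int = 0
    min_level: float = 1e-12
    max_level: float = math.inf

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise ValueError("staircase level must be > 0")
        if not (0 < self.step_down < 1 < self.step_up):
            raise ValueError("need step_down < 1 < step_up")

    def update(self, correct: bool) -> None:
        if correct:
            self.consecutive_correct += 1
            if self.consecutive_correct >= 2:
                self.level = max(self.level * self.step_down, self.min_level)
                self.consecutive_correct = 0
        else:
            self.consecutive_correct = 0
            self.level = min(self.level * self.step_up, self.max_level)


@dataclass(frozen=True)
class PsychometricFit:
    """Weibull accuracy curve P(E) = g + (1-g-l)(1 - exp(-(E/alpha)^beta))."""

    alpha: float
    beta: float
    gamma: float = 0.5
    lam: float = 0.01
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.gamma < 1 - self.lam <= 1):
            raise ValueError("need 0 <= gamma < 1 - lambda <= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")

    def __call__(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        return self.gamma + (1 - self.gamma - self.lam) * (
            1.0 - np.exp(-np.power(e / self.alpha, self.beta)))


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold: float       # deg^2 at the criterion proportion correct
    criterion: float = TARGET_PROPORTION
    sd: float = 0.0        # bootstrap standard deviation
    n_boot: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.sd < 0:
            raise ValueError("threshold must be > 0 and sd >= 0")


def pilot_ideal_energy(spec: StimulusSpec, display: DisplaySpec, sigma2: float,
                       proportion: float = math.sqrt(0.5)) -> float:
    """Closed-form ideal-observer energy threshold used to seed staircases.

    For the equal-prior yes/no ideal, proportion correct is Phi(d'/2) with
    d'^2 = ||s||^2 / sigma_eff^2, so the criterion energy is
    ``d'^2 * sigma_eff^2 * pixel_area`` (sigma_eff^2 accounts for the +-2 sd
    truncation of the displayed noise).
    """
    dprime = 2.0 * norm.ppf(proportion)
    sigma_eff2 = sigma2 * truncated_variance_factor()
    return dprime ** 2 * sigma_eff2 * pixel_area_deg2(display)


def default_staircase(spec: StimulusSpec, display: DisplaySpec,
                      sigma2: float, start_factor: float = 20.0) -> StaircaseState:
    """Staircase starting well above the analytic ideal pilot threshold."""
    return StaircaseState(level=start_factor
                          * pilot_ideal_energy(spec, display, sigma2))


def run_staircase(observer: ObserverModel, spec: StimulusSpec,
                  display: DisplaySpec, n_trials: int,
                  stair: StaircaseState | None = None,
                  seed: int | None = None, *, sigma2: float = 0.16,
                  store_fields: bool = False) -> RunArchive:
    """Simulate a staircase-controlled detection session.

    Per trial: draw present/absent with p = 0.5, scale the noise-free dot to
    the prevailing energy level, add truncated Gaussian noise outside the
    inducer disks, query the observer, score, and update the staircase (down
    one step after two consecutive correct, up one step after each error).
    All raw noise is archived (radial vectors and per-cell pixel sums always;
    full fields when ``store_fields``).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if stair is None:
        stair = default_staircase(spec, display, sigma2)
    else:
        stair = replace(stair)
    rng = np.random.default_rng(seed)
    observer.reseed(np.random.default_rng(rng.integers(2 ** 63)))

    base = render_stimulus(spec, display, present=True)
    background = render_stimulus(spec, display, present=False)
    mask = base.inducer_mask
    free = ~mask
    dot = base.values - background.values      # dot-only contrast pattern
    area = pixel_area_deg2(display)
    base_energy = float(np.sum(dot[free] ** 2)) * area
    if base_energy <= 0:
        raise ValueError("stimulus has no scalable contrast energy")

    # pre-filter the linear pieces once for observers with a front-end filter
    if observer.filters_stimulus:
        dot_t = observer.transform_stimulus(ContrastImage(dot, mask)).values
        bg_t = observer.transform_stimulus(
            ContrastImage(background.values, mask)).values
    else:
        dot_t, bg_t = dot, background.values

    sd = math.sqrt(sigma2)
    n = spec.window_px
    archive = RunArchive(spec.condition.value, n, sigma2, seed, mask,
                         store_fields=store_fields,
                         meta={"observer": type(observer).__name__})
    for t in range(n_trials):
        present = bool(rng.random() < 0.5)
        level = stair.level
        factor = math.sqrt(level / base_energy)
        if hasattr(observer, "set_template_scale"):
            observer.set_template_scale(factor)

        noise = np.zeros((n, n)) if sigma2 == 0 else rng.normal(0, sd, (n, n))
        if sigma2 > 0:
            bad = np.abs(noise) > 2 * sd
            while bad.any():
                noise[bad] = rng.normal(0, sd, int(bad.sum()))
                bad = np.abs(noise) > 2 * sd
            noise[mask] = 0.0

        stim_vals = bg_t + (factor * dot_t if present else 0.0)
        obs_vals = stim_vals + noise  # noise already zero on inducer pixels
        try:
            response = bool(observer.respond(ContrastImage(obs_vals, mask)))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"observer failed at trial {t}: {exc}") from exc
        correct = response == present
        archive.add_trial(
            TrialRecord(index=t, condition=spec.condition.value,
                        present=present, energy=level, noise_ref=t,
                        response=response, correct=correct),
            noise)
        stair.update(correct)
    return archive


# ---------------------------------------------------------------------------
# Psychometric fitting
# ---------------------------------------------------------------------------

def _binned(records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    energy = np.array([r.energy for r in records], dtype=float)
    correct = np.array([r.correct for r in records], dtype=bool)
    levels, inv = np.unique(energy, return_inverse=True)
    k = np.bincount(inv, weights=correct.astype(float), minlength=levels.size)
    m = np.bincount(inv, minlength=levels.size).astype(float)
    return levels, k, m


def fit_weibull(records, gamma: float = 0.5, lam: float = 0.01) -> PsychometricFit:
    """Maximum-likelihood Weibull fit to staircase data.

    Accuracy is pooled at the exact visited energy levels; ``gamma`` (guess
    rate) and ``lam`` (lapse rate) are held fixed and only the scale ``alpha``
    and shape ``beta`` are estimated.
    """
    levels, k, m = _binned(records)
    if levels.size < 2:
        raise FitError("need >= 2 distinct staircase levels")
    n_correct, n_total = k.sum(), m.sum()
    if n_correct == 0 or n_correct == n_total:
        raise FitError("degenerate data: all trials "
                       + ("correct" if n_correct else "incorrect"))

    span = 1 - gamma - lam
    log_levels = np.log(levels)

    def nll(params: np.ndarray) -> float:
        log_a, log_b = params
        beta = math.exp(log_b)
        expo = np.clip(beta * (log_levels - log_a), -700.0, 700.0)
        p = gamma + span * (1.0 - np.exp(-np.exp(expo)))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(p) + (m - k) * np.log1p(-p)))

    # start near the level whose pooled accuracy crosses the midpoint
    acc = k / m
    mid = gamma + span * (1 - math.exp(-1))
    idx = int(np.argmin(np.abs(acc - mid)))
    best = None
    for log_b0 in (math.log(0.8), math.log(1.5), math.log(3.0)):
        res = optimize.minimize(
            nll, x0=np.array([log_levels[idx], log_b0]),
            method="L-BFGS-B",
            bounds=[(log_levels.min() - 12.0, log_levels.max() + 12.0),
                    (math.log(0.05), math.log(50.0))])
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"Weibull fit did not converge: {best}")
    alpha, beta = math.exp(best.x[0]), math.exp(best.x[1])
    return PsychometricFit(alpha=alpha, beta=beta, gamma=gamma, lam=lam,
                           loglik=-best.fun)


def threshold_at(fit: PsychometricFit, criterion: float = TARGET_PROPORTION) -> float:
    """Energy at which the fitted curve reaches ``criterion`` (closed form)."""
    if not (fit.gamma < criterion < 1 - fit.lam):
        raise ValueError(
            f"criterion {criterion} outside ({fit.gamma}, {1 - fit.lam})")
    inner = (1 - fit.lam - criterion) / (1 - fit.gamma - fit.lam)
    return fit.alpha * (-math.log(inner)) ** (1.0 / fit.beta)


def bootstrap_threshold(records, n_boot: int = 500,
                        seed: int | None = None,
                        criterion: float = TARGET_PROPORTION,
                        max_failure_rate: float = 0.2) -> ThresholdEstimate:
    """Threshold with a bootstrap standard deviation over trial resamples."""
    fit = fit_weibull(records)
    point = threshold_at(fit, criterion)
    rng = np.random.default_rng(seed)
    records = list(records)
    n = len(records)
    values = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            rep = fit_weibull([records[i] for i in idx])
            values.append(threshold_at(rep, criterion))
        except (FitError, ValueError):
            failures += 1
    if n_boot and failures > max_failure_rate * n_boot:
        raise FitError(
            f"{failures}/{n_boot} bootstrap replicates failed to converge")
    sd = float(np.std(values)) if values else 0.0
    return ThresholdEstimate(threshold=point, criterion=criterion, sd=sd,
                             n_boot=n_boot)


def ideal_threshold_mc(spec: StimulusSpec, display: DisplaySpec,
                       sigma2: float = 0.16, n_trials: int = 10_000,
                       seed: int | None = None, n_boot: int = 500
                       ) -> tuple[ThresholdEstimate, RunArchive]:
    """Monte-Carlo ideal-observer threshold via the full staircase pipeline."""
    from .observers import IdealObserver
    observer = IdealObserver(spec, display, sigma2)
    archive = run_staircase(observer, spec, display, n_trials, seed=seed,
                            sigma2=sigma2)
    estimate = bootstrap_threshold(archive.records, n_boot=n_boot, seed=seed)
    return estimate, archive


def efficiency(ideal: ThresholdEstimate, observer: ThresholdEstimate) -> float:
    """Ratio of ideal to observer contrast-energy threshold."""
    if ideal.threshold <= 0 or observer.threshold <= 0:
        raise ValueError("thresholds must be > 0")
    return ideal.threshold / observer.threshold
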