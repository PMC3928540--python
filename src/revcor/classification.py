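"""Classification-image estimation and its 1-D reductions.

The classification image combines the mean raw noise field of the four
stimulus-response cells,

    C = (mean[absent, "present"] + mean[present, "present"])
        - (mean[absent, "absent"] + mean[present, "absent"]),

and is reduced to a 99-bin radial profile and to an annularly binned power
spectrum.  Bootstrap resampling of trials gives error bands; re-running the
sorting on freshly drawn noise gives the null ("random classification
image") band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .archive import CELLS, RunArchive, TrialRecord
from .radial import RadialBinning
from .stimuli import ContrastImage, DisplaySpec, pixels_to_degrees

__all__ = [
    "ClassificationImage",
    "RadialProfile",
    "SpectralProfile",
    "ProfileBand",
    "classification_image",
    "smooth_image",
    "infill_inducers",
    "radial_average",
    "radial_classification_profile",
    "spectral_profile",
    "peak_frequency",
    "bootstrap_profiles",
    "null_band",
    "EmptyCellError",
]


class EmptyCellError(ValueError):
    """A stimulus-response cell holds no trials."""


@dataclass
class ClassificationImage:
    weights: np.ndarray
    cell_counts: dict
    condition: str = ""
    inducer_mask: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return sum(self.cell_counts.values())


@dataclass
class RadialProfile:
    radii: np.ndarray   # pixel distances 1..99 from the window center
    values: np.ndarray  # mean noise-contrast weight per annulus

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii.shape != self.values.shape:
            raise ValueError("radii/values length mismatch")


@dataclass
class SpectralProfile:
    frequencies: np.ndarray  # cycles/degree, bin centers, 0..Nyquist
    values: np.ndarray       # mean squared (unitary) Fourier amplitude
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("squared amplitudes must be >= 0")


@dataclass
class ProfileBand:
    x: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    kind: str  # "bootstrap" | "null"

    @property
    def lower(self) -> np.ndarray:
        return self.mean - 2.0 * self.sd

    @property
    def upper(self) -> np.ndarray:
        return self.mean + 2.0 * self.sd


# ---------------------------------------------------------------------------
# Eq-style cell combination
# ---------------------------------------------------------------------------

def _cell_indices(records) -> dict:
    cells: dict = {c: [] for c in CELLS}
    for i, r in enumerate(records):
        cells[(r.present, r.response)].append(i)
    for cell, idx in cells.items():
        if not idx:
            s = "present" if cell[0] else "absent"
            r = "present" if cell[1] else "absent"
            raise EmptyCellError(
                f"no trials in stimulus-{s} / response-{r} cell")
    return cells


def _combine(cell_means: dict) -> np.ndarray:
    return ((cell_means[(False, True)] + cell_means[(True, True)])
            - (cell_means[(False, False)] + cell_means[(True, False)]))


def classification_image(records, noise_archive: RunArchive) -> ClassificationImage:
    """Combine per-cell mean raw noise fields into a classification image.

    Only the noise enters the estimate (the signal is never added back).
    When ``records`` is exactly the archive's own trial list the accumulated
    per-cell sums are used; otherwise the full noise fields are required.
    """
    cells = _cell_indices(records)
    own = (len(records) == noise_archive.n_trials and all(
        a is b or a == b for a, b in zip(records, noise_archive.records)))
    means = {}
    if own:
        for cell in CELLS:
            means[cell] = (noise_archive.cell_sums[cell]
                           / noise_archive.cell_counts[cell])
    else:
        for cell, idx in cells.items():
            acc = np.zeros((noise_archive.window_px, noise_archive.window_px))
            for i in idx:
                acc += noise_archive.noise_field(records[i].noise_ref)
            means[cell] = acc / len(idx)
    return ClassificationImage(
        weights=_combine(means),
        cell_counts={c: len(cells[c]) for c in CELLS},
        condition=noise_archive.condition,
        inducer_mask=noise_archive.inducer_mask.copy())


def smooth_image(image: ClassificationImage | np.ndarray,
                 kernel_px: int = 7):
    """Uniform odd-sized box smoothing with renormalized partial edge kernels."""
    if kernel_px % 2 != 1 or kernel_px < 1:
        raise ValueError("kernel must be odd-sized")
    from scipy.ndimage import uniform_filter
    arr = image.weights if isinstance(image, ClassificationImage) else image
    arr = np.asarray(arr, dtype=float)
    num = uniform_filter(arr, size=kernel_px, mode="constant", cval=0.0)
    den = uniform_filter(np.ones_like(arr), size=kernel_px, mode="constant",
                         cval=0.0)
    out = num / den
    if isinstance(image, ClassificationImage):
        return ClassificationImage(out, dict(image.cell_counts),
                                   image.condition,
                                   None if image.inducer_mask is None
                                   else image.inducer_mask.copy())
    return out


def infill_inducers(image: ClassificationImage,
                    rng: np.random.Generator | int | None = None
                    ) -> ClassificationImage:
    """Replace inducer-region weights with matched random samples (display only).

    The masked pixels are populated with Gaussian draws matched to the mean
    and sd of the unmasked weights so the display blends into its background;
    analysis operations never consume the in-filled image.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = image.weights.copy()
    mask = image.inducer_mask
    if mask is not None and mask.any():
        free = out[~mask]
        out[mask] = gen.normal(float(free.mean()), float(free.std()),
                               int(mask.sum()))
    return ClassificationImage(out, dict(image.cell_counts), image.condition,
                               None if mask is None else mask.copy())


# ---------------------------------------------------------------------------
# Radial reduction
# ---------------------------------------------------------------------------

def radial_average(image: ClassificationImage | np.ndarray,
                   inducer_mask: np.ndarray | None = None,
                   n_bins: int = 99) -> RadialProfile:
    """Mean weight per integer-rounded distance from the window center.

    Bins run 1..``n_bins``; inducer pixels are excluded from the averages.
    """
    if isinstance(image, ClassificationImage):
        if inducer_mask is None:
            inducer_mask = image.inducer_mask
        arr = image.weights
    else:
        arr = np.asarray(image, dtype=float)
    binning = RadialBinning(arr.shape[0], inducer_mask, n_bins)
    return RadialProfile(binning.radii.copy(), binning.mean(arr))


def radial_classification_profile(records, noise_archive: RunArchive
                                  ) -> RadialProfile:
    """Radial profile of the classification image via per-trial radial vectors.

    Exactly equals ``radial_average(classification_image(...))`` by linearity
    of the annular means, but needs only the archived 99-vectors.
    """
    cells = _cell_indices(records)
    rv = noise_archive.radial_vectors
    refs = np.array([r.noise_ref for r in records])
    means = {cell: rv[refs[idx]].mean(axis=0) for cell, idx in cells.items()}
    return RadialProfile(noise_archive.binning.radii.copy(), _combine(means))


# ---------------------------------------------------------------------------
# Spectral reduction
# ---------------------------------------------------------------------------

def spectral_profile(image: ClassificationImage | np.ndarray,
                     display: DisplaySpec) -> SpectralProfile:
    """Annularly binned power spectrum of a (square) classification image.

    The 2-D FFT (unitary normalization) is squared and averaged over annuli
    one DFT sample wide; the axis is converted to cycles/degree via the pixel
    pitch and reported from 0 to the Nyquist frequency.
    """
    arr = (image.weights if isinstance(image, ClassificationImage)
           else np.asarray(image, dtype=float))
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("spectral profile requires a square image")
    n = arr.shape[0]
    power = np.abs(np.fft.fft2(arr, norm="ortho")) ** 2
    ix = np.fft.fftfreq(n) * n  # signed sample indices
    r = np.rint(np.hypot(ix[None, :], ix[:, None])).astype(int)
    n_keep = n // 2 + 1
    keep = r < n_keep
    sums = np.bincount(r[keep], weights=power[keep], minlength=n_keep)
    counts = np.bincount(r[keep], minlength=n_keep)
    pitch = pixels_to_degrees(1.0, display)
    freqs = np.arange(n_keep) / (n * pitch)
    return SpectralProfile(freqs, sums / counts, counts)


def peak_frequency(profile: SpectralProfile, exclude_dc: bool = True) -> float:
    """Frequency of the maximal spectral bin; errors on an exact tie."""
    vals = np.asarray(profile.values, dtype=float)
    freqs = np.asarray(profile.frequencies, dtype=float)
    if vals.size == 0:
        raise ValueError("empty profile")
    if exclude_dc:
        vals, freqs = vals[1:], freqs[1:]
    peak = vals.max()
    winners = np.flatnonzero(vals == peak)
    if winners.size > 1:
        raise ValueError(f"{winners.size} bins tie at the maximum")
    return float(freqs[winners[0]])


# ---------------------------------------------------------------------------
# Resampling bands
# ---------------------------------------------------------------------------

def _smooth_1d(curve: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return curve
    kernel = np.ones(width)
    num = np.convolve(curve, kernel, mode="same")
    den = np.convolve(np.ones_like(curve), kernel, mode="same")
    return num / den


def bootstrap_profiles(records, noise_archive: RunArchive, n: int = 500,
                       smooth_1d: int = 5,
                       seed: int | None = None) -> ProfileBand:
    """Mean +- 2 sd band of smoothed radial profiles over trial resamples."""
    # validate the full-data pipeline before resampling
    radial_classification_profile(records, noise_archive)
    rng = np.random.default_rng(seed)
    records = list(records)
    rv = noise_archive.radial_vectors
    refs = np.array([r.noise_ref for r in records])
    present = np.array([r.present for r in records])
    response = np.array([r.response for r in records])
    n_rec = len(records)
    reps = []
    while len(reps) < n:
        idx = rng.integers(0, n_rec, size=n_rec)
        p, q = present[idx], response[idx]
        try:
            means = {}
            for cell in CELLS:
                sel = (p == cell[0]) & (q == cell[1])
                if not sel.any():
                    raise EmptyCellError("resample emptied a cell")
                means[cell] = rv[refs[idx][sel]].mean(axis=0)
        except EmptyCellError:
            continue
        reps.append(_smooth_1d(_combine(means), smooth_1d))
    reps = np.asarray(reps)
    return ProfileBand(noise_archive.binning.radii.copy(),
                       reps.mean(axis=0), reps.std(axis=0), n, "bootstrap")


def null_band(records, noise_archive: RunArchive, n: int = 200,
              seed: int | None = None, batch: int = 256) -> ProfileBand:
    """Random-classification-image band: fixed labels, freshly drawn noise.

    For each replicate the entire session's noise is replaced by new
    truncated Gaussian fields while the stimulus-response sorting is kept,
    and the radial classification profile is recomputed.  The resulting mean
    is ~0 everywhere; +-2 sd delimits chance-level structure.
    """
    cells = _cell_indices(records)
    rng = np.random.default_rng(seed)
    binning = noise_archive.binning
    sd = math.sqrt(noise_archive.sigma2)
    n_valid = binning.n_valid
    n_rec = len(records)
    cell_of = np.empty(n_rec, dtype=int)
    for ci, cell in enumerate(CELLS):
        cell_of[list(cells[cell])] = ci
    sign = np.array([1.0, 1.0, -1.0, -1.0])
    weight = sign / np.array([len(cells[c]) for c in CELLS], dtype=float)

    reps = np.empty((n, binning.n_bins))
    for rep in range(n):
        acc = np.zeros(binning.n_bins)
        for start in range(0, n_rec, batch):
            b = min(batch, n_rec - start)
            # i.i.d. draws: generate directly in bin-sorted order (float32
            # for speed; the band is a Monte-Carlo summary, not an oracle)
            noise = rng.standard_normal((b, n_valid), dtype=np.float32)
            if sd > 0:
                bad = np.abs(noise) > 2.0
                while bad.any():
                    noise[bad] = rng.standard_normal(int(bad.sum()),
                                                     dtype=np.float32)
                    bad = np.abs(noise) > 2.0
            radial = binning.mean_of_sorted(noise) * sd  # (b, n_bins)
            acc += weight[cell_of[start:start + b]] @ radial
        reps[rep] = acc
    return ProfileBand(binning.radii.copy(), reps.mean(axis=0),
                       reps.std(axis=0), n, "null")
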