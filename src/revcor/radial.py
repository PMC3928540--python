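"""Annular (radial) binning of square analysis windows.

Distances are measured from the geometric window center ``((N-1)/2, (N-1)/2)``
in 0-based pixel coordinates and rounded to the nearest integer; bins run from
1 to ``n_bins`` (99 on the default 200-px window), excluding the sub-pixel
center bin and everything beyond bin ``n_bins``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RadialBinning", "N_BINS_DEFAULT"]

N_BINS_DEFAULT = 99


class EmptyBinError(ValueError):
    """A radial bin contains no usable pixel."""


class RadialBinning:
    """Precomputed pixel-to-annulus assignment for one window geometry.

    Parameters
    ----------
    window_px : side of the square window.
    mask : optional boolean array of pixels to exclude (e.g. inducer disks).
    n_bins : number of annuli; bin ``b`` collects pixels whose center
        distance rounds to ``b``.
    """

    def __init__(self, window_px: int, mask: np.ndarray | None = None,
                 n_bins: int = N_BINS_DEFAULT):
        self.window_px = int(window_px)
        self.n_bins = int(n_bins)
        c = (window_px - 1) / 2.0
        yy, xx = np.mgrid[0:window_px, 0:window_px]
        dist = np.hypot(xx - c, yy - c)
        bins = np.rint(dist).astype(np.int64)
        valid = (bins >= 1) & (bins <= n_bins)
        if mask is not None:
            valid &= ~np.asarray(mask, dtype=bool)
        self.valid = valid
        flat_bins = bins[valid]
        self.counts = np.bincount(flat_bins, minlength=n_bins + 1)[1:]
        if (self.counts == 0).any():
            empty = int(np.flatnonzero(self.counts == 0)[0]) + 1
            raise EmptyBinError(f"radial bin {empty} contains no pixels")
        # stable ordering of valid pixels by bin, for batched reduction
        order = np.argsort(flat_bins, kind="stable")
        self._order = order
        self._boundaries = np.searchsorted(flat_bins[order],
                                           np.arange(1, n_bins + 1))
        self._flat_valid = np.flatnonzero(valid.ravel())
        self.radii = np.arange(1, n_bins + 1)

    @property
    def n_valid(self) -> int:
        return self._flat_valid.size

    def mean(self, image: np.ndarray) -> np.ndarray:
        """Per-annulus mean of a 2-D image (length ``n_bins`` vector)."""
        flat = np.asarray(image, dtype=float).ravel()[self._flat_valid]
        return self.mean_of_valid(flat)

    def mean_of_valid(self, flat_valid: np.ndarray) -> np.ndarray:
        """Per-annulus mean from pre-extracted valid-pixel values."""
        sums = np.add.reduceat(flat_valid[..., self._order], self._boundaries,
                               axis=-1)
        return sums / self.counts

    def mean_of_sorted(self, sorted_vals: np.ndarray) -> np.ndarray:
        """Per-annulus mean of values already laid out in bin-sorted order.

        Only valid for exchangeable (i.i.d.) draws, where the canonical
        pixel order is irrelevant; skips the permutation gather.
        """
        sums = np.add.reduceat(sorted_vals, self._boundaries, axis=-1)
        return sums / self.counts

    def extract_valid(self, image: np.ndarray) -> np.ndarray:
        """Valid-pixel values of a 2-D image, in canonical flat order."""
        return np.asarray(image, dtype=float).ravel()[self._flat_valid]
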