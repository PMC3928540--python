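"""Hotelling T-squared tests on per-trial radial noise vectors.

Each trial contributes a 99-dimensional radial average of its raw noise
field, signed by the response (+1 "present", -1 "absent").  The one-sample
test probes whether the mean vector — proportional to the radial
classification image — differs from zero; the two-sample test compares
conditions.  Both are converted to exact F statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .archive import RunArchive

__all__ = [
    "HotellingResult",
    "trial_vectors",
    "hotelling_one_sample",
    "hotelling_two_sample",
    "format_p",
    "SingularCovarianceError",
]

_COND_LIMIT = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Sample covariance is (numerically) singular."""


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f: float
    df1: int
    df2: int
    p: float

    def __post_init__(self) -> None:
        if self.t2 < 0 or self.f < 0:
            raise ValueError("T^2 and F must be >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def format_p(p: float, floor: float = 1e-4) -> str:
    """Table-style p-value string ("<0.0001" below the print floor)."""
    return f"<{floor:g}" if p < floor else f"{p:.4g}"


def trial_vectors(records, noise_archive: RunArchive) -> np.ndarray:
    """Response-signed per-trial radial noise vectors, shape (n, 99).

    With equal-sized stimulus-response cells the sample mean equals 1/4 of
    the radial classification profile (exact algebraic identity).
    """
    rv = noise_archive.radial_vectors
    refs = np.array([r.noise_ref for r in records])
    signs = np.array([1.0 if r.response else -1.0 for r in records])
    return rv[refs] * signs[:, None]


def _solve_spd(S: np.ndarray, d: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise SingularCovarianceError(
            f"covariance condition number {cond:.3g} exceeds {_COND_LIMIT:.0e}; "
            "collect more trials or merge radial bins")
    from scipy.linalg import cho_factor, cho_solve
    try:
        return cho_solve(cho_factor(S), d)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise SingularCovarianceError(str(exc)) from exc


def hotelling_one_sample(V: np.ndarray) -> HotellingResult:
    """One-sample T^2 of the mean vector against zero.

    ``T^2 = n xbar' S^-1 xbar``; ``F = T^2 (n - p) / (p (n - 1))`` on
    ``(p, n - p)`` degrees of freedom.
    """
    V = np.asarray(V, dtype=float)
    n, p = V.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    xbar = V.mean(axis=0)
    S = np.atleast_2d(np.cov(V, rowvar=False, ddof=1))
    t2 = float(n * xbar @ _solve_spd(S, xbar))
    df1, df2 = p, n - p
    f = t2 * df2 / (p * (n - 1))
    return HotellingResult(t2=t2, f=f, df1=df1, df2=df2,
                           p=float(f_dist.sf(f, df1, df2)))


def hotelling_two_sample(V1: np.ndarray, V2: np.ndarray) -> HotellingResult:
    """Independent two-sample T^2 for a difference of mean vectors.

    ``T^2 = (n1 n2 / (n1 + n2)) d' Sp^-1 d`` with pooled covariance ``Sp``;
    ``F = T^2 (n1 + n2 - p - 1) / (p (n1 + n2 - 2))`` on
    ``(p, n1 + n2 - p - 1)`` degrees of freedom.
    """
    V1 = np.asarray(V1, dtype=float)
    V2 = np.asarray(V2, dtype=float)
    if V1.shape[1] != V2.shape[1]:
        raise ValueError("dimension mismatch between samples")
    n1, p = V1.shape
    n2 = V2.shape[0]
    if n1 + n2 <= p + 1:
        raise ValueError(f"need n1 + n2 > p + 1 (got {n1}+{n2}, p={p})")
    d = V1.mean(axis=0) - V2.mean(axis=0)
    S1 = np.atleast_2d(np.cov(V1, rowvar=False, ddof=1))
    S2 = np.atleast_2d(np.cov(V2, rowvar=False, ddof=1))
    Sp = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    t2 = float(n1 * n2 / (n1 + n2) * d @ _solve_spd(Sp, d))
    df1, df2 = p, n1 + n2 - p - 1
    f = t2 * df2 / (p * (n1 + n2 - 2))
    return HotellingResult(t2=t2, f=f, df1=df1, df2=df2,
                           p=float(f_dist.sf(f, df1, df2)))
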