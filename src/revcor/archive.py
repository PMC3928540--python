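"""Trial records and the per-run noise archive.

A :class:`RunArchive` holds everything a downstream analysis needs from one
simulated session: the trial log, the per-trial radial noise vectors, running
per-pixel noise sums for each stimulus-response cell, and (optionally) the
full noise fields.  Archives round-trip through HDF5 (arrays) plus CSV (trial
log).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .radial import N_BINS_DEFAULT, RadialBinning

__all__ = ["TrialRecord", "RunArchive", "CELLS"]

# (stimulus present, response present) keys in Eq-style order
CELLS = ((False, True), (True, True), (False, False), (True, False))


@dataclass(frozen=True)
class TrialRecord:
    """One detection trial of a simulated session."""

    index: int
    condition: str
    present: bool
    energy: float  # prevailing staircase level (deg^2), also on absent trials
    noise_ref: int
    response: bool
    correct: bool

    def __post_init__(self) -> None:
        if self.correct != (self.response == self.present):
            raise ValueError("correct flag inconsistent with present/response")


class MissingNoiseError(RuntimeError):
    """Full noise fields were requested but not stored in this archive."""


class RunArchive:
    """Accumulating store for one simulated run."""

    def __init__(self, condition: str, window_px: int, sigma2: float,
                 seed: int | None, inducer_mask: np.ndarray,
                 store_fields: bool = False,
                 n_bins: int = N_BINS_DEFAULT,
                 meta: dict | None = None):
        self.condition = condition
        self.window_px = int(window_px)
        self.sigma2 = float(sigma2)
        self.seed = seed
        self.inducer_mask = np.asarray(inducer_mask, dtype=bool)
        self.store_fields = bool(store_fields)
        self.meta = dict(meta or {})
        self.binning = RadialBinning(window_px, self.inducer_mask, n_bins)
        self.records: list[TrialRecord] = []
        self._radial: list[np.ndarray] = []
        self._fields: list[np.ndarray] = []
        self.cell_sums = {c: np.zeros((window_px, window_px)) for c in CELLS}
        self.cell_counts = {c: 0 for c in CELLS}

    # -- accumulation -------------------------------------------------------

    def add_trial(self, record: TrialRecord, noise_values: np.ndarray) -> None:
        self.records.append(record)
        self._radial.append(self.binning.mean(noise_values))
        cell = (record.present, record.response)
        self.cell_sums[cell] += noise_values
        self.cell_counts[cell] += 1
        if self.store_fields:
            self._fields.append(np.array(noise_values, dtype=float))

    # -- views --------------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return len(self.records)

    @property
    def radial_vectors(self) -> np.ndarray:
        """(n_trials, n_bins) per-trial radial means of the raw noise."""
        return np.asarray(self._radial)

    @property
    def has_fields(self) -> bool:
        return bool(self._fields) or (self.store_fields and self.n_trials == 0)

    def noise_field(self, noise_ref: int) -> np.ndarray:
        if not self._fields:
            raise MissingNoiseError(
                "this archive does not store full noise fields; re-run with "
                "store_fields=True (radial analyses remain available)")
        return np.asarray(self._fields[noise_ref], dtype=float)

    def records_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.records])
        if not df.empty and self.seed is not None:
            df["seed"] = self.seed
        return df

    # -- persistence --------------------------------------------------------

    def save(self, h5_path: str | Path, csv_path: str | Path | None = None) -> None:
        import h5py
        h5_path = Path(h5_path)
        h5_path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(h5_path, "w") as f:
            f.attrs["condition"] = self.condition
            f.attrs["window_px"] = self.window_px
            f.attrs["sigma2"] = self.sigma2
            f.attrs["seed"] = -1 if self.seed is None else int(self.seed)
            f.attrs["store_fields"] = self.store_fields
            for k, v in self.meta.items():
                f.attrs[f"meta_{k}"] = v
            f.create_dataset("inducer_mask", data=self.inducer_mask)
            f.create_dataset("radial_vectors", data=self.radial_vectors)
            for i, cell in enumerate(CELLS):
                g = f.create_group(f"cell_{i}")
                g.attrs["present"] = cell[0]
                g.attrs["response"] = cell[1]
                g.attrs["count"] = self.cell_counts[cell]
                g.create_dataset("sum", data=self.cell_sums[cell])
            if self._fields:
                f.create_dataset("noise_fields",
                                 data=np.stack(self._fields),
                                 compression="gzip", compression_opts=1)
            rec = self.records_dataframe()
            if not rec.empty:
                f.create_dataset("trials/index", data=rec["index"].to_numpy())
                f.create_dataset("trials/present",
                                 data=rec["present"].to_numpy(bool))
                f.create_dataset("trials/energy", data=rec["energy"].to_numpy())
                f.create_dataset("trials/noise_ref",
                                 data=rec["noise_ref"].to_numpy())
                f.create_dataset("trials/response",
                                 data=rec["response"].to_numpy(bool))
        if csv_path is not None:
            self.records_dataframe().to_csv(csv_path, index=False)

    @classmethod
    def load(cls, h5_path: str | Path) -> "RunArchive":
        import h5py
        with h5py.File(h5_path, "r") as f:
            seed = int(f.attrs["seed"])
            arch = cls(condition=str(f.attrs["condition"]),
                       window_px=int(f.attrs["window_px"]),
                       sigma2=float(f.attrs["sigma2"]),
                       seed=None if seed == -1 else seed,
                       inducer_mask=f["inducer_mask"][...],
                       store_fields=bool(f.attrs["store_fields"]),
                       meta={k[5:]: f.attrs[k] for k in f.attrs
                             if k.startswith("meta_")})
            radial = f["radial_vectors"][...]
            for i, cell in enumerate(CELLS):
                g = f[f"cell_{i}"]
                arch.cell_sums[cell] = g["sum"][...]
                arch.cell_counts[cell] = int(g.attrs["count"])
            fields = (f["noise_fields"][...] if "noise_fields" in f else None)
            if "trials/index" in f:
                idx = f["trials/index"][...]
                present = f["trials/present"][...]
                energy = f["trials/energy"][...]
                noise_ref = f["trials/noise_ref"][...]
                response = f["trials/response"][...]
                for j in range(idx.size):
                    arch.records.append(TrialRecord(
                        index=int(idx[j]), condition=arch.condition,
                        present=bool(present[j]), energy=float(energy[j]),
                        noise_ref=int(noise_ref[j]),
                        response=bool(response[j]),
                        correct=bool(present[j]) == bool(response[j])))
        arch._radial = [radial[j] for j in range(radial.shape[0])]
        if fields is not None:
            arch._fields = [fields[j] for j in range(fields.shape[0])]
        return arch
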