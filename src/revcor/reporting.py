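"""Assemble figures and tables from analyzed run archives.

Produces a deterministic file set (CSV + PNG + JSON metadata): threshold and
efficiency tables, raw/smoothed classification-image panels, radial profiles
with +-2 sd bands and a dot-edge marker, spectral profiles, and Hotelling
test tables.  Plotting never recomputes numbers — every figure is drawn from
the CSVs it sits next to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .archive import RunArchive
from .classification import (ProfileBand, bootstrap_profiles,
                             classification_image, infill_inducers,
                             radial_classification_profile, smooth_image,
                             spectral_profile, null_band)
from .experiment import bootstrap_threshold, efficiency
from .hotelling import format_p, hotelling_one_sample, trial_vectors
from .stimuli import DisplaySpec

__all__ = ["ReportBundle", "build_report"]


@dataclass
class ReportBundle:
    out_dir: Path
    files: list[str]


class MissingAnalysisError(RuntimeError):
    pass


def _dot_edge_radius_px(archive: RunArchive) -> float:
    return 45.0 / 2.0 if archive.window_px == 200 else archive.window_px * 0.1125


def build_report(runs: dict[str, RunArchive], out_dir: str | Path,
                 display: DisplaySpec | None = None, n_boot: int = 500,
                 n_null: int = 200, seed: int = 0) -> ReportBundle:
    """Build the full report for named run archives.

    ``runs`` maps a label (e.g. ``"ideal_small"``) to its archive.  The
    efficiency table is only emitted when an ideal run and at least one
    non-ideal run share a condition.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not runs:
        raise MissingAnalysisError("no run archives supplied")
    display = display or DisplaySpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    # -- thresholds ---------------------------------------------------------
    rows = []
    estimates = {}
    for label, arch in runs.items():
        est = bootstrap_threshold(arch.records, n_boot=n_boot, seed=seed)
        estimates[label] = est
        rows.append({"run": label, "condition": arch.condition,
                     "observer": arch.meta.get("observer_kind",
                                               arch.meta.get("observer", "?")),
                     "threshold_deg2": est.threshold, "boot_sd": est.sd,
                     "n_boot": est.n_boot, "n_trials": arch.n_trials})
    thresholds = pd.DataFrame(rows)
    thresholds.to_csv(out / "thresholds.csv", index=False)
    files.append("thresholds.csv")

    # -- efficiency (needs an ideal reference per condition) ----------------
    eff_rows = []
    for label, arch in runs.items():
        kind = str(arch.meta.get("observer_kind", ""))
        if kind == "ideal":
            continue
        for ref_label, ref in runs.items():
            if (str(ref.meta.get("observer_kind", "")) == "ideal"
                    and ref.condition == arch.condition):
                eff_rows.append({
                    "run": label, "condition": arch.condition,
                    "ideal_run": ref_label,
                    "efficiency": efficiency(estimates[ref_label],
                                             estimates[label])})
    if eff_rows:
        pd.DataFrame(eff_rows).to_csv(out / "efficiency.csv", index=False)
        files.append("efficiency.csv")

    # -- per-run panels -----------------------------------------------------
    hot_rows = []
    for label, arch in runs.items():
        ci = classification_image(arch.records, arch)
        shown = infill_inducers(ci, rng=np.random.default_rng(seed))
        smoothed = infill_inducers(smooth_image(ci),
                                   rng=np.random.default_rng(seed))
        vmax = max(np.abs(shown.weights).max(),
                   np.abs(smoothed.weights).max()) or 1.0
        fig, axes = plt.subplots(1, 2, figsize=(8, 4))
        for ax, img, title in zip(axes, (shown, smoothed), ("raw", "smoothed")):
            ax.imshow(img.weights, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            ax.set_title(f"{label} ({title})")
            ax.axis("off")
        fig.savefig(out / f"cimage_{label}.png", dpi=120)
        plt.close(fig)
        files.append(f"cimage_{label}.png")

        profile = radial_classification_profile(arch.records, arch)
        boot = bootstrap_profiles(arch.records, arch, n=n_boot, seed=seed)
        null = null_band(arch.records, arch, n=n_null, seed=seed)
        pd.DataFrame({"radius_px": profile.radii, "value": profile.values,
                      "boot_mean": boot.mean, "boot_sd": boot.sd,
                      "null_mean": null.mean, "null_sd": null.sd}
                     ).to_csv(out / f"radial_{label}.csv", index=False)
        files.append(f"radial_{label}.csv")
        _plot_radial(plt, out / f"radial_{label}.png", label, profile, boot,
                     null, _dot_edge_radius_px(arch))
        files.append(f"radial_{label}.png")

        spec = spectral_profile(ci, display)
        pd.DataFrame({"freq_cdeg": spec.frequencies, "value": spec.values}
                     ).to_csv(out / f"spectrum_{label}.csv", index=False)
        files.append(f"spectrum_{label}.csv")

        res = hotelling_one_sample(trial_vectors(arch.records, arch))
        hot_rows.append({"run": label, "df1": res.df1, "df2": res.df2,
                         "F": res.f, "p": format_p(res.p)})

    pd.DataFrame(hot_rows).to_csv(out / "hotelling_one_sample.csv", index=False)
    files.append("hotelling_one_sample.csv")

    meta = {"runs": {label: {"n_trials": a.n_trials, "seed": a.seed,
                             "condition": a.condition,
                             "sigma2": a.sigma2} for label, a in runs.items()},
            "n_boot": n_boot, "n_null": n_null, "report_seed": seed}
    with open(out / "report.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    files.append("report.json")
    return ReportBundle(out, files)


def _plot_radial(plt, path: Path, label: str, profile, boot: ProfileBand,
                 null: ProfileBand, dot_edge_px: float) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(null.x, null.lower, null.upper, color="0.8",
                    label="null +-2 sd")
    ax.fill_between(boot.x, boot.lower, boot.upper, alpha=0.4,
                    label="bootstrap +-2 sd")
    ax.plot(profile.radii, profile.values, ".", ms=3, label="raw profile")
    ax.plot(boot.x, boot.mean, "-", lw=1.2, label="smoothed mean")
    ax.axvline(dot_edge_px, ls="--", color="k", lw=1)
    ax.set_xlabel("distance from center (px)")
    ax.set_ylabel("mean noise weight")
    ax.set_title(label)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
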