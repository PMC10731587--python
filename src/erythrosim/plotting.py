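"""Optional static plots: Hb spaghetti with mean band, and per-VP dose/Hb
dual panels.  Plotting is never load-bearing; all figures are written to
files (no interactive backend required)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .trials import TrialResult


def plot_hb_spaghetti(result: TrialResult, path, title: str = "") -> None:
    """Per-VP Hb trajectories with the population mean +/- SD band."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for vid, g in result.hb_traces.groupby("vp_id"):
        ax.plot(g["week"], g["hb"], color="steelblue", alpha=0.35, lw=0.8)
    stats = result.hb_traces.groupby("week")["hb"].agg(["mean", "std"])
    ax.plot(stats.index, stats["mean"], color="navy", lw=2, label="mean")
    ax.fill_between(stats.index, stats["mean"] - stats["std"],
                    stats["mean"] + stats["std"], color="navy", alpha=0.15)
    lo, hi = result.protocol.target_band
    ax.axhspan(lo, hi, color="green", alpha=0.08, label="target band")
    ax.set_xlabel("week")
    ax.set_ylabel("Hb (g/dL)")
    ax.set_title(title or result.protocol.name)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vp_dose_hb(result: TrialResult, vp_id: str, path) -> None:
    """Dose-adaptation panel for one VP: Hb trajectory above, administered
    dose staircase below (the per-patient titration view)."""
    hb = result.hb_traces[result.hb_traces.vp_id == vp_id]
    a = result.assessments[result.assessments.vp_id == vp_id]
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 5), sharex=True,
                                   height_ratios=[2, 1])
    ax1.plot(hb["week"], hb["hb"], color="navy")
    lo, hi = result.protocol.target_band
    ax1.axhspan(lo, hi, color="green", alpha=0.08)
    ax1.axhline(result.protocol.hold_threshold, color="red", ls="--", lw=0.8)
    ax1.set_ylabel("Hb (g/dL)")
    ax1.set_title(vp_id)
    ax2.step(a["week"], a["dose_after"], where="post", color="darkorange")
    for _, row in a[a.action != "maintain"].iterrows():
        ax2.annotate(row["action"], (row["week"], row["dose_after"]),
                     fontsize=6, rotation=45)
    ax2.set_xlabel("week")
    ax2.set_ylabel(f"dose ({result.drug.dose_unit})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
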