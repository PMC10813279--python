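"""Plotting helpers (r-charts and reference-curve overlays)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "circalight"  # deterministic SVG ids
import matplotlib.pyplot as plt
import numpy as np


def _save(fig, path):
    # strip the embedded creation date so identical runs are byte-identical
    if str(path).endswith(".svg"):
        fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path)

from .association import RChart
from .light_hygiene import ReferenceCurve


def plot_rchart(rchart: RChart, path, title: str | None = None) -> None:
    """Render an r-chart: r per bin, significance markers, fitted cosine."""
    fig, ax = plt.subplots(figsize=(8, 4))
    b = rchart.bins
    ax.plot(b["mid_hour"], b["r"], "-o", ms=3, color="tab:blue", label="r per 30-min bin")
    raw = b["significant_raw"] & ~b["significant_fdr"]
    ax.plot(b.loc[raw, "mid_hour"], b.loc[raw, "r"], "o", ms=6, mfc="none",
            color="tab:orange", label="p < 0.05")
    fdr = b["significant_fdr"]
    ax.plot(b.loc[fdr, "mid_hour"], b.loc[fdr, "r"], "o", ms=6, color="tab:red",
            label=f"BH-FDR q = {rchart.q}")
    if rchart.cosinor_of_r is not None:
        t = np.linspace(0, 24, 481)
        c = rchart.cosinor_of_r
        fit = c.mesor + c.amplitude * np.cos(2 * np.pi * (t - c.acrophase) / c.period)
        ax.plot(t, fit, "--", color="gray",
                label=f"cosinor of r(t), acrophase {c.acrophase:.2f} h")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("Pearson r")
    ax.set_xlim(0, 24)
    ax.set_title(title or (f"r-chart: {rchart.outcome}" if rchart.outcome else "r-chart"))
    ax.legend(fontsize=8)
    fig.tight_layout()
    _save(fig, path)
    plt.close(fig)


def plot_reference_curve(ref: ReferenceCurve, path, profile=None) -> None:
    """Reference curve over the day, optionally with a mean exposure profile."""
    fig, ax = plt.subplots(figsize=(8, 4))
    t = np.linspace(0, 24, 24 * 60, endpoint=False)
    ax.plot(t, ref.value(t), color="tab:red", label="reference curve")
    if profile is not None:
        ax.plot(profile.bin_midpoints_hours(), profile.values, "-o", ms=3,
                color="tab:blue", label="mean exposure")
    ax.set_yscale("log")
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("blue-light irradiance (μW/cm²)")
    ax.set_xlim(0, 24)
    ax.legend(fontsize=8)
    fig.tight_layout()
    _save(fig, path)
    plt.close(fig)
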