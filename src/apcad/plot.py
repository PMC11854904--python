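"""Genome-wide and per-chromosome profile figures.

The genome-wide figure stacks six panels: the four category BAF tracks
(subcategories color-coded: 1A blue / 1B red, 2A red / 2B blue, 3A red /
3B blue, 4A red / 4B blue), the raw BAF of all SNPs, and Log2R.  Called
abnormal segments are shaded.  A zoom renders the four category panels for
one chromosome.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .genome import CHROMOSOMES, default_genome  # noqa: E402

log = logging.getLogger(__name__)

__all__ = ["plot_case"]

SUBCAT_COLOR = {
    "1A": "tab:blue", "1B": "tab:red",
    "2A": "tab:red", "2B": "tab:blue",
    "3A": "tab:red", "3B": "tab:blue",
    "4A": "tab:red", "4B": "tab:blue",
}


def _offsets(genome):
    off, cum = {}, 0
    for c in CHROMOSOMES:
        if c in genome:
            off[c] = cum
            cum += genome.length(c)
    return off, cum


def plot_case(df: pd.DataFrame, report=None, out_path="apcad_profiles.png",
              zoom: str | None = None, dpi: int = 120) -> str:
    """Render the profile figure; returns the written path."""
    genome = default_genome()
    if zoom is not None:
        return _plot_zoom(df, str(zoom), out_path, dpi)
    off, total = _offsets(genome)

    fig, axes = plt.subplots(6, 1, figsize=(16, 13), sharex=True)
    x_all = df["position_bp"] + df["chromosome"].map(off).fillna(0)

    for i, cat in enumerate("1234"):
        ax = axes[i]
        for sub in (cat + "A", cat + "B"):
            sel = df["subcategory"] == sub
            ax.plot(x_all[sel] / 1e6, df.loc[sel, "embryo_baf"], ".",
                    ms=1.5, color=SUBCAT_COLOR[sub], rasterized=True, label=sub)
        ax.set_ylabel(f"cBAF cat {cat}")
        ax.set_ylim(-0.05, 1.05)
        ax.legend(loc="upper right", markerscale=8, fontsize=7)
    axes[4].plot(x_all / 1e6, df["embryo_baf"], ".", ms=1.0, color="0.4",
                 rasterized=True)
    axes[4].set_ylabel("rBAF")
    axes[4].set_ylim(-0.05, 1.05)
    axes[5].plot(x_all / 1e6, df["embryo_log2r"], ".", ms=1.0, color="0.4",
                 rasterized=True)
    axes[5].set_ylabel("Log2R")
    axes[5].set_ylim(-2.5, 1.5)
    axes[5].set_xlabel("genome position (Mb)")

    for c, o in off.items():
        for ax in axes:
            ax.axvline(o / 1e6, color="0.85", lw=0.6, zorder=0)
        axes[0].text((o + genome.length(c) / 2) / 1e6, 1.08, c,
                     ha="center", fontsize=7)
    if report is not None:
        for chrom, calls in report.per_chromosome.items():
            if chrom not in off:
                continue
            for call in calls:
                if call.event in ("disomy", "no_call"):
                    continue
                lo = (off[chrom] + call.start_bp) / 1e6
                hi = (off[chrom] + call.end_bp) / 1e6
                for ax in axes:
                    ax.axvspan(lo, hi, color="gold", alpha=0.15, zorder=0)
    fig.tight_layout()
    try:
        fig.savefig(out_path, dpi=dpi)
    except Exception:  # plotting failures are logged, never fatal
        log.exception("failed to write figure %s", out_path)
    finally:
        plt.close(fig)
    return str(out_path)


def _plot_zoom(df, chromosome, out_path, dpi):
    sub = df[df["chromosome"] == chromosome]
    fig, axes = plt.subplots(4, 1, figsize=(12, 9), sharex=True)
    for i, cat in enumerate("1234"):
        ax = axes[i]
        for s in (cat + "A", cat + "B"):
            sel = sub["subcategory"] == s
            ax.plot(sub.loc[sel, "position_bp"] / 1e6, sub.loc[sel, "embryo_baf"],
                    ".", ms=3, color=SUBCAT_COLOR[s], label=s)
        ax.set_ylabel(f"cBAF cat {cat}")
        ax.set_ylim(-0.05, 1.05)
        ax.legend(loc="upper right", markerscale=4, fontsize=8)
    axes[-1].set_xlabel(f"chromosome {chromosome} position (Mb)")
    fig.tight_layout()
    try:
        fig.savefig(out_path, dpi=dpi)
    except Exception:
        log.exception("failed to write figure %s", out_path)
    finally:
        plt.close(fig)
    return str(out_path)
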