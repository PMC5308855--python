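"""Volcano plots for disproportionality screens.

Each screened exposure is one point at (ln ROR, -log10 P); the horizontal
red line marks P = 0.05 and the point colour encodes the number of event
reports (blue few, red many).  Exposures with an undefined ROR (a zero cell)
have no x coordinate and are omitted.
"""

from __future__ import annotations

import math
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .disproportionality import VOLCANO_BASELINE, SignalResult

__all__ = ["volcano_plot"]


def volcano_plot(results: Sequence[SignalResult], out_path=None, ax=None,
                 title: str = "", annotate: int = 0):
    """Draw the volcano plot of a screen; optionally label the top exposures.

    Returns the matplotlib axes.  ``annotate`` labels the given number of
    smallest-P exposures.
    """
    points = [r for r in results if not math.isnan(r.ln_ror)]
    if ax is None:
        _, ax = plt.subplots(figsize=(6.5, 5))
    if points:
        scatter = ax.scatter(
            [r.ln_ror for r in points],
            [r.neg_log10_p for r in points],
            c=[r.n_event_reports for r in points],
            cmap="coolwarm", s=28, edgecolors="none", zorder=3,
        )
        ax.figure.colorbar(scatter, ax=ax, label="event reports")
    ax.axhline(VOLCANO_BASELINE, color="red", linewidth=1, zorder=2)
    ax.axvline(0.0, color="grey", linewidth=0.8, linestyle=":", zorder=1)
    for r in sorted(points, key=lambda r: r.p_value)[:annotate]:
        ax.annotate(r.exposure_label, (r.ln_ror, r.neg_log10_p),
                    fontsize=8, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("ln ROR")
    ax.set_ylabel(r"$-\log_{10} P$")
    if title:
        ax.set_title(title)
    if out_path is not None:
        ax.figure.savefig(out_path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
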