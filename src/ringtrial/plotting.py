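"""Box-plot overlays of collective results, survey-style.

Each figure shows, for one (survey, analyte, sample): a background box for
ALL participants combined (25-75 % box, 10/90-percentile whiskers, median
line) overlaid with one box per manufacturer collective, the "other" pool
rendered once.  Percentiles use linear interpolation between order
statistics so the geometry is reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")  # headless-safe; never requires a display
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluation import form_collectives

__all__ = ["box_stats", "render_collective_boxes"]

PERCENTILES = (10.0, 25.0, 50.0, 75.0, 90.0)


def box_stats(
    values: Sequence[float] | pd.Series,
    percentiles: Sequence[float] = PERCENTILES,
) -> dict[str, float]:
    """Whisker/box/median levels via linear-interpolation percentiles."""
    arr = np.asarray(pd.Series(values, dtype=float).dropna(), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    p10, p25, p50, p75, p90 = np.percentile(
        arr, percentiles, method="linear"
    )
    return {
        "whislo": float(p10),
        "q1": float(p25),
        "med": float(p50),
        "q3": float(p75),
        "whishi": float(p90),
        "n": int(arr.size),
    }


def render_collective_boxes(
    results: pd.DataFrame,
    *,
    analyte: str,
    sample_id: str,
    min_size: int = 4,
    out: Optional[Union[str, Path]] = None,
    title: Optional[str] = None,
    log_scale: bool = True,
) -> plt.Figure:
    """One background all-participant box overlaid with per-collective boxes.

    ``results`` is an (already outlier-filtered) result table for a single
    survey.  Returns the figure; when ``out`` is given the figure is also
    written there (format from the suffix, e.g. ``.png`` or ``.svg``).
    With no plottable data an explicit empty-figure notice is rendered
    instead of silently producing a blank file.
    """
    sel = results[
        (results["analyte"] == analyte)
        & (results["sample_id"] == sample_id)
        & results["concentration_ku_l"].notna()
    ]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    if sel.empty:
        ax.text(
            0.5, 0.5, f"no plottable data for {analyte} / {sample_id}",
            ha="center", va="center", transform=ax.transAxes,
        )
        ax.set_axis_off()
        if out is not None:
            _save(fig, out)
        return fig

    all_stats = box_stats(sel["concentration_ku_l"])
    collectives = form_collectives(sel, min_size=min_size)
    labels = [c.manufacturer_code for c in collectives]
    stats = [box_stats(c.members["concentration_ku_l"]) for c in collectives]

    n_pos = len(labels)
    # background band spanning the axis: all-participant box + median line
    ax.axhspan(all_stats["q1"], all_stats["q3"], color="#c8e6c9", zorder=0,
               label="all participants 25–75 %")
    for level in (all_stats["whislo"], all_stats["whishi"]):
        ax.axhline(level, color="#66bb6a", lw=1.0, ls=":", zorder=1)
    ax.axhline(all_stats["med"], color="#d32f2f", lw=1.5, zorder=1,
               label="all-participant median")

    bxp_stats = [
        {
            "label": f"{lab}\n(n={st['n']})",
            "whislo": st["whislo"],
            "q1": st["q1"],
            "med": st["med"],
            "q3": st["q3"],
            "whishi": st["whishi"],
            "fliers": [],
        }
        for lab, st in zip(labels, stats)
    ]
    ax.bxp(bxp_stats, positions=range(1, n_pos + 1), showfliers=False,
           widths=0.55, zorder=2)
    if log_scale and (sel["concentration_ku_l"] > 0).all():
        ax.set_yscale("log")
    ax.set_ylabel("sIgE [kU/L]")
    ax.set_title(title or f"{analyte} — sample {sample_id}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if out is not None:
        _save(fig, out)
    return fig


def _save(fig: plt.Figure, out: Union[str, Path]) -> None:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150)
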