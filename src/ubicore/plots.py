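"""Publication-style Ub-Ab, Var-Ab and U-U renderings.

Conventions follow the field's figures: ubiquity axes run 0-100%,
abundance axes are log10 with a default floor of 1e-4 (log10 = -4, one
part per ten thousand), the two-parameter cutoff is marked with a red
bull's-eye, and only curves passing above it are colored and labeled
(capped at the 50 most abundant taxa); the rest are greyed out.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .comparison import UUCurve
from .core_election import CoreCutoff, UbiquityCurve
from .variation import VarAbRecord

__all__ = ["PlotStyle", "plot_ubab", "plot_varab", "plot_uu",
           "make_ubab_figure", "make_varab_figure", "make_uu_figure"]

DEFAULT_FLOOR = 1e-4


@dataclass(frozen=True)
class PlotStyle:
    floor: float = DEFAULT_FLOOR  # x-axis lower limit (abundance)
    n_colored: int = 50  # color at most this many taxa, by mean abundance

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError(f"floor must be > 0, got {self.floor}")
        if self.n_colored < 0:
            raise ValueError(f"n_colored must be >= 0, got {self.n_colored}")


def _step_xy(curve: UbiquityCurve, floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Log10-abundance grid and ubiquity (%) for step plotting from the floor."""
    xs = np.concatenate([[floor], curve.breakpoints[curve.breakpoints > floor], [1.0]])
    ys = curve(xs) * 100.0
    return np.log10(xs), ys


def make_ubab_figure(
    curves: Sequence[UbiquityCurve],
    cutoff: CoreCutoff | None = None,
    style: PlotStyle = PlotStyle(),
    title: str | None = None,
) -> plt.Figure:
    """Overlaid ubiquity-vs-log10(abundance) curves for one cohort.

    Curves passing above the bull's-eye (ubiquity at the abundance cutoff
    strictly greater than the ubiquity cutoff) are colored and labeled;
    others are grey.  At most ``style.n_colored`` taxa are colored,
    ranked by cohort-mean abundance.
    """
    if not curves:
        raise ValueError("no curves to plot")
    elected = []
    if cutoff is not None:
        elected = [c for c in curves if c(cutoff.abundance) > cutoff.ubiquity]
        elected.sort(key=lambda c: c.mean_abundance(), reverse=True)
        elected = elected[: style.n_colored]
    chosen = {c.taxon for c in elected}

    fig, ax = plt.subplots(figsize=(6, 5))
    for c in curves:
        if c.taxon in chosen:
            continue
        x, y = _step_xy(c, style.floor)
        ax.step(x, y, where="post", color="0.75", lw=0.8, zorder=1)
    cmap = plt.get_cmap("tab20")
    for i, c in enumerate(elected):
        x, y = _step_xy(c, style.floor)
        ax.step(x, y, where="post", color=cmap(i % 20), lw=1.6, zorder=3, label=c.taxon)
    if cutoff is not None:
        ax.plot(
            [math.log10(cutoff.abundance)], [cutoff.ubiquity * 100.0],
            marker="o", ms=12, mfc="none", mec="red", mew=2, zorder=4,
        )
        ax.plot([math.log10(cutoff.abundance)], [cutoff.ubiquity * 100.0],
                marker=".", color="red", zorder=4)
    handles, labels = ax.get_legend_handles_labels()
    if labels:
        ax.legend(handles, labels, fontsize=7, loc="upper right")
    ax.set_xlim(math.log10(style.floor), 0.0)
    ax.set_ylim(0.0, 100.0)
    ax.set_xlabel(r"$\log_{10}$(abundance)")
    ax.set_ylabel("ubiquity (%)")
    if title:
        ax.set_title(title)
    return fig


def make_varab_figure(
    records: Sequence[VarAbRecord],
    core_set: set[str] | frozenset[str] = frozenset(),
    minor_core_set: set[str] | frozenset[str] = frozenset(),
) -> plt.Figure:
    """Scatter of sd vs mean log10 abundance, glyph area proportional to
    ubiquity; core filled blue, minor core green, the rest unfilled."""
    overlap = set(core_set) & set(minor_core_set)
    if overlap:
        raise ValueError(f"core and minor-core sets must be disjoint; both contain {sorted(overlap)}")
    fig, ax = plt.subplots(figsize=(6, 5))
    max_area = 220.0
    for r in records:
        sd = 0.0 if r.sd_log_abundance is None else r.sd_log_abundance
        area = max(max_area * r.ubiquity, 6.0)
        if r.taxon in core_set:
            fc, ec, z = "tab:blue", "tab:blue", 3
        elif r.taxon in minor_core_set:
            fc, ec, z = "tab:green", "tab:green", 3
        else:
            fc, ec, z = "none", "0.4", 2
        ax.scatter([r.mean_log_abundance], [sd], s=area, facecolors=fc,
                   edgecolors=ec, linewidths=0.8, zorder=z)
    ax.set_xlabel(r"mean $\log_{10}$(abundance)")
    ax.set_ylabel(r"sd $\log_{10}$(abundance)")
    return fig


def make_uu_figure(
    curves: Sequence[UUCurve],
    labels: tuple[str, str] = ("cohort X", "cohort Y"),
    top_k: int = 5,
) -> plt.Figure:
    """Ubiquity-vs-ubiquity traces with the grey identity diagonal; the
    ``top_k`` most deviating taxa get their argmax point labeled."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot([0, 100], [0, 100], color="0.7", lw=3, zorder=1)
    ranked = sorted(curves, key=lambda c: c.ks, reverse=True)
    labeled = {c.taxon for c in ranked[: max(top_k, 0)]}
    cmap = plt.get_cmap("tab10")
    ci = 0
    for c in curves:
        x = c.ubiquity_x * 100.0
        y = c.ubiquity_y * 100.0
        if c.taxon in labeled and c.ks > 0:
            color = cmap(ci % 10)
            ci += 1
            ax.plot(x, y, color=color, lw=1.4, zorder=3)
            px, py = c.argmax_pair
            ax.plot([px * 100], [py * 100], marker="o", ms=4, color=color, zorder=4)
            ax.annotate(c.taxon, (px * 100, py * 100), fontsize=7,
                        textcoords="offset points", xytext=(4, 4))
        else:
            ax.plot(x, y, color="0.8", lw=0.8, zorder=2)
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel(f"ubiquity in {labels[0]} (%)")
    ax.set_ylabel(f"ubiquity in {labels[1]} (%)")
    return fig


def _save(fig: plt.Figure, out_path: str) -> str:
    # fixed hashsalt + stripped timestamps: identical inputs -> identical bytes
    with matplotlib.rc_context({"svg.hashsalt": "ubicore"}):
        fig.savefig(out_path, metadata=_stable_metadata(out_path))
    plt.close(fig)
    return out_path


def _stable_metadata(out_path: str) -> dict | None:
    # strip timestamps so identical inputs give identical vector output
    if out_path.endswith(".svg"):
        return {"Date": None}
    if out_path.endswith(".pdf"):
        return {"CreationDate": None}
    return None


def plot_ubab(
    curves: Sequence[UbiquityCurve],
    cutoff: CoreCutoff | None,
    style: PlotStyle = PlotStyle(),
    out_path: str = "ubab.svg",
    title: str | None = None,
) -> str:
    return _save(make_ubab_figure(curves, cutoff, style, title), out_path)


def plot_varab(
    records: Sequence[VarAbRecord],
    core_set: set[str] | frozenset[str] = frozenset(),
    minor_core_set: set[str] | frozenset[str] = frozenset(),
    out_path: str = "varab.svg",
) -> str:
    return _save(make_varab_figure(records, core_set, minor_core_set), out_path)


def plot_uu(
    curves: Sequence[UUCurve],
    labels: tuple[str, str] = ("cohort X", "cohort Y"),
    out_path: str = "uu.svg",
    top_k: int = 5,
) -> str:
    return _save(make_uu_figure(curves, labels, top_k), out_path)


def top_colored(mean_abundances: Mapping[str, float], n: int = 50) -> list[str]:
    """The taxa that receive colors: the ``n`` most abundant by cohort mean."""
    return sorted(mean_abundances, key=lambda t: mean_abundances[t], reverse=True)[:n]
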