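"""Visualization of behavioral streams and analysis results.

Multirow event rasters ("kebab-line" plots) for annotated streams, timeseries
with event-band overlays, chromatic cross-recurrence plots, burstiness
panels (per-train IOI histogram plus burstiness–memory scatter) and directed
Granger-influence graphs. Figures are deterministic for fixed inputs; tests
assert structural element counts rather than pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .burstiness import analyze_train, inter_onset_intervals
from .crqa import CrossRecurrenceMatrix
from .data import BinarySpikeTrain, EventSequence
from .errors import ConfigurationError
from .granger import GCMatrixResult

__all__ = [
    "PlotSpec",
    "plot_multirow_events",
    "plot_timeseries_with_events",
    "plot_crp",
    "plot_burstiness_panel",
    "plot_gc_graph",
]

_DEFAULT_CYCLE = ["tab:blue", "black", "tab:red", "tab:green", "tab:orange",
                  "tab:purple", "tab:brown", "tab:cyan"]


@dataclass
class PlotSpec:
    """Layout for event-stream plots: per-code colors, lane order, window."""

    colors: dict = field(default_factory=dict)
    code_order: list | None = None  # top-to-bottom lane order within a stream
    window: tuple[float, float] | None = None
    figsize: tuple[float, float] = (10.0, 4.0)
    bar_height: float = 1.0


def _codes_in(sequences: list[EventSequence]) -> list:
    codes = []
    for seq in sequences:
        for rec in seq:
            if rec.code not in codes:
                codes.append(rec.code)
    return codes


def plot_multirow_events(
    sequences: list[EventSequence],
    spec: PlotSpec | None = None,
    path=None,
    ax=None,
):
    """One horizontal bar lane per (stream, code) with baseline guide lines.

    Lanes of one stream touch vertically so contingencies across streams read
    at a glance; codes keep the same color in every stream. Unmapped codes
    raise when an explicit color map is given.
    """
    spec = spec or PlotSpec()
    codes = spec.code_order or _codes_in(sequences)
    if spec.colors:
        missing = [c for c in codes if c not in spec.colors]
        if missing:
            raise ConfigurationError(f"no color mapped for codes: {missing}")
        colors = spec.colors
    else:
        colors = {c: _DEFAULT_CYCLE[i % len(_DEFAULT_CYCLE)] for i, c in enumerate(codes)}
    if ax is None:
        fig, ax = plt.subplots(figsize=spec.figsize)
    else:
        fig = ax.figure
    h = spec.bar_height
    extent = max([s.duration for s in sequences] + [1.0])
    yticks, ylabels = [], []
    lane = 0
    for seq in sequences:
        for code in codes:
            y0 = lane * h
            ax.axhline(y0, color="0.6", lw=0.6, zorder=1)  # kebab guide line
            bars = [(r.onset, r.duration) for r in seq if r.code == code]
            if bars:
                ax.broken_barh(bars, (y0, h * 0.95), facecolors=colors[code], zorder=2)
            yticks.append(y0 + h / 2)
            ylabels.append(f"{seq.label or 'stream'}:{code}")
            lane += 1
        lane += 1  # gap between streams
    ax.set_yticks(yticks)
    ax.set_yticklabels(ylabels, fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_xlim(spec.window or (0, extent))
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_timeseries_with_events(
    times: np.ndarray,
    values: np.ndarray,
    events: EventSequence,
    spec: PlotSpec | None = None,
    path=None,
    ax=None,
):
    """Point-marker timeseries with a labeled event band along the top.

    Segment boundaries in the band mark each event's start and stop; events
    extending beyond the series extent are clipped with a warning.
    """
    import logging

    spec = spec or PlotSpec()
    if ax is None:
        fig, ax = plt.subplots(figsize=spec.figsize)
    else:
        fig = ax.figure
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ax.plot(times, values, "+", ms=4, color="0.3")
    if len(times):
        t_max = times.max()
        top = values.max() + 0.08 * max(np.ptp(values), 1.0)
        band_h = 0.05 * max(np.ptp(values), 1.0)
        codes = _codes_in([events])
        colors = spec.colors or {
            c: _DEFAULT_CYCLE[i % len(_DEFAULT_CYCLE)] for i, c in enumerate(codes)
        }
        for rec in events:
            if rec.onset > t_max:
                logging.getLogger(__name__).warning(
                    "event at %.3g s beyond series extent; clipped", rec.onset
                )
                continue
            end = min(rec.offset, t_max)
            ax.broken_barh([(rec.onset, end - rec.onset)], (top, band_h),
                           facecolors=colors.get(rec.code, "gray"))
            ax.annotate(str(rec.code), ((rec.onset + end) / 2, top + band_h),
                        ha="center", va="bottom", fontsize=7)
    ax.set_xlabel("time (s)")
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_crp(
    crm: CrossRecurrenceMatrix,
    colors: dict[int, str] | None = None,
    path=None,
    ax=None,
):
    """Chromatic cross-recurrence plot: one color per match category on a
    white background, origin at the lower-left."""
    from matplotlib.colors import BoundaryNorm, ListedColormap

    cats = sorted(set(np.unique(crm.rec)))
    colors = colors or crm.rule.colors
    defaults = {1: "tab:red", -1: "tab:blue"}
    palette = []
    for c in cats:
        if c == 0:
            palette.append("white")
        else:
            palette.append(colors.get(c) or defaults.get(c) or
                           _DEFAULT_CYCLE[abs(c) % len(_DEFAULT_CYCLE)])
    cmap = ListedColormap(palette)
    bounds = [c - 0.5 for c in cats] + [cats[-1] + 0.5]
    norm = BoundaryNorm(bounds, cmap.N)
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    ax.imshow(crm.rec, origin="lower", cmap=cmap, norm=norm, interpolation="none")
    ax.set_xlabel(crm.x_label or "series x (samples)")
    ax.set_ylabel(crm.y_label or "series y (samples)")
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_burstiness_panel(
    trains: list[BinarySpikeTrain],
    path=None,
    seed: int | None = 0,
):
    """IOI histogram per train plus a burstiness–memory scatter.

    The scatter includes auto-generated periodic and Poisson reference trains
    matched to the first input, anchoring the plot near B = −1 and B ≈ 0.
    """
    from .simulate import simulate_periodic_train, simulate_poisson_train

    n = len(trains)
    fig, axes = plt.subplots(1, n + 1, figsize=(4 * (n + 1), 3.2))
    axes = np.atleast_1d(axes)
    points = []
    for i, train in enumerate(trains):
        iois = inter_onset_intervals(train)
        axes[i].hist(iois.intervals, bins="auto", color="0.4")
        axes[i].set_title(train.label or f"train {i + 1}", fontsize=9)
        axes[i].set_xlabel("inter-onset interval (s)")
        est = analyze_train(train)
        points.append((train.label or f"train {i + 1}", est.M, est.B))
    if trains:
        proto = inter_onset_intervals(trains[0])
        mean_ioi = max(int(round(proto.mean * trains[0].rate)), 2)
        refs = [
            ("periodic ref", simulate_periodic_train(mean_ioi, proto.n + 1, jitter=1, seed=seed)),
            ("poisson ref", simulate_poisson_train(
                min(1.0 / mean_ioi, 0.5),
                T=int(math.ceil((proto.n + 2) * mean_ioi * 2)), seed=seed)),
        ]
        for name, ref in refs:
            est = analyze_train(ref)
            points.append((name, est.M, est.B))
    ax = axes[-1]
    for name, m, b in points:
        ax.scatter([0.0 if m is None else m], [b], label=name)
    ax.set_xlabel("memory M (lag-1 autocorrelation)")
    ax.set_ylabel("burstiness B")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.axhline(0, color="0.8", lw=0.6)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_gc_graph(result: GCMatrixResult, path=None, ax=None):
    """Directed influence graph: one node per variable, one arrow per
    significant link; positive links red with the magnitude printed near the
    arrowhead, negative links blue."""
    m = result.gcause.shape[0]
    labels = result.labels or [str(i) for i in range(m)]
    angles = 2 * np.pi * np.arange(m) / m
    xs, ys = np.cos(angles), np.sin(angles)
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    ax.scatter(xs, ys, s=600, facecolors="white", edgecolors="black", zorder=3)
    for i in range(m):
        ax.annotate(labels[i], (xs[i], ys[i]), ha="center", va="center",
                    fontsize=8, zorder=4)
    for src in range(m):
        for tgt in range(m):
            sig = result.significance[src, tgt]
            if src == tgt or sig == 0:
                continue
            color = "tab:red" if sig > 0 else "tab:blue"
            start = np.array([xs[src], ys[src]])
            end = np.array([xs[tgt], ys[tgt]])
            vec = end - start
            dist = np.linalg.norm(vec)
            shrink = 0.18 / dist if dist else 0
            a = start + vec * shrink
            b = end - vec * shrink
            ax.annotate("", xy=b, xytext=a, zorder=2,
                        arrowprops=dict(arrowstyle="-|>", color=color, lw=1.6,
                                        connectionstyle="arc3,rad=0.12"))
            mid = b - vec * 0.12
            ax.annotate(f"{result.gcause[src, tgt]:.2f}", mid, fontsize=7,
                        color=color, zorder=4)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.set_aspect("equal")
    ax.axis("off")
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
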