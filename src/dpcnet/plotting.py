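"""Diagnostic plots for the sweep and the final component structure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .components import FinalStructure, SweepTrace
from .network import DPCNGraph, magnitude_decay


def plot_magnitude_decay(dpcn: DPCNGraph, ax=None):
    """Edge count surviving each magnitude threshold (log-y step plot)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    decay = magnitude_decay(dpcn)
    ax.step(decay["threshold"], decay["n_edges"], where="post")
    ax.set_xlabel("contact weight (magnitude)")
    ax.set_ylabel("number of edges")
    ax.set_yscale("log")
    return ax


def plot_sweep(trace: SweepTrace, final: FinalStructure | None = None, ax=None):
    """Component count as a function of the smallest weight left in the
    graph; the critical weight of the final structure is highlighted."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    curve = trace.level_curve()
    ax.step(curve["weight"], curve["n_components"], where="post")
    if final is not None:
        ax.axvline(final.critical_weight, color="crimson", ls="--", lw=1)
        ax.plot([final.critical_weight], [final.max_count], "o", color="crimson")
    ax.set_xlabel("contact weight")
    ax.set_ylabel("number of connected components")
    return ax


def plot_vanishing_boxplot(final: FinalStructure, ax=None):
    """Box plot of the vanishing points of the final components."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 4))
    ax.boxplot([final.vanishing_points()], tick_labels=["final CC structure"])
    ax.set_ylabel("vanishing point")
    return ax


def plot_diameter_vs_vanishing(final: FinalStructure, d_min: int = 3, ax=None):
    """Scatter of component diameter against vanishing point; the major
    components (d >= d_min) are emphasized."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    vp = final.vanishing_points()
    d = [c.diameter for c in final.components]
    major = [di >= d_min for di in d]
    ax.scatter(vp, d, c=["crimson" if m else "steelblue" for m in major], s=30)
    ax.axhline(d_min - 0.5, color="gray", ls=":", lw=1)
    ax.set_xlabel("vanishing point")
    ax.set_ylabel("diameter d")
    return ax


def save(ax, path: str) -> None:
    ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(ax.figure)
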