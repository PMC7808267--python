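"""Graphics: design diagram, sequence-level summaries, and a forest plot
of strategy values.

Figures are plain matplotlib and deterministic for fixed input; tests
assert structure (artist counts), not pixels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .design import SmartDesign
from .estimation import AtsEstimates

__all__ = ["plot_design", "plot_sequence_summary", "plot_forest", "render_plots"]


def plot_design(design: SmartDesign, ax=None, title: str | None = None,
                legend: bool = True):
    """Design diagram: circles for treatment assignments, diamonds for
    intermediate evaluations, one terminal point per sequence."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    seqs = design.sequences()
    n_seq = len(seqs)
    y_seq = np.linspace(1, 0, n_seq)
    # stage-2 leaves at x=2, evaluation nodes at x=1, arms at x=0.5, root at 0
    arm_y = {}
    eval_y = {}
    for i, (a1, o2, a2) in enumerate(seqs):
        ax.plot(2.0, y_seq[i], "o", color="C0", ms=7, zorder=3)
        ax.annotate(str(a2), (2.05, y_seq[i]), fontsize=8, va="center")
        eval_y.setdefault((a1, o2), []).append(y_seq[i])
        arm_y.setdefault(a1, []).append(y_seq[i])
    for (a1, o2), ys in eval_y.items():
        ym = float(np.mean(ys))
        ax.plot(1.0, ym, "D", color="C1", ms=7, zorder=3)
        ax.annotate(f"O2={o2}", (0.98, ym + 0.02), fontsize=8, ha="right")
        for y in ys:
            ax.plot([1.0, 2.0], [ym, y], "-", color="0.6", lw=1, zorder=1)
    for a1, ys in arm_y.items():
        ym = float(np.mean(ys))
        ax.plot(0.5, ym, "o", color="C0", ms=9, zorder=3)
        ax.annotate(f"A1={a1}", (0.5, ym + 0.03), fontsize=9, ha="center")
        for (aa, o2), ys2 in eval_y.items():
            if aa == a1:
                ax.plot([0.5, 1.0], [ym, float(np.mean(ys2))], "-",
                        color="0.6", lw=1, zorder=1)
    root_y = float(np.mean(y_seq))
    ax.plot(0.0, root_y, "s", color="C2", ms=9, zorder=3)
    for a1, ys in arm_y.items():
        ax.plot([0.0, 0.5], [root_y, float(np.mean(ys))], "-",
                color="0.6", lw=1, zorder=1)
    if legend:
        ax.plot([], [], "o", color="C0", label="treatment assignment")
        ax.plot([], [], "D", color="C1", label="intermediate evaluation")
        ax.legend(loc="lower left", fontsize=8)
    if title:
        ax.set_title(title)
    ax.set_xlim(-0.2, 2.4)
    ax.axis("off")
    return ax


def plot_sequence_summary(
    data: pd.DataFrame,
    family: str = "gaussian",
    ax=None,
    reference: bool = True,
    color: str = "C0",
    title: str | None = None,
    xlab: str = "Treatment sequence",
    ylab: str = "Outcome",
):
    """Per-sequence outcome summary: box plots for a continuous outcome,
    bar chart of response proportions for a binary one, with an optional
    reference line at the overall mean."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    groups = data.groupby(["A1", "O2", "A2"])["Y"]
    labels = [f"({a},{o},{b})" for (a, o, b) in groups.groups]
    if family == "binomial":
        props = groups.mean().to_numpy()
        ax.bar(np.arange(len(props)), props, color=color)
        ax.set_xticks(np.arange(len(props)), labels, rotation=45, fontsize=8)
    else:
        series = [y.to_numpy() for _, y in groups]
        ax.boxplot(series, tick_labels=labels)
    if reference:
        ax.axhline(float(data["Y"].mean()), color="C3", ls="--", lw=1)
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    if title:
        ax.set_title(title)
    return ax


def plot_forest(estimates: AtsEstimates, ax=None, title: str | None = None):
    """Forest plot of estimated strategy values with confidence
    intervals, one row per strategy, reference line at zero."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    tab = estimates.table
    ypos = np.arange(len(tab))[::-1]
    ax.errorbar(
        tab["value"], ypos,
        xerr=[tab["value"] - tab["ci_low"], tab["ci_high"] - tab["value"]],
        fmt="o", color="C0", capsize=3,
    )
    ax.axvline(0.0, color="0.5", ls=":", lw=1)
    ax.set_yticks(ypos, [s.code for s in estimates.strategies])
    ax.set_xlabel("Strategy value")
    if title:
        ax.set_title(title)
    return ax


def render_plots(
    which: str,
    out: str,
    design: SmartDesign | None = None,
    data: pd.DataFrame | None = None,
    estimates: AtsEstimates | None = None,
    family: str = "gaussian",
    **options,
):
    """Render one named figure (``diagram``, ``summary`` or ``forest``)
    to a file."""
    if which == "diagram":
        if design is None:
            raise ValueError("diagram needs a design")
        ax = plot_design(design, **options)
    elif which == "summary":
        if data is None:
            raise ValueError("summary needs trial data")
        ax = plot_sequence_summary(data, family=family, **options)
    elif which == "forest":
        if estimates is None:
            raise ValueError("forest needs strategy estimates")
        ax = plot_forest(estimates, **options)
    else:
        raise ValueError(f"unknown plot key {which!r}")
    fig = ax.figure
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out
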