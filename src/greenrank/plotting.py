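"""Figures: layered Hasse diagram and bivariate rank scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .poset import HasseDiagram, assign_levels


def plot_hasse(diagram: HasseDiagram, ax=None):
    """Draw the covering relation with objects laid out by level (level 1,
    the best end, at the bottom).  Layout is plain: objects are spread
    uniformly within each level; no crossing minimisation."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    levels = assign_levels(diagram)
    by_level: dict[int, list] = {}
    for o, lv in levels.items():
        by_level.setdefault(lv, []).append(o)
    pos = {}
    for lv, objs in by_level.items():
        for k, o in enumerate(sorted(objs, key=str)):
            pos[o] = ((k + 1) / (len(objs) + 1), lv)
    for s, t in diagram.covers or ():
        ax.plot(*zip(pos[s], pos[t]), color="0.6", lw=1, zorder=1)
    for o, (x, y) in pos.items():
        members = diagram.equivalence_classes[o]
        label = ",".join(str(m) for m in members)
        ax.scatter([x], [y], s=250, color="white", edgecolor="black", zorder=2)
        ax.annotate(label, (x, y), ha="center", va="center", fontsize=8, zorder=3)
    ax.set_yticks(sorted(by_level))
    ax.set_ylabel("level (1 = best)")
    ax.set_xticks([])
    return ax


def plot_bivariate_ranks(table: pd.DataFrame, ax=None):
    """Scatter of greenness vs performance averaged ranks; Pareto-front
    procedures highlighted."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    front = table[table["pareto"]]
    rest = table[~table["pareto"]]
    ax.scatter(rest["greenness_rank"], rest["performance_rank"],
               color="0.5", label="dominated")
    ax.scatter(front["greenness_rank"], front["performance_rank"],
               color="tab:green", label="Pareto front")
    for pid, row in table.iterrows():
        ax.annotate(str(pid), (row["greenness_rank"], row["performance_rank"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("greenness averaged rank (lower = greener)")
    ax.set_ylabel("performance averaged rank (lower = better)")
    ax.legend()
    return ax
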