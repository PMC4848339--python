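"""Partial orders over procedures: orientation, dominance order, covering
relation (Hasse diagram), and structural descriptors.

Two procedures are comparable only when one is at least as good on *every*
variable of the information basis (IB); the Hasse diagram is the transitive
reduction of that dominance order.  All variables are first oriented so
that lower = better, hence minimal elements sit at level 1 (the "good" end)
and maximal elements at the top.

Procedures with identical oriented rows are merged into equivalence
classes; the order lives on class representatives and every report lists
class members.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .data import ProcedureTable, VariableSpec
from .exceptions import CompletenessError, PosetError, SchemaError, ValidationError


@dataclass(frozen=True)
class OrientedMatrix:
    """A complete N x R matrix with all variables oriented lower = better.

    ``orientation_audit`` records, per variable, the transform applied —
    purely for provenance; any strictly order-reversing transform yields
    the same poset.
    """

    procedure_ids: tuple
    variable_names: tuple[str, ...]
    values: np.ndarray
    orientation_audit: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if np.isnan(self.values).any():
            raise CompletenessError("oriented matrix contains missing values")
        if self.values.shape != (len(self.procedure_ids), len(self.variable_names)):
            raise ValidationError("matrix shape does not match ids/variables")


def orient_matrix(
    table: ProcedureTable, variable_set: Iterable[str]
) -> OrientedMatrix:
    """Select ``variable_set`` columns and orient each so lower = better.

    Transforms: ``low_is_good`` — identity; ``high_is_good`` — reflection
    ``scale_max - value`` (scale_max from the VariableSpec, else the column
    maximum); ``target_100`` — ``|100 - value|`` (recoveries on either side
    of 100% are equally imperfect).
    """
    names = [v for v in table.variable_names if v in set(variable_set)]
    missing = set(variable_set) - set(names)
    if missing:
        raise SchemaError(f"variables not in table: {sorted(missing)}")
    sub = table.values[names]
    incomplete = sub.columns[sub.isna().any()].tolist()
    if incomplete:
        raise CompletenessError(
            f"missing values in selected columns {incomplete}; run "
            f"validate_completeness first"
        )
    out = np.empty(sub.shape, dtype=float)
    audit: dict[str, str] = {}
    for j, name in enumerate(names):
        spec = table.spec(name)
        col = sub[name].to_numpy(dtype=float)
        if spec.orientation == "low_is_good":
            out[:, j] = col
            audit[name] = "identity"
        elif spec.orientation == "high_is_good":
            anchor = spec.scale_max if spec.scale_max is not None else float(col.max())
            out[:, j] = anchor - col
            audit[name] = f"reflected: {anchor:g} - value"
        else:  # target_100
            out[:, j] = np.abs(100.0 - col)
            audit[name] = "|100 - value|"
    return OrientedMatrix(tuple(sub.index), tuple(names), out, audit)


@dataclass
class HasseDiagram:
    """A partial order on equivalence-class representatives.

    ``order`` holds the strict pairs (s, t) meaning s < t (s better);
    ``covers`` the covering pairs of the transitive reduction, or ``None``
    until :func:`transitive_reduction` fills them.  The reflexive pairs are
    implied.  ``equivalence_classes`` maps each representative to all its
    members (itself included).
    """

    objects: tuple
    order: frozenset
    covers: frozenset | None = None
    equivalence_classes: dict = field(default_factory=dict)

    def __post_init__(self):
        objs = set(self.objects)
        if not self.equivalence_classes:
            self.equivalence_classes = {o: (o,) for o in self.objects}
        for s, t in self.order:
            if s not in objs or t not in objs:
                raise PosetError(f"order pair ({s!r}, {t!r}) outside objects")
            if s == t:
                raise PosetError("strict order must be irreflexive")
        strict = self.order
        for s, t in strict:
            if (t, s) in strict:
                raise PosetError(f"antisymmetry violated for ({s!r}, {t!r})")
            # transitivity check is O(|order| * n); cheap at the sizes used
        for s, t in strict:
            for u in objs:
                if (s, u) in strict and (u, t) in strict and (s, t) not in strict:
                    raise PosetError("order not transitive")

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def leq(self, s, t) -> bool:
        """s <= t in the (reflexive) order."""
        return s == t or (s, t) in self.order

    def comparable(self, s, t) -> bool:
        return s == t or (s, t) in self.order or (t, s) in self.order

    @property
    def members(self) -> tuple:
        """All original ids, across equivalence classes."""
        return tuple(m for rep in self.objects
                     for m in self.equivalence_classes[rep])

    def to_networkx(self, use_covers: bool = True) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.objects)
        edges = self.covers if (use_covers and self.covers is not None) else self.order
        g.add_edges_from(edges)
        return g


@dataclass(frozen=True)
class PosetSummary:
    """Structural descriptors of a Hasse diagram."""

    maximal: frozenset
    minimal: frozenset
    isolated: frozenset
    levels: dict
    height: int
    width: int


def build_order(matrix: OrientedMatrix) -> HasseDiagram:
    """Dominance order: s <= t iff y_r(s) <= y_r(t) for every variable r.

    Rows equal on all variables collapse into one equivalence class whose
    representative is the first member in row order.
    """
    ids = matrix.procedure_ids
    vals = matrix.values
    # leq[i, j]: row i <= row j on every coordinate
    leq = (vals[:, None, :] <= vals[None, :, :]).all(axis=2)
    equal = leq & leq.T

    classes: dict = {}
    rep_of: dict[int, int] = {}
    for i in range(len(ids)):
        for j in range(i):
            if equal[i, j]:
                rep_of[i] = rep_of[j]
                break
        else:
            rep_of[i] = i
    for i, r in rep_of.items():
        classes.setdefault(ids[r], []).append(ids[i])

    reps = [i for i in range(len(ids)) if rep_of[i] == i]
    strict = frozenset(
        (ids[i], ids[j])
        for i in reps for j in reps
        if i != j and leq[i, j] and not equal[i, j]
    )
    objects = tuple(ids[i] for i in reps)
    return HasseDiagram(
        objects, strict,
        equivalence_classes={r: tuple(v) for r, v in classes.items()},
    )


def transitive_reduction(diagram: HasseDiagram) -> HasseDiagram:
    """Fill the covering relation: the minimal edge set whose transitive
    closure is the strict order (the edges drawn in a Hasse diagram)."""
    g = nx.DiGraph()
    g.add_nodes_from(diagram.objects)
    g.add_edges_from(diagram.order)
    if not nx.is_directed_acyclic_graph(g):
        raise PosetError("cycle in strict order; equivalence merge failed")
    covers = frozenset(nx.transitive_reduction(g).edges())
    return HasseDiagram(
        diagram.objects, diagram.order, covers,
        dict(diagram.equivalence_classes),
    )


def _require_covers(diagram: HasseDiagram) -> frozenset:
    if diagram.covers is None:
        raise PosetError("covers not computed; call transitive_reduction first")
    return diagram.covers


def extremal_objects(diagram: HasseDiagram):
    """(maximal, minimal, isolated): objects with no cover above / below /
    either — isolated objects are comparable to nothing."""
    covers = _require_covers(diagram)
    has_above = {s for s, _ in covers}
    has_below = {t for _, t in covers}
    maximal = frozenset(o for o in diagram.objects if o not in has_above)
    minimal = frozenset(o for o in diagram.objects if o not in has_below)
    return maximal, minimal, maximal & minimal


def assign_levels(diagram: HasseDiagram) -> dict:
    """Longest-chain layering from the bottom: minimal objects get level 1
    (the green end); level(x) = 1 + max level among objects x covers."""
    covers = _require_covers(diagram)
    g = diagram.to_networkx()
    levels: dict = {}
    for node in nx.topological_sort(g):
        below = [levels[s] for s, t in covers if t == node]
        levels[node] = 1 + max(below, default=0)
    return levels


def height_width(diagram: HasseDiagram) -> tuple[int, int]:
    """Height = number of objects in the longest chain; width = size of the
    largest antichain, exact via Dilworth's chain-cover / bipartite matching
    duality."""
    levels = assign_levels(diagram)
    height = max(levels.values())
    n = diagram.n_objects
    # Dilworth: width = minimum chain cover = n - maximum matching in the
    # bipartite graph with an edge (u, v) for every strict pair u < v.
    g = nx.Graph()
    left = {o: ("L", o) for o in diagram.objects}
    right = {o: ("R", o) for o in diagram.objects}
    g.add_nodes_from(left.values(), bipartite=0)
    g.add_nodes_from(right.values(), bipartite=1)
    for s, t in diagram.order:
        g.add_edge(left[s], right[t])
    matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=set(left.values()))
    width = n - len(matching) // 2
    return height, width


def summarize(diagram: HasseDiagram) -> PosetSummary:
    maximal, minimal, isolated = extremal_objects(diagram)
    levels = assign_levels(diagram)
    height, width = height_width(diagram)
    return PosetSummary(maximal, minimal, isolated, levels, height, width)


def hasse_from_table(
    table: ProcedureTable, variable_set: Iterable[str]
) -> tuple[HasseDiagram, OrientedMatrix]:
    """Convenience: orient -> build order -> transitive reduction."""
    matrix = orient_matrix(table, variable_set)
    return transitive_reduction(build_order(matrix)), matrix


# ------------------------------------------------------------------ export

def to_dot(diagram: HasseDiagram, levels: Mapping | None = None) -> str:
    """Graphviz DOT of the covering relation; nodes carry their level and
    equivalence-class members, edges point upward (worse)."""
    covers = _require_covers(diagram)
    levels = levels or assign_levels(diagram)
    lines = ["digraph hasse {", "  rankdir=BT;"]
    for o in diagram.objects:
        members = diagram.equivalence_classes[o]
        label = "{" + ",".join(str(m) for m in members) + "}" \
            if len(members) > 1 else str(o)
        lines.append(
            f'  "{o}" [label="{label}", level={levels[o]}];'
        )
    by_level: dict[int, list] = {}
    for o, lv in levels.items():
        by_level.setdefault(lv, []).append(o)
    for lv, objs in sorted(by_level.items()):
        same = " ".join(f'"{o}";' for o in objs)
        lines.append(f"  {{ rank=same; {same} }}")
    for s, t in sorted(covers, key=str):
        lines.append(f'  "{s}" -> "{t}";')
    lines.append("}")
    return "\n".join(lines)


def write_graphml(diagram: HasseDiagram, path) -> None:
    g = diagram.to_networkx()
    levels = assign_levels(diagram)
    for o in g.nodes:
        g.nodes[o]["level"] = int(levels[o])
        g.nodes[o]["members"] = ",".join(
            str(m) for m in diagram.equivalence_classes[o]
        )
    nx.write_graphml(nx.relabel_nodes(g, {o: str(o) for o in g.nodes}), path)


def write_cover_matrix(diagram: HasseDiagram, path) -> None:
    """Covering relation as a 0/1 CSV matrix (rows cover columns... rows
    covered-by columns: entry [s, t] = 1 iff s is covered by t)."""
    covers = _require_covers(diagram)
    objs = list(diagram.objects)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + [str(o) for o in objs])
        for s in objs:
            writer.writerow(
                [str(s)] + [1 if (s, t) in covers else 0 for t in objs]
            )
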