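"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own algorithms: the
transitive closure is Warshall's loop, average ranks come from full
permutation enumeration, and the maximum antichain from exhaustive subset
search.  They anchor the property tests for the order-theoretic code.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from greenrank.poset import HasseDiagram, transitive_reduction
from greenrank.simulate import random_poset


# ------------------------------------------------------------- oracles

def oracle_closure(objects, pairs) -> frozenset:
    """Transitive closure of strict pairs (Warshall)."""
    objects = list(objects)
    rel = {(s, t) for s, t in pairs}
    for k in objects:
        for i in objects:
            for j in objects:
                if (i, k) in rel and (k, j) in rel:
                    rel.add((i, j))
    return frozenset(rel)


def oracle_average_ranks(objects, strict) -> dict:
    """Mean position of each object over all order-respecting
    permutations, by exhaustive enumeration."""
    objects = list(objects)
    sums = {o: 0 for o in objects}
    count = 0
    for perm in itertools.permutations(objects):
        pos = {o: i for i, o in enumerate(perm)}
        if all(pos[s] < pos[t] for s, t in strict):
            count += 1
            for i, o in enumerate(perm):
                sums[o] += i + 1
    assert count > 0
    return {o: sums[o] / count for o in objects}


def oracle_count_extensions(objects, strict) -> int:
    count = 0
    for perm in itertools.permutations(objects):
        pos = {o: i for i, o in enumerate(perm)}
        if all(pos[s] < pos[t] for s, t in strict):
            count += 1
    return count


def oracle_max_antichain(objects, strict) -> int:
    """Largest pairwise-incomparable subset, exhaustively."""
    objects = list(objects)
    comparable = {(s, t) for s, t in strict} | {(t, s) for s, t in strict}
    best = 0
    for r in range(len(objects), 0, -1):
        for subset in itertools.combinations(objects, r):
            if all(
                (a, b) not in comparable
                for a, b in itertools.combinations(subset, 2)
            ):
                return r
    return best


# ------------------------------------------------------------- fixtures

def chain(n: int) -> HasseDiagram:
    ids = tuple(range(1, n + 1))
    strict = frozenset(
        (i, j) for i in ids for j in ids if i < j
    )
    return transitive_reduction(HasseDiagram(ids, strict))


def antichain(n: int) -> HasseDiagram:
    return transitive_reduction(
        HasseDiagram(tuple(range(1, n + 1)), frozenset())
    )


def diamond() -> HasseDiagram:
    strict = frozenset({("a", "b"), ("a", "c"), ("a", "d"),
                        ("b", "d"), ("c", "d")})
    return transitive_reduction(HasseDiagram(("a", "b", "c", "d"), strict))


@pytest.fixture
def small_posets():
    """A spread of named small posets."""
    v_poset = transitive_reduction(
        HasseDiagram(("a", "b", "c"), frozenset({("a", "c"), ("b", "c")}))
    )
    return {
        "chain5": chain(5),
        "antichain4": antichain(4),
        "diamond": diamond(),
        "v": v_poset,
    }


@pytest.fixture
def random_posets():
    """50 seeded random posets with up to 8 objects."""
    rng = np.random.default_rng(20160401)
    out = []
    for _ in range(50):
        n = int(rng.integers(2, 9))
        p = float(rng.uniform(0.1, 0.6))
        out.append(random_poset(n, p, rng=rng))
    return out
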