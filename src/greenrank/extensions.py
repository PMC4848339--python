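"""Average ranks over linear extensions of a partial order.

A linear extension is a total order consistent with every relation of the
poset; an object's averaged rank is its mean position over the set of
extensions.  The number of extensions grows like N! in the worst case, so
exact computation (recursion over the lattice of order ideals, bitmask
dynamic programming) is restricted to small posets; larger ones are handled
by the Bubley-Dyer Markov chain, a lazy random walk on extensions via
adjacent transpositions whose stationary distribution is uniform.

Equivalence classes of tied procedures enter the ranking as single objects;
members inherit their representative's averaged rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ExactSizeError, PosetError, ValidationError
from .poset import HasseDiagram

#: Largest poset handled exactly by default.  Exact average ranks walk the
#: lattice of order ideals, which has up to 2^N elements (antichain worst
#: case); 20 keeps that comfortably within memory and seconds.
EXACT_THRESHOLD_DEFAULT = 20


@dataclass(frozen=True)
class RankVector:
    """Averaged ranks per object (class representative), in [1, N].

    Invariants: the ranks of the N representatives sum to N(N+1)/2, and
    s < t in the order implies rank(s) < rank(t) (for the exact method;
    the sampled method satisfies it in expectation).
    """

    average_rank: dict
    method: str  # "exact" | "sampled"
    n_samples: int | None = None
    seed: int | None = None

    def expanded(self, diagram: HasseDiagram) -> dict:
        """Ranks for every original id; class members inherit their
        representative's rank."""
        out = {}
        for rep, rank in self.average_rank.items():
            for member in diagram.equivalence_classes[rep]:
                out[member] = rank
        return out

    def to_rows(self):
        return [
            {
                "id": obj, "average_rank": rank, "method": self.method,
                "n_samples": self.n_samples, "seed": self.seed,
            }
            for obj, rank in self.average_rank.items()
        ]


def _bitmask_poset(diagram: HasseDiagram):
    """Objects as indices 0..n-1 with a strict-predecessor bitmask each."""
    objs = list(diagram.objects)
    idx = {o: i for i, o in enumerate(objs)}
    pred = [0] * len(objs)
    for s, t in diagram.order:
        pred[idx[t]] |= 1 << idx[s]
    return objs, pred


def _ideal_counts(n: int, pred: list[int]) -> dict[int, int]:
    """f[S] = number of linear extensions of the sub-poset induced by the
    order ideal S (elements of S placed in positions 1..|S|)."""
    f = {0: 1}
    frontier = [0]
    for _ in range(n):
        nxt: dict[int, int] = {}
        for S in frontier:
            fS = f[S]
            for i in range(n):
                bit = 1 << i
                if not (S & bit) and (pred[i] & S) == pred[i]:
                    T = S | bit
                    if T in nxt:
                        nxt[T] += fS
                    else:
                        nxt[T] = fS
        f.update(nxt)
        frontier = list(nxt)
    return f


def count_linear_extensions(
    diagram: HasseDiagram, exact_threshold: int = EXACT_THRESHOLD_DEFAULT
) -> int:
    """Exact number of linear extensions, by order-ideal recursion.

    Refuses posets with more than ``exact_threshold`` objects — use
    :func:`bubley_dyer_average_ranks` for average ranks of large posets.
    """
    n = diagram.n_objects
    if n > exact_threshold:
        raise ExactSizeError(
            f"{n} objects exceeds the exact threshold {exact_threshold}; "
            f"use the Bubley-Dyer sampler for average ranks"
        )
    objs, pred = _bitmask_poset(diagram)
    f = _ideal_counts(n, pred)
    return f[(1 << n) - 1]


def exact_average_ranks(
    diagram: HasseDiagram, exact_threshold: int = EXACT_THRESHOLD_DEFAULT
) -> RankVector:
    """Exact averaged rank of every object over all linear extensions.

    Uses two passes over the ideal lattice: f[S] counts extensions of the
    ideal S, h[S] counts extensions of its complement filter; an object x
    sits at position |S|+1 in f[S] * h[S | {x}] extensions for each ideal S
    to which x is addable, so its averaged rank is the f*h-weighted mean of
    those positions.
    """
    n = diagram.n_objects
    if n > exact_threshold:
        raise ExactSizeError(
            f"{n} objects exceeds the exact threshold {exact_threshold}"
        )
    if n == 0:
        raise PosetError("empty diagram")
    objs, pred = _bitmask_poset(diagram)
    full = (1 << n) - 1
    f = _ideal_counts(n, pred)

    # h[S]: number of linear extensions of the complement of ideal S.
    h = {full: 1}
    by_size: list[list[int]] = [[] for _ in range(n + 1)]
    for S in f:
        by_size[S.bit_count()].append(S)
    for size in range(n - 1, -1, -1):
        for S in by_size[size]:
            total = 0
            for i in range(n):
                bit = 1 << i
                if not (S & bit) and (pred[i] & S) == pred[i]:
                    total += h[S | bit]
            h[S] = total

    e = f[full]
    pos_sum = [0] * n
    for S, fS in f.items():
        k = S.bit_count() + 1
        for i in range(n):
            bit = 1 << i
            if not (S & bit) and (pred[i] & S) == pred[i]:
                pos_sum[i] += k * fS * h[S | bit]
    ranks = {objs[i]: pos_sum[i] / e for i in range(n)}
    return RankVector(ranks, method="exact")


def _initial_extension(diagram: HasseDiagram) -> list[int]:
    """Deterministic topological order of object indices."""
    objs, pred = _bitmask_poset(diagram)
    n = len(objs)
    placed = 0
    out: list[int] = []
    remaining = set(range(n))
    while remaining:
        for i in sorted(remaining):
            if (pred[i] & placed) == pred[i]:
                out.append(i)
                placed |= 1 << i
                remaining.discard(i)
                break
        else:
            raise PosetError("cycle in strict order")
    return out


def bubley_dyer_average_ranks(
    diagram: HasseDiagram,
    n_samples: int = 10_000,
    burn_in: int | None = None,
    thinning: int | None = None,
    seed: int | None = None,
) -> RankVector:
    """Averaged ranks estimated by the Bubley-Dyer chain.

    The chain state is a linear extension.  Each step draws a position p
    uniformly from 1..N-1 and, with probability 1/2 (the lazy coin that
    guarantees convergence), swaps the elements at p and p+1 if they are
    incomparable.  States are recorded every ``thinning`` steps after
    ``burn_in`` steps; defaults are burn_in = N^3 and thinning = N.
    Identical (input, parameters, seed) give identical output.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if seed is None:
        raise ValidationError("a seed is required; no implicit randomness")
    n = diagram.n_objects
    if n == 0:
        raise PosetError("empty diagram")
    objs = list(diagram.objects)
    state = np.array(_initial_extension(diagram), dtype=np.intp)

    if n == 1:
        return RankVector({objs[0]: 1.0}, "sampled", n_samples, seed)

    burn_in = n ** 3 if burn_in is None else burn_in
    thinning = n if thinning is None else thinning

    idx = {o: i for i, o in enumerate(objs)}
    comparable = np.zeros((n, n), dtype=bool)
    for s, t in diagram.order:
        comparable[idx[s], idx[t]] = True
        comparable[idx[t], idx[s]] = True

    rng = np.random.default_rng(seed)
    total_steps = burn_in + n_samples * thinning
    rank_sum = np.zeros(n, dtype=float)
    positions_template = np.arange(1, n + 1, dtype=float)

    chunk = 1 << 16
    done = 0
    recorded = 0
    next_record = burn_in + thinning
    while done < total_steps:
        m = min(chunk, total_steps - done)
        ps = rng.integers(0, n - 1, size=m)
        coins = rng.random(size=m) < 0.5
        for k in range(m):
            if coins[k]:
                p = ps[k]
                a, b = state[p], state[p + 1]
                if not comparable[a, b]:
                    state[p], state[p + 1] = b, a
            done += 1
            if done == next_record:
                rank_sum[state] += positions_template
                recorded += 1
                next_record += thinning
                if recorded == n_samples:
                    next_record = -1
    ranks = rank_sum / n_samples
    return RankVector(
        {objs[i]: float(ranks[i]) for i in range(n)},
        "sampled", n_samples, seed,
    )


def average_ranks(
    diagram: HasseDiagram,
    exact_threshold: int = EXACT_THRESHOLD_DEFAULT,
    n_samples: int = 10_000,
    burn_in: int | None = None,
    thinning: int | None = None,
    seed: int | None = None,
) -> RankVector:
    """Exact ranks when the poset is small enough, sampled otherwise."""
    if diagram.n_objects <= exact_threshold:
        return exact_average_ranks(diagram, exact_threshold)
    return bubley_dyer_average_ranks(
        diagram, n_samples=n_samples, burn_in=burn_in,
        thinning=thinning, seed=seed,
    )
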