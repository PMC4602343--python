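"""Independent brute-force references for the expectation formulas.

Every closed-form expectation in :mod:`dcjmoments.moments` is validated
on small instances against an exact computation here: the random
transposition walk via its exact cycle-type (conjugacy class) Markov
chain, the DCJ chain via full enumeration of perfect matchings, and the
random-graph component count via Monte-Carlo.  The exact oracles use
rational arithmetic throughout - no floats - so agreement is literal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "exact_transposition_cycle_expectation",
    "transposition_cycle_expectation_by_enumeration",
    "exact_small_genome_breakpoint_expectation",
    "montecarlo_components",
    "MonteCarloResult",
]

_MAX_PARTITION_N = 10
_MAX_MATCHING_N = 4


def _partitions(n: int) -> list[tuple[int, ...]]:
    """All integer partitions of n, parts descending."""

    def gen(rest: int, mx: int):
        if rest == 0:
            yield ()
            return
        for first in range(min(rest, mx), 0, -1):
            for tail in gen(rest - first, first):
                yield (first,) + tail

    return list(gen(n, n))


def _partition_step(
    dist: dict[tuple[int, ...], Fraction], n: int
) -> dict[tuple[int, ...], Fraction]:
    """One uniform random transposition applied to a cycle-type distribution.

    A transposition on elements in distinct cycles of sizes i, j merges
    them; on two elements of one size-i cycle it splits it into sizes
    (s, i-s), with i pairs giving each unordered split s != i-s and i/2
    pairs giving the split (i/2, i/2).
    """
    pairs = math.comb(n, 2)
    out: dict[tuple[int, ...], Fraction] = {}

    def add(p: tuple[int, ...], w: Fraction) -> None:
        out[p] = out.get(p, Fraction(0)) + w

    for part, w in dist.items():
        parts = list(part)
        m = len(parts)
        # merges: unordered index pairs of distinct cycles
        for ii in range(m):
            for jj in range(ii + 1, m):
                prob = Fraction(parts[ii] * parts[jj], pairs)
                merged = parts[:ii] + parts[ii + 1 : jj] + parts[jj + 1 :] + [
                    parts[ii] + parts[jj]
                ]
                add(tuple(sorted(merged, reverse=True)), w * prob)
        # splits within one cycle
        for ii in range(m):
            i = parts[ii]
            if i < 2:
                continue
            rest = parts[:ii] + parts[ii + 1 :]
            for s in range(1, i // 2 + 1):
                npairs = i // 2 if 2 * s == i else i
                prob = Fraction(npairs, pairs)
                add(tuple(sorted(rest + [s, i - s], reverse=True)), w * prob)
    return out


def exact_transposition_cycle_expectation(n: int, k: int) -> Fraction:
    """Exact E(number of cycles) of a permutation obtained from the
    identity on n elements by k uniform random transpositions, by
    evolving the exact distribution over cycle types."""
    if n > _MAX_PARTITION_N:
        raise ValueError(f"partition-chain oracle limited to n <= {_MAX_PARTITION_N}")
    if n < 2:
        raise ValueError("need n >= 2")
    dist: dict[tuple[int, ...], Fraction] = {tuple([1] * n): Fraction(1)}
    for _ in range(k):
        dist = _partition_step(dist, n)
    total = sum(dist.values())
    if total != 1:
        raise AssertionError(f"probability leak: weights sum to {total}")
    return sum((w * len(p) for p, w in dist.items()), Fraction(0))


def transposition_cycle_expectation_by_enumeration(n: int, k: int) -> Fraction:
    """Same expectation by literal enumeration over S_n (n! states); an
    independent derivation guarding the partition-chain oracle itself."""
    if n > 6:
        raise ValueError("permutation enumeration limited to n <= 6")
    perms = list(itertools.permutations(range(n)))
    index = {p: i for i, p in enumerate(perms)}
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def cycles(p: tuple[int, ...]) -> int:
        seen = [False] * n
        c = 0
        for s in range(n):
            if not seen[s]:
                c += 1
                while not seen[s]:
                    seen[s] = True
                    s = p[s]
        return c

    dist = {index[tuple(range(n))]: Fraction(1)}
    w_each = Fraction(1, len(pairs))
    for _ in range(k):
        nxt: dict[int, Fraction] = {}
        for si, w in dist.items():
            p = list(perms[si])
            for i, j in pairs:
                q = p[:]
                q[i], q[j] = q[j], q[i]
                ti = index[tuple(q)]
                nxt[ti] = nxt.get(ti, Fraction(0)) + w * w_each
        dist = nxt
    return sum((w * cycles(perms[si]) for si, w in dist.items()), Fraction(0))


# ---------------------------------------------------------------------------
# DCJ chain over all perfect matchings
# ---------------------------------------------------------------------------


def _perfect_matchings(verts: tuple[int, ...]) -> list[frozenset[tuple[int, int]]]:
    if not verts:
        return [frozenset()]
    first, rest = verts[0], verts[1:]
    out = []
    for i, v in enumerate(rest):
        sub = rest[:i] + rest[i + 1 :]
        for m in _perfect_matchings(sub):
            out.append(m | {(first, v)})
    return out


def exact_small_genome_breakpoint_expectation(n: int, a: int, k: int) -> Fraction:
    """Exact E(breakpoints) after k uniform DCJs, by evolving the full
    distribution over the (2n-1)!! perfect matchings on 2n vertices.

    The starting matching pairs vertices consecutively; its first ``a``
    adjacencies are taken as observed, and B(M) counts how many of them
    are absent from M.
    """
    if n > _MAX_MATCHING_N:
        raise ValueError(f"matching-chain oracle limited to n <= {_MAX_MATCHING_N}")
    if not 0 <= a <= n:
        raise ValueError("need 0 <= a <= n")
    verts = tuple(range(2 * n))
    states = _perfect_matchings(verts)
    index = {m: i for i, m in enumerate(states)}
    start = frozenset((2 * i, 2 * i + 1) for i in range(n))
    observed = sorted(start)[:a]
    n_moves = n * (n - 1)
    w_each = Fraction(1, n_moves)

    # precompute transitions
    transitions: list[list[int]] = []
    for m in states:
        edges = sorted(m)
        outs = []
        for i, (A, B) in enumerate(edges):
            for C, D in edges[i + 1 :]:
                for new1, new2 in (
                    (tuple(sorted((A, C))), tuple(sorted((B, D)))),
                    (tuple(sorted((A, D))), tuple(sorted((B, C)))),
                ):
                    m2 = (m - {(A, B), (C, D)}) | {new1, new2}
                    outs.append(index[m2])
        assert len(outs) == n_moves
        transitions.append(outs)

    dist: dict[int, Fraction] = {index[start]: Fraction(1)}
    for _ in range(k):
        nxt: dict[int, Fraction] = {}
        for si, w in dist.items():
            for ti in transitions[si]:
                nxt[ti] = nxt.get(ti, Fraction(0)) + w * w_each
        dist = nxt
    if sum(dist.values()) != 1:
        raise AssertionError("probability leak in matching chain")
    bp = {i: sum(1 for e in observed if e not in m) for i, m in enumerate(states)}
    return sum((w * bp[si] for si, w in dist.items()), Fraction(0))


# ---------------------------------------------------------------------------
# Monte-Carlo components of the growing random multigraph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonteCarloResult:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    replicates: int


def montecarlo_components(
    n: int,
    k: int,
    replicates: int = 1000,
    seed: int | None = None,
    ci: float = 0.99,
) -> MonteCarloResult:
    """Mean component count of an n-vertex multigraph after k uniform
    random edges (parallel edges allowed), with a normal-approximation
    confidence interval."""
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    # z for two-sided ci without scipy: 0.99 -> 2.5758, 0.95 -> 1.96
    z = {0.99: 2.5758293035489004, 0.95: 1.959963984540054}.get(ci)
    if z is None:
        raise ValueError("ci must be 0.95 or 0.99")
    counts = np.empty(replicates)
    for r in range(replicates):
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        comp = n
        us = rng.integers(0, n, size=k)
        vs = rng.integers(0, n - 1, size=k)
        for u, v in zip(us, vs):
            if v >= u:
                v += 1  # uniform unordered pair of distinct vertices
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
                comp -= 1
        counts[r] = comp
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    half = z * sd / math.sqrt(replicates)
    return MonteCarloResult(mean, sd, mean - half, mean + half, replicates)
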