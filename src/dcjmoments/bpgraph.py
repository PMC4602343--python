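"""Breakpoint graphs of two genomes and the parsimony DCJ distance.

The breakpoint graph is the union of the adjacency matchings of two
genomes on the same gene set: a disjoint set of cycles alternating
between the adjacencies of genome 1 and genome 2.  Restricted to the
observed adjacencies the union decomposes into cycles and paths; the
*observed* breakpoint graph closes every path with telomeric/fictional
vertices so as to maximize the cycle count, while the *real* breakpoint
graph uses the true correspondence of telomeric and fictional vertices
(known only when the evolutionary history is tracked, e.g. by the
simulator).

Cycle lengths are counted as the number of adjacencies of ONE genome on
the cycle, so a trivial cycle (two parallel edges) has length 1 and the
lengths of all cycles sum to n.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome import AugmentedGenome

__all__ = [
    "BreakpointGraph",
    "observed_breakpoint_graph",
    "real_breakpoint_graph",
    "dcj_distance",
    "cycle_count_gap",
]


@dataclass(frozen=True)
class BreakpointGraph:
    """Cycle-length multiset of a breakpoint graph.

    ``cycles`` maps cycle length -> multiplicity; ``kind`` is "observed"
    or "real"; ``n`` is the adjacency count of either genome.
    """

    cycles: tuple[tuple[int, int], ...]  # sorted (length, multiplicity)
    kind: str
    n: int

    @classmethod
    def from_lengths(cls, lengths: list[int], kind: str, n: int) -> "BreakpointGraph":
        counts = Counter(lengths)
        total = sum(lengths)
        if total != n:
            raise ValueError(f"cycle lengths sum to {total}, expected n={n}")
        return cls(cycles=tuple(sorted(counts.items())), kind=kind, n=n)

    @property
    def n_cycles(self) -> int:
        return sum(m for _, m in self.cycles)

    @property
    def distance(self) -> int:
        return self.n - self.n_cycles

    def cycle_lengths(self) -> list[int]:
        out: list[int] = []
        for length, mult in self.cycles:
            out.extend([length] * mult)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(length, mult, self.kind) for length, mult in self.cycles],
            columns=["cycle_length", "multiplicity", "graph_kind"],
        )


def _check_pair(G1: AugmentedGenome, G2: AugmentedGenome) -> None:
    if not G1.same_gene_set(G2):
        raise ValueError("genomes are on different gene sets")


def observed_cycle_lengths(
    nbr1: list[int], nbr2: list[int], g: int, n: int
) -> list[int]:
    """Cycle lengths of the cycle-maximizing common augmentation, from
    observed-adjacency partner arrays (0 marks a missing edge).

    The union of the observed adjacencies decomposes into cycles and
    paths.  Each path is closed into its own cycle: an even-edge path by
    one shared telomeric vertex, an odd-edge path (end edges in the same
    genome) by two fictional vertices and a fictional adjacency of that
    genome.  Closing all paths independently needs ``n - a1 - t1``
    genome-1 fictional adjacencies for the odd genome-1 paths; if fewer
    are available, pairs of opposite-genome odd paths are chained
    through shared telomeric vertices instead, each chaining costing one
    cycle (the cheapest repair, so the count stays maximal).  Remaining
    adjacency budget becomes trivial cycles of two parallel edges.
    """
    lengths: list[int] = []
    odd1: list[int] = []  # edge counts of odd paths with genome-1 end edges
    odd2: list[int] = []
    n_even = 0
    a1 = 0
    visited = bytearray(2 * g + 1)
    for start in range(1, 2 * g + 1):
        if nbr1[start]:
            a1 += 1  # each genome-1 edge counted from both ends; halved below
        if visited[start] or (nbr1[start] and nbr2[start]):
            continue
        visited[start] = 1
        edges = 0
        cur = start
        use1 = nbr1[start] != 0
        first_is_1 = use1
        while True:
            nxt = nbr1[cur] if use1 else nbr2[cur]
            if nxt == 0:
                break
            edges += 1
            visited[nxt] = 1
            cur = nxt
            use1 = not use1
        if edges % 2 == 0:
            n_even += 1
            lengths.append(edges // 2 + 1)
        elif first_is_1:
            odd1.append(edges)
        else:
            odd2.append(edges)
    for start in range(1, 2 * g + 1):  # pure observed cycles
        if visited[start]:
            continue
        edges = 0
        cur = start
        use1 = True
        while True:
            visited[cur] = 1
            cur = nbr1[cur] if use1 else nbr2[cur]
            edges += 1
            use1 = not use1
            if cur == start and use1:
                break
        lengths.append(edges // 2)

    a1 //= 2
    t1 = 2 * g - 2 * a1
    fict1 = n - a1 - t1  # genome-1 fictional-adjacency budget
    merges = max(0, len(odd1) - fict1)
    if merges > len(odd2) or fict1 < 0:
        raise ValueError(
            "no common augmentation with this n: increase f "
            f"(need {len(odd1) - len(odd2)} more fictional adjacency pairs)"
        )
    for _ in range(merges):  # chain an odd1 with an odd2 path: one cycle
        e1, e2 = odd1.pop(), odd2.pop()
        lengths.append((e1 + e2) // 2 + 2)
    lengths.extend((e + 3) // 2 for e in odd1)
    lengths.extend((e + 3) // 2 for e in odd2)
    trivial = fict1 - (len(odd1) + merges) + merges  # = fict1 - len(odd1)
    lengths.extend([1] * trivial)
    return lengths


def observed_breakpoint_graph(
    G1: AugmentedGenome,
    G2: AugmentedGenome,
    n: int | None = None,
) -> BreakpointGraph:
    """Cycle-maximizing breakpoint graph built from observed adjacencies
    only (see :func:`observed_cycle_lengths` for the construction).

    ``n`` defaults to the common adjacency count of the augmented inputs;
    pass it explicitly when comparing non-augmented genomes.
    """
    _check_pair(G1, G2)
    if n is None:
        n1, n2 = G1.n, G2.n
        if G1.is_perfect_matching() and G2.is_perfect_matching():
            if n1 != n2:
                raise ValueError(f"augmented genomes disagree on n ({n1} != {n2})")
            n = n1
        else:
            raise ValueError("pass n explicitly for non-augmented genomes")
    g = G1.g
    nbr1 = [0] * (2 * g + 1)  # 0 = no edge
    nbr2 = [0] * (2 * g + 1)
    for u, v in G1.observed_adjacencies:
        nbr1[u], nbr1[v] = v, u
    for u, v in G2.observed_adjacencies:
        nbr2[u], nbr2[v] = v, u
    lengths = observed_cycle_lengths(nbr1, nbr2, g, n)
    return BreakpointGraph.from_lengths(lengths, kind="observed", n=n)


def real_breakpoint_graph(
    G1: AugmentedGenome,
    G2: AugmentedGenome,
    correspondence: dict[int, int] | None = None,
) -> BreakpointGraph:
    """Breakpoint graph of the two full augmented matchings.

    Both genomes must be augmented on the same vertex set, as produced by
    the simulator (DCJs never change the vertex set).  ``correspondence``
    optionally relabels G2's telomeric/fictional vertex ids to G1's,
    expressing which shared vertex closes which path; it must cover all
    of G2's non-observed vertices when given.
    """
    _check_pair(G1, G2)
    if G1.n != G2.n:
        raise ValueError(f"augmented genomes disagree on n ({G1.n} != {G2.n})")
    non_obs1 = G1.telomeric | G1.fictional
    non_obs2 = G2.telomeric | G2.fictional
    adj2 = G2.adjacencies
    if correspondence is not None:
        missing = non_obs2 - set(correspondence)
        if missing:
            raise ValueError(f"correspondence misses vertices {sorted(missing)[:5]}")
        if set(correspondence.values()) != non_obs1:
            raise ValueError("correspondence is not a bijection onto G1's vertices")
        relabel = lambda v: correspondence.get(v, v)  # noqa: E731
        adj2 = frozenset(
            tuple(sorted((relabel(u), relabel(v)))) for u, v in adj2
        )
    elif non_obs1 != non_obs2:
        raise ValueError("genomes have different non-observed vertex sets; "
                         "supply a correspondence")

    verts = sorted(set(G1.observed_vertices) | non_obs1)
    nbr1: dict[int, int] = {}
    nbr2: dict[int, int] = {}
    for u, v in G1.adjacencies:
        nbr1[u], nbr1[v] = v, u
    for u, v in adj2:
        nbr2[u], nbr2[v] = v, u

    lengths: list[int] = []
    visited: set[int] = set()
    for start in verts:
        if start in visited:
            continue
        edges = 0
        cur = start
        use1 = True
        while True:
            visited.add(cur)
            nxt = nbr1[cur] if use1 else nbr2[cur]
            edges += 1
            use1 = not use1
            cur = nxt
            if cur == start and use1:
                break
        lengths.append(edges // 2)
    return BreakpointGraph.from_lengths(lengths, kind="real", n=G1.n)


def dcj_distance(bg: BreakpointGraph) -> int:
    """n minus the cycle count; on the observed graph this is the
    parsimony DCJ distance."""
    return bg.distance


def cycle_count_gap(observed_bg: BreakpointGraph, real_bg: BreakpointGraph) -> int:
    """Observed-graph cycles minus real-graph cycles (always >= 0)."""
    return observed_bg.n_cycles - real_bg.n_cycles
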