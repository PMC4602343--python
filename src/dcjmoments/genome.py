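"""Genomes as matchings on gene extremities.

A genome with ``g`` genes is a graph on the ``2g`` *gene extremities*
(head and tail of each oriented gene) carrying two matchings: the gene
arcs (tail -> head of each gene) and the *adjacencies* linking extremities
that are consecutive on a chromosome.  Extremities in no adjacency are
*telomeres*.  For the DCJ Markov chain the genome is *augmented*: every
telomere is matched to a fresh telomeric vertex, and an even number ``f``
of fictional vertices is added, matched pairwise, so that the adjacency
set becomes a perfect matching with ``n = 2g - a + f/2`` edges.

Vertex encoding: gene ``i`` (1-based) has tail ``2i - 1`` and head
``2i``; telomeric and fictional vertices take fresh ids above ``2g``.
Adjacencies are stored as sorted 2-tuples of vertex ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "head",
    "tail",
    "ModelParams",
    "AugmentedGenome",
    "build_genome",
    "augment",
    "apply_dcj",
    "enumerate_dcj_moves",
    "count_breakpoints",
    "random_genome",
    "GenomeFormatError",
]


class GenomeFormatError(ValueError):
    """Raised for malformed gene orders (duplicate/missing gene ids...)."""


def tail(gene: int) -> int:
    """Vertex id of the tail extremity of (positive) gene ``gene``."""
    return 2 * gene - 1


def head(gene: int) -> int:
    """Vertex id of the head extremity of (positive) gene ``gene``."""
    return 2 * gene


def _adj(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class ModelParams:
    """Parameters (g, a, f, n) of the DCJ model for one genome.

    g: number of genes; a: number of observed adjacencies; f: number of
    fictional vertices (even); n = 2g - a + f/2: total adjacency count.
    """

    g: int
    a: int
    f: int

    def __post_init__(self) -> None:
        if self.f < 0 or self.f % 2:
            raise ValueError(f"f must be even and non-negative, got {self.f}")
        if self.a > self.g:
            raise ValueError(f"a={self.a} exceeds g={self.g}")

    @property
    def n(self) -> int:
        return 2 * self.g - self.a + self.f // 2

    @property
    def telomeres(self) -> int:
        return 2 * self.g - 2 * self.a

    @classmethod
    def from_an(cls, a: int, n: int) -> "ModelParams":
        """Any (g, f) realizing the given observed/total adjacency counts
        (the expectation formulas depend on a and n only)."""
        if n < a:
            raise ValueError(f"need n >= a, got a={a}, n={n}")
        return cls(g=a, a=a, f=2 * (n - a))


@dataclass(frozen=True)
class AugmentedGenome:
    """A genome, possibly augmented to a perfect matching.

    ``adjacencies`` holds sorted vertex-id pairs.  ``telomeric`` and
    ``fictional`` are the ids of the non-observed vertices (empty before
    augmentation).  ``arcs`` maps each gene id to its (tail, head) vertex
    pair; arcs never take part in comparisons.
    """

    g: int
    adjacencies: frozenset[tuple[int, int]]
    telomeric: frozenset[int] = frozenset()
    fictional: frozenset[int] = frozenset()
    arcs: tuple[tuple[int, int], ...] = field(default=(), compare=False)

    # -- derived counts ------------------------------------------------
    @property
    def observed_vertices(self) -> range:
        return range(1, 2 * self.g + 1)

    def is_observed_vertex(self, v: int) -> bool:
        return 1 <= v <= 2 * self.g

    @property
    def observed_adjacencies(self) -> frozenset[tuple[int, int]]:
        lim = 2 * self.g
        return frozenset(p for p in self.adjacencies if p[1] <= lim)

    @property
    def a(self) -> int:
        return len(self.observed_adjacencies)

    @property
    def f(self) -> int:
        return len(self.fictional)

    @property
    def n(self) -> int:
        return len(self.adjacencies)

    @property
    def params(self) -> ModelParams:
        return ModelParams(g=self.g, a=self.a, f=self.f)

    @property
    def telomere_extremities(self) -> frozenset[int]:
        """Observed extremities not in any observed adjacency."""
        matched = {v for p in self.observed_adjacencies for v in p}
        return frozenset(v for v in self.observed_vertices if v not in matched)

    def adjacency_kind(self, pair: tuple[int, int]) -> str:
        u, v = pair
        obs = self.is_observed_vertex
        if obs(u) and obs(v):
            return "observed"
        if obs(u) or obs(v):
            return "telomeric"
        return "fictional"

    def is_perfect_matching(self) -> bool:
        verts = [v for p in self.adjacencies for v in p]
        expected = set(self.observed_vertices) | self.telomeric | self.fictional
        return len(verts) == len(set(verts)) and set(verts) == expected

    def validate(self) -> None:
        if not self.is_perfect_matching():
            raise ValueError("adjacencies are not a perfect matching of the vertex set")
        if self.telomeric & self.fictional:
            raise ValueError("telomeric and fictional vertex ids overlap")
        for v in self.telomeric | self.fictional:
            if self.is_observed_vertex(v):
                raise ValueError(f"vertex {v} is in the gene-extremity range")

    def same_gene_set(self, other: "AugmentedGenome") -> bool:
        return self.g == other.g


def build_genome(
    chromosomes: list[list[int]],
    circular: list[bool] | bool = False,
) -> AugmentedGenome:
    """Build the (non-augmented) genome of signed gene orders.

    Each chromosome is a list of signed gene ids; sign flips the gene's
    orientation.  Every gene id 1..g must appear exactly once overall.
    """
    if isinstance(circular, bool):
        circular = [circular] * len(chromosomes)
    if len(circular) != len(chromosomes):
        raise GenomeFormatError("circular flags do not match chromosome count")

    seen: set[int] = set()
    for chrom in chromosomes:
        for s in chrom:
            if s == 0:
                raise GenomeFormatError("gene id 0 is not allowed")
            gid = abs(s)
            if gid in seen:
                raise GenomeFormatError(f"duplicate gene id {gid}")
            seen.add(gid)
    g = len(seen)
    if seen != set(range(1, g + 1)):
        missing = sorted(set(range(1, g + 1)) - seen)[:5]
        raise GenomeFormatError(f"gene ids must be 1..{g}; missing {missing}")

    adjacencies: set[tuple[int, int]] = set()
    for chrom, circ in zip(chromosomes, circular):
        if not chrom:
            raise GenomeFormatError("empty chromosome")
        # left/right extremities of each signed gene
        ends = [
            (tail(abs(s)), head(abs(s))) if s > 0 else (head(abs(s)), tail(abs(s)))
            for s in chrom
        ]
        for (_, right), (left, _) in zip(ends, ends[1:]):
            adjacencies.add(_adj(right, left))
        if circ:
            adjacencies.add(_adj(ends[-1][1], ends[0][0]))

    arcs = tuple((tail(i), head(i)) for i in range(1, g + 1))
    return AugmentedGenome(g=g, adjacencies=frozenset(adjacencies), arcs=arcs)


def augment(genome: AugmentedGenome, f: int = 0) -> AugmentedGenome:
    """Augment with telomeric vertices (one per telomere) and ``f`` fictional
    vertices matched pairwise, yielding a perfect matching of n adjacencies.

    Fresh vertices take consecutive ids above the existing maximum; fictional
    vertices are paired consecutively (the pairing is a free choice of the
    model and this one is deterministic).
    """
    if f < 0 or f % 2:
        raise ValueError(f"f must be even and non-negative, got {f}")
    if genome.telomeric or genome.fictional:
        raise ValueError("genome is already augmented")
    telomeres = sorted(genome.telomere_extremities)
    nxt = 2 * genome.g + 1
    adjacencies = set(genome.adjacencies)
    telomeric: set[int] = set()
    for x in telomeres:
        adjacencies.add(_adj(x, nxt))
        telomeric.add(nxt)
        nxt += 1
    fictional = set(range(nxt, nxt + f))
    for i in range(nxt, nxt + f, 2):
        adjacencies.add((i, i + 1))
    out = AugmentedGenome(
        g=genome.g,
        adjacencies=frozenset(adjacencies),
        telomeric=frozenset(telomeric),
        fictional=frozenset(fictional),
        arcs=genome.arcs,
    )
    out.validate()
    return out


def apply_dcj(
    G: AugmentedGenome,
    adjacency1: tuple[int, int],
    adjacency2: tuple[int, int],
    choice: int,
) -> AugmentedGenome:
    """Apply one DCJ: replace adjacencies AB, CD by AC+BD (choice 0) or
    AD+BC (choice 1), with (A,B) and (C,D) the sorted forms of the inputs.
    """
    a1 = _adj(*adjacency1)
    a2 = _adj(*adjacency2)
    if a1 == a2:
        raise ValueError("a DCJ needs two distinct adjacencies")
    if a1 not in G.adjacencies or a2 not in G.adjacencies:
        raise ValueError("adjacency not present in genome")
    A, B = a1
    C, D = a2
    if choice == 0:
        new1, new2 = _adj(A, C), _adj(B, D)
    elif choice == 1:
        new1, new2 = _adj(A, D), _adj(B, C)
    else:
        raise ValueError("choice must be 0 or 1")
    adjacencies = (set(G.adjacencies) - {a1, a2}) | {new1, new2}
    return replace(G, adjacencies=frozenset(adjacencies))


def enumerate_dcj_moves(
    G: AugmentedGenome,
) -> list[tuple[tuple[int, int], tuple[int, int], int]]:
    """All n(n-1) equiprobable DCJ moves on ``G`` (pair of adjacencies plus
    one of two rewirings)."""
    adjs = sorted(G.adjacencies)
    moves = []
    for i, a1 in enumerate(adjs):
        for a2 in adjs[i + 1 :]:
            moves.append((a1, a2, 0))
            moves.append((a1, a2, 1))
    return moves


def count_breakpoints(G1: AugmentedGenome, G2: AugmentedGenome) -> int:
    """Number of observed adjacencies of ``G1`` absent from ``G2``.

    A breakpoint of G1 w.r.t. G2 is an observed adjacency AB of G1 such
    that A and B are not adjacent in G2; only observable data enters.
    """
    if not G1.same_gene_set(G2):
        raise ValueError("genomes are on different gene sets")
    return sum(1 for p in G1.observed_adjacencies if p not in G2.adjacencies)


def random_genome(
    g: int,
    telomere_count: int,
    f: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AugmentedGenome:
    """Uniformly random genome: match the 2g gene extremities at random,
    leaving exactly ``telomere_count`` of them unmatched, then augment
    with telomeric vertices and ``f`` fictional vertices.
    """
    if telomere_count < 0 or telomere_count % 2:
        raise ValueError("telomere_count must be even and non-negative")
    if telomere_count > 2 * g:
        raise ValueError("telomere_count exceeds 2g")
    if rng is None:
        rng = np.random.default_rng(seed)
    perm = rng.permutation(2 * g) + 1  # vertex ids 1..2g
    matched = perm[telomere_count:]
    adjacencies = frozenset(
        _adj(int(matched[i]), int(matched[i + 1])) for i in range(0, len(matched), 2)
    )
    arcs = tuple((tail(i), head(i)) for i in range(1, g + 1))
    genome = AugmentedGenome(g=g, adjacencies=adjacencies, arcs=arcs)
    return augment(genome, f=f)
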