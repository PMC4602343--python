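"""The uniform DCJ Markov chain, with coupled comparison processes.

At each step one of the n(n-1) equiprobable DCJs is applied to the
current augmented genome (an unordered pair of distinct adjacencies plus
a fair rewiring choice).  The simulator tracks, per step:

* B_k, the number of breakpoints of the start genome w.r.t. the current
  one (always recorded; O(1) per step);
* cycle counts of the real and observed breakpoint graphs against the
  start genome (optional; the real graph uses the simulator's knowledge
  of vertex identity through the DCJ history);
* the cycle count of a permutation coupled to the chain: when a DCJ cuts
  adjacencies mapped to elements ea and eb, the transposition (ea eb) is
  applied, and the two new adjacencies are remapped to ea and eb - after
  a breakpoint-graph fission, so as to respect the cycles; otherwise
  smallest adjacency to smallest element.  The coupling consumes no
  extra randomness: the rewiring bit already decides whether a
  same-cycle DCJ splits its cycle.

An independent growing-multigraph process (k uniform edges over distinct
vertex pairs, parallel edges allowed) provides per-step component counts
for the random-graph analogy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bpgraph import observed_cycle_lengths
from .genome import AugmentedGenome, ModelParams

__all__ = ["Trajectory", "simulate", "coupled_random_graph"]


@dataclass
class Trajectory:
    """Per-step statistics of one simulated DCJ history (k = 0..k_max)."""

    params: ModelParams
    seed: int | None
    k: np.ndarray
    breakpoints: np.ndarray
    obs_cycles: np.ndarray | None = None
    real_cycles: np.ndarray | None = None
    perm_cycles: np.ndarray | None = None
    components: np.ndarray | None = None
    final_genome: AugmentedGenome | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"k": self.k, "B": self.breakpoints}
        for name, arr in [
            ("obs_cycles", self.obs_cycles),
            ("real_cycles", self.real_cycles),
            ("perm_cycles", self.perm_cycles),
            ("graph_components", self.components),
        ]:
            if arr is not None:
                cols[name] = arr
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _union_cycle_vertices(p0: list[int], p: list[int], start: int) -> list[int]:
    """Vertices of the cycle of union(M0, M_current) through ``start``,
    walking M0 first."""
    out = [start]
    cur = p0[start]
    use0 = False
    while cur != start or not use0:
        out.append(cur)
        cur = p0[cur] if use0 else p[cur]
        use0 = not use0
    return out


def _perm_cycle(s: list[int], e: int) -> list[int]:
    out = [e]
    cur = s[e]
    while cur != e:
        out.append(cur)
        cur = s[cur]
    return out


def simulate(
    G0: AugmentedGenome,
    k_max: int,
    seed: int | None = None,
    record_cycles: bool = False,
    couple: bool = False,
    components: bool = False,
    obs_every: int = 1,
) -> Trajectory:
    """Run ``k_max`` uniform random DCJs from the augmented genome ``G0``.

    ``record_cycles`` adds observed-breakpoint-graph cycle counts every
    ``obs_every`` steps (-1 marks unrecorded steps) and per-step
    real-breakpoint-graph cycle counts; ``couple`` additionally runs the
    coupled transposition walk (and implies cycle tracking);
    ``components`` attaches an independent random-multigraph component
    trajectory on the same n.  Deterministic under a fixed seed, and the
    breakpoint trajectory does not depend on which optional statistics
    are recorded.
    """
    G0.validate()
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    n = G0.n
    if n < 2:
        raise ValueError("need n >= 2 adjacencies")
    g = G0.g
    verts = sorted({v for p in G0.adjacencies for v in p})
    if verts != list(range(1, 2 * n + 1)):
        raise ValueError("simulate expects contiguous vertex ids 1..2n")
    track_real = couple or (record_cycles and obs_every == 1)

    rng = np.random.default_rng(seed)
    partner = [0] * (2 * n + 1)
    for u, v in G0.adjacencies:
        partner[u], partner[v] = v, u
    partner0 = partner[:]

    # observed adjacencies of G0, for O(1) breakpoint updates
    obs0 = [0] * (2 * n + 1)
    for u, v in G0.observed_adjacencies:
        obs0[u], obs0[v] = v, u
    a = G0.a
    intact = a

    B = np.zeros(k_max + 1, dtype=np.int64)
    obs_cy = np.zeros(k_max + 1, dtype=np.int64) if record_cycles else None
    real_cy = np.zeros(k_max + 1, dtype=np.int64) if track_real else None
    perm_cy = np.zeros(k_max + 1, dtype=np.int64) if couple else None

    if record_cycles:
        obs_cy[0] = n
    if track_real:
        real_cy[0] = n
    real_count = n

    if couple:
        s = list(range(2 * n + 1))  # successor array of the identity (1..n used)
        elem_of = {
            (u, v) if u < v else (v, u): e + 1
            for e, (u, v) in enumerate(sorted(G0.adjacencies))
        }
        perm_count = n
        perm_cy[0] = n

    two_n = 2 * n
    for step in range(1, k_max + 1):
        # uniform unordered pair of distinct adjacencies + fair rewiring bit
        i = int(rng.integers(0, two_n)) + 1
        A, Bv = i, partner[i]
        lo, hi = (A, Bv) if A < Bv else (Bv, A)
        j = int(rng.integers(0, two_n - 2)) + 1
        if j >= lo:
            j += 1
        if j >= hi:
            j += 1
        C, D = j, partner[j]
        bit = int(rng.integers(0, 2))

        e1 = (A, Bv) if A < Bv else (Bv, A)
        e2 = (C, D) if C < D else (D, C)

        if track_real:
            cyc = _union_cycle_vertices(partner0, partner, A)
            same_bp = C in cyc  # D is on the same current edge as C
        if couple:
            ea, eb = elem_of[e1], elem_of[e2]
            pc = _perm_cycle(s, ea)
            same_perm = eb in pc
            s[ea], s[eb] = s[eb], s[ea]
            perm_count += 1 if same_perm else -1

        # apply the DCJ
        if bit == 0:
            p1, p2 = (A, C), (Bv, D)
        else:
            p1, p2 = (A, D), (Bv, C)
        for u, v in (p1, p2):
            partner[u], partner[v] = v, u
        new1 = (p1[0], p1[1]) if p1[0] < p1[1] else (p1[1], p1[0])
        new2 = (p2[0], p2[1]) if p2[0] < p2[1] else (p2[1], p2[0])

        # breakpoint bookkeeping
        for u, v in (e1, e2):
            if obs0[u] == v:
                intact -= 1
        for u, v in (new1, new2):
            if obs0[u] == v:
                intact += 1
        B[step] = a - intact

        if track_real:
            if not same_bp:
                real_count -= 1  # fusion
                split = False
            else:
                cyc_after = _union_cycle_vertices(partner0, partner, new1[0])
                split = new2[0] not in cyc_after
                if split:
                    real_count += 1
            real_cy[step] = real_count

        if record_cycles:
            if step % obs_every == 0 or step == k_max:
                pa = [x if x <= 2 * g else 0 for x in partner0[: 2 * g + 1]]
                pb = [x if x <= 2 * g else 0 for x in partner[: 2 * g + 1]]
                obs_cy[step] = len(observed_cycle_lengths(pa, pb, g, n))
            else:
                obs_cy[step] = -1

        if couple:
            del elem_of[e1], elem_of[e2]
            lo_e, hi_e = min(ea, eb), max(ea, eb)
            gamma, delta = (new1, new2) if new1 < new2 else (new2, new1)
            assign = (lo_e, hi_e)  # smallest adjacency -> smallest element
            if same_bp and split:
                # respect the cycles: put gamma with the permutation cycle
                # holding elements of its breakpoint-graph cycle-mates
                g_mates = _cycle_mate_elements(
                    partner0, partner, gamma, delta, elem_of
                )
                qa = set(_perm_cycle(s, ea))
                if g_mates & qa:
                    assign = (ea, eb)
                elif g_mates and g_mates & set(_perm_cycle(s, eb)):
                    assign = (eb, ea)
            elem_of[gamma], elem_of[delta] = assign
            perm_cy[step] = perm_count

    comp = None
    if components:
        sub = np.random.default_rng(seed).integers(0, 2**31 - 1) if seed is not None else None
        comp = coupled_random_graph(n, k_max, seed=sub)

    final = AugmentedGenome(
        g=g,
        adjacencies=frozenset(
            (v, partner[v]) for v in range(1, 2 * n + 1) if v < partner[v]
        ),
        telomeric=G0.telomeric,
        fictional=G0.fictional,
        arcs=G0.arcs,
    )
    return Trajectory(
        params=G0.params,
        seed=seed,
        k=np.arange(k_max + 1),
        breakpoints=B,
        obs_cycles=obs_cy,
        real_cycles=real_cy,
        perm_cycles=perm_cy,
        components=comp,
        final_genome=final,
    )


def _cycle_mate_elements(p0, p, gamma, delta, elem_of) -> set[int]:
    """Elements mapped from the current-genome adjacencies sharing gamma's
    breakpoint-graph cycle (gamma and delta excluded)."""
    out: set[int] = set()
    start = gamma[0]
    cur = p0[start]  # first hop along M0; hops then alternate
    via_current = True  # the next hop follows a current-genome adjacency
    while True:
        nxt = p[cur] if via_current else p0[cur]
        if via_current:
            key = (cur, nxt) if cur < nxt else (nxt, cur)
            if key != gamma and key != delta and key in elem_of:
                out.add(elem_of[key])
        cur = nxt
        if via_current and cur == start:
            break
        via_current = not via_current
    return out


def coupled_random_graph(n: int, k: int, seed: int | None = None) -> np.ndarray:
    """Component counts Co_0..Co_k of an n-vertex multigraph grown by
    adding one uniform random edge (over distinct vertex pairs, parallel
    edges allowed) per step."""
    if n < 2:
        raise ValueError("need n >= 2")
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out = np.empty(k + 1, dtype=np.int64)
    out[0] = comp = n
    us = rng.integers(0, n, size=k)
    vs = rng.integers(0, n - 1, size=k)
    for step in range(1, k + 1):
        u = int(us[step - 1])
        v = int(vs[step - 1])
        if v >= u:
            v += 1
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            comp -= 1
        out[step] = comp
    return out
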