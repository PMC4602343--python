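"""Reading and writing gene orders in the UniMoG/GRIMM dialect.

A genome starts with a ``>name`` line; each chromosome is a run of
whitespace-separated signed integers terminated by ``$`` (linear) or
``)`` (circular), possibly spanning lines.  Example::

    >red
    1 2 3 $
    >blue
    3 2 1 $
"""

from __future__ import annotations

import io as _io
from pathlib import Path

from .genome import AugmentedGenome, GenomeFormatError, build_genome, head, tail

__all__ = ["read_genomes", "write_genomes", "parse_genomes", "format_genomes"]


def parse_genomes(text: str) -> list[tuple[str, AugmentedGenome]]:
    """Parse UniMoG text into (name, genome) pairs; raise
    :class:`GenomeFormatError` with a line number on malformed input."""
    genomes: list[tuple[str, AugmentedGenome]] = []
    name: str | None = None
    chroms: list[list[int]] = []
    flags: list[bool] = []
    current: list[int] = []

    def flush(lineno: int) -> None:
        nonlocal name, chroms, flags, current
        if name is None:
            return
        if current:
            raise GenomeFormatError(
                f"line {lineno}: unterminated chromosome in genome {name!r}"
            )
        if not chroms:
            raise GenomeFormatError(f"line {lineno}: genome {name!r} has no genes")
        try:
            genomes.append((name, build_genome(chroms, flags)))
        except GenomeFormatError as exc:
            raise GenomeFormatError(f"genome {name!r}: {exc}") from exc
        name, chroms, flags, current = None, [], [], []

    lineno = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush(lineno)
            name = line[1:].strip() or f"genome{len(genomes) + 1}"
            continue
        if name is None:
            raise GenomeFormatError(f"line {lineno}: gene data before any '>' header")
        for tok in line.split():
            if tok == "$" or tok == ")":
                if not current:
                    raise GenomeFormatError(f"line {lineno}: empty chromosome")
                chroms.append(current)
                flags.append(tok == ")")
                current = []
            else:
                try:
                    current.append(int(tok))
                except ValueError:
                    raise GenomeFormatError(
                        f"line {lineno}: bad token {tok!r}"
                    ) from None
    flush(lineno + 1)
    return genomes


def read_genomes(path: str | Path) -> list[tuple[str, AugmentedGenome]]:
    return parse_genomes(Path(path).read_text())


def format_genomes(genomes: list[tuple[str, AugmentedGenome]]) -> str:
    """Render genomes back to UniMoG text (chromosomes recovered by
    walking gene arcs and adjacencies)."""
    out = _io.StringIO()
    for name, G in genomes:
        out.write(f">{name}\n")
        for signed, circ in _chromosomes(G):
            out.write(" ".join(str(s) for s in signed))
            out.write(" )\n" if circ else " $\n")
    return out.getvalue()


def write_genomes(path: str | Path, genomes: list[tuple[str, AugmentedGenome]]) -> None:
    Path(path).write_text(format_genomes(genomes))


def _chromosomes(G: AugmentedGenome):
    """Recover (signed gene list, circular) chromosomes from the matching."""
    adj_partner: dict[int, int] = {}
    for u, v in G.observed_adjacencies:
        adj_partner[u], adj_partner[v] = v, u
    seen: set[int] = set()

    def walk(start_gene: int, start_at_tail: bool):
        signed = []
        gene, at_tail = start_gene, start_at_tail
        while gene not in seen:
            seen.add(gene)
            signed.append(gene if at_tail else -gene)
            exit_v = head(gene) if at_tail else tail(gene)
            nxt = adj_partner.get(exit_v)
            if nxt is None:
                return signed, False
            gene = (nxt + 1) // 2
            at_tail = nxt == tail(gene)
        return signed, True  # returned to the start: circular

    chroms = []
    # linear chromosomes first: start from telomeric extremities
    for v in sorted(G.telomere_extremities):
        gene = (v + 1) // 2
        if gene in seen:
            continue
        signed, _ = walk(gene, start_at_tail=(v == tail(gene)))
        chroms.append((signed, False))
    for gene in range(1, G.g + 1):
        if gene not in seen:
            signed, _ = walk(gene, start_at_tail=True)
            chroms.append((signed, True))
    return chroms
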