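"""Model/Results interface over the DCJ distance estimators.

:class:`DCJDistanceModel` is built from a pair of genomes on the same
gene set; :meth:`~DCJDistanceModel.fit` runs one or several
method-of-moments estimators of the number of DCJs separating them and
returns a :class:`DCJDistanceResults` carrying the estimates,
saturation flags and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import estimators as est
from .bpgraph import observed_breakpoint_graph
from .genome import AugmentedGenome, count_breakpoints
from .io import read_genomes
from .moments import bd_expected_components, eh_expected_cycles_table

_ALL_METHODS = ("dcj_tilde", "parsimony", "seq_coding", "eh", "bd")


class DCJDistanceModel:
    """Estimate the number of DCJ rearrangements between two genomes.

    Parameters
    ----------
    genome1, genome2:
        Genomes on the same gene set (augmented or not).
    f:
        Fictional-vertex count of the DCJ model.  Defaults to
        ``choose_f``'s lower bound 2|a1 - a2|.

    The model's n is ``2g - a1 + f/2`` computed on genome 1 (the
    reference whose breakpoints are counted).
    """

    def __init__(
        self,
        genome1: AugmentedGenome,
        genome2: AugmentedGenome,
        f: int | None = None,
    ) -> None:
        if not genome1.same_gene_set(genome2):
            raise ValueError("genomes are on different gene sets")
        self.genome1 = genome1
        self.genome2 = genome2
        self.a1 = genome1.a
        self.a2 = genome2.a
        self.g = genome1.g
        self.f = est.choose_f(self.a1, self.a2, self.g) if f is None else f
        if self.f % 2:
            raise ValueError("f must be even")
        self.n = 2 * self.g - self.a1 + self.f // 2
        self.breakpoints = count_breakpoints(genome1, genome2)

    @classmethod
    def from_file(cls, path, f: int | None = None) -> "DCJDistanceModel":
        """Build from a UniMoG gene-order file holding (at least) two genomes."""
        genomes = read_genomes(path)
        if len(genomes) < 2:
            raise ValueError(f"need two genomes in {path}, found {len(genomes)}")
        (_, g1), (_, g2) = genomes[0], genomes[1]
        return cls(g1, g2, f=f)

    def fit(
        self,
        methods: str | tuple[str, ...] = ("dcj_tilde", "parsimony"),
        k_max: int | None = None,
        N_choice: str | float = "exact",
    ) -> "DCJDistanceResults":
        """Run the requested estimators.

        ``k_max`` bounds the grid inversion of the cycle-based (eh/bd)
        estimators; it defaults to 4n, past the saturation scale.
        """
        if isinstance(methods, str):
            methods = (methods,)
        unknown = set(methods) - set(_ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        n = self.n
        if k_max is None:
            k_max = 4 * n
        results: dict[str, est.EstimateResult] = {}
        cycles = None
        if {"parsimony", "eh", "bd"} & set(methods):
            bg = observed_breakpoint_graph(self.genome1, self.genome2, n=n)
            cycles = bg.n_cycles
        for m in methods:
            if m == "dcj_tilde":
                results[m] = est.dcj_tilde(self.breakpoints, self.a1, n)
            elif m == "seq_coding":
                results[m] = est.seq_coding_estimate(
                    self.breakpoints, self.a1, n, N_choice=N_choice
                )
            elif m == "parsimony":
                results[m] = est.EstimateResult(
                    "parsimony", float(cycles), float(n - cycles),
                    params={"n": n}, diagnostics={"cycles": cycles},
                )
            elif m == "eh":
                table = eh_expected_cycles_table(n, k_max)
                results[m] = est.grid_invert(cycles, table, k_max, method="eh")
            elif m == "bd":
                table = [bd_expected_components(n, k) for k in range(k_max + 1)]
                results[m] = est.grid_invert(cycles, table, k_max, method="bd")
        return DCJDistanceResults(model=self, estimates=results)


@dataclass
class DCJDistanceResults:
    """Fitted estimates of the DCJ step count for one genome pair."""

    model: DCJDistanceModel
    estimates: dict[str, est.EstimateResult]

    def __getitem__(self, method: str) -> est.EstimateResult:
        return self.estimates[method]

    @property
    def k_hat(self) -> float:
        """Estimate of the first fitted method (fit order)."""
        return next(iter(self.estimates.values())).k_hat

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": r.method,
                "statistic": r.statistic,
                "k_hat": r.k_hat,
                "saturated": r.saturated,
            }
            for r in self.estimates.values()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "DCJ distance estimation",
            "=" * 55,
            f"genes g={m.g}  observed adjacencies a1={m.a1}, a2={m.a2}",
            f"fictional vertices f={m.f}  total adjacencies n={m.n}",
            f"observed breakpoints B={m.breakpoints}",
            "-" * 55,
            f"{'method':<12}{'statistic':>12}{'k_hat':>12}{'saturated':>12}",
        ]
        for r in self.estimates.values():
            k_txt = "inf" if r.saturated and r.k_hat == float("inf") else f"{r.k_hat:.3f}"
            lines.append(
                f"{r.method:<12}{r.statistic:>12.3f}{k_txt:>12}"
                f"{str(r.saturated):>12}"
            )
        lines.append("=" * 55)
        return "\n".join(lines)
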