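"""Scripted estimator-comparison experiments on simulated DCJ histories.

Two studies are provided, at configurable scale:

* :func:`run_sequence_length_sweep` - the sequence-coding sweep: one genome evolved by
  DCJ, its breakpoint trajectory inverted through the binary-sequence
  estimator for several coded sequence lengths N, against the direct
  closed-form inversion.  Sequences shorter than ~4a overestimate the
  step count, longer ones underestimate it.
* :func:`run_estimator_comparison` - comparison of the parsimony distance with the
  moment estimators (closed-form breakpoint inversion; grid inversion
  of the transposition-walk cycle expectation, "eh"; grid inversion of
  the random-graph component series, "bd") along one or several
  simulated trajectories.

The default configuration follows the published experimental setup
(a = 980 observed adjacencies, n = 1020 total adjacencies, 4000 steps),
realized as g = 1000 genes, 40 telomeres and f = 0.  The reduced
configuration (n = 120, 400 steps, 5 replicates) keeps every qualitative
feature at desk-test cost and is what the test-suite runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators as est
from .genome import random_genome
from .moments import bd_expected_components, eh_expected_cycles_table
from .simulate import simulate

__all__ = ["ExperimentConfig", "run_sequence_length_sweep", "run_estimator_comparison"]

SWEEP_COLUMNS = ["k", "replicate", "estimator", "statistic", "k_hat", "saturated"]
COMPARISON_COLUMNS = ["k", "replicate", "B", "obs_cycles", "parsimony",
                "dcj_tilde", "eh", "bd"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Scale and seeding of an estimator-comparison run.

    The genome has ``g`` genes, ``telomeres`` unmatched extremities and
    ``f`` fictional vertices, so a = g - telomeres/2 ... (2g-telomeres)/2
    observed adjacencies and n = 2g - a + f/2 total adjacencies.
    """

    g: int = 1000
    telomeres: int = 40
    f: int = 0
    k_max: int = 4000
    replicates: int = 1
    seed: int = 0
    N_sweep: tuple[str, ...] = ("2n", "4a", "exact", "n(2n-1)")
    out_dir: str | None = None

    @property
    def a(self) -> int:
        return (2 * self.g - self.telomeres) // 2

    @property
    def n(self) -> int:
        return 2 * self.g - self.a + self.f // 2

    @classmethod
    def published_scale(cls, **kw) -> "ExperimentConfig":
        """a=980, n=1020, 4000 steps, single run."""
        return cls(**kw)

    @classmethod
    def reduced(cls, **kw) -> "ExperimentConfig":
        """a=114, n=120, 400 steps, 5 replicates: desk-scale defaults."""
        defaults = dict(g=117, telomeres=6, f=0, k_max=400, replicates=5)
        defaults.update(kw)
        return cls(**defaults)

    def start_genome(self, replicate: int = 0):
        return random_genome(
            self.g, self.telomeres, f=self.f, seed=self.seed + replicate
        )


def _maybe_write(df: pd.DataFrame, config: ExperimentConfig, name: str) -> None:
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, sep="\t", index=False)


def run_sequence_length_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Sequence-length sweep: estimate k from B_k for each coded length N
    in ``config.N_sweep``, plus the direct closed-form inversion."""
    rows = []
    a, n = config.a, config.n
    for rep in range(config.replicates):
        traj = simulate(config.start_genome(rep), config.k_max,
                        seed=config.seed + rep)
        for k in range(config.k_max + 1):
            B = int(traj.breakpoints[k])
            r = est.dcj_tilde(B, a, n)
            rows.append((k, rep, "dcj_tilde", B, r.k_hat, r.saturated))
            for N_choice in config.N_sweep:
                r = est.seq_coding_estimate(B, a, n, N_choice=N_choice)
                rows.append(
                    (k, rep, f"seq[N={N_choice}]", B, r.k_hat, r.saturated)
                )
    df = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    _maybe_write(df, config, "seq_sweep.tsv")
    return df


def run_estimator_comparison(config: ExperimentConfig) -> pd.DataFrame:
    """Estimator comparison along simulated trajectories: parsimony,
    closed-form breakpoint inversion, and grid inversions of the
    transposition-walk cycle expectation (eh) and the random-graph
    component series (bd), all applied to each step's statistics.

    The eh/bd estimators invert the observed breakpoint-graph cycle
    count against precomputed expectation tables for k = 0..k_max.
    """
    a, n, k_max = config.a, config.n, config.k_max
    eh_table = eh_expected_cycles_table(n, k_max)
    bd_table = [bd_expected_components(n, k) for k in range(k_max + 1)]
    rows = []
    for rep in range(config.replicates):
        traj = simulate(
            config.start_genome(rep), k_max, seed=config.seed + rep,
            record_cycles=True,
        )
        for k in range(k_max + 1):
            B = int(traj.breakpoints[k])
            cyc = int(traj.obs_cycles[k])
            rows.append(
                (
                    k,
                    rep,
                    B,
                    cyc,
                    float(n - cyc),
                    est.dcj_tilde(B, a, n).k_hat,
                    est.grid_invert(cyc, eh_table, k_max, method="eh").k_hat,
                    est.grid_invert(cyc, bd_table, k_max, method="bd").k_hat,
                )
            )
    df = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
    _maybe_write(df, config, "estimator_comparison.tsv")
    return df
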