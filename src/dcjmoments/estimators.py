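"""Method-of-moments estimators of the number of DCJs between two genomes.

Each estimator inverts the expected value of an observable statistic as
a function of the step count k:

* ``dcj_tilde`` - analytic inversion of the exact closed-form expected
  breakpoint count (the package's headline estimator);
* ``seq_coding_estimate`` - codes adjacencies as a binary sequence of a
  chosen length N and inverts the sequence-evolution expectation;
* ``grid_invert`` - numerical inversion over an integer grid, used for
  the transposition-walk (EH) and random-graph (BD) cycle-based
  estimators, which have series rather than invertible closed forms;
* ``parsimony_distance`` - the minimum number of DCJs (n minus the
  observed breakpoint-graph cycle count), for comparison.

Past k = O(n log n) the statistics saturate at their stationary values
and carry no signal; estimators then return a flagged sentinel rather
than raising, so batch experiments run to completion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .bpgraph import observed_breakpoint_graph
from .genome import AugmentedGenome
from .moments import _decay_base

__all__ = [
    "EstimateResult",
    "dcj_tilde",
    "choose_f",
    "grid_invert",
    "seq_coding_estimate",
    "parsimony_distance",
]

_METHODS = frozenset({"dcj_tilde", "eh", "bd", "seq_coding", "parsimony"})


@dataclass(frozen=True)
class EstimateResult:
    """One estimate of the DCJ step count k.

    ``k_hat`` is +inf when the observed statistic lies at or beyond its
    stationary expectation (``saturated=True``).
    """

    method: str
    statistic: float
    k_hat: float
    saturated: bool = False
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.saturated and self.k_hat < 0:
            raise ValueError("k_hat must be non-negative")


def dcj_tilde(B: float, a: int, n: int) -> EstimateResult:
    """Analytic inversion of the expected breakpoint count:

    k_hat = log(1 - B(2n-1)/(a(2n-2))) / log(1 - 1/(n-1) - 1/n).

    B may be non-integer (mean of replicates).  B at or beyond the
    stationary value a(2n-2)/(2n-1) yields a saturated result.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 <= B <= a:
        raise ValueError(f"need 0 <= B <= a, got B={B}, a={a}")
    params = {"a": a, "n": n}
    asymptote = a * (2 * n - 2) / (2 * n - 1)
    if B >= asymptote:
        return EstimateResult(
            "dcj_tilde", B, math.inf, saturated=True, params=params,
            diagnostics={"asymptote": asymptote},
        )
    k_hat = math.log(1.0 - B * (2 * n - 1) / (a * (2 * n - 2))) / math.log(
        _decay_base(n)
    )
    return EstimateResult("dcj_tilde", B, k_hat, params=params)


def choose_f(a1: int, a2: int, g: int, upper: int | None = None) -> int:
    """Default fictional-vertex count for comparing two genomes.

    Returns the lower end of the admissible bracket, 2|a1 - a2| (always
    even): the minimum needed so that a DCJ scenario between the two
    genomes exists, since DCJs never change the telomeric-plus-fictional
    vertex count.  The bracket's upper end (of order the equilibrium
    telomere count) is not settled; pass ``upper`` to clamp against it.
    """
    f = 2 * abs(a1 - a2)
    if upper is not None and f > upper:
        raise ValueError(f"required f={f} exceeds requested upper bound {upper}")
    return f


def grid_invert(
    observed: float,
    expectation_fn: Callable[[int], float] | Sequence[float],
    k_max: int,
    method: str = "eh",
) -> EstimateResult:
    """k_hat = argmin over integer k in [0, k_max] of
    |observed - expectation(k)|, ties broken toward the smallest k.

    ``expectation_fn`` may be a callable or a precomputed table of length
    at least k_max+1 (the usual case: expectation tables are expensive).
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if callable(expectation_fn):
        table = [expectation_fn(k) for k in range(k_max + 1)]
    else:
        table = list(expectation_fn[: k_max + 1])
        if len(table) < k_max + 1:
            raise ValueError("expectation table shorter than k_max + 1")
    best_k, best_err = 0, abs(observed - table[0])
    for k in range(1, k_max + 1):
        err = abs(observed - table[k])
        if err < best_err:
            best_k, best_err = k, err
    return EstimateResult(
        method,
        observed,
        float(best_k),
        saturated=(best_k == k_max),
        diagnostics={"grid_max": k_max, "residual": best_err},
    )


def seq_coding_estimate(
    B: float,
    a: int,
    n: int,
    N_choice: str | float = "exact",
) -> EstimateResult:
    """Estimate k by coding adjacencies as a binary sequence of length N.

    The observed difference count is D = 2B (each breakpoint differs
    from both genomes' sides).  Substitution steps are recovered by
    inverting the sequence expectation, k_s = log(1 - 2D/N)/log(1 - 2/N),
    then rescaled to DCJ steps via the decay-rate identification
    k = k_s log(1 - 2/N) / log(1 - 1/(n-1) - 1/n).

    ``N_choice``: "exact" (4a(2n-2)/(2n-1), under which the estimate
    coincides with dcj_tilde), "4a", "2n", "n(2n-1)", or a number.
    Shorter sequences overestimate k; longer ones underestimate it.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 <= B <= a:
        raise ValueError(f"need 0 <= B <= a, got B={B}")
    choices: dict[str, float] = {
        "exact": 4.0 * a * (2 * n - 2) / (2 * n - 1),
        "4a": 4.0 * a,
        "2n": 2.0 * n,
        "n(2n-1)": float(n * (2 * n - 1)),
    }
    if isinstance(N_choice, str):
        if N_choice not in choices:
            raise ValueError(f"N_choice must be one of {sorted(choices)} or a number")
        N = choices[N_choice]
    else:
        N = float(N_choice)
    if N <= 2:
        raise ValueError("need N > 2")
    D = 2.0 * B
    params = {"a": a, "n": n, "N": N, "N_choice": str(N_choice)}
    if D >= N / 2.0:
        return EstimateResult(
            "seq_coding", B, math.inf, saturated=True, params=params
        )
    k_s = math.log(1.0 - 2.0 * D / N) / math.log(1.0 - 2.0 / N)
    k_hat = k_s * math.log(1.0 - 2.0 / N) / math.log(_decay_base(n))
    return EstimateResult(
        "seq_coding", B, k_hat, params=params, diagnostics={"k_s": k_s}
    )


def parsimony_distance(
    G1: AugmentedGenome, G2: AugmentedGenome, n: int | None = None
) -> EstimateResult:
    """Minimum number of DCJs between two genomes: n minus the cycle
    count of the (cycle-maximizing) observed breakpoint graph."""
    bg = observed_breakpoint_graph(G1, G2, n=n)
    return EstimateResult(
        "parsimony",
        float(bg.n_cycles),
        float(bg.distance),
        params={"n": bg.n},
        diagnostics={"cycles": bg.n_cycles},
    )
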