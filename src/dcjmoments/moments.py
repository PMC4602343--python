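"""Closed-form and series expectations for the DCJ chain and its analogues.

Implements, for a genome with ``a`` observed adjacencies out of ``n``
total adjacencies evolving by uniform random DCJs:

* the exact expected breakpoint count after k DCJs (closed form and the
  equivalent two-probability recurrence);
* the binary Jukes-Cantor-like sequence expectations (single-site and
  four-sites-at-a-time variants) and the exact parameter mapping under
  which half the expected sequence differences equals the expected
  breakpoint count;
* the Eriksen-Hultman exact expectation for the random-transposition
  walk on the symmetric group (with the a_pq coefficient table),
  evaluated in exact rationals or arbitrary-precision floats;
* the random-graph (tree-count series) approximation of the expected
  number of components after k random multigraph edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import mpmath

from .genome import ModelParams

__all__ = [
    "SeqModelParams",
    "expected_breakpoints",
    "expected_breakpoints_exact",
    "breakpoint_recurrence",
    "seq_expected_differences",
    "seq4_expected_differences",
    "proposition_mapping",
    "eh_coefficients",
    "eh_formula",
    "eh_expected_cycles",
    "eh_expected_cycles_table",
    "bd_expected_components",
    "PrecisionError",
]


class PrecisionError(ArithmeticError):
    """Raised when floating-point cancellation is detected in Eq.-style sums."""


@dataclass(frozen=True)
class SeqModelParams:
    """Binary-sequence model: length N, step count k_s, per-step change
    probability p_s and no-revert probability q_u."""

    N: float
    k_s: float

    @property
    def p_s(self) -> float:
        return 2.0 / self.N

    @property
    def q_u(self) -> float:
        return 1.0 - 2.0 / self.N


def _decay_base(n: int) -> float:
    return 1.0 - 1.0 / (n - 1) - 1.0 / n


def expected_breakpoints(params: ModelParams, k: int | float) -> float:
    """Expected number of breakpoints between G and G_k after k random DCJs:
    a * (2n-2)/(2n-1) * (1 - (1 - 1/(n-1) - 1/n)^k).
    """
    n, a = params.n, params.a
    if n < 2:
        raise ValueError(f"need n >= 2, got n={n}")
    if k < 0:
        raise ValueError("k must be non-negative")
    return a * (2 * n - 2) / (2 * n - 1) * (1.0 - _decay_base(n) ** k)


def expected_breakpoints_exact(params: ModelParams, k: int) -> Fraction:
    """Exact-rational version of :func:`expected_breakpoints`."""
    n, a = params.n, params.a
    if n < 2:
        raise ValueError(f"need n >= 2, got n={n}")
    base = 1 - Fraction(1, n - 1) - Fraction(1, n)
    return Fraction(a) * Fraction(2 * n - 2, 2 * n - 1) * (1 - base**k)


def breakpoint_recurrence(params: ModelParams, k: int) -> float:
    """Expected breakpoints by iterating P_k = P_{k-1} (q_u - p_s) + p_s
    from P_0 = 0, with p_s = 2/n (cut probability) and
    q_u = 1 - 1/(n(n-1)) (no-rejoin probability); equals the closed form.
    """
    n, a = params.n, params.a
    if n < 2:
        raise ValueError(f"need n >= 2, got n={n}")
    p_s = 2.0 / n
    q_u = 1.0 - 1.0 / (n * (n - 1))
    P = 0.0
    for _ in range(k):
        P = P * (q_u - p_s) + p_s
    return a * P


def seq_expected_differences(N: float, k_s: int | float) -> float:
    """Expected differing sites between binary sequences of length N after
    k_s equiprobable single-site substitutions: (N/2)(1 - (1 - 2/N)^k_s)."""
    if N < 2:
        raise ValueError("need N >= 2")
    return N / 2.0 * (1.0 - (1.0 - 2.0 / N) ** k_s)


def seq4_expected_differences(N: float, k_s: int | float) -> float:
    """Expected differing sites when substitutions occur four at a time
    (one DCJ cuts and reforms two adjacencies, i.e. changes 4 sites):
    (N/2)(1 - (1 - 8/N)^k_s)."""
    if N < 8:
        raise ValueError("need N >= 8")
    return N / 2.0 * (1.0 - (1.0 - 8.0 / N) ** k_s)


def proposition_mapping(params: ModelParams, k: int | float) -> SeqModelParams:
    """Exact (N, k_s) under which half the expected sequence differences
    equals the expected DCJ breakpoint count:

    N = 4a(2n-2)/(2n-1)  (~ 4a),  and  k_s chosen so that
    (1 - 2/N)^k_s = (1 - 1/(n-1) - 1/n)^k  (~ 4ka/n).
    """
    n, a = params.n, params.a
    if a == 0:
        raise ValueError("mapping needs a > 0")
    if n < 2:
        raise ValueError("need n >= 2")
    N = 4.0 * a * (2 * n - 2) / (2 * n - 1)
    k_s = k * math.log(_decay_base(n)) / math.log(1.0 - 2.0 / N)
    return SeqModelParams(N=N, k_s=k_s)


# ---------------------------------------------------------------------------
# Eriksen-Hultman: random transpositions on S_n
# ---------------------------------------------------------------------------


def _binom2(x: int) -> int:
    return x * (x - 1) // 2


def eh_coefficients(n: int) -> list[tuple[Fraction, Fraction]]:
    """Exact (a_pq, base_pq) pairs of the transposition-walk expectation:

    a_pq = (-1)^(n-p-q+1) (p-q+1)^2 / ((n-q+1)^2 (n-p)) C(n-p-1, q-1) C(n, p)
    base_pq = (C(p,2) + C(q-1,2) - C(n-p-q+2,2)) / C(n,2)

    for 1 <= p <= n-1, 1 <= q <= min(p, n-p).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    out: list[tuple[Fraction, Fraction]] = []
    cn2 = _binom2(n)
    for p in range(1, n):
        for q in range(1, min(p, n - p) + 1):
            sign = -1 if (n - p - q + 1) % 2 else 1
            a_pq = (
                sign
                * Fraction((p - q + 1) ** 2, (n - q + 1) ** 2 * (n - p))
                * math.comb(n - p - 1, q - 1)
                * math.comb(n, p)
            )
            base = Fraction(_binom2(p) + _binom2(q - 1) - _binom2(n - p - q + 2), cn2)
            out.append((a_pq, base))
    return out


def _harmonic(n: int) -> Fraction:
    return sum((Fraction(1, i) for i in range(1, n + 1)), Fraction(0))


def _eh_dps(n: int, k: int) -> int:
    # a_pq carries C(n,p)*C(n-p-1,q-1) ~ 2^(1.5n); keep ~1.5n*log10(2)
    # digits of headroom beyond the 15-digit target (the doubled-precision
    # re-evaluation still guards against shortfall)
    return max(30, int(0.46 * n) + 30)


def eh_formula(
    n: int,
    k: int,
    exact: bool = False,
    dps: int | None = None,
) -> float | Fraction:
    """The transposition-walk expectation series, evaluated verbatim:

    n - H_n + sum_pq a_pq base_pq^k.

    Exact small-n evaluation shows this is the expected transposition
    DISTANCE n - E(cycles), not the cycle count itself (at n=2 it gives
    0, 1, 0, 1, ... while the cycle count is 2, 1, 2, 1, ...); use
    :func:`eh_expected_cycles` for the cycle expectation.

    ``exact=True`` returns a Fraction (small n only: cost grows with
    C(n,2)^k denominators).  Otherwise evaluates with mpmath at working
    precision ``dps`` (default scales with n) and recomputes at doubled
    precision to detect catastrophic cancellation.
    """
    coeffs = eh_coefficients(n)
    lead = Fraction(n) - _harmonic(n)
    if exact:
        return lead + sum(a * b**k for a, b in coeffs)

    def _eval(dps_: int) -> mpmath.mpf:
        with mpmath.workdps(dps_):
            total = mpmath.mpf(lead.numerator) / lead.denominator
            for a, b in coeffs:
                af = mpmath.mpf(a.numerator) / a.denominator
                bf = mpmath.mpf(b.numerator) / b.denominator
                total += af * bf**k
            return total

    dps_ = dps if dps is not None else _eh_dps(n, k)
    v1 = _eval(dps_)
    v2 = _eval(2 * dps_)
    if abs(v1 - v2) > 1e-9 * max(1.0, abs(v2)):
        raise PrecisionError(
            f"cancellation detected in transposition-walk sum at n={n}, k={k}: "
            f"{v1} vs {v2} at doubled precision"
        )
    return float(v2)


def eh_expected_cycles(
    n: int,
    k: int,
    exact: bool = False,
    dps: int | None = None,
) -> float | Fraction:
    """Expected cycle count of a permutation obtained from the identity on
    n elements by k uniform random transpositions (n minus the distance
    series; orientation validated against the exact partition-chain
    oracle)."""
    v = eh_formula(n, k, exact=exact, dps=dps)
    return (Fraction(n) - v) if exact else (n - v)


def eh_expected_cycles_table(n: int, k_max: int, dps: int | None = None) -> list[float]:
    """E(cycles) for k = 0..k_max, sharing one coefficient pass.

    Used by the grid-inversion estimators, which need the whole curve.
    """
    coeffs = eh_coefficients(n)
    lead = Fraction(n) - _harmonic(n)
    dps_ = dps if dps is not None else _eh_dps(n, k_max)

    def _table(dps__: int) -> list[mpmath.mpf]:
        with mpmath.workdps(dps__):
            lead_f = mpmath.mpf(lead.numerator) / lead.denominator
            afs = [mpmath.mpf(a.numerator) / a.denominator for a, _ in coeffs]
            bfs = [mpmath.mpf(b.numerator) / b.denominator for _, b in coeffs]
            pows = afs[:]  # a * base^0
            out = []
            for _k in range(k_max + 1):
                out.append(lead_f + mpmath.fsum(pows))
                pows = [p * b for p, b in zip(pows, bfs)]
            return out

    vals = _table(dps_)
    # cancellation check on a few anchors
    with mpmath.workdps(2 * dps_):
        for kchk in {0, k_max // 2, k_max}:
            ref = _eval_eh_once(coeffs, lead, kchk)
            if abs(vals[kchk] - ref) > 1e-9 * max(1.0, abs(ref)):
                raise PrecisionError(
                    f"cancellation detected in transposition-walk table at "
                    f"n={n}, k={kchk}"
                )
    return [float(n - v) for v in vals]


def _eval_eh_once(coeffs, lead: Fraction, k: int) -> mpmath.mpf:
    total = mpmath.mpf(lead.numerator) / lead.denominator
    for a, b in coeffs:
        af = mpmath.mpf(a.numerator) / a.denominator
        bf = mpmath.mpf(b.numerator) / b.denominator
        total += af * bf**k
    return total


# ---------------------------------------------------------------------------
# Berestycki-Durrett: components of a growing random multigraph
# ---------------------------------------------------------------------------


def bd_expected_components(
    n: int,
    k: int | float,
    tolerance: float = 1e-12,
) -> float:
    """Tree-count series approximating the expected number of components of
    an n-vertex multigraph after k uniform random edges:

    (n^2 / 2k) * sum_{i>=1} i^(i-2)/i! * ((2k/n) e^(-2k/n))^i.

    The i=1 term is n e^(-2k/n), so the k->0 limit is n (that limit fixes
    the prefactor reading).  The series argument c e^(-c), c = 2k/n,
    never exceeds 1/e, so truncation at term < ``tolerance`` terminates;
    a hard cap of 10n terms guards the slow-convergence point c = 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return float(n)
    c = 2.0 * k / n
    log_x = math.log(c) - c  # log of the series argument, <= -1
    prefactor = n * n / (2.0 * k)
    total = 0.0
    i = 1
    cap = 10 * n
    while True:
        # i^(i-2)/i! * x^i in log space
        log_term = (i - 2) * math.log(i) - math.lgamma(i + 1) + i * log_x
        term = prefactor * math.exp(log_term)
        total += term
        if term < tolerance or i >= cap:
            break
        i += 1
    return total
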