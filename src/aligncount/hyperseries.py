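"""Exact evaluation of terminating generalized hypergeometric series.

A series ``pFq(a1..ap; b1..bq; d) = sum_k [prod (ai)_k / (k! prod (bj)_k)] d^k``
terminates when some upper parameter is a non-positive integer; all terms
beyond ``K = min(-a)`` (minimum over such parameters) contain a vanished
rising factorial.  Accumulation is exact rational throughout — there is no
floating-point mode.

The two representations provided on top of the raw evaluator:

* ``f_hyp(n, m) = 2F1(-m, -n; 1; 2)`` — total alignments.
* ``h_hyp(n, m)`` — fully reduced alignments as a difference of two ``4F3``
  values at argument ``16/27``, scaled by binomial prefactors.  One lower
  parameter of each ``4F3`` is always a non-positive integer of the form
  ``-(m+n-c)/3``, but its Pochhammer first vanishes strictly beyond the
  termination index, so no division by zero ever occurs in-range; the
  evaluator still guards for it and ``h_hyp`` falls back to the closed sum
  should a degenerate cell ever appear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .closed_forms import FormulaDiscrepancyError, h_closed

__all__ = [
    "PFQSpec",
    "SingularitySeriesError",
    "NonTerminatingSeriesError",
    "pochhammer",
    "pfq_terminating",
    "f_hyp",
    "h_hyp",
]

RationalLike = int | Fraction


class NonTerminatingSeriesError(ValueError):
    """No upper parameter is a non-positive integer: series does not terminate."""


class SingularitySeriesError(ZeroDivisionError):
    """A lower-parameter rising factorial vanished before termination."""


@dataclass(frozen=True)
class PFQSpec:
    """Parameters of one terminating pFq evaluation.

    ``upper`` and ``lower`` are exact rationals; ``argument`` is the series
    argument d.  At least one upper parameter must be a non-positive integer.
    """

    upper: tuple[Fraction, ...]
    lower: tuple[Fraction, ...]
    argument: Fraction

    @staticmethod
    def make(
        upper: list[RationalLike],
        lower: list[RationalLike],
        argument: RationalLike,
    ) -> "PFQSpec":
        return PFQSpec(
            tuple(Fraction(a) for a in upper),
            tuple(Fraction(b) for b in lower),
            Fraction(argument),
        )

    def termination_index(self) -> int:
        """Smallest K such that every term beyond K vanishes."""
        ks = [
            -int(a)
            for a in self.upper
            if a.denominator == 1 and a <= 0
        ]
        if not ks:
            raise NonTerminatingSeriesError(
                f"no non-positive-integer upper parameter in {self.upper}"
            )
        return min(ks)


def pochhammer(a: RationalLike, k: int) -> Fraction:
    """Rising factorial ``(a)_k = a (a+1) ... (a+k-1)``, with ``(a)_0 = 1``."""
    if k < 0:
        raise ValueError(f"pochhammer order must be >= 0, got {k}")
    a = Fraction(a)
    out = Fraction(1)
    for t in range(k):
        out *= a + t
    return out


def pfq_terminating(spec: PFQSpec) -> Fraction:
    """Exact value of a terminating pFq by term-by-term rational accumulation.

    Terms are built incrementally (each term is the previous one times a
    rational ratio), so the cost is linear in the termination index.
    """
    K = spec.termination_index()
    total = Fraction(1)  # k = 0 term
    term = Fraction(1)
    for k in range(1, K + 1):
        num = Fraction(1)
        for a in spec.upper:
            num *= a + (k - 1)
        den = Fraction(k)
        for b in spec.lower:
            factor = b + (k - 1)
            if factor == 0:
                if num == 0:
                    # matched zero: term and all later ones are 0/0-free zeros
                    return total
                raise SingularitySeriesError(
                    f"lower parameter {b} vanished at term {k} (K={K})"
                )
            den *= factor
        term = term * num / den * spec.argument
        total += term
    return total


def f_hyp(n: int, m: int) -> int:
    """Total alignments via ``2F1(-m, -n; 1; 2)``."""
    if n < 0 or m < 0:
        raise ValueError(f"lengths must be non-negative, got ({n}, {m})")
    spec = PFQSpec.make([-m, -n], [1], 2)
    val = pfq_terminating(spec)
    if val.denominator != 1 or val < 0:
        raise FormulaDiscrepancyError(n, m, val, -1)
    return val.numerator


def _h_prefactor_4f3(n: int, m: int) -> Fraction:
    """One scaled 4F3 block of the h representation.

    ``(m+n)!/(m! n!) * 4F3((1-m)/2, -m/2, (1-n)/2, -n/2;
    -(m+n)/3, (1-m-n)/3, (2-m-n)/3; 16/27)``.
    """
    spec = PFQSpec.make(
        [Fraction(1 - m, 2), Fraction(-m, 2), Fraction(1 - n, 2), Fraction(-n, 2)],
        [Fraction(-(m + n), 3), Fraction(1 - m - n, 3), Fraction(2 - m - n, 3)],
        Fraction(16, 27),
    )
    scale = Fraction(math.factorial(m + n), math.factorial(m) * math.factorial(n))
    return scale * pfq_terminating(spec)


def h_hyp(n: int, m: int) -> int:
    """Fully reduced alignments as a difference of two scaled 4F3 values.

    The second block is the first evaluated at ``(n-1, m-1)``; it is absent
    when either length is zero (the count is then 1 outright).
    """
    if n < 0 or m < 0:
        raise ValueError(f"lengths must be non-negative, got ({n}, {m})")
    if n == 0 or m == 0:
        return 1
    try:
        val = _h_prefactor_4f3(n, m) - _h_prefactor_4f3(n - 1, m - 1)
    except SingularitySeriesError:
        # degenerate lower parameter: hypergeometric form inapplicable here
        return h_closed(n, m)
    if val.denominator != 1 or val < 0:
        raise FormulaDiscrepancyError(n, m, val, -1)
    return val.numerator
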