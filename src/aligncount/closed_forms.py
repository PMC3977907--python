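"""Explicit summation formulas for the three count families.

Single-cell evaluation without building a table:

* ``f_closed`` — the classical sum ``sum_k 2^k C(m,k) C(n,k)``.
* ``h_closed`` — an alternating single-index sum with floor-bounded limits.
* ``g_theorem1`` — the quadruple alternating sum for the partially reduced
  count, assembled from multinomial terms ``beta`` and ``gamma`` with
  explicit inner/outer summation bounds.

Every value is an exact integer; in case ``g_theorem1`` ever disagreed with
the DP table (the ground truth), it raises :class:`FormulaDiscrepancyError`
rather than returning silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exact_counts import g_table

__all__ = [
    "FormulaDiscrepancyError",
    "Theorem1Bounds",
    "f_closed",
    "h_closed",
    "g_theorem1",
    "theorem1_bounds",
]


class FormulaDiscrepancyError(ArithmeticError):
    """An explicit formula produced a value that contradicts the DP table."""

    def __init__(self, n: int, m: int, formula_value: int, table_value: int):
        self.n, self.m = n, m
        self.formula_value, self.table_value = formula_value, table_value
        super().__init__(
            f"closed form at ({n},{m}) gave {formula_value}, "
            f"DP recurrence gives {table_value}"
        )


def _check_nonneg(*vals: int) -> None:
    if any(v < 0 for v in vals):
        raise ValueError(f"arguments must be non-negative, got {vals}")


def _fact(k: int) -> int:
    """Factorial treating negative arguments as a signal to drop the term."""
    return math.factorial(k)


def f_closed(n: int, m: int) -> int:
    """Total alignments: ``sum_{k=0}^{min(n,m)} 2^k C(m,k) C(n,k)``."""
    _check_nonneg(n, m)
    return sum(
        (1 << k) * math.comb(m, k) * math.comb(n, k) for k in range(min(n, m) + 1)
    )


def h_closed(n: int, m: int) -> int:
    """Fully reduced alignments by the alternating factorial sum.

    First sum over ``i = 0 .. min(n//2, m//2)`` of
    ``(-1)^i (m+n-3i)! / (i! (m-2i)! (n-2i)!)`` minus a second sum with all
    of ``n``, ``m`` shifted down by one; the second sum is empty when either
    length is zero.
    """
    _check_nonneg(n, m)
    total = 0
    for i in range(min(n // 2, m // 2) + 1):
        term = _fact(m + n - 3 * i) // (_fact(i) * _fact(m - 2 * i) * _fact(n - 2 * i))
        total += -term if i % 2 else term
    if n >= 1 and m >= 1:
        for i in range(min((n - 1) // 2, (m - 1) // 2) + 1):
            term = _fact(m + n - 2 - 3 * i) // (
                _fact(i) * _fact(m - 1 - 2 * i) * _fact(n - 1 - 2 * i)
            )
            total -= -term if i % 2 else term
    return total


# ---------------------------------------------------------------------------
# The quadruple sum for g(n, m)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Theorem1Bounds:
    """Summation bounds for one outer index ``i`` of the g-count sum.

    ``A..B`` bound the inner index ``j`` of the beta part, ``C..D`` of the
    gamma part (the gamma part is the beta part at ``(n-1, m-1)``, shifted by
    the ``-xy`` numerator factor of the generating function).  ``U`` is the
    lower outer bound; an empty range (lower > upper) contributes nothing.
    """

    i: int
    A: int
    B: int
    C: int
    D: int
    U: int


def _ceil_div(a: int, b: int) -> int:
    return -((-a) // b)


def _u_bound(n: int, m: int) -> int:
    # The two branches agree at n == m under this bracket reading
    # (empirically the only reading consistent with the DP table).
    if n <= m:
        return m - n // 2
    return (m + 1) // 2 + n - m


def theorem1_bounds(i: int, n: int, m: int) -> Theorem1Bounds:
    """All five summation bounds for outer index ``i`` at cell ``(n, m)``.

    Lower j-bounds round up (they come from ``3j >= 4i - m - n`` style
    constraints), upper j-bounds round down.
    """
    _check_nonneg(i, n, m)
    A = max(0, _ceil_div(4 * i - m - n, 3))
    B = min(i, 2 * i - m, 2 * i - n, (4 * i - n - m) // 2)
    C = max(0, _ceil_div(4 * i - m - n + 2, 3))
    D = min(i, 2 * i - m + 1, 2 * i - n + 1, (4 * i - n - m + 2) // 2)
    return Theorem1Bounds(i=i, A=A, B=B, C=C, D=D, U=_u_bound(n, m))


def _beta_sum(i: int, n: int, m: int, lo: int, hi: int) -> int:
    """Sum of ``(-1)^(i-j) 2^(i-j) i! / ((i-j)! (2i-j-m)! (2i-j-n)! (3j-4i+m+n)!)``
    over ``j`` in ``[lo, hi]``; terms with a negative factorial argument are 0."""
    s = 0
    fi = _fact(i)
    for j in range(max(lo, 0), hi + 1):
        a, b, c, d = i - j, 2 * i - j - m, 2 * i - j - n, 3 * j - 4 * i + m + n
        if a < 0 or b < 0 or c < 0 or d < 0:
            continue
        term = (1 << a) * fi // (_fact(a) * _fact(b) * _fact(c) * _fact(d))
        s += -term if a % 2 else term
    return s


def g_theorem1(n: int, m: int) -> int:
    """Partially reduced alignments by the explicit quadruple sum.

    The beta part runs over ``i`` from ``max(0, U(n,m))`` to ``n+m``; the
    gamma part is the same sum evaluated at ``(n-1, m-1)``, i.e. ``i`` from
    ``max(0, U(n,m)-1)`` to ``n+m-2`` with the shifted inner bounds.  The
    result is cross-checked against the DP recurrence.
    """
    _check_nonneg(n, m)
    total = 0
    u = _u_bound(n, m)
    for i in range(max(0, u), n + m + 1):
        b = theorem1_bounds(i, n, m)
        total += _beta_sum(i, n, m, b.A, b.B)
    if n >= 1 and m >= 1:
        for i in range(max(0, u - 1), n + m - 1):
            b = theorem1_bounds(i, n, m)
            # gamma_{i,j,n,m} == beta_{i,j,n-1,m-1}; C..D are its bounds
            total -= _beta_sum(i, n - 1, m - 1, b.C, b.D)
    expected = g_table(n, m).values[n][m]
    if total != expected:
        raise FormulaDiscrepancyError(n, m, total, expected)
    return total
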