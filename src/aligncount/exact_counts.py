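"""Ground-truth dynamic-programming tables for the three alignment-count families.

An *alignment* of two sequences of lengths ``n`` and ``m`` is a sequence of
columns, each holding either two residues or one residue against a gap —
equivalently a monotone lattice path from ``(0, 0)`` to ``(n, m)`` with unit
steps right (D), up (I) and diagonal (M).  Three count families arise from how
adjacent complementary gap columns are identified:

``f(n, m)``
    total alignments (no identification); the Delannoy-type recurrence
    ``f(n,m) = f(n-1,m) + f(n,m-1) + f(n-1,m-1)``.
``h(n, m)``
    fully reduced alignments: a D column adjacent to an I column (either
    order) is identified with a single match column M.
``g(n, m)``
    partially reduced alignments: the two orders DI and ID are identified
    with each other but kept distinct from M; ``h <= g <= f`` always, with
    strict inequalities off the boundary rows.

Each family is the coefficient sequence of a rational bivariate generating
function, and the tables here are computed from the *delta-corrected* full
recurrence read off that generating function: writing the denominator with
positive constant term, ``den * series = num`` gives a recurrence valid on the
whole grid (entries at negative indices are zero, Kronecker-delta source terms
come from the numerator), so no boundary line is left undefined.  All
arithmetic is arbitrary-precision integer; no count ever passes through a
float.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Family(enum.Enum):
    """The three alignment-count families."""

    F = "f"  # total alignments
    H = "h"  # fully reduced
    G = "g"  # partially reduced

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CountTable:
    """Dense ``(n_max+1) x (m_max+1)`` grid of exact alignment counts.

    ``values[n][m]`` is the count for sequence lengths ``n`` and ``m``.
    Entries are Python ints (arbitrary precision); boundary rows are
    identically 1 for every family.
    """

    family: Family
    n_max: int
    m_max: int
    values: list[list[int]] = field(repr=False)

    def __getitem__(self, key: tuple[int, int]) -> int:
        n, m = key
        return self.values[n][m]

    def diagonal(self) -> list[int]:
        """Entries ``(k, k)`` for ``k`` up to ``min(n_max, m_max)``."""
        return [self.values[k][k] for k in range(min(self.n_max, self.m_max) + 1)]


def _check_dims(n_max: int, m_max: int) -> None:
    if n_max < 0 or m_max < 0:
        raise ValueError(f"table dimensions must be >= 0, got ({n_max}, {m_max})")


def f_table(n_max: int, m_max: int) -> CountTable:
    """Table of total alignment counts f(n, m).

    Recurrence ``f(n,m) = f(n-1,m) + f(n,m-1) + f(n-1,m-1)`` with a unit
    source at the origin (out-of-range terms are 0), equivalent to the
    initial conditions ``f(n,0) = f(0,m) = 1``.
    """
    _check_dims(n_max, m_max)
    t = [[0] * (m_max + 1) for _ in range(n_max + 1)]
    for n in range(n_max + 1):
        for m in range(m_max + 1):
            v = 1 if n == 0 and m == 0 else 0
            if n >= 1:
                v += t[n - 1][m]
            if m >= 1:
                v += t[n][m - 1]
            if n >= 1 and m >= 1:
                v += t[n - 1][m - 1]
            t[n][m] = v
    return CountTable(Family.F, n_max, m_max, t)


def h_table(n_max: int, m_max: int) -> CountTable:
    """Table of fully reduced alignment counts h(n, m).

    From ``H(x,y) = (1 - xy) / (1 - x - y + x^2 y^2)`` the full-grid
    recurrence is ``h(n,m) - h(n-1,m) - h(n,m-1) + h(n-2,m-2)
    = [n=m=0] - [n=m=1]``, which fixes the ``n=1`` and ``m=1`` lines that
    the bare recurrence (stated only for n, m >= 2) leaves open.
    """
    _check_dims(n_max, m_max)
    t = [[0] * (m_max + 1) for _ in range(n_max + 1)]
    for n in range(n_max + 1):
        for m in range(m_max + 1):
            if n == 0 and m == 0:
                v = 1
            elif n == 1 and m == 1:
                v = -1
            else:
                v = 0
            if n >= 1:
                v += t[n - 1][m]
            if m >= 1:
                v += t[n][m - 1]
            if n >= 2 and m >= 2:
                v -= t[n - 2][m - 2]
            t[n][m] = v
    return CountTable(Family.H, n_max, m_max, t)


def g_table(n_max: int, m_max: int) -> CountTable:
    """Table of partially reduced alignment counts g(n, m).

    From ``G(x,y) = (1 - xy) / (1 - x - y - xy + 2 x^2 y^2)`` the full-grid
    recurrence is ``g(n,m) - g(n-1,m-1) - g(n-1,m) - g(n,m-1) + 2 g(n-2,m-2)
    = [n=m=0] - [n=m=1]``.
    """
    _check_dims(n_max, m_max)
    t = [[0] * (m_max + 1) for _ in range(n_max + 1)]
    for n in range(n_max + 1):
        for m in range(m_max + 1):
            if n == 0 and m == 0:
                v = 1
            elif n == 1 and m == 1:
                v = -1
            else:
                v = 0
            if n >= 1:
                v += t[n - 1][m]
            if m >= 1:
                v += t[n][m - 1]
            if n >= 1 and m >= 1:
                v += t[n - 1][m - 1]
            if n >= 2 and m >= 2:
                v -= 2 * t[n - 2][m - 2]
            t[n][m] = v
    return CountTable(Family.G, n_max, m_max, t)


_TABLE_BUILDERS = {Family.F: f_table, Family.H: h_table, Family.G: g_table}


def table(family: Family, n_max: int, m_max: int) -> CountTable:
    """Dispatch to the builder for ``family``."""
    return _TABLE_BUILDERS[family](n_max, m_max)
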