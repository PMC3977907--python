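"""Bivariate rational generating-function expansion.

Each count family is the coefficient table of a rational function
``num(x,y) / den(x,y)`` with unit constant term in the denominator:

* total:              ``1 / (1 - x - y - xy)``
* fully reduced:      ``(1 - xy) / (1 - x - y + x^2 y^2)``
* partially reduced:  ``(1 - xy) / (1 - x - y - xy + 2 x^2 y^2)``

Expansion extracts coefficients ``c(n, m)`` from the convolution identity
``den * c = num``, giving a third computational route independent of both
the DP recurrences and the explicit sums.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exact_counts import Family

__all__ = ["BivariatePoly", "RationalGF", "preset", "series_coeffs"]


@dataclass(frozen=True)
class BivariatePoly:
    """Sparse integer polynomial in two variables: ``{(i, j): coeff}``."""

    coeffs: dict[tuple[int, int], int]

    def __post_init__(self) -> None:
        for (i, j), c in self.coeffs.items():
            if i < 0 or j < 0:
                raise ValueError(f"negative exponent ({i}, {j})")
            if c == 0:
                raise ValueError(f"stored zero coefficient at ({i}, {j})")

    def __getitem__(self, key: tuple[int, int]) -> int:
        return self.coeffs.get(key, 0)

    def multiply_truncated(
        self, grid: list[list[int]], n_max: int, m_max: int
    ) -> list[list[int]]:
        """Product of this polynomial with a coefficient grid, truncated."""
        out = [[0] * (m_max + 1) for _ in range(n_max + 1)]
        for (i, j), c in self.coeffs.items():
            for n in range(i, n_max + 1):
                for m in range(j, m_max + 1):
                    out[n][m] += c * grid[n - i][m - j]
        return out


@dataclass(frozen=True)
class RationalGF:
    """Ratio of two bivariate polynomials with unit denominator constant."""

    numerator: BivariatePoly
    denominator: BivariatePoly


def preset(family: Family) -> RationalGF:
    """Numerator/denominator pair of the named family's generating function.

    Stored sign-normalized with denominator constant term +1 (the total-count
    function is conventionally written with an overall minus which cancels).
    """
    one = {(0, 0): 1}
    one_minus_xy = {(0, 0): 1, (1, 1): -1}
    if family is Family.F:
        return RationalGF(
            BivariatePoly(dict(one)),
            BivariatePoly({(0, 0): 1, (1, 0): -1, (0, 1): -1, (1, 1): -1}),
        )
    if family is Family.H:
        return RationalGF(
            BivariatePoly(dict(one_minus_xy)),
            BivariatePoly({(0, 0): 1, (1, 0): -1, (0, 1): -1, (2, 2): 1}),
        )
    if family is Family.G:
        return RationalGF(
            BivariatePoly(dict(one_minus_xy)),
            BivariatePoly(
                {(0, 0): 1, (1, 0): -1, (0, 1): -1, (1, 1): -1, (2, 2): 2}
            ),
        )
    raise ValueError(f"unknown family {family!r}")  # pragma: no cover


def series_coeffs(gf: RationalGF, n_max: int, m_max: int) -> list[list[int]]:
    """Coefficient grid of the power-series expansion of ``gf`` on a window.

    Solves ``den * c = num`` cell by cell:
    ``c(n,m) = (num(n,m) - sum_{(i,j) != (0,0)} den(i,j) c(n-i, m-j)) / den(0,0)``.
    Requires ``den(0,0) = +-1`` so the series has integer coefficients.
    """
    if n_max < 0 or m_max < 0:
        raise ValueError(f"window must be non-negative, got ({n_max}, {m_max})")
    d0 = gf.denominator[0, 0]
    if d0 not in (1, -1):
        raise ValueError(f"denominator constant term must be +-1, got {d0}")
    den = [(ij, c) for ij, c in gf.denominator.coeffs.items() if ij != (0, 0)]
    c = [[0] * (m_max + 1) for _ in range(n_max + 1)]
    for n in range(n_max + 1):
        for m in range(m_max + 1):
            acc = gf.numerator[n, m]
            for (i, j), coeff in den:
                if i <= n and j <= m:
                    acc -= coeff * c[n - i][m - j]
            c[n][m] = acc * d0  # d0 is +-1, so integer division is exact
    return c
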