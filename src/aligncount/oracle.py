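"""Brute-force alignment enumeration and reduced-form counting.

This module grounds the count formulas in their semantics.  An alignment of
sequences of lengths ``n`` and ``m`` is a word over ``{M, I, D}`` where M is
a residue-residue column, D puts a residue of the first sequence over a gap,
and I a gap over a residue of the second sequence; so ``#M + #D = n`` and
``#M + #I = m``.  The number of such words is the total count f(n, m).

Adjacent complementary gap columns (a D next to an I, in either order) carry
no residue-residue information; the two reduction semantics differ in what
the pair is identified with:

* *full* reduction: the pair collapses to a match column M.  The fully
  reduced forms are words containing no ``DI`` or ``ID``, and h(n, m) counts
  them.
* *partial* reduction: the two orders are identified with **each other** but
  kept distinct from a match.  The pair fuses into an unordered gap-pair
  column, written P here.  The partially reduced forms are column sequences
  over ``{M, I, D, P}`` with no unfused D-I adjacency, and g(n, m) counts
  them.

In both cases the counted objects are the distinct *reduced forms*, not the
connected components of the rewrite graph: the rewriting is not confluent
(``IDI`` reduces both to ``MI`` and to ``IM``), so one alignment can
contribute to several forms, and the form count sits strictly between the
component count and the total count.  Two independent routes are provided —
exhaustive rewriting of every alignment to all of its normal forms, and
direct enumeration of the constrained forms — and both must agree with the
table values.
"""

from __future__ import annotations

import enum
from functools import lru_cache

__all__ = [
    "Relation",
    "EnumerationCapError",
    "enumerate_alignments",
    "reduced_forms",
    "count_classes",
    "canonical_count",
    "render_alignment",
]

#: default cap on n + m for exhaustive enumeration (word counts explode)
DEFAULT_CAP = 14


class Relation(enum.Enum):
    """The two gap-reduction semantics."""

    G_RELATION = "g"  # DI, ID -> P (fused unordered pair, distinct from M)
    H_RELATION = "h"  # DI, ID -> M (collapse to a match column)

    @property
    def replacement(self) -> str:
        return "P" if self is Relation.G_RELATION else "M"


class EnumerationCapError(ValueError):
    def __init__(self, n: int, m: int, cap: int, bound: int):
        super().__init__(
            f"enumeration of ({n}, {m}) needs {bound} words; "
            f"n + m = {n + m} exceeds cap {cap}"
        )
        self.bound = bound


def _check_cap(n: int, m: int, cap: int) -> None:
    if n < 0 or m < 0:
        raise ValueError(f"lengths must be non-negative, got ({n}, {m})")
    if n + m > cap:
        from .closed_forms import f_closed

        raise EnumerationCapError(n, m, cap, f_closed(n, m))


def enumerate_alignments(n: int, m: int, cap: int = DEFAULT_CAP) -> set[str]:
    """All alignment words of two sequences of lengths ``n`` and ``m``.

    Multiset permutations of ``k`` Ms, ``n - k`` Ds and ``m - k`` Is for
    every match count ``k``; the result size equals f(n, m).
    """
    _check_cap(n, m, cap)
    words: set[str] = set()

    def extend(prefix: list[str], left_n: int, left_m: int) -> None:
        if left_n == 0 and left_m == 0:
            words.add("".join(prefix))
            return
        if left_n and left_m:
            prefix.append("M")
            extend(prefix, left_n - 1, left_m - 1)
            prefix.pop()
        if left_n:
            prefix.append("D")
            extend(prefix, left_n - 1, left_m)
            prefix.pop()
        if left_m:
            prefix.append("I")
            extend(prefix, left_n, left_m - 1)
            prefix.pop()

    extend([], n, m)
    return words


def reduced_forms(word: str, relation: Relation) -> frozenset[str]:
    """All normal forms of one alignment word under the relation's rewriting.

    Repeatedly replaces any adjacent complementary gap pair (``DI`` or
    ``ID``) by the relation's single column until none remains, following
    every possible reduction order.  The rewriting is not confluent, so the
    result can contain more than one form.
    """
    return _nf_memo(word, relation.replacement)


@lru_cache(maxsize=1 << 20)
def _nf_memo(word: str, rep: str) -> frozenset[str]:
    forms: set[str] = set()
    reducible = False
    for p in range(len(word) - 1):
        if word[p : p + 2] in ("DI", "ID"):
            reducible = True
            forms |= _nf_memo(word[:p] + rep + word[p + 2 :], rep)
    return frozenset(forms) if reducible else frozenset({word})


def count_classes(n: int, m: int, relation: Relation, cap: int = DEFAULT_CAP) -> int:
    """Number of distinct reduced forms among all alignments of ``(n, m)``.

    Exhaustive route: enumerate every alignment and collect all of its
    normal forms; the size of the union is h(n, m) for the full relation
    and g(n, m) for the partial one.
    """
    forms: set[str] = set()
    for w in enumerate_alignments(n, m, cap):
        forms |= reduced_forms(w, relation)
    return len(forms)


def canonical_count(n: int, m: int, relation: Relation, cap: int = DEFAULT_CAP) -> int:
    """Reduced-form count by direct enumeration, never touching raw words.

    Counts column sequences with no adjacent complementary plain gaps: over
    ``{M, D, I}`` for the full relation (a fused pair *is* an M there), and
    over ``{M, D, I, P}`` for the partial relation (P consumes one residue
    of each sequence, like M, but is a distinct column type).  Cross-checks
    :func:`count_classes`.
    """
    _check_cap(n, m, cap)
    with_p = relation is Relation.G_RELATION

    @lru_cache(maxsize=None)
    def rec(left_n: int, left_m: int, last: str) -> int:
        if left_n == 0 and left_m == 0:
            return 1
        total = 0
        if left_n and left_m:
            total += rec(left_n - 1, left_m - 1, "M")
            if with_p:
                total += rec(left_n - 1, left_m - 1, "P")
        if left_n and last != "I":
            total += rec(left_n - 1, left_m, "D")
        if left_m and last != "D":
            total += rec(left_n, left_m - 1, "I")
        return total

    return rec(n, m, "")


def render_alignment(word: str, x: str, y: str) -> tuple[str, str]:
    """The two gapped rows an alignment word prints as.

    M emits the next residue of both sequences, D a residue of ``x`` over
    ``-``, I a ``-`` over a residue of ``y``.
    """
    bad = set(word) - set("MID")
    if bad:
        raise ValueError(f"invalid steps {sorted(bad)} in alignment word")
    if word.count("M") + word.count("D") != len(x):
        raise ValueError(f"word {word!r} consumes a different length than {x!r}")
    if word.count("M") + word.count("I") != len(y):
        raise ValueError(f"word {word!r} consumes a different length than {y!r}")
    top, bottom = [], []
    i = j = 0
    for step in word:
        if step == "M":
            top.append(x[i])
            bottom.append(y[j])
            i += 1
            j += 1
        elif step == "D":
            top.append(x[i])
            bottom.append("-")
            i += 1
        else:
            top.append("-")
            bottom.append(y[j])
            j += 1
    return "".join(top), "".join(bottom)
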