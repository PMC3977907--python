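# Methods

## Objects and semantics

An alignment of two sequences of lengths n and m is encoded as a word over
{M, D, I}: M consumes one residue of each sequence, D one residue of the
first only (residue over gap), I one of the second only.  Words with
#M + #D = n and #M + #I = m biject with monotone lattice paths from (0, 0)
to (n, m), and f(n, m) counts them.

A D column adjacent to an I column is an *adjacent complementary gap pair*.
The two reduction semantics treat such a pair differently:

* **Full reduction** (family h): the pair is identified with a match column
  M.  A fully reduced form is a word containing neither `DI` nor `ID`, and
  h(n, m) is the number of such words.
* **Partial reduction** (family g): the two orders `DI` and `ID` are
  identified with each other but not with M.  A partially reduced form is a
  column sequence over {M, D, I, P}, where P is the fused unordered pair
  (consuming one residue of each sequence, like M, but a distinct column
  type), with no remaining unfused D–I adjacency.  g(n, m) counts these.

A subtlety worth stating explicitly, because it is easy to get wrong: h and
g count *distinct reduced forms*, not equivalence classes of alignments
under the transitive closure of the rewriting.  The rewriting
`DI | ID → M` (or `→ P`) is not confluent — `IDI` reduces both to `MI` and
to `IM` — so a single alignment can contribute several forms, and the form
count sits strictly between the closure's component count and f.  Only the
reduced-form reading reproduces the recurrences and generating functions
(checked exhaustively by the oracle tests: for g, the naive
swap-equivalence component count is already wrong at (1, 2), giving 3
against g(1, 2) = 4).

## Computational routes

Every family is computed by independent exact routes that the test suite
and `census verify` compare cell by cell.

1. **Dynamic programming** (`exact_counts`).  The authority.  Each family's
   rational generating function, written with positive unit constant term
   in the denominator, yields a *delta-corrected* recurrence valid on the
   whole grid: denominator ⊛ coefficients = numerator, with out-of-range
   terms zero and Kronecker-delta sources from the numerator.  For g:
   g(n,m) − g(n−1,m−1) − g(n−1,m) − g(n,m−1) + 2g(n−2,m−2) =
   [n=m=0] − [n=m=1].  This fixes the n=1 and m=1 lines that the bare
   recurrences (stated only for n, m ≥ 2 with axis initial conditions)
   leave open, with no special cases.  O(n·m) big-integer cells.

2. **Explicit sums** (`closed_forms`).  f by Σ 2^k C(m,k) C(n,k); h by the
   alternating factorial sum with floor-bounded limits; g by the quadruple
   alternating sum over multinomial terms
   β(i,j) = (−1)^(i−j) 2^(i−j) i! / ((i−j)! (2i−j−m)! (2i−j−n)! (3j−4i+m+n)!),
   with the γ part equal to the β part evaluated at (n−1, m−1) (it arises
   from the −xy factor in the numerator of G).  Conventions fixed here:
   lower j-bounds round **up** (they come from constraints of the form
   3j ≥ 4i − m − n), upper j-bounds round **down**; the outer lower bound is
   U(n, m) = m − ⌊n/2⌋ for n ≤ m and ⌊(m+1)/2⌋ + n − m for n ≥ m, clamped
   at 0 — the only bracket reading under which the two branches agree at
   n = m and the sum reproduces the DP table (verified exhaustively on
   0 ≤ n, m ≤ 60 during development, and on 0..40 in the suite).  Any term
   containing a factorial of a negative integer is 0; this also makes the
   γ-part inner bounds robust to off-by-one readings.  `g_theorem1`
   cross-checks itself against the DP table on every call and raises a
   formula-discrepancy error rather than return a wrong value.

3. **Terminating hypergeometric series** (`hyperseries`).  Exact rational
   term-by-term accumulation of pFq with a non-positive-integer upper
   parameter; the termination index is the *minimum* of −a over such
   parameters (every later term contains a vanished rising factorial).
   f(n,m) = ₂F₁(−m, −n; 1; 2).  h(n,m) is a difference of two ₄F₃ values at
   argument 16/27 with binomial prefactors, the second block being the
   first at (n−1, m−1).  One lower parameter, of the form −(m+n−c)/3 with
   c ∈ {0, 1, 2}, is always a non-positive integer; its rising factorial
   first vanishes at term index (m+n−c)/3 + 1, which always exceeds the
   termination index min(⌊m/2⌋, ⌊n/2⌋) (for m ≤ n, (2m−2)/3 + 1 ≤ m/2 has
   no solutions), so the series is never actually singular.  The evaluator
   still guards every denominator factor and `h_hyp` would fall back to the
   closed sum on a degenerate cell; the observed exception set on
   0 ≤ n, m ≤ 40 is empty.

4. **Series expansion** (`genfun`).  Coefficient extraction from the stored
   numerator/denominator pairs by the convolution recurrence; requires only
   a ±1 denominator constant term.  Mirrors what a computer-algebra
   `Coefficient` command would produce, without leaving integer arithmetic.

5. **Enumeration oracle** (`oracle`).  For n + m ≤ 14 (configurable cap;
   f(7,7) is already tens of thousands of words) the alignments are built
   explicitly.  Reduced forms are counted by two independent methods:
   exhaustive rewriting of every word to all of its normal forms
   (memoized), and direct recursive enumeration of the constrained column
   sequences.  Agreement of both with the DP tables is the central
   semantic validation of the artifact.

## Parameters and defaults

* Enumeration cap n + m ≤ 14 — keeps the oracle's word sets in the tens of
  thousands; beyond it the formula routes are the only ones available.
* `census count --route auto` uses the DP table and cross-checks the
  closed forms up to 60×60 (beyond that the quadratic closed-form terms
  add noticeable cost for no extra assurance; the DP is the authority).
* Scientific notation: 6 significant digits, round half-even, computed
  from the exact integer via decimal string arithmetic — float conversion
  of a 35-digit integer can be off in the last printed digit.
* Threshold search (`census threshold`) grows one square table
  incrementally (O(s) new cells per diagonal step) and compares exact
  integers; the bound is parsed exactly from mantissa/exponent notation.
  The partially reduced diagonal first exceeds 10⁸⁰ at n = 115 exactly:
  g(114,114) ≤ 10⁸⁰ < g(115,115), so the published sufficiency bound is
  also the minimum.

## Problem sizes in the default runs

The test suite checks route equivalence on the 41×41 window (all families,
all applicable routes), structural properties (symmetry, unit boundary,
monotonicity, strict h < g < f chain) on 31×31, and oracle agreement for
all n + m ≤ 12; the acceptance script builds the 101×101 partially reduced
table.  These sizes exercise every code path and boundary line while
keeping the whole suite within seconds on one CPU.

## Inputs

The counts depend only on sequence lengths.  `census fasta` takes the
first record of each FASTA file (warning if more follow), case-insensitive
A/C/G/T/N by default, arbitrary non-gap residues with `--no-validate`;
gap characters are always rejected because the inputs are unaligned
sequences.  No other external data formats are involved.

## Known limitations

* No asymptotics or diagonal closed forms; the package computes exact
  values only.
* The hypergeometric route covers f and h only; no such representation is
  implemented for g (the quadruple sum, the DP and the series expansion
  cover it three ways).
* Multiple-sequence (more than two) alignment counts are out of scope.
* The oracle is exponential by nature and hard-capped; it is a validation
  device, not a production route.
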