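"""Semantics: enumeration, reduced forms and rendering of alignment words."""

import pytest

from aligncount import (
    Family,
    Relation,
    canonical_count,
    count_classes,
    enumerate_alignments,
    render_alignment,
)
from aligncount.oracle import EnumerationCapError, reduced_forms


def test_enumeration_smallest_cases():
    assert enumerate_alignments(1, 1) == {"M", "DI", "ID"}
    assert enumerate_alignments(0, 3) == {"III"}
    assert enumerate_alignments(0, 0) == {""}


def test_enumeration_size_is_total_count(tables):
    for n in range(7):
        for m in range(7):
            assert len(enumerate_alignments(n, m)) == tables[Family.F][n, m]


def test_enumeration_cap_enforced():
    with pytest.raises(EnumerationCapError) as err:
        enumerate_alignments(8, 8)
    assert err.value.bound > 0


def test_reduction_is_not_confluent():
    """One alignment can reduce to several distinct forms — the reason the
    reduced-form counts exceed naive rewrite-graph component counts."""
    assert reduced_forms("IDI", Relation.H_RELATION) == {"MI", "IM"}
    assert reduced_forms("IDI", Relation.G_RELATION) == {"PI", "IP"}
    assert reduced_forms("M", Relation.H_RELATION) == {"M"}


def test_background_example_collapses_to_ungapped_form():
    # the two 5-column alignments of a 3-mer vs a 4-mer with adjacent
    # complementary gaps both reduce to the 4-column form
    assert "MMMI" in reduced_forms("MDIMI", Relation.H_RELATION)
    assert "MMMI" in reduced_forms("MIDMI", Relation.H_RELATION)
    # under partial reduction they share the fused form instead
    assert reduced_forms("MDIMI", Relation.G_RELATION) == {"MPMI"}
    assert reduced_forms("MIDMI", Relation.G_RELATION) == {"MPMI"}


def test_one_vs_one_reduced_forms():
    assert count_classes(1, 1, Relation.G_RELATION) == 2  # {M, P}
    assert count_classes(1, 1, Relation.H_RELATION) == 1  # {M}
    assert canonical_count(1, 1, Relation.G_RELATION) == 2
    assert canonical_count(1, 1, Relation.H_RELATION) == 1


@pytest.mark.parametrize("relation, family", [
    (Relation.G_RELATION, Family.G),
    (Relation.H_RELATION, Family.H),
])
def test_reduced_form_counts_match_tables(relation, family, tables):
    """The central semantic validation: rewriting normal forms and direct
    canonical enumeration both reproduce the recurrence tables."""
    for n in range(7):
        for m in range(7):
            want = tables[family][n, m]
            assert count_classes(n, m, relation) == want, (n, m)
            assert canonical_count(n, m, relation) == want, (n, m)


def test_every_alignment_has_a_reduced_form():
    for relation in Relation:
        for w in enumerate_alignments(3, 3):
            forms = reduced_forms(w, relation)
            assert forms
            for form in forms:
                assert "DI" not in form and "ID" not in form


def test_render_paper_tables():
    assert render_alignment("MDIMI", "CGT", "ACTT") == ("CG-T-", "A-CTT")
    assert render_alignment("MIDMI", "CGT", "ACTT") == ("C-GT-", "AC-TT")
    assert render_alignment("MMMI", "CGT", "ACTT") == ("CGT-", "ACTT")


def test_render_rejects_inconsistent_word():
    with pytest.raises(ValueError):
        render_alignment("MM", "CGT", "AC")
    with pytest.raises(ValueError):
        render_alignment("MXM", "AB", "AB")
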