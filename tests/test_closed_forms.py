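"""Explicit sums against the DP recurrences, and the summation bounds."""

import pytest

from aligncount import (
    Family,
    f_closed,
    g_theorem1,
    h_closed,
    table,
    theorem1_bounds,
)

RANGE = 25  # cell-by-cell closed-form window for the default test run


def test_f_closed_direct_values():
    assert f_closed(0, 7) == 1
    assert f_closed(1, 1) == 3  # 1 + 2*C(1,1)*C(1,1)


def test_h_closed_direct_values():
    assert h_closed(4, 0) == 1
    # first sum 2!/1 = 2, second sum 0!/1 = 1
    assert h_closed(1, 1) == 1


@pytest.mark.parametrize("fn", [f_closed, h_closed, g_theorem1])
def test_negative_arguments_rejected(fn):
    with pytest.raises(ValueError):
        fn(-1, 2)


@pytest.mark.parametrize(
    "family, fn",
    [(Family.F, f_closed), (Family.H, h_closed), (Family.G, g_theorem1)],
)
def test_closed_forms_match_dp_tables(family, fn):
    t = table(family, RANGE, RANGE)
    for n in range(RANGE + 1):
        for m in range(RANGE + 1):
            assert fn(n, m) == t[n, m], (family, n, m)


@pytest.mark.parametrize("fn", [f_closed, h_closed, g_theorem1])
def test_closed_forms_symmetric(fn):
    for n in range(10):
        for m in range(10):
            assert fn(n, m) == fn(m, n)


def test_g_reference_value_via_quadruple_sum():
    assert g_theorem1(10, 10) == 2003204


def test_bounds_empty_range_contract():
    from aligncount.closed_forms import _beta_sum

    b0 = theorem1_bounds(0, 0, 0)
    assert (b0.A, b0.B) == (0, 0)
    # outer index past the termination point: inner window must be empty
    b = theorem1_bounds(1, 0, 0)
    assert b.A > b.B
    assert _beta_sum(1, 0, 0, b.A, b.B) == 0


def test_outer_lower_bound_branches_agree_on_diagonal():
    for m in range(0, 20):
        le = theorem1_bounds(0, m, m).U  # n <= m branch
        ge = theorem1_bounds(0, m, m).U  # n >= m branch (same cell)
        assert le == ge == m - m // 2


def test_outer_lower_bound_is_symmetric():
    for n in range(12):
        for m in range(12):
            assert theorem1_bounds(0, n, m).U == theorem1_bounds(0, m, n).U


def test_outer_lower_bound_is_tight():
    """Dropping the lower outer bound to 0 must not change the sum: all
    skipped terms have empty inner ranges."""
    from aligncount.closed_forms import _beta_sum, _u_bound

    for n in range(8):
        for m in range(8):
            u = max(0, _u_bound(n, m))
            for i in range(u):
                b = theorem1_bounds(i, n, m)
                assert _beta_sum(i, n, m, b.A, b.B) == 0, (i, n, m)
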