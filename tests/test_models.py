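"""Closed-form class distributions: frozen values, identities, domains."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetralink.models import (
    THREE_LOCUS_CLASSES,
    CoClassCounts,
    ModelParams,
    TetradClassCounts,
    co_class_probs,
    simplex_gamete_probs,
    tetrad_phenotype_probs,
    three_locus_phenotype_probs,
)

ALPHA_GRID = [0.0, 0.05, 0.15, 0.5, 1.0]
R_GRID = [0.0, 0.05, 0.2, 0.45, 0.6, 0.75]


@pytest.mark.parametrize(
    "alpha, r, expected",
    [
        (0.0, 0.0, (0.5, 0.0, 0.0, 0.5)),
        (0.0, 0.5, (0.291667, 0.208333, 0.152778, 0.347222)),
        (0.1, 0.2, (0.390000, 0.085000, 0.067667, 0.457333)),
    ],
)
def test_tetrad_phenotype_probs_values(alpha, r, expected):
    np.testing.assert_allclose(
        tetrad_phenotype_probs(alpha, r), expected, atol=5e-7
    )


def test_tetrad_probs_sum_to_one_and_in_range():
    for a in ALPHA_GRID:
        for r in R_GRID:
            p = tetrad_phenotype_probs(a, r)
            assert abs(p.sum() - 1.0) < 1e-12
            assert (p >= -1e-15).all() and (p <= 1.0).all()


def test_carrier_marginal_is_simplex_frequency():
    # f_y + f_g = (2 - alpha)/4 for every r: the proximal-locus marginal
    # does not depend on recombination
    for a in ALPHA_GRID:
        for r in R_GRID:
            p = tetrad_phenotype_probs(a, r)
            assert abs(p[0] + p[1] - (2.0 - a) / 4.0) < 1e-12


@pytest.mark.parametrize(
    "alpha, expected",
    [(0.0, (0.5, 0.5)), (0.2, (0.45, 0.55)), (1.0, (0.25, 0.75))],
)
def test_simplex_gamete_probs(alpha, expected):
    pair = simplex_gamete_probs(alpha)
    np.testing.assert_allclose(pair, expected, atol=1e-12)
    assert abs(sum(pair) - 1.0) < 1e-12


@pytest.mark.parametrize(
    "alpha, p, expected",
    [
        (0.0, 0.0, (0.0, 1.0, 0.0, 0.0, 0.0)),
        (0.5, 0.2, (0.45, 0.458333, 0.05, 0.008333, 0.033333)),
        (0.0, 0.24, (0.0, 0.9, 0.0, 0.02, 0.08)),
    ],
)
def test_co_class_probs_values(alpha, p, expected):
    np.testing.assert_allclose(co_class_probs(alpha, p), expected, atol=5e-7)


def test_co_class_probs_small_p_limit():
    # as p -> 0 the mass concentrates on classes 1-2 in ratio alpha:(1-alpha)
    for a in (0.1, 0.5):
        f = co_class_probs(a, 1e-9)
        assert f[2:].sum() < 1e-8
        assert abs(f[0] / f[1] - a / (1.0 - a)) < 1e-6


@given(
    alpha=st.floats(0.0, 1.0),
    p=st.floats(0.0, 1.0),
    r=st.floats(0.0, 0.75),
)
@settings(max_examples=200, derandomize=True)
def test_probability_vectors_valid(alpha, p, r):
    for vec in (tetrad_phenotype_probs(alpha, r), co_class_probs(alpha, p)):
        assert abs(vec.sum() - 1.0) < 1e-12
        assert (vec >= -1e-12).all()


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(alpha=-0.1, r=0.2),
        dict(alpha=1.2, r=0.2),
        dict(alpha=0.0, r=0.76),
        dict(alpha=0.0, r=-0.01),
    ],
)
def test_tetrad_probs_domain_errors(kwargs):
    with pytest.raises(ValueError):
        tetrad_phenotype_probs(**kwargs)


def test_model_params_invariants():
    ModelParams(alpha=0.1, beta=0.2, r=0.6, p=0.3)
    with pytest.raises(ValueError):
        ModelParams(r=0.8)
    with pytest.raises(ValueError):
        ModelParams(alpha=-0.2)


def test_count_containers_validate():
    c = TetradClassCounts(1, 2, 3, 4)
    assert c.n == 10
    with pytest.raises(ValueError):
        TetradClassCounts(-1, 0, 0, 5)
    with pytest.raises(ValueError):
        TetradClassCounts(0, 0, 0, 0)
    assert CoClassCounts(1, 1, 1, 1, 1).n == 5
    with pytest.raises(ValueError):
        CoClassCounts(0, 0, 0, 0, 0)


# ---------------------------------------------------------------------------
# three-locus distributions


def _event_masses(probs):
    none = ab = bc = double = 0.0
    for cls, p in zip(THREE_LOCUS_CLASSES, probs):
        a, b, c = (ch.isupper() for ch in cls)
        rec_ab, rec_bc = a != b, b != c
        if rec_ab and rec_bc:
            double += p
        elif rec_ab:
            ab += p
        elif rec_bc:
            bc += p
        else:
            none += p
    return none, ab, bc, double


def test_disomic_three_locus_independence_and_zero():
    p = three_locus_phenotype_probs(0.2, 0.1, 1.0, "disomic")
    assert abs(p.sum() - 1.0) < 1e-12
    none, ab, bc, double = _event_masses(p)
    assert abs(double - 0.02) < 1e-12
    # split evenly over the two double-recombinant phase classes
    i_abc = THREE_LOCUS_CLASSES.index("AbC")
    i_abc2 = THREE_LOCUS_CLASSES.index("aBc")
    assert abs(p[i_abc] - 0.01) < 1e-12 and abs(p[i_abc2] - 0.01) < 1e-12
    p0 = three_locus_phenotype_probs(0.2, 0.1, 0.0, "disomic")
    assert abs(_event_masses(p0)[3]) < 1e-12


def test_disomic_three_locus_factorizes_under_independence():
    # with coincidence 1 the (rec_AB, rec_BC) events are independent
    for r1, r2 in [(0.1, 0.3), (0.25, 0.05)]:
        none, ab, bc, double = _event_masses(
            three_locus_phenotype_probs(r1, r2, 1.0, "disomic")
        )
        assert abs(double - r1 * r2) < 1e-12
        assert abs(ab - r1 * (1 - r2)) < 1e-12
        assert abs(bc - (1 - r1) * r2) < 1e-12


def test_disomic_infeasible_coincidence_raises():
    with pytest.raises(ValueError):
        three_locus_phenotype_probs(0.4, 0.4, 4.0, "disomic")


def test_tetrasomic_three_locus_margins_match_two_locus_model():
    # marginalizing the distal locus must reproduce the closed-form
    # four-class distribution at (alpha, r1), for any r2
    for alpha in (0.0, 0.1, 0.3):
        for r1 in (0.05, 0.2, 0.6):
            probs = three_locus_phenotype_probs(r1, 0.15, 1.0, "tetrasomic", alpha)
            assert abs(probs.sum() - 1.0) < 1e-12
            marg = np.zeros(4)
            for cls, p in zip(THREE_LOCUS_CLASSES, probs):
                a, b, _ = (ch.isupper() for ch in cls)
                marg[{(True, True): 0, (True, False): 1,
                      (False, True): 2, (False, False): 3}[(a, b)]] += p
            np.testing.assert_allclose(
                marg, tetrad_phenotype_probs(alpha, r1), atol=1e-12
            )


def test_tetrasomic_distal_margin_matches_when_independent():
    # under coincidence 1 the B-C margin equals the two-locus model at
    # (alpha_B, r2) where alpha_B is the emergent double-reduction level
    # at locus B; at alpha = 0 and r1 = 0 it is exactly alpha_B = 0
    probs = three_locus_phenotype_probs(0.0, 0.3, 1.0, "tetrasomic", 0.0)
    marg = np.zeros(4)
    for cls, p in zip(THREE_LOCUS_CLASSES, probs):
        _, b, c = (ch.isupper() for ch in cls)
        marg[{(True, True): 0, (True, False): 1,
              (False, True): 2, (False, False): 3}[(b, c)]] += p
    np.testing.assert_allclose(marg, tetrad_phenotype_probs(0.0, 0.3), atol=1e-12)
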