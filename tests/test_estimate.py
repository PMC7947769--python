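"""Estimators: frozen examples, Fisher consistency, sampling recovery."""

import numpy as np
import pytest
from scipy.special import xlogy

from tetralink.estimate import (
    cm_per_mb,
    estimate_alpha_gamete,
    estimate_alpha_tetrad,
    estimate_p_co,
    estimate_r_diploid,
    estimate_r_tetrasomic,
    expected_co_per_chromosome,
    neutrality_test,
    EstimateWithSE,
)
from tetralink.models import (
    CoClassCounts,
    TetradClassCounts,
    co_class_probs,
    tetrad_phenotype_probs,
)


def expected_tetrad_counts(alpha, r, n):
    return TetradClassCounts(
        *(int(round(x)) for x in n * tetrad_phenotype_probs(alpha, r))
    )


# ---------------------------------------------------------------------------
# double reduction


def test_alpha_tetrad_balanced_counts_zero():
    est = estimate_alpha_tetrad(TetradClassCounts(250, 250, 250, 250), "proximal")
    assert est.value == 0.0 and not est.truncated


def test_alpha_tetrad_proximal_and_distal_closed_forms():
    counts = TetradClassCounts(3510, 765, 609, 4116)  # exact at alpha=.1, r=.2
    prox = estimate_alpha_tetrad(counts, "proximal")
    dist = estimate_alpha_tetrad(counts, "distal")
    assert abs(prox.value - 0.1) < 1e-12
    assert abs(dist.value - 0.169333) < 5e-7


def test_alpha_tetrad_se_matches_binomial_oracle():
    est = estimate_alpha_tetrad(TetradClassCounts(300, 300, 200, 200), "proximal")
    assert abs(est.se - 0.061968) < 5e-7
    # at expected counts (any r: the carrier marginal is r-free), the
    # pooled-count variance equals (4 - alpha^2)/n exactly
    for alpha in (0.0, 0.1, 0.3):
        for r in (0.0, 0.2, 0.6):
            n = 1_000_000
            f = tetrad_phenotype_probs(alpha, r) * n
            m1, m2 = f[0] + f[1], f[2] + f[3]
            var = 16.0 * m1 * m2 / n**3
            assert abs(var - (4.0 - alpha**2) / n) < 1e-12


def test_alpha_tetrad_truncates_negative():
    est = estimate_alpha_tetrad(TetradClassCounts(300, 300, 200, 200), "proximal")
    assert est.value == 0.0 and est.truncated


@pytest.mark.parametrize(
    "n1, n2, value", [(500, 500, 0.0), (450, 550, 0.2)]
)
def test_alpha_gamete_values(n1, n2, value):
    est = estimate_alpha_gamete(n1, n2)
    assert abs(est.value - value) < 1e-12


def test_alpha_gamete_se_printed_variance():
    est = estimate_alpha_gamete(450, 550)
    assert abs(est.se - np.sqrt(15.6816 / 3960.0)) < 1e-9
    assert abs(est.se - 0.062927) < 5e-6
    with pytest.raises(ValueError):
        estimate_alpha_gamete(0, 0)


# ---------------------------------------------------------------------------
# recombination fraction


def test_r_tetrasomic_all_parental_boundary():
    fit = estimate_r_tetrasomic(TetradClassCounts(500, 0, 0, 500))
    assert fit.r.value == 0.0 and fit.r.truncated


@pytest.mark.parametrize(
    "counts, alpha_true, r_true",
    [
        ((366, 84, 58, 392), 0.0, 0.2),
        ((3510, 765, 609, 4116), 0.1, 0.2),
    ],
)
def test_r_tetrasomic_exact_expected_counts(counts, alpha_true, r_true):
    fit = estimate_r_tetrasomic(TetradClassCounts(*counts))
    assert abs(fit.alpha.value - alpha_true) < 1e-9
    assert abs(fit.r.value - r_true) < 1e-4


def test_r_tetrasomic_fisher_consistency_grid():
    # exact expected counts recover the generating r to high precision,
    # including r > 0.5 (tetrasomic admissible range)
    n = 1_000_000
    for alpha in (0.0, 0.05, 0.15):
        for r in (0.05, 0.2, 0.45, 0.6):
            f = tetrad_phenotype_probs(alpha, r) * n
            counts = TetradClassCounts(*(int(round(x)) for x in f))
            fit = estimate_r_tetrasomic(counts)
            assert abs(fit.r.value - r) < 1e-5
            assert abs(fit.alpha.value - alpha) < 1e-4


def test_r_tetrasomic_joint_mode_agrees():
    counts = TetradClassCounts(3510, 765, 609, 4116)
    prof = estimate_r_tetrasomic(counts)
    joint = estimate_r_tetrasomic(counts, joint=True)
    assert abs(prof.r.value - joint.r.value) < 1e-3


def test_r_tetrasomic_sampling_recovery(rng):
    # multinomial samples at n=1000: mean estimate within 3 MC SEs of
    # truth and empirical SD within 30% of the asymptotic SE
    n, reps = 1000, 200
    for alpha, r in [(0.0, 0.05), (0.0, 0.45), (0.15, 0.2), (0.05, 0.6)]:
        probs = tetrad_phenotype_probs(alpha, r)
        draws = rng.multinomial(n, probs, size=reps)
        fits = [estimate_r_tetrasomic(TetradClassCounts(*d)) for d in draws]
        vals = np.array([f.r.value for f in fits])
        ses = np.array([f.r.se for f in fits])
        mc_se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - r) < 3.5 * mc_se + 1e-3
        assert abs(vals.std(ddof=1) - ses.mean()) < 0.3 * ses.mean()


@pytest.mark.parametrize(
    "counts, r, se",
    [
        ((500, 0, 0, 500), 0.0, 0.0),
        ((450, 50, 50, 450), 0.1, 0.009487),
        ((250, 250, 250, 250), 0.5, None),
    ],
)
def test_r_diploid_values(counts, r, se):
    est = estimate_r_diploid(TetradClassCounts(*counts))
    assert abs(est.value - r) < 1e-12
    if se is not None:
        assert abs(est.se - se) < 5e-7


def test_r_diploid_never_exceeds_half():
    est = estimate_r_diploid(TetradClassCounts(100, 500, 300, 100))
    assert est.value == 0.5 and est.truncated


# ---------------------------------------------------------------------------
# crossover probability per interval


@pytest.mark.parametrize(
    "counts, p_true",
    [
        ((500, 500, 0, 0, 0), 0.0),
        ((0, 900, 0, 20, 80), 0.24),
        ((540, 550, 60, 10, 40), 0.2),
    ],
)
def test_p_co_closed_form(counts, p_true):
    fit = estimate_p_co(CoClassCounts(*counts))
    assert abs(fit.p.value - p_true) < 1e-9


def test_p_co_alpha_and_delta():
    counts = CoClassCounts(540, 550, 60, 10, 40)
    n, n1, n2 = 1200, 540, 550
    delta = np.sqrt(n**2 + 2 * n * (5 * n1 - 6 * n2) + (5 * n1 + 6 * n2) ** 2)
    assert delta == 6000.0  # the minus root gives the admissible estimate
    fit = estimate_p_co(counts)
    assert abs(fit.alpha.value - 0.5) < 1e-12


def test_p_co_matches_numeric_argmax_random(rng):
    # closed form vs dense-grid maximization of the five-class likelihood
    grid = np.arange(1e-6, 1.0, 1e-5)
    for _ in range(100):
        a = rng.uniform(0.02, 0.95)
        p = rng.uniform(0.02, 0.95)
        draw = rng.multinomial(2000, co_class_probs(a, p))
        counts = CoClassCounts(*draw)
        fit = estimate_p_co(counts)
        a_hat = fit.alpha.value
        ll = xlogy(draw[:, None], co_class_probs_grid(a_hat, grid)).sum(axis=0)
        p_grid = grid[int(np.argmax(ll))]
        assert abs(fit.p.value - p_grid) <= 1e-4


def co_class_probs_grid(alpha, p):
    return np.stack(
        [
            alpha * (1.0 - p / 2.0),
            (1.0 - alpha) * (1.0 - 5.0 * p / 12.0),
            alpha * p / 2.0,
            (1.0 - alpha) * p / 12.0,
            (1.0 - alpha) * p / 3.0,
        ]
    )


def test_expected_co_per_chromosome():
    est = expected_co_per_chromosome([0.2, 0.24, 0.0])
    assert abs(est.value - 0.44) < 1e-12
    assert expected_co_per_chromosome([1.0] * 5).value == 5.0
    with pytest.raises(ValueError):
        expected_co_per_chromosome([])
    quad = expected_co_per_chromosome(
        [EstimateWithSE(0.2, 0.03), EstimateWithSE(0.1, 0.04)]
    )
    assert abs(quad.se - 0.05) < 1e-12


# ---------------------------------------------------------------------------
# neutrality and map density


def test_neutrality_disomic():
    perfect = neutrality_test(TetradClassCounts(250, 250, 250, 250), "disomic")
    assert perfect.statistic == 0.0 and perfect.pvalue == 1.0
    skew = neutrality_test(TetradClassCounts(300, 300, 200, 200), "disomic")
    assert abs(skew.statistic - 40.0) < 1e-9
    assert skew.pvalue < 1e-9


def test_neutrality_tetrasomic_null_attainable():
    n = 10_000
    counts = TetradClassCounts(
        *(int(round(x)) for x in n * tetrad_phenotype_probs(0.1, 0.2))
    )
    res = neutrality_test(counts, "tetrasomic")
    assert res.statistic == 0.0 and res.pvalue == 1.0
    # strong distortion is detected
    bad = neutrality_test(TetradClassCounts(100, 100, 400, 400), "tetrasomic")
    assert bad.pvalue < 1e-6


def test_cm_per_mb():
    assert cm_per_mb(0.2, 0.05) == 400.0
    assert cm_per_mb(0.0, 1.0) == 0.0
    assert abs(cm_per_mb(0.6143, 0.1) - 614.3) < 1e-9
    with pytest.raises(ValueError):
        cm_per_mb(0.2, 0.0)
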