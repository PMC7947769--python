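"""Samplers: determinism, calibration contracts, round trips."""

import numpy as np
import pytest

from tetralink.estimate import estimate_r_tetrasomic
from tetralink.interference import cc_from_haploid_counts
from tetralink.models import tetrad_phenotype_probs
from tetralink.simulate import (
    make_genotype_matrices,
    sample_class_counts,
    simulate_diploid_tetrads,
    simulate_tetraploid_gametes,
    simulate_tetraploid_tetrads,
    tetrad_counts_from_gametes,
    three_locus_counts_from_spores,
)


def test_sample_class_counts_basics():
    assert (sample_class_counts([1, 0, 0, 0], 100, seed=1) == [100, 0, 0, 0]).all()
    a = sample_class_counts([0.3, 0.7], 1000, seed=42)
    b = sample_class_counts([0.3, 0.7], 1000, seed=42)
    assert (a == b).all()
    with pytest.raises(ValueError):
        sample_class_counts([0.5, 0.6], 10, seed=0)


def test_sample_class_counts_clt(rng):
    p = 0.37
    draws = rng.multinomial(1000, [p, 1 - p], size=1000)[:, 0] / 1000
    assert abs(draws.mean() - p) < 3 * np.sqrt(p * (1 - p) / 1e6)


# ---------------------------------------------------------------------------
# diploid tetrads


def test_diploid_tetrads_no_recombination(rng):
    origins, registry = simulate_diploid_tetrads([0.0, 0.0], 100, rng=rng)
    assert registry == []
    assert (np.diff(origins, axis=2) == 0).all()


def test_diploid_tetrads_recombinant_fraction(rng):
    n = 10_000
    origins, _ = simulate_diploid_tetrads([0.2], n, rng=rng)
    rec = (origins[:, :, 0] != origins[:, :, 1]).mean()
    assert abs(rec - 0.2) < 3 * np.sqrt(0.2 * 0.8 / (4 * n))


def test_diploid_tetrads_reciprocity_and_balance(rng):
    origins, _ = simulate_diploid_tetrads([0.3, 0.25], 500, rng=rng)
    # every locus column of every tetrad carries exactly two of each origin
    assert (origins.sum(axis=1) == 2).all()


def test_diploid_tetrads_coincidence_controls_double_rate(rng):
    n = 40_000
    for c, expected in [(1.0, 0.02), (0.0, 0.0)]:
        origins, _ = simulate_diploid_tetrads([0.2, 0.1], n, coincidence=c, rng=rng)
        r1 = origins[:, :, 0] != origins[:, :, 1]
        r2 = origins[:, :, 1] != origins[:, :, 2]
        double = (r1 & r2).mean()
        assert abs(double - expected) <= 3 * np.sqrt(max(expected, 2e-5) / (4 * n)) + 1e-4


def test_diploid_tetrads_round_trip_cc(rng):
    origins, _ = simulate_diploid_tetrads([0.2, 0.1], 25_000, rng=rng)
    res = cc_from_haploid_counts(three_locus_counts_from_spores(origins))
    assert abs(res.c_joint - 1.0) < 0.15


def test_diploid_infeasible_inputs():
    with pytest.raises(ValueError):
        simulate_diploid_tetrads([0.6], 10, seed=0)
    with pytest.raises(ValueError):
        simulate_diploid_tetrads([0.4, 0.4], 10, coincidence=2.0, seed=0)


# ---------------------------------------------------------------------------
# tetraploid gametes (calibrated)


def test_bivalent_pairing_has_no_double_reduction(rng):
    g = simulate_tetraploid_gametes(0.0, [0.2], 50_000, pairing="bivalent", rng=rng)
    carrier = (g[:, :, 0] == 0).any(axis=1).mean()
    assert abs(carrier - 0.5) < 3 * np.sqrt(0.25 / 50_000)
    with pytest.raises(ValueError):
        simulate_tetraploid_gametes(0.1, [0.2], 10, pairing="bivalent", seed=0)


@pytest.mark.parametrize("alpha", [0.0, 0.05, 0.15])
@pytest.mark.parametrize("r", [0.05, 0.2, 0.45])
def test_quadrivalent_class_frequencies_match_closed_form(alpha, r):
    n = 60_000
    g = simulate_tetraploid_gametes(alpha, [r], n, seed=round(1000 * (alpha + r)))
    counts = tetrad_counts_from_gametes(g)
    freq = counts.as_array() / n
    expected = tetrad_phenotype_probs(alpha, r)
    tol = 3 * np.sqrt(expected * (1 - expected) / n) + 1e-9
    assert (np.abs(freq - expected) < tol).all()


def test_quadrivalent_carrier_frequency(rng):
    g = simulate_tetraploid_gametes(0.12, [0.3], 80_000, rng=rng)
    carrier = (g[:, :, 0] == 0).any(axis=1).mean()
    expect = (2 - 0.12) / 4
    assert abs(carrier - expect) < 3 * np.sqrt(expect * (1 - expect) / 80_000)


def test_quadrivalent_independence_across_intervals(rng):
    g = simulate_tetraploid_gametes(0.0, [0.2, 0.15], 60_000, coincidence=1.0, rng=rng)
    # per-chromatid switch events are independent across the two intervals
    sw1 = g[:, :, 0] != g[:, :, 1]
    sw2 = g[:, :, 1] != g[:, :, 2]
    # note a chromatid can switch and return only via distinct homologs,
    # so origin inequality identifies the switch exactly
    p11 = (sw1 & sw2).mean()
    assert abs(p11 - 0.2 * 0.15) < 3 * np.sqrt(0.03 * 0.97 / (2 * 60_000))


def test_round_trip_estimator_recovery(rng):
    n = 50_000
    g = simulate_tetraploid_gametes(0.1, [0.2], n, rng=rng)
    fit = estimate_r_tetrasomic(tetrad_counts_from_gametes(g))
    assert abs(fit.r.value - 0.2) < 3 * fit.r.se


def test_same_seed_bit_identical():
    a = simulate_tetraploid_gametes(0.1, [0.2, 0.3], 500, seed=7)
    b = simulate_tetraploid_gametes(0.1, [0.2, 0.3], 500, seed=7)
    assert (a == b).all()
    c, _ = simulate_diploid_tetrads([0.2], 500, seed=7)
    d, _ = simulate_diploid_tetrads([0.2], 500, seed=7)
    assert (c == d).all()


# ---------------------------------------------------------------------------
# mechanistic tetrads and genotype matrices


def test_mechanistic_tetrads_conserve_chromatids(rng):
    spores, registry = simulate_tetraploid_tetrads([0.4, 0.4], 300, rng=rng)
    assert spores.shape == (300, 4, 2, 3)
    # simplex dosage sums to 2 copies per tetrad at every locus
    dosage = (spores == 0).sum(axis=2)
    assert (dosage.sum(axis=1) == 2).all()
    # at the first locus each spore holds chromatids of two distinct homologs
    assert (spores[:, :, 0, 0] != spores[:, :, 1, 0]).all()


def test_mechanistic_double_reduction_emerges(rng):
    # with crossovers, some spores become sister-derived at distal loci
    spores, _ = simulate_tetraploid_tetrads([0.9] * 3, 2000, rng=rng)
    same = spores[:, :, 0, -1] == spores[:, :, 1, -1]
    assert 0.0 < same.mean() < 1.0 / 6.0 + 0.05


def test_genotype_matrices_no_co_no_noise():
    mats, truth = make_genotype_matrices(
        "disomic", 4, 20, 500_000, expected_co=0.0, seed=3
    )
    assert truth.empty
    for gm in mats:
        assert (np.diff(gm.dosages.astype(int), axis=0) == 0).all()


def test_genotype_matrices_reciprocal_switch(rng):
    mats, truth = make_genotype_matrices(
        "disomic", 30, 10, 200_000, expected_co=1.0, rng=rng
    )
    for _, row in truth.iterrows():
        gm = mats[row.tetrad]
        k = int(np.where(gm.positions == row.start)[0][0])
        delta = gm.dosages[k + 1].astype(int) - gm.dosages[k].astype(int)
        assert sorted(delta) == [-1, 0, 0, 1]


def test_genotype_matrices_positions_validated():
    with pytest.raises(ValueError):
        make_genotype_matrices(
            "disomic", 1, 3, 1000, positions=[10, 10, 20], seed=0
        )
    with pytest.raises(ValueError):
        make_genotype_matrices("disomic", 1, 1, 1000, seed=0)
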