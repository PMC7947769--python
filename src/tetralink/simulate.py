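"""Gametogenesis and tetrad samplers for disomic and tetrasomic meiosis.

This is the package's synthetic-data generator.  It provides

* :func:`sample_class_counts` — multinomial sampling of any of the
  closed-form class distributions;
* :func:`simulate_diploid_tetrads` — a four-strand-bundle meiosis model
  for a diploid parent, with per-interval recombination fractions and a
  coincidence scale coupling crossovers in adjacent intervals;
* :func:`simulate_tetraploid_gametes` — diploid gametes of an
  autotetraploid simplex parent under quadrivalent pairing (the
  calibrated chromatid-origin model whose class frequencies reproduce the
  closed-form tetrasomic distributions exactly, with double reduction as
  an input dial) or bivalent pairing (double reduction structurally
  impossible);
* :func:`simulate_tetraploid_tetrads` — an optional mechanistic
  eight-chromatid meiosis (crossovers, then meiosis I/II divisions) in
  which double reduction is emergent rather than dialled; used for
  realism checks and tetrad-consistent genotype matrices;
* :func:`make_genotype_matrices` — spores x markers dosage matrices with
  a ground-truth crossover registry, the fixture generator for crossover
  calling.

All samplers take a seed or a :class:`numpy.random.Generator` and are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    TetradClassCounts,
    three_locus_phenotype_probs,
)
from .cocall import GenotypeMatrix

__all__ = [
    "SimScenario",
    "sample_class_counts",
    "sample_three_locus_counts",
    "simulate_diploid_tetrads",
    "simulate_tetraploid_gametes",
    "simulate_tetraploid_tetrads",
    "make_genotype_matrices",
    "tetrad_counts_from_gametes",
    "three_locus_counts_from_spores",
]


def _rng_from(seed=None, rng: Optional[np.random.Generator] = None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass
class SimScenario:
    """Declarative simulation scenario (mirrors the flat config format).

    ``r`` holds one recombination fraction per marker interval, ``alpha``
    the double-reduction coefficient at the proximal locus.  ``pairing``
    selects the tetrasomic mode: ``quadrivalent`` (calibrated, alpha as a
    dial) or ``bivalent`` (alpha forced to 0).
    """

    ploidy: str = "disomic"
    pairing: str = "quadrivalent"
    r: Sequence[float] = field(default_factory=lambda: [0.2])
    alpha: float = 0.0
    coincidence: float = 1.0
    n: int = 1000
    seed: Optional[int] = None
    output: str = "gametes"  # gametes | tetrads | genotype-matrix


def sample_class_counts(probs, n: int, seed=None, rng=None) -> np.ndarray:
    """One multinomial draw of ``n`` individuals over a class distribution."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be a 1-D probability vector summing to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    return _rng_from(seed, rng).multinomial(n, np.clip(p, 0.0, None) / p.clip(0).sum())


def sample_three_locus_counts(
    n: int,
    r1: float,
    r2: float,
    coincidence: float = 1.0,
    ploidy: str = "disomic",
    alpha: float = 0.0,
    seed=None,
    rng=None,
) -> np.ndarray:
    """Sample the 8-class three-marker phenotype counts of one segregant
    population.  Segregants are independently collected gametes, so the
    population counts are exactly multinomial in the class distribution
    of :func:`tetralink.models.three_locus_phenotype_probs`."""
    probs = three_locus_phenotype_probs(r1, r2, coincidence, ploidy, alpha)
    return sample_class_counts(probs, n, seed=seed, rng=rng)


# ---------------------------------------------------------------------------
# Diploid four-strand tetrads


def _co_indicator_chain(
    r: np.ndarray, coincidence: float, n: int, rng: np.random.Generator,
    scale: float = 2.0,
) -> np.ndarray:
    """Markov chain of per-interval crossover indicators.

    Marginal P(CO in interval k) = scale * r_k, and for adjacent intervals
    P(CO_k and CO_{k+1}) = scale^2 * c * r_k * r_{k+1}, so that the
    spore-level double-recombinant rate equals c * r_k * r_{k+1}.
    """
    m = scale * r
    if np.any(m > 1.0 + 1e-12):
        raise ValueError("recombination fraction too large for the tetrad model")
    co = np.zeros((n, len(r)), dtype=bool)
    co[:, 0] = rng.random(n) < m[0]
    for k in range(1, len(r)):
        p11 = coincidence * m[k - 1] * m[k]
        if p11 > min(m[k - 1], m[k]) + 1e-12 or 1.0 - m[k - 1] - m[k] + p11 < -1e-12:
            raise ValueError(
                f"infeasible coincidence {coincidence} for intervals {k-1},{k}"
            )
        prev = co[:, k - 1]
        p_given1 = p11 / m[k - 1] if m[k - 1] > 0 else 0.0
        p_given0 = (m[k] - p11) / (1.0 - m[k - 1]) if m[k - 1] < 1 else 0.0
        u = rng.random(n)
        co[:, k] = np.where(prev, u < p_given1, u < p_given0)
    return co


def simulate_diploid_tetrads(
    r: Sequence[float],
    n_tetrads: int,
    coincidence: float = 1.0,
    seed=None,
    rng=None,
):
    """Simulate tetrads of a diploid parent heterozygous at ``len(r)+1``
    coupled loci (all dominant alleles on homolog 0).

    A four-chromatid bundle receives at most one crossover per marker
    interval with probability ``2 r_k`` between one chromatid of each
    homolog (chosen uniformly), so the recombinant-spore fraction equals
    ``r_k`` exactly and the spore-level double-recombination rate across
    adjacent intervals equals ``coincidence * r_k * r_{k+1}``.

    Returns
    -------
    origins : numpy.ndarray of shape (n_tetrads, 4, n_loci)
        Homolog of origin (0 or 1) of each spore at each locus; spores
        carry the dominant allele where the origin is 0.
    registry : list of (tetrad, interval, (spore_a, spore_b))
        Every placed crossover with the chromatid pair it involved.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("disomic recombination fractions must lie in [0, 0.5]")
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    gen = _rng_from(seed, rng)
    n_loci = len(r) + 1
    co = _co_indicator_chain(r, coincidence, n_tetrads, gen)
    origins = np.zeros((n_tetrads, 4, n_loci), dtype=np.int8)
    origins[:, :, 0] = np.array([0, 0, 1, 1], dtype=np.int8)
    registry: list[tuple[int, int, tuple[int, int]]] = []
    # pre-draw chromatid choices
    pick = gen.integers(0, 2, size=(n_tetrads, len(r), 2))
    for k in range(len(r)):
        origins[:, :, k + 1] = origins[:, :, k]
        for t in np.nonzero(co[:, k])[0]:
            col = origins[t, :, k]
            zeros = np.nonzero(col == 0)[0]
            ones = np.nonzero(col == 1)[0]
            a = int(zeros[pick[t, k, 0]])
            b = int(ones[pick[t, k, 1]])
            origins[t, a, k + 1], origins[t, b, k + 1] = (
                origins[t, b, k + 1],
                origins[t, a, k + 1],
            )
            registry.append((int(t), k, (min(a, b), max(a, b))))
    return origins, registry


def _as_individuals(origins: np.ndarray, n_loci: int) -> np.ndarray:
    """Normalize origin arrays to shape (n, n_chromatids, n_loci).

    Accepted inputs: (n, L) haploid spores; (n, 2, L) diploid gametes;
    (n_tetrads, 4, L) tetrads of haploid spores; (n_tetrads, 4, 2, L)
    tetrads of diploid spores.
    """
    arr = np.asarray(origins)
    if arr.shape[-1] != n_loci:
        raise ValueError(f"expected {n_loci} loci on the last axis, got {arr.shape}")
    if arr.ndim == 2:  # haploid spores
        return arr[:, None, :]
    if arr.ndim == 3 and arr.shape[1] == 2:  # diploid gametes
        return arr
    if arr.ndim == 3 and arr.shape[1] == 4:  # tetrads of haploid spores
        return arr.reshape(-1, arr.shape[-1])[:, None, :]
    if arr.ndim == 4 and arr.shape[1] == 4 and arr.shape[2] == 2:
        return arr.reshape(-1, 2, arr.shape[-1])
    raise ValueError(f"unrecognized origin array shape {arr.shape}")


def tetrad_counts_from_gametes(origins: np.ndarray) -> TetradClassCounts:
    """Collapse two-locus gamete/spore origins to the four fluorescent
    phenotype classes (Y, G, R, B).

    ``origins`` has shape (n, n_chromatids, 2) for diploid gametes of a
    tetraploid, or (n, 2) / (n_tetrads, 4, 2) for haploid spores; a
    carrier at a locus is any chromatid with origin 0.
    """
    has = (_as_individuals(origins, n_loci=2) == 0)
    carrier = has.any(axis=1)  # (n, 2)
    idx = (~carrier[:, 0]).astype(int) * 2 + (~carrier[:, 1]).astype(int)
    counts = np.bincount(idx, minlength=4)
    # idx: 0 = both (Y), 1 = locus1 only (G), 2 = locus2 only (R), 3 = none (B)
    return TetradClassCounts(*(int(c) for c in counts))


def three_locus_counts_from_spores(origins: np.ndarray) -> np.ndarray:
    """Collapse three-locus spore/gamete origins to the 8 canonical
    presence/absence classes (``THREE_LOCUS_CLASSES`` order)."""
    has = (_as_individuals(origins, n_loci=3) == 0)
    carrier = has.any(axis=1)  # (n, 3)
    idx = (
        (~carrier[:, 0]).astype(int) * 4
        + (~carrier[:, 1]).astype(int) * 2
        + (~carrier[:, 2]).astype(int)
    )
    return np.bincount(idx, minlength=8)


# ---------------------------------------------------------------------------
# Tetraploid gametes (calibrated chromatid-origin model)


def simulate_tetraploid_gametes(
    alpha: float,
    r: Sequence[float],
    n: int,
    coincidence: float = 1.0,
    pairing: str = "quadrivalent",
    seed=None,
    rng=None,
) -> np.ndarray:
    """Simulate diploid gametes of an autotetraploid simplex parent
    (dominant alleles on homolog 0 at every locus).

    Quadrivalent pairing (calibrated mode): the gamete's chromatid pair
    at the first locus is sister-derived with probability ``alpha``
    (uniform homolog), otherwise two distinct homologs uniform over the 6
    pairs; each chromatid then switches homolog origin across interval
    ``k`` with probability ``r_k`` (destination uniform over the other
    three homologs), adjacent switch indicators coupled so that
    P(switch in both) = ``coincidence * r_k * r_{k+1}``.  Two-locus class
    frequencies converge to the closed-form tetrasomic distribution at
    the same (alpha, r).

    Bivalent pairing: homologs pair two by two (partner of homolog 0
    uniform), each gamete takes one chromatid from each bivalent and
    switches only to the within-bivalent partner; double reduction is
    structurally impossible, so ``alpha`` must be 0.

    Returns an array of shape (n, 2, n_loci) of homolog origins in 0..3.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.75)):
        raise ValueError("tetrasomic recombination fractions must lie in [0, 0.75]")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = _rng_from(seed, rng)
    n_loci = len(r) + 1

    if pairing == "quadrivalent":
        origins = np.empty((n, 2, n_loci), dtype=np.int8)
        dr = gen.random(n) < alpha
        solo = gen.integers(0, 4, size=n)
        pairs = np.array([(i, j) for i in range(4) for j in range(i + 1, 4)])
        pick = pairs[gen.integers(0, 6, size=n)]
        origins[:, 0, 0] = np.where(dr, solo, pick[:, 0])
        origins[:, 1, 0] = np.where(dr, solo, pick[:, 1])
        for c in range(2):
            sw = _co_indicator_chain(r, coincidence, n, gen, scale=1.0)
            step = gen.integers(1, 4, size=(n, len(r)))
            for k in range(len(r)):
                prev = origins[:, c, k]
                origins[:, c, k + 1] = np.where(
                    sw[:, k], (prev + step[:, k]) % 4, prev
                ).astype(np.int8)
        return origins

    if pairing == "bivalent":
        if alpha != 0.0:
            raise ValueError("double reduction requires quadrivalent pairing; "
                             "alpha must be 0 under bivalent pairing")
        if np.any(r > 0.5):
            raise ValueError("bivalent recombination fractions must lie in [0, 0.5]")
        partner0 = gen.integers(1, 4, size=n)
        others = np.array([[b for b in range(1, 4) if b != a] for a in range(1, 4)])
        rest = others[partner0 - 1]  # the other bivalent, per gamete
        biv = np.stack(
            [np.zeros(n, dtype=int), partner0, rest[:, 0], rest[:, 1]], axis=1
        )  # columns: biv1 = (0, partner), biv2 = (x, y)
        origins = np.empty((n, 2, n_loci), dtype=np.int8)
        side = gen.integers(0, 2, size=(n, 2))
        origins[:, 0, 0] = np.take_along_axis(biv[:, :2], side[:, :1], axis=1)[:, 0]
        origins[:, 1, 0] = np.take_along_axis(biv[:, 2:], side[:, 1:], axis=1)[:, 0]
        for c in range(2):
            lo = biv[:, 0 + 2 * c]
            hi = biv[:, 1 + 2 * c]
            sw = _co_indicator_chain(r, coincidence, n, gen, scale=1.0)
            for k in range(len(r)):
                prev = origins[:, c, k]
                other = np.where(prev == lo, hi, lo)
                origins[:, c, k + 1] = np.where(sw[:, k], other, prev).astype(np.int8)
        return origins

    raise ValueError(f"unknown pairing {pairing!r}")


# ---------------------------------------------------------------------------
# Mechanistic tetraploid tetrads (eight-chromatid bundle)


def simulate_tetraploid_tetrads(
    chiasma_prob: Sequence[float],
    n_tetrads: int,
    seed=None,
    rng=None,
):
    """Mechanistic quadrivalent meiosis producing tetrads of four diploid
    spores that exhaust the eight-chromatid bundle.

    Per marker interval, one crossover occurs with probability
    ``chiasma_prob[k]`` between two chromatids of (currently) different
    homolog origin, chosen uniformly; meiosis I then partitions the four
    centromeres two by two at random, and meiosis II pairs one chromatid
    of each homolog within a cell into a spore.  Double reduction is
    emergent here — a spore ends up with two copies of the same parental
    segment only when crossovers between the centromere and the locus
    re-sort segments — rather than an input dial, so use this mode for
    tetrad-consistent fixtures and realism checks, not for calibrated
    estimator validation.

    Returns
    -------
    spores : numpy.ndarray of shape (n_tetrads, 4, 2, n_loci)
        Homolog of origin of each spore's two chromatids at each locus.
    registry : list of (tetrad, interval, (chromatid_a, chromatid_b))
        Placed crossovers, chromatid indices in the 8-strand bundle.
    """
    q = np.asarray(chiasma_prob, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("chiasma probabilities must lie in [0, 1]")
    gen = _rng_from(seed, rng)
    n_loci = len(q) + 1
    strands = np.zeros((n_tetrads, 8, n_loci), dtype=np.int8)
    strands[:, :, 0] = np.repeat(np.arange(4, dtype=np.int8), 2)
    co = gen.random((n_tetrads, len(q))) < q
    registry: list[tuple[int, int, tuple[int, int]]] = []
    for k in range(len(q)):
        strands[:, :, k + 1] = strands[:, :, k]
        for t in np.nonzero(co[:, k])[0]:
            col = strands[t, :, k]
            a = int(gen.integers(0, 8))
            cand = np.nonzero(col != col[a])[0]
            if len(cand) == 0:
                continue
            b = int(cand[gen.integers(0, len(cand))])
            strands[t, a, k + 1 :], strands[t, b, k + 1 :] = (
                strands[t, b, k + 1 :].copy(),
                strands[t, a, k + 1 :].copy(),
            )
            registry.append((int(t), k, (min(a, b), max(a, b))))
    # meiosis I: partition centromeres {0..3} into two cells; II: pair off
    spores = np.empty((n_tetrads, 4, 2, n_loci), dtype=np.int8)
    partner = gen.integers(1, 4, size=n_tetrads)
    flip = gen.integers(0, 2, size=(n_tetrads, 2, 2))
    for t in range(n_tetrads):
        x = int(partner[t])
        rest = [h for h in (1, 2, 3) if h != x]
        cells = [(0, x), (rest[0], rest[1])]
        for ci, (ha, hb) in enumerate(cells):
            ua, ub = int(flip[t, ci, 0]), int(flip[t, ci, 1])
            s1 = (2 * ha + ua, 2 * hb + ub)
            s2 = (2 * ha + 1 - ua, 2 * hb + 1 - ub)
            spores[t, 2 * ci] = strands[t, list(s1)]
            spores[t, 2 * ci + 1] = strands[t, list(s2)]
    return spores, registry


# ---------------------------------------------------------------------------
# Genotype-matrix fixtures for crossover calling


def make_genotype_matrices(
    ploidy: str,
    n_tetrads: int,
    n_markers: int,
    chrom_length_bp: int,
    expected_co: float = 1.0,
    noise: float = 0.0,
    positions: Optional[Sequence[int]] = None,
    chrom: str = "chr1",
    seed=None,
    rng=None,
):
    """Fabricate per-tetrad genotype matrices plus a ground-truth
    crossover registry.

    Markers are evenly spaced along the chromosome unless ``positions``
    (strictly increasing, bp) is given.  Crossovers are distributed over
    marker intervals proportionally to physical length so that the
    expected number per tetrad is ``expected_co``.  ``noise`` is a
    symmetric per-genotype error rate (dosage flip for haploid spores,
    +/-1 within bounds for diploid spores).

    Returns ``(matrices, truth)`` where ``matrices`` is a list of
    :class:`tetralink.cocall.GenotypeMatrix` (one per tetrad) and
    ``truth`` a BED-like DataFrame of true crossover intervals
    (0-based, half-open) with tetrad and chromatid-pair annotation.
    """
    if n_markers < 2:
        raise ValueError("need at least two markers")
    gen = _rng_from(seed, rng)
    if positions is None:
        positions = np.linspace(
            chrom_length_bp / (n_markers + 1),
            chrom_length_bp * n_markers / (n_markers + 1),
            n_markers,
        ).astype(int)
    positions = np.asarray(positions, dtype=int)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("marker positions must be strictly increasing")
    lengths = np.diff(positions).astype(float)
    weights = lengths / lengths.sum()

    if ploidy == "disomic":
        r = np.minimum(expected_co * weights / 2.0, 0.5)
        origins, registry = simulate_diploid_tetrads(r, n_tetrads, rng=gen)
        dosage = (origins == 0).astype(np.int8)  # (n, 4, L)
        max_dose = 1
    elif ploidy == "tetrasomic":
        q = np.minimum(expected_co * weights, 1.0)
        spores, registry = simulate_tetraploid_tetrads(q, n_tetrads, rng=gen)
        dosage = (spores == 0).sum(axis=2).astype(np.int8)  # (n, 4, L)
        max_dose = 2
    else:
        raise ValueError(f"unknown ploidy {ploidy!r}")

    if noise > 0:
        flip = gen.random(dosage.shape) < noise
        if max_dose == 1:
            dosage = np.where(flip, 1 - dosage, dosage).astype(np.int8)
        else:
            step = np.where(gen.random(dosage.shape) < 0.5, -1, 1)
            step = np.where(dosage == 0, 1, np.where(dosage == max_dose, -1, step))
            dosage = np.where(flip, dosage + step, dosage).astype(np.int8)

    matrices = [
        GenotypeMatrix(
            chrom=chrom,
            positions=positions.copy(),
            dosages=dosage[t].T.copy(),  # markers x spores
            ploidy=ploidy,
            marker_ids=[f"m{j}" for j in range(n_markers)],
        )
        for t in range(n_tetrads)
    ]
    truth = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "start": int(positions[k]),
                "end": int(positions[k + 1]),
                "tetrad": t,
                "pair": f"{a}-{b}",
            }
            for (t, k, (a, b)) in registry
        ],
        columns=["chrom", "start", "end", "tetrad", "pair"],
    )
    return matrices, truth


def simulate_scenario(scenario: SimScenario):
    """Dispatch a :class:`SimScenario` to the matching sampler."""
    if scenario.output == "genotype-matrix":
        return make_genotype_matrices(
            scenario.ploidy,
            n_tetrads=scenario.n,
            n_markers=max(len(scenario.r) + 1, 2),
            chrom_length_bp=1_000_000,
            seed=scenario.seed,
        )
    if scenario.ploidy == "disomic":
        return simulate_diploid_tetrads(
            scenario.r, scenario.n, scenario.coincidence, seed=scenario.seed
        )
    return simulate_tetraploid_gametes(
        scenario.alpha,
        scenario.r,
        scenario.n,
        scenario.coincidence,
        pairing=scenario.pairing,
        seed=scenario.seed,
    )
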