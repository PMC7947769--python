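"""Phenotype-class probability models for disomic and tetrasomic inheritance.

An autotetraploid carrying a dominant marker on exactly one of its four
homologs (a *simplex* marker) produces diploid gametes whose marker
phenotypes deviate from disomic expectations for two reasons: quadrivalent
pairing allows *double reduction* (the two sister-derived allele copies end
up in the same gamete, with probability ``alpha``), and the recombination
fraction ``r`` between two loci can range up to 0.75 rather than 0.5,
because a chromatid leaving its homolog has three, not one, homologs to
join.

The closed-form class distributions here are the shared foundation for the
maximum-likelihood estimators (:mod:`tetralink.estimate`), the coincidence
coefficient machinery (:mod:`tetralink.interference`) and the gametogenesis
samplers (:mod:`tetralink.simulate`).

Generative model
----------------
All tetrasomic distributions in this module arise from a single
chromatid-origin process.  A diploid gamete is an unordered pair of
chromatids.  At the proximal locus the pair is sister-derived (both
chromatids copies of the same homolog, uniform over the 4) with probability
``alpha``; otherwise the two chromatids come from two distinct homologs
(uniform over the 6 pairs).  Across a marker interval with recombination
fraction ``r`` each chromatid independently switches its homolog of origin
with probability ``r``, the destination uniform over the other three
homologs.  The two-locus phenotype margins of this process reproduce the
four-class distribution :func:`tetrad_phenotype_probs` exactly, which is
the calibration contract used throughout the package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ModelParams",
    "TetradClassCounts",
    "CoClassCounts",
    "TETRAD_CLASSES",
    "CO_CLASSES",
    "THREE_LOCUS_CLASSES",
    "tetrad_phenotype_probs",
    "simplex_gamete_probs",
    "co_class_probs",
    "three_locus_phenotype_probs",
]

#: Canonical order of the four fluorescent tetrad-spore phenotype classes:
#: yellow (both markers), green (proximal only), red (distal only), black
#: (neither).
TETRAD_CLASSES = ("Y", "G", "R", "B")

#: Canonical order of the five crossover-phenotype tetrad classes.
CO_CLASSES = ("c1", "c2", "c3", "c4", "c5")

#: Canonical order of the eight three-marker presence/absence phenotype
#: classes, descending lexicographic with the coupling parent (all three
#: dominant alleles present) first.  For haploid segregants these are the
#: eight haplotypes; for diploid segregants of a tetraploid they are the
#: dominant phenotype classes.
THREE_LOCUS_CLASSES = (
    "ABC", "ABc", "AbC", "Abc", "aBC", "aBc", "abC", "abc",
)


def _check_unit(name: str, x: float, hi: float = 1.0) -> None:
    if not (0.0 <= x <= hi):
        raise ValueError(f"{name}={x!r} out of range [0, {hi}]")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-locus tetrasomic tetrad model.

    Attributes
    ----------
    alpha : float
        Double-reduction coefficient at the proximal locus, in [0, 1].
    beta : float
        Double-reduction coefficient at the distal locus, in [0, 1].  Does
        not enter the four-class likelihood; it is estimated from the
        regrouped class counts (see :func:`tetralink.estimate.estimate_alpha_tetrad`).
    r : float
        Recombination fraction between the loci; [0, 0.75] under
        tetrasomic inheritance, [0, 0.5] under disomic.
    p : float
        Probability of one crossover in a marker interval, in [0, 1].
    """

    alpha: float = 0.0
    beta: float = 0.0
    r: float = 0.0
    p: float = 0.0

    def __post_init__(self) -> None:
        _check_unit("alpha", self.alpha)
        _check_unit("beta", self.beta)
        _check_unit("r", self.r, hi=0.75)
        _check_unit("p", self.p)


@dataclass(frozen=True)
class TetradClassCounts:
    """Counts of the four fluorescent phenotype classes in one population.

    ``n_y`` spores carry both marker alleles, ``n_g`` only the proximal
    (green) allele, ``n_r`` only the distal (red) allele, ``n_b`` neither.
    """

    n_y: int
    n_g: int
    n_r: int
    n_b: int

    def __post_init__(self) -> None:
        for name in ("n_y", "n_g", "n_r", "n_b"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name}={v!r} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("all class counts are zero")

    @property
    def n(self) -> int:
        return self.n_y + self.n_g + self.n_r + self.n_b

    def as_array(self) -> np.ndarray:
        return np.array([self.n_y, self.n_g, self.n_r, self.n_b], dtype=float)

    @classmethod
    def from_sequence(cls, seq) -> "TetradClassCounts":
        a, b, c, d = (int(x) for x in seq)
        return cls(a, b, c, d)


@dataclass(frozen=True)
class CoClassCounts:
    """Counts of the five crossover-phenotype tetrad classes."""

    n1: int
    n2: int
    n3: int
    n4: int
    n5: int

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3", "n4", "n5"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name}={v!r} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("all class counts are zero")

    @property
    def n(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4 + self.n5

    def as_array(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3, self.n4, self.n5], dtype=float)

    @classmethod
    def from_sequence(cls, seq) -> "CoClassCounts":
        return cls(*(int(x) for x in seq))


def tetrad_phenotype_probs(alpha: float, r: float) -> np.ndarray:
    """Four-class phenotype distribution of diploid spores from a simplex
    x simplex autotetraploid cross (parent ``GBBB/RCCC``).

    Returns ``(f_y, f_g, f_r, f_b)`` in the :data:`TETRAD_CLASSES` order:

    .. math::

        f_y &= \\tfrac{1}{12}[2(3-3r+r^2) - \\alpha(3-6r+5r^2)] \\\\
        f_g &= \\tfrac{r}{12}[6-2r-\\alpha(6-5r)] \\\\
        f_r &= \\tfrac{1}{36}(2+\\alpha)\\,r(6-r) \\\\
        f_b &= \\tfrac{1}{36}(2+\\alpha)(3-r)^2

    The carrier marginal satisfies ``f_y + f_g = (2 - alpha)/4`` for every
    ``r`` (the simplex single-locus frequency).

    Parameters
    ----------
    alpha : float
        Double-reduction coefficient at the proximal locus, in [0, 1].
    r : float
        Recombination fraction between the loci, in [0, 0.75].
    """
    _check_unit("alpha", alpha)
    _check_unit("r", r, hi=0.75)
    f_y = (2.0 * (3.0 - 3.0 * r + r * r) - alpha * (3.0 - 6.0 * r + 5.0 * r * r)) / 12.0
    f_g = r * (6.0 - 2.0 * r - alpha * (6.0 - 5.0 * r)) / 12.0
    f_r = (2.0 + alpha) * r * (6.0 - r) / 36.0
    f_b = (2.0 + alpha) * (3.0 - r) ** 2 / 36.0
    return np.array([f_y, f_g, f_r, f_b])


def simplex_gamete_probs(alpha: float) -> tuple[float, float]:
    """Single-locus gamete class probabilities for a simplex parent ABBB.

    Returns ``((2 - alpha)/4 carrier AB, (2 + alpha)/4 non-carrier BB)``
    conditional on the two observable gamete classes; the pair sums to 1.
    """
    _check_unit("alpha", alpha)
    return ((2.0 - alpha) / 4.0, (2.0 + alpha) / 4.0)


def co_class_probs(alpha: float, p: float) -> np.ndarray:
    """Five-class tetrad crossover-phenotype distribution for one marker
    interval of an autotetraploid ``AB/ab/ab/ab``.

    Returns, in :data:`CO_CLASSES` order::

        ( alpha*(1 - p/2),
          (1-alpha)*(1 - 5p/12),
          alpha*p/2,
          (1-alpha)*p/12,
          (1-alpha)*p/3 )

    where ``alpha`` is the double-reduction coefficient at the
    centromere-proximal flanking marker and ``p`` the probability of one
    crossover in the interval.  Classes 1 and 3 are the double-reduction
    classes; at ``p -> 0`` mass concentrates on classes 1-2 in ratio
    ``alpha : 1-alpha``.
    """
    _check_unit("alpha", alpha)
    _check_unit("p", p)
    return np.array(
        [
            alpha * (1.0 - p / 2.0),
            (1.0 - alpha) * (1.0 - 5.0 * p / 12.0),
            alpha * p / 2.0,
            (1.0 - alpha) * p / 12.0,
            (1.0 - alpha) * p / 3.0,
        ]
    )


# ---------------------------------------------------------------------------
# Three coupled simplex loci


def _switch_joint(r1: float, r2: float, c: float) -> np.ndarray:
    """Joint law of the two per-interval switch indicators (s1, s2).

    ``P(s1=1, s2=1) = c * r1 * r2`` with marginals r1, r2; the coincidence
    scale ``c`` equals 1 under independence.
    """
    p11 = c * r1 * r2
    joint = np.array(
        [
            [1.0 - r1 - r2 + p11, r2 - p11],
            [r1 - p11, p11],
        ]
    )
    if joint.min() < -1e-12:
        raise ValueError(
            f"infeasible coincidence: c={c}, r1={r1}, r2={r2} give a negative "
            "double/single recombination class probability"
        )
    return np.clip(joint, 0.0, None)


def _phenotype_index(has_a: bool, has_b: bool, has_c: bool) -> int:
    # descending-lex order of THREE_LOCUS_CLASSES
    return (0 if has_a else 4) + (0 if has_b else 2) + (0 if has_c else 1)


def _disomic_three_locus(r1: float, r2: float, c: float) -> np.ndarray:
    joint = _switch_joint(r1, r2, c)
    probs = np.zeros(8)
    # haploid gametes of a coupling parent ABC/abc; phase classes split evenly
    for s1 in (0, 1):
        for s2 in (0, 1):
            w = joint[s1, s2] / 2.0
            for start in (0, 1):  # 0 = ABC homolog
                h1 = start
                h2 = h1 ^ s1
                h3 = h2 ^ s2
                probs[_phenotype_index(h1 == 0, h2 == 0, h3 == 0)] += w
    return probs


@lru_cache(maxsize=4096)
def _tetrasomic_three_locus(r1: float, r2: float, c: float, alpha: float) -> tuple:
    joint = _switch_joint(r1, r2, c)
    # per-chromatid transition tensor T[h1, h2, h3]
    T = np.zeros((4, 4, 4))
    for h1 in range(4):
        for s1 in (0, 1):
            if s1 == 0:
                h2s = [(h1, 1.0)]
            else:
                h2s = [(h, 1.0 / 3.0) for h in range(4) if h != h1]
            for h2, w2 in h2s:
                for s2 in (0, 1):
                    if s2 == 0:
                        h3s = [(h2, 1.0)]
                    else:
                        h3s = [(h, 1.0 / 3.0) for h in range(4) if h != h2]
                    for h3, w3 in h3s:
                        T[h1, h2, h3] += joint[s1, s2] * w2 * w3
    # collapse to per-chromatid carrier indicators: M[h1, b2, b3] is the
    # probability the chromatid's origin is homolog 0 (b=1) or not (b=0)
    # at loci 2 and 3, given locus-1 origin h1
    M = np.zeros((4, 2, 2))
    is0 = (np.arange(4) == 0).astype(int)
    for b2 in (0, 1):
        for b3 in (0, 1):
            mask = (is0[:, None] == b2) & (is0[None, :] == b3)
            M[:, b2, b3] = (T * mask[None, :, :]).sum(axis=(1, 2))
    # locus-1 chromatid-pair configurations
    configs: list[tuple[int, int, float]] = []
    for i in range(4):
        configs.append((i, i, alpha / 4.0))
    for i, j in itertools.combinations(range(4), 2):
        configs.append((i, j, (1.0 - alpha) / 6.0))
    probs = np.zeros(8)
    for h1a, h1b, w in configs:
        has1 = h1a == 0 or h1b == 0
        pair = M[h1a][:, :, None, None] * M[h1b][None, None, :, :]
        for b2a in (0, 1):
            for b3a in (0, 1):
                for b2b in (0, 1):
                    for b3b in (0, 1):
                        k = _phenotype_index(has1, bool(b2a or b2b), bool(b3a or b3b))
                        probs[k] += w * pair[b2a, b3a, b2b, b3b]
    return tuple(probs)


def three_locus_phenotype_probs(
    r1: float,
    r2: float,
    coincidence: float = 1.0,
    ploidy: str = "disomic",
    alpha: float = 0.0,
) -> np.ndarray:
    """Phenotype-class distribution at three coupled simplex markers A-B-C.

    Parameters
    ----------
    r1, r2 : float
        Recombination fractions of the two adjacent intervals (A-B, B-C);
        [0, 0.5] disomic, [0, 0.75] tetrasomic.
    coincidence : float
        Scale on the double-recombination probability: the probability that
        a chromatid recombines in both intervals is
        ``coincidence * r1 * r2``; 1.0 means independence.
    ploidy : {"disomic", "tetrasomic"}
        Disomic: haploid gametes of a coupling diploid parent ABC/abc;
        returns the 8 haplotype classes.  Tetrasomic: diploid gametes of a
        simplex parent ABC/abc/abc/abc under the quadrivalent chromatid
        model (see module docstring); returns the 8 dominant
        presence/absence classes.
    alpha : float
        Double-reduction coefficient at the proximal locus (tetrasomic
        only).  Double reduction at the distal loci is emergent from the
        chromatid process, not a free parameter.

    Returns
    -------
    numpy.ndarray
        Probabilities in :data:`THREE_LOCUS_CLASSES` order; sum to 1.
    """
    if ploidy == "disomic":
        _check_unit("r1", r1, hi=0.5)
        _check_unit("r2", r2, hi=0.5)
        if alpha != 0.0:
            raise ValueError("alpha must be 0 under disomic inheritance")
        return _disomic_three_locus(r1, r2, coincidence)
    if ploidy == "tetrasomic":
        _check_unit("r1", r1, hi=0.75)
        _check_unit("r2", r2, hi=0.75)
        _check_unit("alpha", alpha)
        return np.array(
            _tetrasomic_three_locus(float(r1), float(r2), float(coincidence), float(alpha))
        )
    raise ValueError(f"unknown ploidy {ploidy!r}")
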