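"""Maximum-likelihood estimators for tetrasomic and disomic tetrad data.

Estimators implemented here:

* closed-form double-reduction coefficients from four-class tetrad counts
  (proximal and distal locus) and from single-locus gamete counts;
* recombination fraction ``r`` between two fluorescent markers, by a
  two-step profile likelihood under the tetrasomic four-class model
  (``r`` admissible on [0, 0.75]) or directly as the recombinant-spore
  fraction under disomic inheritance (``r`` on [0, 0.5]);
* per-interval crossover probability ``p`` from five-class tetrad
  crossover phenotypes, by a closed-form root of the profile score with
  the admissible root selected in [0, 1];
* the expected crossover count per chromosome as the sum of interval
  ``p`` estimates;
* a segregation-neutrality test of the single-locus carrier fraction;
* centimorgan-per-megabase map-density conversion.

Standard errors are asymptotic, from observed Fisher information.
Estimates that fall outside their admissible range are truncated to the
boundary and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import xlogy

from .models import (
    CoClassCounts,
    TetradClassCounts,
    co_class_probs,
    tetrad_phenotype_probs,
)

__all__ = [
    "EstimateWithSE",
    "TetradMrfEstimate",
    "CoRateEstimate",
    "NeutralityTest",
    "tetrad_loglik",
    "co_loglik",
    "estimate_alpha_tetrad",
    "estimate_alpha_gamete",
    "estimate_r_tetrasomic",
    "estimate_r_diploid",
    "estimate_p_co",
    "expected_co_per_chromosome",
    "neutrality_test",
    "cm_per_mb",
]

R_MAX_TETRASOMIC = 0.75
R_MAX_DISOMIC = 0.5
#: Largest double-reduction coefficient attainable under random chromatid
#: segregation through a quadrivalent; used as the profile range of the
#: tetrasomic neutrality test.
ALPHA_MAX_MECHANISTIC = 1.0 / 6.0


@dataclass(frozen=True)
class EstimateWithSE:
    """A point estimate with its asymptotic standard error.

    ``truncated`` is True when the unconstrained optimum fell outside the
    admissible parameter range and was clipped to the boundary.
    ``loglik`` is the log-likelihood at the reported estimate (NaN for
    purely moment-based estimates).
    """

    value: float
    se: float
    truncated: bool = False
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")

    def __str__(self) -> str:  # Table-style rendering
        flag = " (truncated)" if self.truncated else ""
        return f"{self.value:.4f} ± {self.se:.4f}{flag}"


@dataclass(frozen=True)
class TetradMrfEstimate:
    """Joint output of the two-step tetrasomic tetrad analysis."""

    r: EstimateWithSE
    alpha: EstimateWithSE
    beta: EstimateWithSE


@dataclass(frozen=True)
class CoRateEstimate:
    """Per-interval crossover probability with the double-reduction
    coefficient implied by the same five-class counts."""

    p: EstimateWithSE
    alpha: EstimateWithSE


@dataclass(frozen=True)
class NeutralityTest:
    statistic: float
    pvalue: float
    df: int = 1
    ploidy: str = "disomic"


def tetrad_loglik(counts: TetradClassCounts, alpha: float, r: float) -> float:
    """Multinomial log-likelihood of the four-class tetrasomic model
    (zero counts contribute zero even at zero-probability classes)."""
    return float(xlogy(counts.as_array(), tetrad_phenotype_probs(alpha, r)).sum())


def co_loglik(counts: CoClassCounts, alpha: float, p: float) -> float:
    """Multinomial log-likelihood of the five-class crossover model."""
    return float(xlogy(counts.as_array(), co_class_probs(alpha, p)).sum())


def estimate_alpha_tetrad(
    counts: TetradClassCounts, locus: str = "proximal"
) -> EstimateWithSE:
    """Closed-form double-reduction MLE from four-class tetrad counts.

    The proximal-locus estimator pools the carrier classes {Y, G} against
    {R, B}:  ``alpha_hat = 2 (n_r + n_b - n_y - n_g) / n``.  The
    distal-locus variant exchanges the roles of the green-only and
    red-only classes, pooling {Y, R} against {G, B}.  Negative estimates
    are truncated at 0 and flagged.  The standard error is
    ``sqrt(16 * m1 * m2 / n^3)`` with ``m1, m2`` the two pooled counts,
    which equals the binomial-information value ``sqrt((4 - alpha^2)/n)``
    at expected counts.
    """
    n = counts.n
    if locus == "proximal":
        m1 = counts.n_y + counts.n_g
        m2 = counts.n_r + counts.n_b
    elif locus == "distal":
        m1 = counts.n_y + counts.n_r
        m2 = counts.n_g + counts.n_b
    else:
        raise ValueError(f"locus must be 'proximal' or 'distal', got {locus!r}")
    raw = 2.0 * (m2 - m1) / n
    value = min(max(raw, 0.0), 1.0)
    se = float(np.sqrt(16.0 * m1 * m2 / n**3))
    return EstimateWithSE(value=value, se=se, truncated=(value != raw))


def estimate_alpha_gamete(n1: int, n2: int) -> EstimateWithSE:
    """Double-reduction MLE from single-locus gamete counts.

    ``n1`` carriers (AB) and ``n2`` non-carriers (BB) from a simplex
    parent ABBB give ``alpha_hat = 2 (n2 - n1) / (n1 + n2)`` with sampling
    variance ``(4 - alpha^2)^2 / [(2 + alpha)^2 n1 + (2 - alpha)^2 n2]``
    evaluated at the unclipped estimate.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("gamete counts must be non-negative")
    n = n1 + n2
    if n == 0:
        raise ValueError("empty gamete sample")
    raw = 2.0 * (n2 - n1) / n
    var = (4.0 - raw**2) ** 2 / ((2.0 + raw) ** 2 * n1 + (2.0 - raw) ** 2 * n2)
    value = min(max(raw, 0.0), 1.0)
    return EstimateWithSE(value=value, se=float(np.sqrt(var)), truncated=(value != raw))


def _tetrad_probs_unchecked(alpha: float, r: np.ndarray) -> np.ndarray:
    """Four-class probabilities for an array of r values; shape (4, len)."""
    f_y = (2.0 * (3.0 - 3.0 * r + r * r) - alpha * (3.0 - 6.0 * r + 5.0 * r * r)) / 12.0
    f_g = r * (6.0 - 2.0 * r - alpha * (6.0 - 5.0 * r)) / 12.0
    f_r = (2.0 + alpha) * r * (6.0 - r) / 36.0
    f_b = (2.0 + alpha) * (3.0 - r) ** 2 / 36.0
    return np.stack([f_y, f_g, f_r, f_b])


def _profile_r_mle(
    counts: TetradClassCounts, alpha: float, r_max: float
) -> tuple[float, float, bool]:
    """Maximize the four-class log-likelihood over r in [0, r_max].

    Dense-grid scan (the score equation is a degree-5 polynomial with
    possibly several roots) followed by bounded scalar refinement in the
    best grid bracket.  Returns (r_hat, loglik, at_boundary).
    """
    eps = 1e-9

    def nll(r: float) -> float:
        return -tetrad_loglik(counts, alpha, r)

    grid = np.linspace(eps, r_max - eps, 751)
    vals = -xlogy(counts.as_array()[:, None], _tetrad_probs_unchecked(alpha, grid)).sum(axis=0)
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    r_hat = float(res.x)
    # accept an exact boundary if it beats the interior optimum
    boundary = False
    for b in (0.0, r_max):
        if nll(b) < res.fun:
            r_hat, boundary = b, True
    if r_hat < 1e-7:
        r_hat, boundary = 0.0, True
    elif r_hat > r_max - 1e-7:
        r_hat, boundary = r_max, True
    return r_hat, tetrad_loglik(counts, alpha, r_hat), boundary


def _curvature_se(loglik_of, x_hat: float, lo: float, hi: float, h: float = 1e-5) -> float:
    """SE from the observed information -d2 loglik / dx2 by central
    difference, shifting the stencil inside [lo, hi] at boundaries."""
    x0 = min(max(x_hat, lo + h), hi - h)
    d2 = (loglik_of(x0 + h) - 2.0 * loglik_of(x0) + loglik_of(x0 - h)) / h**2
    if d2 >= 0:
        return float("nan")
    return float(np.sqrt(-1.0 / d2))


def estimate_r_tetrasomic(
    counts: TetradClassCounts, joint: bool = False
) -> TetradMrfEstimate:
    """Two-step profile MLE of the recombination fraction from four-class
    tetrad counts under tetrasomic inheritance.

    Step 1 estimates the proximal double-reduction coefficient by the
    closed form of :func:`estimate_alpha_tetrad` (whose information comes
    from single-locus segregation, so it is computed at ``r = 0``); the
    distal coefficient is reported alongside.  Step 2 maximizes the
    four-class log-likelihood over ``r`` in [0, 0.75] with ``alpha`` fixed
    at step 1's estimate.  The SE of ``r_hat`` is
    ``sqrt(-1 / d2L/dr2)`` at the optimum.

    With ``joint=True`` a 2-D maximization over (alpha, r) is used as a
    cross-check mode; alpha's closed-form SE is still reported.
    """
    arr = counts.as_array()
    if np.count_nonzero(arr) < 2:
        warnings.warn(
            "single observed phenotype class: recombination fraction is at "
            "a degenerate boundary",
            stacklevel=2,
        )
    alpha_est = estimate_alpha_tetrad(counts, locus="proximal")
    beta_est = estimate_alpha_tetrad(counts, locus="distal")
    alpha_hat = alpha_est.value
    if joint:
        def nll2(theta):
            a, r = theta
            return -tetrad_loglik(counts, a, r)

        best = None
        for a0 in (0.01, 0.1):
            for r0 in (0.1, 0.3, 0.6):
                res = optimize.minimize(
                    nll2, x0=[a0, r0], method="L-BFGS-B",
                    bounds=[(0.0, 1.0), (1e-9, R_MAX_TETRASOMIC - 1e-9)],
                )
                if best is None or res.fun < best.fun:
                    best = res
        alpha_hat = float(best.x[0])
        r_hat, ll, boundary = float(best.x[1]), -float(best.fun), False
    else:
        r_hat, ll, boundary = _profile_r_mle(counts, alpha_hat, R_MAX_TETRASOMIC)
    se = _curvature_se(lambda r: tetrad_loglik(counts, alpha_hat, r),
                       r_hat, 0.0, R_MAX_TETRASOMIC)
    if np.isnan(se):
        se = 0.0
    r_est = EstimateWithSE(value=r_hat, se=se, truncated=boundary, loglik=ll)
    return TetradMrfEstimate(r=r_est, alpha=alpha_est, beta=beta_est)


def estimate_r_diploid(counts: TetradClassCounts) -> EstimateWithSE:
    """Recombinant-spore-fraction estimate of ``r`` for diploid tetrad
    spores with markers in coupling: ``r_hat = (n_g + n_r) / n``, binomial
    SE, clipped to [0, 0.5]."""
    n = counts.n
    raw = (counts.n_g + counts.n_r) / n
    value = min(raw, R_MAX_DISOMIC)
    se = float(np.sqrt(value * (1.0 - value) / n))
    return EstimateWithSE(value=value, se=se, truncated=(value != raw))


def estimate_p_co(counts: CoClassCounts) -> CoRateEstimate:
    """Closed-form MLE of the per-interval crossover probability ``p``
    from five-class tetrad crossover phenotypes.

    The double-reduction coefficient is profiled out as
    ``alpha_hat = (n1 + n3)/n`` (classes 1 and 3 are the double-reduction
    classes).  The profile score in ``p`` is quadratic,
    ``5 n p^2 - (22 n - 10 n1 - 12 n2) p + 24 (n - n1 - n2) = 0``, giving

        ``p_hat = (11 n - 5 n1 - 6 n2 +/- Delta) / (5 n)``,
        ``Delta = sqrt(n^2 + 2 n (5 n1 - 6 n2) + (5 n1 + 6 n2)^2)``.

    The root lying in [0, 1] is taken (if both qualify, the one with the
    higher likelihood).  SE from the observed information of the
    five-class likelihood at the optimum.
    """
    n = counts.n
    n1, n2 = counts.n1, counts.n2
    m = n - n1 - n2  # recombinant-class total
    alpha_hat = (counts.n1 + counts.n3) / n
    alpha_se = float(np.sqrt(alpha_hat * (1.0 - alpha_hat) / n))
    delta = float(np.sqrt(n**2 + 2.0 * n * (5.0 * n1 - 6.0 * n2) + (5.0 * n1 + 6.0 * n2) ** 2))
    roots = [(11.0 * n - 5.0 * n1 - 6.0 * n2 + s * delta) / (5.0 * n) for s in (1.0, -1.0)]
    tol = 1e-12
    valid = [p for p in roots if -tol <= p <= 1.0 + tol]
    if not valid:
        raise ArithmeticError(
            f"no admissible crossover-probability root in [0, 1]: roots={roots}"
        )
    if len(valid) == 2:
        valid.sort(key=lambda p: -co_loglik(counts, alpha_hat, min(max(p, 0.0), 1.0)))
    p_hat = min(max(valid[0], 0.0), 1.0)
    # observed information of the profile likelihood in p
    def d2(p: float) -> float:
        out = 0.0
        out -= n1 / (2.0 - p) ** 2 if n1 else 0.0
        out -= n2 * (25.0 / 144.0) / (1.0 - 5.0 * p / 12.0) ** 2 if n2 else 0.0
        out -= m / p**2 if m else 0.0
        return out

    info = -d2(min(max(p_hat, 1e-9), 1.0 - 1e-9))
    se = float(np.sqrt(1.0 / info)) if info > 0 else 0.0
    ll = co_loglik(counts, alpha_hat, p_hat)
    p_est = EstimateWithSE(value=p_hat, se=se, truncated=(p_hat != valid[0]), loglik=ll)
    return CoRateEstimate(p=p_est, alpha=EstimateWithSE(value=alpha_hat, se=alpha_se))


def expected_co_per_chromosome(
    p_estimates, se_estimates=None
) -> EstimateWithSE:
    """Expected number of crossovers on a chromosome: the sum of the
    per-interval crossover probabilities, SE by quadrature sum assuming
    independent intervals."""
    p = [float(x.value) if isinstance(x, EstimateWithSE) else float(x) for x in p_estimates]
    if len(p) == 0:
        raise ValueError("no interval estimates supplied")
    for x in p:
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"interval crossover probability {x} outside [0, 1]")
    if se_estimates is None:
        se_list = [
            float(x.se) if isinstance(x, EstimateWithSE) else 0.0 for x in p_estimates
        ]
    else:
        se_list = [float(s) for s in se_estimates]
    return EstimateWithSE(value=float(np.sum(p)), se=float(np.sqrt(np.sum(np.square(se_list)))))


def neutrality_test(counts: TetradClassCounts, ploidy: str = "disomic") -> NeutralityTest:
    """Test for deviation of the proximal-marker carrier fraction from
    neutral segregation.

    Disomic: chi-square (score) test of the carrier fraction
    ``(n_y + n_g)/n`` against 1/2.  Tetrasomic: the neutral carrier
    fraction is ``(2 - alpha)/4`` which is free of ``r``; a 1-df
    likelihood-ratio test profiles ``alpha`` over [0, 1/6] (the
    mechanistically attainable range), so any carrier fraction inside
    [11/24, 1/2] is exactly neutral.
    """
    n = counts.n
    n_carrier = counts.n_y + counts.n_g
    if ploidy == "disomic":
        stat = (n_carrier - n / 2.0) ** 2 / (n / 4.0)
        return NeutralityTest(statistic=float(stat),
                              pvalue=float(stats.chi2.sf(stat, 1)), ploidy=ploidy)
    if ploidy == "tetrasomic":
        q_hat = n_carrier / n
        lo = (2.0 - ALPHA_MAX_MECHANISTIC) / 4.0  # 11/24
        hi = 0.5

        def ll(q: float) -> float:
            return float(xlogy(n_carrier, q) + xlogy(n - n_carrier, 1.0 - q))

        if lo <= q_hat <= hi:
            return NeutralityTest(statistic=0.0, pvalue=1.0, ploidy=ploidy)
        q0 = lo if q_hat < lo else hi
        stat = 2.0 * (ll(q_hat) - ll(q0))
        return NeutralityTest(statistic=float(stat),
                              pvalue=float(stats.chi2.sf(stat, 1)), ploidy=ploidy)
    raise ValueError(f"unknown ploidy {ploidy!r}")


def cm_per_mb(r: float, physical_length_mb: float) -> float:
    """Map density in centimorgans per megabase: ``100 * r / length``."""
    if physical_length_mb <= 0:
        raise ValueError("physical length must be positive (Mb)")
    return 100.0 * r / physical_length_mb
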