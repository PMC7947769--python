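"""Coincidence-coefficient estimation and simulation-based significance.

Crossover (position) interference over two adjacent marker intervals
A-B and B-C is quantified by coincidence coefficients:

* joint form      ``c_AB-BC = r_AB&BC / (r_AB * r_BC)``
* conditional     ``c_AB/BC = r_AB|BC / r_AB|not-BC``
* conditional     ``c_BC/AB = r_BC|AB / r_BC|not-AB``

all equal to 1 in the absence of interference; values below 1 indicate
positive interference (a crossover suppresses nearby crossovers).

For haploid segregants of a diploid parent, recombination events are
directly countable from the eight three-marker phenotype classes and the
coefficients are exact count ratios.  For diploid segregants of an
autotetraploid parent, dominant phenotypes do not reveal double
recombination by counting, so the coefficients are estimated by maximum
likelihood under the tetrasomic three-locus chromatid model
(:func:`tetralink.models.three_locus_phenotype_probs`), the joint
coefficient being the model's coincidence scale.

Significance of a deviation from 1 is assessed empirically: segregant
populations of the same size are resimulated under independent
recombination (coincidence 1) with the interval recombination fractions
taken from the observed data, and a two-sided add-one permutation-style
p-value is computed from the null distribution of ``|c - 1|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.special import xlogy

from .models import THREE_LOCUS_CLASSES, three_locus_phenotype_probs

__all__ = [
    "CCResult",
    "NullScenario",
    "cc_from_haploid_counts",
    "cc_from_tetraploid_counts",
    "cc_null_test",
    "collapse_to_event_classes",
]

#: Index of each canonical phenotype class in the four recombination-event
#: classes (none, AB-only, BC-only, double), from presence patterns:
#: AB recombinant iff presence differs between A and B, analogously BC.
_EVENT_OF_CLASS = {}
for _i, _h in enumerate(THREE_LOCUS_CLASSES):
    _a, _b, _c = (ch.isupper() for ch in _h)
    _EVENT_OF_CLASS[_i] = (2 if _a != _b else 0) + (1 if _b != _c else 0)
# event codes: 0 none, 2 AB-only, 1 BC-only, 3 double


@dataclass(frozen=True)
class CCResult:
    """The three coincidence coefficients for one three-marker region."""

    c_joint: float
    c_ab_given_bc: float
    c_bc_given_ab: float
    r_ab: float = float("nan")
    r_bc: float = float("nan")
    alpha: float = float("nan")
    pvalues: Optional[dict] = None
    n_sim: int = 0
    boundary: bool = False

    def coefficients(self) -> dict:
        return {
            "c_joint": self.c_joint,
            "c_ab_given_bc": self.c_ab_given_bc,
            "c_bc_given_ab": self.c_bc_given_ab,
        }


@dataclass(frozen=True)
class NullScenario:
    """Configuration of the independent-recombination null simulation:
    population size and per-interval recombination fractions extracted
    from the observed data (plus alpha for tetrasomic populations)."""

    ploidy: str
    n: int
    r_ab: float
    r_bc: float
    alpha: float = 0.0


def collapse_to_event_classes(counts8: np.ndarray) -> np.ndarray:
    """Collapse 8 phase-resolved haplotype counts (canonical order) to
    the 4 recombination-event classes (none, AB-only, BC-only, double)."""
    counts8 = np.asarray(counts8, dtype=float)
    if counts8.shape != (8,):
        raise ValueError("expected 8 phenotype-class counts")
    out = np.zeros(4)
    for i, ev in _EVENT_OF_CLASS.items():
        out[{0: 0, 2: 1, 1: 2, 3: 3}[ev]] += counts8[i]
    return out


def cc_from_haploid_counts(counts) -> CCResult:
    """Coincidence coefficients by direct counting from haploid
    three-marker segregant counts.

    ``counts`` is either the 8 phase-resolved haplotype classes in
    canonical :data:`tetralink.models.THREE_LOCUS_CLASSES` order, or the
    4 recombination-event classes (none, AB-only, BC-only, double).
    Raises if an interval shows no recombinants (undefined coefficient).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.shape == (8,):
        arr = collapse_to_event_classes(arr)
    if arr.shape != (4,):
        raise ValueError("expected 8 haplotype or 4 event-class counts")
    n_none, n_ab, n_bc, n_double = arr
    n = arr.sum()
    if n <= 0:
        raise ValueError("empty segregant population")
    r_ab = (n_ab + n_double) / n
    r_bc = (n_bc + n_double) / n
    for name, val in (("A-B", r_ab), ("B-C", r_bc)):
        if val == 0:
            raise ZeroDivisionError(
                f"no recombinants in interval {name}: coincidence undefined"
            )
    c_joint = (n_double / n) / (r_ab * r_bc)
    # conditional forms need recombinants/non-recombinants in the
    # conditioning interval
    denom_bc = n_bc + n_double
    denom_nobc = n_none + n_ab
    denom_ab = n_ab + n_double
    denom_noab = n_none + n_bc
    if min(denom_bc, denom_nobc, denom_ab, denom_noab, n_ab, n_bc) == 0:
        raise ZeroDivisionError("conditional coincidence undefined (empty stratum)")
    c_ab_bc = (n_double / denom_bc) / (n_ab / denom_nobc)
    c_bc_ab = (n_double / denom_ab) / (n_bc / denom_noab)
    return CCResult(
        c_joint=float(c_joint),
        c_ab_given_bc=float(c_ab_bc),
        c_bc_given_ab=float(c_bc_ab),
        r_ab=float(r_ab),
        r_bc=float(r_bc),
    )


def _tetraploid_negloglik(theta: np.ndarray, counts: np.ndarray) -> float:
    r1, r2, c, a = theta
    try:
        probs = three_locus_phenotype_probs(r1, r2, c, "tetrasomic", a)
    except ValueError:
        return 1e12
    if probs.min() < 0:
        return 1e12
    return -float(xlogy(counts, np.clip(probs, 1e-300, None)).sum())


def cc_from_tetraploid_counts(counts, fit_alpha: bool = True) -> CCResult:
    """Maximum-likelihood coincidence coefficients from dominant
    three-marker phenotype counts of diploid segregants of an
    autotetraploid parent.

    Fits (r_AB, r_BC, coincidence, alpha) to the 8 dominant phenotype
    classes under the tetrasomic three-locus chromatid model.  The joint
    coefficient is the fitted coincidence scale; the conditional
    coefficients follow from the fitted per-chromatid switch
    distribution:  ``c_AB/BC = c (1 - r_BC) / (1 - c r_BC)`` and
    symmetrically.  A fit on the coincidence feasibility boundary is
    flagged.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (8,):
        raise ValueError("expected 8 dominant phenotype-class counts "
                         f"in {THREE_LOCUS_CLASSES} order")
    if counts.sum() <= 0:
        raise ValueError("empty segregant population")

    # moment-based starting value for alpha from the locus-A carrier
    # marginal (2 - alpha)/4
    n_tot = counts.sum()
    q_a = counts[:4].sum() / n_tot
    a0 = min(max(2.0 - 4.0 * q_a, 0.01), 0.5) if fit_alpha else 0.0

    def fit_from(x0):
        # feasibility c*r1*r2 <= min(r1, r2) is enforced by the penalty
        # inside the objective
        return optimize.minimize(
            _tetraploid_negloglik,
            x0=np.array(x0),
            args=(counts,),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 3000},
        )

    best = None
    for x0 in ([0.2, 0.2, 1.0, a0], [0.35, 0.35, 0.5, a0]):
        res = fit_from(x0)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("tetraploid coincidence fit failed to converge")
    r1, r2, c, a = best.x
    r1, r2 = abs(r1), abs(r2)
    c = max(c, 0.0)
    a = min(max(a, 0.0), 1.0)
    cmax = min(r1, r2) / (r1 * r2) if r1 * r2 > 0 else np.inf
    boundary = c >= cmax - 1e-6 or c <= 1e-6
    c_ab_bc = c * (1.0 - r2) / (1.0 - c * r2) if c * r2 < 1 else float("inf")
    c_bc_ab = c * (1.0 - r1) / (1.0 - c * r1) if c * r1 < 1 else float("inf")
    return CCResult(
        c_joint=float(c),
        c_ab_given_bc=float(c_ab_bc),
        c_bc_given_ab=float(c_bc_ab),
        r_ab=float(r1),
        r_bc=float(r2),
        alpha=float(a),
        boundary=bool(boundary),
    )


def _simulate_null_coefficients(
    scenario: NullScenario, n_sim: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    probs = three_locus_phenotype_probs(
        scenario.r_ab,
        scenario.r_bc,
        1.0,
        scenario.ploidy,
        scenario.alpha if scenario.ploidy == "tetrasomic" else 0.0,
    )
    draws = rng.multinomial(scenario.n, probs, size=n_sim)
    keys = ("c_joint", "c_ab_given_bc", "c_bc_given_ab")
    out = {k: np.full(n_sim, np.nan) for k in keys}
    for i in range(n_sim):
        try:
            if scenario.ploidy == "disomic":
                res = cc_from_haploid_counts(draws[i])
            else:
                res = cc_from_tetraploid_counts(draws[i])
        except (ZeroDivisionError, RuntimeError):
            continue
        for k in keys:
            out[k][i] = getattr(res, k)
    return out


def cc_null_test(
    observed: CCResult,
    scenario: NullScenario,
    n_sim: int = 1000,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> CCResult:
    """Attach empirical p-values to observed coincidence coefficients.

    Simulates ``n_sim`` segregant populations of the scenario's size
    under independent recombination (coincidence = 1) with the scenario's
    interval recombination fractions, recomputes each coefficient, and
    reports the two-sided add-one empirical p-value
    ``p = (1 + #{|c_sim - 1| >= |c_obs - 1|}) / (n_valid + 1)`` per
    coefficient.  Null replicates where a coefficient is undefined (no
    recombinants in a stratum) are dropped from its denominator.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100 for a meaningful p-value")
    if scenario.n < 1 or not (0 < scenario.r_ab) or not (0 < scenario.r_bc):
        raise ValueError("scenario must carry a positive population size and "
                         "positive interval recombination fractions")
    gen = rng if rng is not None else np.random.default_rng(seed)
    sims = _simulate_null_coefficients(scenario, n_sim, gen)
    pvalues = {}
    for k, obs in observed.coefficients().items():
        vals = sims[k]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            pvalues[k] = float("nan")
            continue
        exceed = int(np.sum(np.abs(vals - 1.0) >= abs(obs - 1.0) - 1e-12))
        pvalues[k] = (1.0 + exceed) / (len(vals) + 1.0)
    return CCResult(
        c_joint=observed.c_joint,
        c_ab_given_bc=observed.c_ab_given_bc,
        c_bc_given_ab=observed.c_bc_given_ab,
        r_ab=observed.r_ab,
        r_bc=observed.r_bc,
        alpha=observed.alpha,
        pvalues=pvalues,
        n_sim=n_sim,
        boundary=observed.boundary,
    )
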