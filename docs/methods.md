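# Methods

This note documents the statistical models, the simulator that stands in for
experimental tetrad data, the numerical choices, and the limits of what the
test suite demonstrates.

## Two-locus tetrasomic tetrad model

A simplex × simplex autotetraploid (`GBBB/RCCC`: green marker proximal to the
centromere, red distal, each on a single homolog) produces diploid spores
classified by fluorescence into yellow/green/red/black. The class
probabilities `f_y, f_g, f_r, f_b` (README) are functions of the
double-reduction coefficient `α` at the proximal locus and the recombination
fraction `r ∈ [0, 0.75]`. Two structural identities matter:

* the carrier marginal `f_y + f_g = (2−α)/4` is independent of `r`, so the
  proximal `α` is estimable from single-locus segregation alone;
* every class probability is linear in `α`, so the four-class model never
  identifies a second (distal) double-reduction parameter. The distal
  coefficient `β` is instead estimated by applying the same closed form to
  the regrouped classes `{Y,R}` vs `{G,B}`. Under the generative chromatid
  model below, segregation distortion at the distal locus is partly driven by
  recombination, so `β̂` measures distal-locus distortion rather than a
  second free dial; this mirrors how the estimator behaves on real data,
  where the distal coefficient is likewise read off the regrouped counts.

### Generative chromatid model

All tetrasomic machinery in the package derives from one process. A diploid
gamete is an unordered chromatid pair. At the proximal locus the pair is
sister-derived with probability `α` (homolog uniform over 4), otherwise two
distinct homologs (uniform over the 6 pairs). Across a marker interval with
recombination fraction `r`, each chromatid independently switches its homolog
of origin with probability `r`, destination uniform over the other three
homologs. Coupling of the switch indicators in adjacent intervals is
controlled by a coincidence scale `c`: `P(switch in both) = c·r₁·r₂`.

This process reproduces the four closed-form class probabilities *exactly*
(verified analytically and to machine precision in tests), which is the
calibration contract: the printed two-locus distribution is the ground truth,
and the chromatid process is the unique minimal extension we use wherever a
three-locus distribution or a sampler is needed. The free-recombination limit
of the process is `r = 3/4`, matching the admissible range of `r̂`.

## Estimators and numerics

* **`α̂` (tetrad closed form).** `2(m₂−m₁)/n` for pooled classes; negative
  values are truncated to 0 and flagged (boundary estimates are reported as
  `0.0000 ± SE`). The variance `16 m₁ m₂ / n³` equals the binomial-information
  value `(4−α²)/n` at expected counts.
* **`α̂` (gamete counts).** `2(n₂−n₁)/(n₁+n₂)`, variance
  `(4−α²)²/[(2+α)²n₁+(2−α)²n₂]` evaluated at the unclipped estimate.
* **`r̂` (tetrasomic).** Two-step profile: `α` fixed at its closed form, then
  the log-likelihood maximized over `r ∈ [0, 0.75]` by a 751-point grid scan
  followed by bounded scalar refinement (`xatol` 1e−10). The grid guards
  against spurious roots of the degree-5 score polynomial; a boundary optimum
  sets the truncation flag. SE from a central-difference second derivative
  (step 1e−5), with the stencil shifted inside the domain at boundaries. A
  joint 2-D (α, r) maximization is available as a cross-check mode and agrees
  with the profile to ~1e−3 on well-conditioned counts.
* **`p̂` (crossover probability).** The profile score is the quadratic
  `5np² − (22n−10n₁−12n₂)p + 24(n−n₁−n₂) = 0`; its discriminant equals the
  closed-form `Δ²` printed in the README, which we verified symbolically and
  against dense-grid likelihood maximization on random count vectors (gate at
  1e−4 with a 1e−5 grid). The admissible root in `[0, 1]` is selected; if
  both roots qualify the one with higher likelihood wins. `α̂ = (n₁+n₃)/n`
  from the two double-reduction classes.
* **Neutrality test.** Disomic: χ² score test of the carrier fraction against
  1/2. Tetrasomic: the neutral value `(2−α)/4` depends on the unknown `α`, so
  a 1-df LRT profiles `α` over `[0, 1/6]` — the range attainable by random
  chromatid segregation through a quadrivalent — making any carrier fraction
  in `[11/24, 1/2]` exactly neutral. The test's form for the tetrasomic case
  is this package's construction, chosen because the carrier marginal is the
  only `r`-free testable quantity.
* **Significance of `α̂`/`β̂`** in report tables is Wald (estimate/SE), an
  assumption documented here since boundary truncation makes the Wald test
  conservative near 0.

## Coincidence coefficients

Haploid segregants: direct counting, exact ratios; undefined coefficients
(no recombinants in a stratum) raise rather than return a placeholder.

Diploid segregants of a tetraploid: dominant phenotypes cannot count double
recombinants, so `(r₁, r₂, c, α)` is fitted by maximum likelihood over the
8-class dominant phenotype distribution of the chromatid model (Nelder–Mead,
two starts — one at the independence point, one at half coincidence — with a
moment-based `α` start from the locus-A carrier marginal; infeasible
parameter regions are rejected by penalty). The joint coefficient is the
fitted `c`; conditional forms follow from the switch-event joint law:
`c_AB/BC = c(1−r₂)/(1−c·r₂)` and symmetrically. This ML route is a model
reconstruction, not a counting identity: its numerical values on real
dominant-marker data should not be expected to coincide with direct-count
estimates, and the fit of `c` at n = 1,000 has a sampling SD of roughly
0.2–0.3 with mild upward skew. A fit on the feasibility boundary
(`c·r₁·r₂ = min(r₁,r₂)` or `c = 0`) is flagged.

Empirical p-values use the add-one estimator, two-sided through the ordering
of `|c − 1|`, over populations resimulated at `c = 1` with the observed
population size and fitted interval recombination fractions. Segregants are
independently collected gametes, so null populations are drawn as multinomial
samples of the exact class distribution; the gametogenesis-level sampler is
separately verified to produce the same class frequencies. Calibration
(rejection rate 5% ± 3% at nominal 5%) is checked in the acceptance suite
with 200 outer replicates and 199 inner replicates per test — sizes chosen to
keep the default suite in seconds while leaving the add-one estimator's
granularity (1/200) well below the tolerance.

## Simulators

* **Diploid tetrads.** Four-strand bundle; at most one crossover per marker
  interval, placed with probability `2r` between one chromatid of each
  homolog, so the recombinant-spore fraction is exactly `r` and the
  spore-level double-recombination rate across adjacent intervals is
  `c·r₁·r₂` (feasibility `4c·r₁r₂ ≤ min(2r₁, 2r₂)` enforced). The at-most-one
  crossover simplification is exact for the observable contract (spore
  recombination indicators) at `r ≤ 0.5` and keeps the true-crossover
  registry unambiguous for calling fixtures.
* **Tetraploid gametes (calibrated, canonical).** The chromatid-origin
  process above, with `α` an input dial; class frequencies converge to the
  closed forms (checked on the grid `α ∈ {0, 0.05, 0.15} × r ∈ {0.05, 0.2,
  0.45}` within 3 Monte-Carlo SEs at n = 60,000). Bivalent mode pairs
  homologs two by two, forbids double reduction (`α` must be 0), and gives a
  carrier frequency of exactly 1/2; its `r` is the within-bivalent
  recombination fraction. Gametes are iid; when grouped into tetrads of four
  the grouping is a reshape and tetrad-level allele conservation is *not*
  guaranteed in this mode — use the mechanistic mode for tetrad-consistent
  data.
* **Tetraploid tetrads (mechanistic).** Eight-chromatid quadrivalent bundle:
  per-interval crossovers between chromatids of different current origin,
  then meiosis I (random 2+2 centromere partition) and meiosis II (one
  chromatid of each homolog per spore). Double reduction *emerges* from
  crossovers re-sorting segments rather than being dialled, and every
  tetrad's summed allele dosage is conserved (2 of 8 for a simplex marker).
  The per-interval input here is a chiasma probability, not calibrated to an
  observable `r`; the mode exists for realism checks and crossover-calling
  fixtures, where only the truth registry and dosage patterns matter.
* **Genotype matrices.** Markers evenly spaced (or user-supplied positions),
  crossovers distributed proportionally to physical interval length with an
  `expected_co` total per tetrad, optional symmetric dosage noise. Emulates
  the structure of dense sequencing-derived marker sets at a reduced marker
  count; fixtures in tests use 10–25 markers per chromosome so the suite
  stays fast, since calling correctness is per-interval and does not depend
  on marker density.

What the simulators deliberately do not model: gene conversion tracts,
chromatid interference, pairing-partner switching along the quadrivalent,
sequencing errors beyond symmetric dosage noise, and structural variation.
Passing recovery tests therefore demonstrate estimator correctness under
clean tetrasomic inheritance, not robustness to those artefacts.

## Crossover calling

Markers are first filtered to the clean heterozygous configurations (2:2 of
4 in diploid tetrads; 2:6/6:2 of 8 in tetraploid tetrads); filtering only
drops rows and is idempotent. A crossover is a reciprocal exchange: exactly
one spore up by one dose and one down by one between adjacent kept markers.
Non-reciprocal changes (3:1 patterns, shared ±1 across more than two spores)
are logged and skipped, never called. Calls closer than 10 kb — measured
between interval midpoints, since a call's position is the half-open interval
between flanking markers with no midpoint interpolation — are collapsed
pairwise left-to-right within a run, keeping the leftmost of each pair; a run
of k calls keeps ⌈k/2⌉ regardless of sweep direction. Tetraploid
phase-ambiguous intervals yield no observed calls by design; their crossover
content is covered by the interval-probability estimator, and the two totals
are always reported separately (summed only under an explicit flag).

## Reference scenarios and problem sizes

The acceptance experiments use per-chromosome reference parameter sets
(tetraploid `α`, `r` and diploid `r` with sampling SDs for yeast chromosomes
1, 6, 13, 14, 15) as generating truths, n = 10,000 tetrads per recovery
experiment, and a 1,000-replicate null with n = 1,000 segregants per
replicate for interference calibration — sizes at which every estimator's
Monte-Carlo error is several times smaller than the acceptance tolerance of
three sampling SDs, while the whole script runs in seconds. All randomness
flows from a single `SeedSequence` so runs are reproducible per seed.

## Known limitations

* The two-step profile MLE treats `α̂` as known when maximizing over `r`;
  the reported `SE(r̂)` conditions on `α̂` and slightly understates total
  uncertainty when `α` is poorly determined.
* The tetraploid coincidence fit is weakly identified at small n; treat
  `c` estimates from dominant-marker data as order-of-magnitude measures of
  interference and rely on the simulation p-values, not on Wald intervals.
* `estimate_r_diploid` assumes markers in coupling and clips at 0.5;
  repulsion-phase inputs must be recoded upstream.
* The mechanistic tetraploid mode does not model pairing-partner switching
  along the quadrivalent, so its emergent double-reduction level is an
  approximation bounded by the random-chromatid-segregation maximum of 1/6.
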