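# tetralink

Tetrasomic linkage analysis for budding-yeast tetrad data: maximum-likelihood
estimation of recombination frequency and double reduction in autotetraploids,
crossover-count prediction, coincidence-coefficient interference tests with
simulation nulls, and crossover calling from tetrad genotype matrices.

## The problem

Measuring meiotic recombination frequency (MRF) in a diploid is routine: with
two linked markers in coupling, the recombinant-spore fraction of a tetrad
population estimates `r` directly. In an autotetraploid the same measurement
is confounded by tetrasomic inheritance. Quadrivalent pairing allows **double
reduction** — with probability `α` a diploid gamete receives two
sister-derived copies of the same homolog — which distorts segregation ratios,
and a chromatid that recombines away from its homolog has three possible
partners, so `r` is admissible on `[0, 0.75]` rather than `[0, 0.5]`. Naive
disomic analysis of tetraploid marker data is therefore biased, which is the
methodological gap this package fills for comparisons of recombination between
diploid and genome-duplicated (autotetraploid) yeast.

## The model

For a simplex × simplex two-marker cross (`GBBB/RCCC`), the diploid spores
fall in four fluorescent phenotype classes — yellow (both markers), green
(proximal only), red (distal only), black (neither) — with probabilities

    f_y(α,r) = [2(3−3r+r²) − α(3−6r+5r²)] / 12
    f_g(α,r) = r[6−2r−α(6−5r)] / 12
    f_r(α,r) = (2+α) r (6−r) / 36
    f_b(α,r) = (2+α)(3−r)² / 36

The carrier marginal `f_y + f_g = (2−α)/4` is free of `r`, so `α` has the
closed-form MLE `α̂ = 2(n_r+n_b−n_y−n_g)/n` with `Var(α̂) =
16(n_y+n_g)(n_r+n_b)/n³` (equal to `(4−α²)/n` at expected counts); the distal
coefficient `β̂` uses the regrouped classes. `r̂` then maximizes the
multinomial log-likelihood `L = Σ nᵢ log fᵢ(α̂, r)` over `[0, 0.75]`
(two-step profile; the score equation is a degree-5 polynomial, solved by
dense grid plus bounded refinement), with `SE(r̂) = sqrt(−1/∂²L/∂r²)`.

For crossover-count prediction, one marker interval of an `AB/ab/ab/ab`
tetraploid yields five tetrad phenotype classes with probabilities
`(α(1−p/2), (1−α)(1−5p/12), αp/2, (1−α)p/12, (1−α)p/3)` where `p` is the
probability of one crossover in the interval; the profile score is quadratic
in `p`, giving the closed form `p̂ = (11n−5n₁−6n₂ ± Δ)/5n` with
`Δ = sqrt(n² + 2n(5n₁−6n₂) + (5n₁+6n₂)²)` and the root taken in `[0, 1]`.
Summing `p̂` over the intervals of a chromosome predicts its expected
crossover count per meiosis.

Crossover interference over adjacent intervals A–B and B–C is quantified by
coincidence coefficients `c_AB−BC = r_AB∩BC/(r_AB·r_BC)` and the two
conditional forms, all 1 under independence; significance comes from an
empirical null of resimulated segregant populations with independent
recombination. For haploid segregants the coefficients are direct count
ratios; for diploid segregants of a tetraploid (where dominant phenotypes
hide double recombinants) they are fitted by ML under an exact tetrasomic
three-locus chromatid model whose two-locus margins reproduce the class
probabilities above.

## Worked example

```python
from tetralink import estimate_r_tetrasomic
from tetralink.simulate import simulate_tetraploid_gametes, tetrad_counts_from_gametes

gametes = simulate_tetraploid_gametes(alpha=0.1, r=[0.2], n=50_000, seed=1)
counts = tetrad_counts_from_gametes(gametes)
fit = estimate_r_tetrasomic(counts)
print(fit.alpha, fit.r)
```

prints

```
0.0888 ± 0.0089 0.1982 ± 0.0022
```

i.e. from 50,000 simulated gametes of a tetraploid with true double reduction
0.1 and true recombination fraction 0.2, the two-step profile MLE recovers
`α̂ = 0.089 ± 0.009` and `r̂ = 0.198 ± 0.002` — both within two standard
errors of the truth. The `examples/` directory has one short script per
capability (tetrad MRF estimation, crossover prediction, interference
testing, crossover calling, pairing modes); each prints the numbers it
computes and what they mean. A thin CLI (`tetralink estimate-tetrad`,
`estimate-co`, `interference`, `call-co`, `simulate`, `pipeline`) wraps the
same functions for TSV-file workflows and writes a reproducibility manifest
with every run.

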