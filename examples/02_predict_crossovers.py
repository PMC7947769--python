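"""Predict the expected crossover count of a chromosome.

Builds five-class crossover-phenotype tetrad counts for two marker
intervals (exact expected counts at p = 0.2 and p = 0.24), estimates the
per-interval crossover probability by the closed-form MLE, and sums the
estimates into an expected crossover count per meiosis.
"""

import numpy as np

from tetralink import estimate_p_co, expected_co_per_chromosome
from tetralink.models import CoClassCounts, co_class_probs

interval_params = [(0.5, 0.2), (0.0, 0.24)]  # (alpha, p) per interval
fits = []
for alpha, p in interval_params:
    counts = CoClassCounts(*(np.round(1200 * co_class_probs(alpha, p)).astype(int)))
    fit = estimate_p_co(counts)
    fits.append(fit)
    print(f"interval at alpha={alpha}: p_hat = {fit.p}  (truth {p})")

total = expected_co_per_chromosome([f.p for f in fits])
print(f"expected crossovers on the chromosome: {total}")
print("The sum of interval p estimates is the chromosome's expected")
print("crossover count per meiosis; SEs combine in quadrature.")
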