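"""Simulate a rifampicin-chase experiment and refit the half-lives.

Generates Ct tables for the mock-condition design (UTR half-life 3.1 min,
ORF 7.2 min; 2 probed regions x 3 biological x 3 technical replicates at
0/5/10/30 min, sigma_Ct = 0.15), converts them to relative quantities
with the comparative-Ct method, and fits one pooled exponential decay
per compartment with a bootstrap 95% interval.
"""

import numpy as np

from ribochase import (
    SimulationParams,
    courses_from_rq,
    delta_delta_ct,
    simulate_chase,
)
from ribochase.decay import fit_with_ci

LN2 = np.log(2.0)

params = SimulationParams(
    f_term=0.959,
    lambda_utr=LN2 / 3.1,
    lambda_orf=LN2 / 7.2,
    ct_noise_sd=0.15,
    seed=42,
)

ct_table = simulate_chase(params, condition="mock")
print(f"simulated {len(ct_table)} qPCR wells "
      f"({ct_table.target.eq('16S').sum()} reference)")

rq = delta_delta_ct(ct_table)
for course in courses_from_rq(rq):
    fit = fit_with_ci(course, n_boot=500, seed=0)
    print(
        f"{course.compartment}: half-life {fit.half_life:.2f} min "
        f"(95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}, "
        f"lambda {fit.lambda_hat:.4f} /min, {fit.n_points} points)"
    )

# The fitted half-lives recover the generative truths (3.1 and 7.2 min)
# to within the noise; the intervals quantify the replicate scatter.
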