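"""Direct population-size estimation from an RDS survey.

Builds a synthetic hidden population of 20,000 MSM in which 3,000 are
registered with an NGO, draws a degree-biased RDS-style sample of 2,000
respondents, and recovers the total population size with the RDS-II
(Volz-Heckathorn) proportion estimator and the multiplier method
N = T / p_hat.
"""

import kpsize as kp

TRUE_SIZE = 20_000
NGO_TOTAL = 3_000

respondents, counts = kp.generate_rds_population(
    TRUE_SIZE, {"ngo": NGO_TOTAL}, n_respondents=2_000, seed=11
)

p_hat = kp.rds2_proportion(respondents, "ngo")
ci = kp.rds2_proportion_ci(respondents, "ngo", n_boot=1000, seed=1)
estimate = kp.multiplier_estimate(counts[0], p_hat, ci)

print(f"RDS-II proportion covered by the NGO: {p_hat:.4f} "
      f"(truth {NGO_TOTAL / TRUE_SIZE:.4f})")
print(f"bootstrap 95% CI for the proportion:  ({ci[0]:.4f}, {ci[1]:.4f})")
print(f"multiplier size estimate: {estimate.n_hat:.0f} "
      f"(95% CI {estimate.ci_low:.0f}-{estimate.ci_high:.0f}), "
      f"truth {TRUE_SIZE}")
# The proportion CI inverts into a size CI with the bounds flipped: a
# larger covered proportion implies a smaller total population.
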