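"""Working with the packaged Côte d'Ivoire direct estimates.

Loads the 19 published multiplier-method size estimates for the five
departments with MSM survey data and shows the regression transforms:
log fractions (using the five-commune Abidjan male 18-29 population) and
CI-derived variance multipliers.
"""

import kpsize as kp

estimates = kp.load_reference_direct_estimates()
print(f"{len(estimates)} direct estimates across "
      f"{len({e.area_id for e in estimates})} departments\n")

ABIDJAN_N = 368_097  # male 18-29 population of the five central communes
print("Abidjan log fractions and variance multipliers:")
for e in estimates:
    if e.area_id != "Abidjan":
        continue
    y = kp.to_log_fraction(e, ABIDJAN_N)
    w = kp.ci_to_weight(e)
    print(f"  {e.method_label:14s} n={e.n_hat:6.0f} "
          f"y=log(n/N)={y:7.3f}  w=(log CI ratio)^2={w:.3f}")

weights = {(e.area_id, e.method_label): kp.ci_to_weight(e)
           for e in estimates}
worst = sorted(weights, key=weights.get, reverse=True)[:3]
print("\nlargest variance multipliers (least-precise estimates):")
for key in worst:
    print(f"  {key[0]:14s} {key[1]:10s} w={weights[key]:.3f}")
# Observations with wide CIs (large w) are down-weighted in the
# heteroscedastic regression by 1/w.
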