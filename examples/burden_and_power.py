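"""Sex-stratified de novo burden testing and power estimation.

Reproduces the arithmetic of the female-vs-male constrained PTV contrast
(rates 0.066 vs 0.033 per child give a rate ratio of 2.0) and shows how
many cases the one-sided exact binomial design needs for 80% power.
"""

from dnvsex import binomial_burden_test, power_curve
from dnvsex.burden import rate_ratio

# female vs male cases: counts scaled to a 106 female / 590 male cohort
k_f, k_m, n_f, n_m = 7, 19, 106, 590
res = binomial_burden_test(k_f, k_m, n_f, n_m, group_a="female", group_b="male")
print(f"rates: {res.rate_a:.3f} per female, {res.rate_b:.3f} per male")
print(f"rate ratio {res.rr:.1f}, one-sided exact binomial P = {res.p:.2f}")
print(f"printed-rate check: 0.066/0.033 -> RR {rate_ratio(0.066, 0.033)}")

null_p = n_f / (n_f + n_m)          # female share of samples under the null
alt_p = k_f / (k_f + k_m)           # female share of events observed
pc = power_curve(null_p, alt_p, [250, 500, 1000, 2000, 4000])
print(pc.to_string(index=False))
reached = pc[pc["power"] >= 0.8]
if len(reached):
    print(f"-> the observed event split reaches 80% power from about "
          f"{reached['n'].iloc[0]} pooled events; smaller effects need far "
          "larger cohorts")
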