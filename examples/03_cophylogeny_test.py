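"""Co-phylogeny test on a simulated scenario with planted host shifts.

Simulates 16 co-diverging host/parasite pairs in which 3 parasite lineages
switched to a different host lineage, estimates TN93 distance matrices
from the sequences, and runs the Procrustean co-phylogeny test. The global
m2 (residual sum of squares) measures incongruence; the permutation
p-value tests the null of no host-parasite congruence; per-link jackknife
residuals flag the host-shift links.
"""

import numpy as np

from codiv import paco_test, scenario_distances, simulate_scenario

scenario = simulate_scenario(n_tips=16, n_shifts=3, seed=42)
dh, dp = scenario_distances(scenario)
result = paco_test(dh, dp, scenario.true_links, n_perm=9999, seed=1)

print(f"global m2 = {result.m2_global:.4f}")
print(f"permutation P = {result.p_value:.5g} ({result.n_permutations} permutations)")
print()
print(f"{'link':>12} {'resid^2':>9} {'jackknife':>10} {'upper95':>9}  truth")
shifted = set(scenario.shifted_links)
for lr in sorted(result.link_residuals, key=lambda r: -r.jackknife_estimate):
    tag = "HOST SHIFT" if (lr.host, lr.parasite) in shifted else ""
    print(
        f"{lr.host + '-' + lr.parasite:>12} {lr.observed:9.4f} "
        f"{lr.jackknife_estimate:10.4f} {lr.upper_ci:9.4f}  {tag}"
    )
print()
top3 = {
    (lr.host, lr.parasite)
    for lr in sorted(result.link_residuals, key=lambda r: -r.jackknife_estimate)[:3]
}
print(
    f"co-divergence is detected despite the shifts (P << 0.05), and "
    f"{len(top3 & shifted)}/3 of the largest jackknife residuals are the "
    "planted host shifts."
)
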