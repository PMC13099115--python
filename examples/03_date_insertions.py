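"""Date ERV insertions from LTR-pair divergence (T = K/2r).

Simulates LTR pairs of known age, re-estimates the age from the K2P distance
between the two LTRs, and prints truth vs estimate. At integration both LTRs
are identical; each accumulates substitutions at r = 2.3e-9 /site/year, so
K estimates 2 r T.
"""

import numpy as np

from ervkit import date_ltr_pair
from ervkit.kimura import evolve_codes
from ervkit.util import decode, substream

r = 2.3e-9
rng = substream(11, "example-dating")
ltr = rng.integers(0, 4, size=600).astype(np.uint8)

print(f"{'truth (My)':>10} {'mean K':>9} {'mean estimate (My)':>18} "
      f"{'identical LTRs':>15}")
for age_my in (0.1, 0.5, 1.0, 2.0, 3.5):
    t = age_my * 1e6
    res = [date_ltr_pair(decode(evolve_codes(ltr, r * t, 2.0, rng)),
                         decode(evolve_codes(ltr, r * t, 2.0, rng)))
           for _ in range(50)]
    mean_k = float(np.mean([x.K for x in res]))
    mean_t = float(np.mean([x.T_years for x in res])) / 1e6
    frac0 = float(np.mean([x.identical_ltrs for x in res]))
    print(f"{age_my:>10.1f} {mean_k:>9.5f} {mean_t:>18.2f} {frac0:>15.2f}")
# Averaged over 50 pairs per age the estimator is unbiased; single pairs are
# Poisson-noisy (a 600-bp pair at 1 My expects only ~2.8 differences).
# K = 0 (identical LTRs) is an age-0 lower bound, and its frequency decays
# with age - exactly the pattern used to argue for recent insertions.
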