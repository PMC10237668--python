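"""Prior predictive screening of the candidate prior scales.

For each candidate sd in {10, 1.5, 1, 0.5, 0.25}, simulates datasets from
the intercept model's prior and summarizes (a) the dataset-level
proportion of subjective choices and (b) the trial-level choice
probabilities.  A normal(0, 10) prior — flat-looking in log-odds space —
implies listeners who essentially never or always choose the subjective
continuation; sds of 1.5, 1, and 0.5 cover (0, 1) without such extremes.
"""

import numpy as np

from soprosody import (
    GenerativeParams,
    PRIOR_PREDICTIVE_SDS,
    PriorSpec,
    gen_responses,
    prior_predictive,
)

design = gen_responses(40, GenerativeParams(seed=0))
print(f"{'prior sd':>8} {'prop. 5-95%':>12} {'trial P outside':>16} "
      f"{'mean prop.':>11}")
for sd in PRIOR_PREDICTIVE_SDS:
    prop = prior_predictive("m0", PriorSpec(sd), design, seed=1)
    trial = prior_predictive("m0", PriorSpec(sd), design, seed=1,
                             statistic="trial_probability")
    inside = np.mean((prop > 0.05) & (prop < 0.95))
    outside = np.mean((trial < 0.05) | (trial > 0.95))
    print(f"{sd:>8} {inside:>12.2f} {outside:>16.2f} {prop.mean():>11.3f}")
# "prop. 5-95%": share of simulated datasets with a non-extreme choice
# proportion; "trial P outside": share of trial-level probabilities below
# 0.05 or above 0.95 (the never/always behaviour of the sd=10 prior).
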