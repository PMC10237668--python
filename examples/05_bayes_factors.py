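"""Bayes factors for the prosody term under three priors.

Fits m0 (no prosody) and m1 (prosody) to one synthetic dataset under
normal(0, sd) priors with sd in {1.5, 1, 0.5}, estimates each model's
evidence by bridge sampling, and prints BF10.  Narrower priors commit the
alternative model to plausible effect sizes, so BF10 grows as the prior
tightens when a real effect is present.  Runtime is a few minutes.
"""

from soprosody import (
    BAYES_FACTOR_SDS,
    GenerativeParams,
    PriorSpec,
    REDUCED_SETTINGS,
    bayes_factor,
    gen_responses,
)

data = gen_responses(40, GenerativeParams(seed=21))
print("BF10 for the prosody term (m1 vs m0):")
for sd in BAYES_FACTOR_SDS:
    bf = bayes_factor("m1", "m0", PriorSpec(sd), data, seed=3,
                      **REDUCED_SETTINGS)
    print(f"  prior normal(0, {sd:>3}): BF10 = {bf.bf10:6.2f}  ({bf.band}; "
          f"bridge CVs {bf.cv_with:.3f}/{bf.cv_without:.3f})")
# BF10 > 1 supports including prosody; the exact value depends on the
# realized synthetic effect in this dataset.
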