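"""Sample-size planning for a target confidence-interval length.

Before running a rhythm experiment one can ask: how many balanced samples
are needed so the 95% CI of the amplitude (or acrophase) is no longer than
a chosen target, given the expected noise level?
"""

import rhythmfit as rf

noise_sd = 0.5
print("amplitude CI target -> minimal n (noise SD 0.5, 95% level)")
for target in (0.8, 0.4, 0.2, 0.1):
    n = rf.required_sample_size(target, "amplitude", noise_sd=noise_sd)
    print(f"  {target:4.2f} -> n = {n}")

print("\nacrophase CI target (rad) at design amplitude 1.0")
for target in (0.8, 0.4, 0.2):
    n = rf.required_sample_size(target, "acrophase", noise_sd=noise_sd,
                                amplitude=1.0)
    print(f"  {target:4.2f} -> n = {n}")
# Halving the target roughly quadruples the required n: CI length shrinks
# like 1/sqrt(n). Acrophase precision additionally scales with 1/amplitude,
# so weak rhythms need disproportionately more samples for good timing.
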