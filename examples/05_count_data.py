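"""Rhythm detection in count data with log-link cosinor GLMs.

Counts (e.g. spikes, events, reads per time bin) are generated with a
Poisson law whose log-intensity follows a 24 h cosinor curve, then fitted
with Poisson and generalized Poisson models on the same trigonometric
design.
"""

import rhythmfit as rf

spec = rf.SignalSpec(period_hours=24.0, n_components=1, mesor=1.0,
                     component_amplitudes=(0.8,), noise_amplitude=0.0,
                     step_hours=1.0, n_replicates=3)
df = rf.generate_counts(spec, seed=1)
t, y = df["x"].to_numpy(), df["y"].to_numpy()

for family in ("poisson", "generalized_poisson"):
    fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1, family))
    amp, phi = rf.polar_params(*fit.component_pair(1))
    print(f"{family:20s} log-mesor {fit.mesor:.3f}  "
          f"log-amplitude {amp:.3f}  acrophase {phi:+.3f} rad  "
          f"p = {fit.p_overall:.3g}")
# Both families recover the generating log-scale parameters (mesor 1.0,
# amplitude 0.8, acrophase 0); the likelihood-ratio p-values confirm the
# rhythm. The generalized Poisson additionally estimates a dispersion
# parameter, making it robust to over- or under-dispersed counts.
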