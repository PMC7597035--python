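"""Fit a single-component cosinor and test for rhythmicity.

Builds one noisy 24 h rhythm (amplitude 1, MESOR 0.5, noise SD 0.5, sampled
every 2 h over 48 h in triplicate), fits the cosinor model and prints the
rhythm parameters with confidence intervals.
"""

import rhythmfit as rf

spec = rf.SignalSpec(period_hours=24.0, n_components=1, mesor=0.5,
                     noise_amplitude=0.5, step_hours=2.0, n_replicates=3)
df = rf.generate_signal(spec, seed=1, label="demo")

fit = rf.fit_single(df["x"].to_numpy(), df["y"].to_numpy(), period_hours=24.0)
ci = rf.confidence_intervals(fit, level=0.95)
za = rf.zero_amplitude_test(fit)

print(f"MESOR      {fit.mesor:8.3f}  (95% CI {ci.mesor[1]:.3f} .. {ci.mesor[2]:.3f})")
print(f"amplitude  {fit.amplitude:8.3f}  (95% CI {ci.amplitude[1]:.3f} .. {ci.amplitude[2]:.3f})")
print(f"acrophase  {fit.acrophase_rad:8.3f} rad "
      f"(peak at {-fit.acrophase_rad * 24 / (2 * 3.141592653589793):.2f} h)")
print(f"zero-amplitude test: F = {za.statistic:.1f}, p = {za.p_value:.3g}")
# The amplitude CI excluding 0 and the tiny p-value both say: this series is
# rhythmic; the acrophase locates its daily peak near time 0.
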