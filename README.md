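# rhythmfit

Cosinor rhythmometry for Python: detection, quantification and comparison of
biological rhythms (circadian and otherwise) in time-series measurements.

Biologists routinely need to answer three questions about a measured
quantity — gene expression, hormone concentration, activity counts, event
rates: *is it rhythmic*, *what are its rhythm parameters*, and *did the
rhythm change between conditions?* `rhythmfit` answers all three with the
classical cosinor framework: trigonometric regression that is linear in its
coefficients once the period is fixed.

## The model

A rhythm with period *P* and *N* harmonic components is modelled as

    y(t) = M + Σᵢ₌₁ᴺ [ A_{i,1} sin(2πit/P) + A_{i,2} cos(2πit/P) ] + e(t)

where *M* is the MESOR (rhythm-adjusted mean) and harmonic *i* has period
*P/i*. For a single component the rhythm parameters have closed forms:
amplitude A = √(A₁² + A₂²) and acrophase φ = atan2(−A₁, A₂) wrapped into
(−2π, 0], so the peak falls at t = −φ·P/(2π) hours. Multi-component
parameters (amplitude, acrophase, peaks/troughs) are read off the fitted
curve on a dense grid.

On top of the fits the package provides:

- **rhythm detection** — zero-amplitude F-test, overall model F-test,
  lack-of-fit test against replicate (pure) error;
- **model selection** — extra sum-of-squares F-test
  F = ((SSR₁−SSR₂)/SSR₂)/((DoF₁−DoF₂)/DoF₂) over nested component counts,
  plus a Lomb–Scargle period scan;
- **count data** — Poisson, generalized Poisson and negative-binomial
  cosinor GLMs with a log link;
- **population-mean cosinor** — per-individual fits averaged on the
  coefficient scale, with a Hotelling-type zero-amplitude test (k ≥ 3
  individuals);
- **differential rhythmicity** — joint single-component model with a group
  indicator, joint multi-component model with per-coefficient t-tests, and
  a nonlinear amplitude/phase parameterisation; acrophase shifts are
  reported wrapped into (−π, π];
- **multiple testing** — Benjamini–Hochberg q-values across batch analyses;
- **design of experiments** — minimal sample size for a target CI length;
- **synthetic data** — a seeded generator of multi-harmonic signals (and
  Poisson counts) with known ground truth, including the standard
  four-scenario benchmark suite;
- **figures** — fit overlays, comparison panels and polar acrophase plots,
  with the plotted numbers embedded as JSON metadata.

## Worked example

```python
import rhythmfit as rf

suite = rf.generate_benchmark_suite(seed=1)          # four benchmark groups
table = rf.analyze_all(suite.measurements, periods=[24.0], max_components=3)
print(table[["test", "n_components", "amplitude", "acrophase_rad", "p", "q"]])
```

prints

```
 test  n_components  amplitude  acrophase_rad         p         q
test1             1     0.9335         -6.189 6.594e-18 6.594e-18
test2             1     0.9548         -3.091 8.771e-20  1.17e-19
test3             3      1.276      -0.006283 9.899e-35  1.98e-34
test4             3      1.278         -3.154 2.192e-37 8.767e-37
```

The two single-harmonic groups select 1 component and the two
three-harmonic groups select 3; the acrophases near 0/−2π versus −π
reflect peaks at 0 h versus 12 h; every q-value is far below 0.05, so all
four rhythms survive FDR adjustment. The `examples/` directory walks
through each capability (fitting, selection, population models,
differential analysis, count data, sample-size planning) as short
narrative scripts.

A thin CLI wraps the same functions:

```sh
rhythmfit generate --scenario benchmark --seed 1 --out data.csv
rhythmfit select --in data.csv --periods 24 --max-components 3 --out results.csv
rhythmfit compare --in data.csv --pairs test1:test2,test3:test4 --out cmp.csv
```

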