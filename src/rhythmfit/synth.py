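"""Synthetic rhythmic time series with known ground truth.

The generator produces multi-harmonic cosinor signals

    y(t) = M + sum_{i=1}^{N} a_i * cos(2*pi*i*t/P + i*phi) + e(t)

where harmonic *i* has period ``P/i`` and the fundamental acrophase ``phi``
enters harmonic *i* as ``i*phi``: the acrophase therefore acts as a rigid
time shift of the whole waveform, so ``phi = pi`` delays any profile by half
a period.  The additive error ``e(t)`` is zero-mean, i.i.d., with scale set
by ``noise_amplitude`` (Gaussian sigma by default, half-width for the
uniform option).

The four benchmark scenarios (``test1``..``test4``) share a 24 h period, a
48 h span, noise amplitude 0.5 and three replicates; they differ in harmonic
count (1 vs 3), sampling step (2 h vs 1 h) and acrophase (0 vs pi).  Unless
overridden, harmonic *i* carries amplitude ``1/i`` and the MESOR is 0, which
gives the 3-component scenarios a multi-peak profile that a single harmonic
cannot fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import MeasurementSet

__all__ = [
    "SignalSpec",
    "GeneratedSet",
    "generate_signal",
    "generate_counts",
    "generate_benchmark_suite",
    "BENCHMARK_SPECS",
]


@dataclass(frozen=True)
class SignalSpec:
    """Ground-truth description of one synthetic rhythmic signal."""

    period_hours: float = 24.0
    n_components: int = 1
    component_amplitudes: tuple[float, ...] | None = None
    acrophase_rad: float = 0.0
    mesor: float = 0.0
    noise_amplitude: float = 0.5
    span_hours: float = 48.0
    step_hours: float = 2.0
    n_replicates: int = 3
    dependence: str = "independent"  # or "per_individual"
    noise_distribution: str = "gaussian"  # or "uniform"

    def __post_init__(self):
        for name in ("period_hours", "step_hours", "span_hours"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be a finite positive number, got {v!r}")
        if self.n_components < 1 or self.n_replicates < 1:
            raise ValidationError("n_components and n_replicates must be >= 1")
        if self.span_hours < self.period_hours:
            raise ValidationError("span_hours must cover at least one full period")
        if self.noise_amplitude < 0:
            raise ValidationError("noise_amplitude must be non-negative")
        if self.component_amplitudes is None:
            # default: fundamental 1, harmonic i gets 1/i
            amps = tuple(1.0 / i for i in range(1, self.n_components + 1))
            object.__setattr__(self, "component_amplitudes", amps)
        else:
            amps = tuple(float(a) for a in self.component_amplitudes)
            if len(amps) != self.n_components:
                raise ValidationError(
                    "component_amplitudes length must equal n_components"
                )
            if any(a < 0 for a in amps):
                raise ValidationError("component amplitudes must be non-negative")
            object.__setattr__(self, "component_amplitudes", amps)
        if self.dependence not in ("independent", "per_individual"):
            raise ValidationError("dependence must be 'independent' or 'per_individual'")
        if self.noise_distribution not in ("gaussian", "uniform"):
            raise ValidationError("noise_distribution must be 'gaussian' or 'uniform'")

    def times(self) -> np.ndarray:
        """Sampling grid 0, step, 2*step, ... , inclusive of span when exact."""
        n = int(math.floor(self.span_hours / self.step_hours + 1e-9)) + 1
        return np.arange(n) * self.step_hours

    def curve(self, t) -> np.ndarray:
        """Noiseless signal evaluated at times ``t`` (hours)."""
        t = np.asarray(t, dtype=float)
        y = np.full(t.shape, float(self.mesor))
        for i, a in enumerate(self.component_amplitudes, start=1):
            y = y + a * np.cos(2 * np.pi * i * t / self.period_hours + i * self.acrophase_rad)
        return y

    @property
    def noise_variance(self) -> float:
        """Variance of the additive error under the configured noise law."""
        a = self.noise_amplitude
        return a * a if self.noise_distribution == "gaussian" else a * a / 3.0


@dataclass
class GeneratedSet:
    """A generated measurement collection together with its ground truth."""

    measurements: MeasurementSet
    truth: dict[str, SignalSpec]
    seed: int

    def __post_init__(self):
        labels = set(self.measurements.groups)
        missing = labels - set(self.truth)
        if missing:
            raise ValidationError(f"groups without ground truth: {sorted(missing)}")


def _noise(rng: np.random.Generator, spec: SignalSpec, size: int) -> np.ndarray:
    if spec.noise_amplitude == 0:
        return np.zeros(size)
    if spec.noise_distribution == "gaussian":
        return rng.normal(0.0, spec.noise_amplitude, size)
    return rng.uniform(-spec.noise_amplitude, spec.noise_amplitude, size)


def generate_signal(spec: SignalSpec, seed, label: str = "signal") -> pd.DataFrame:
    """Generate one group of noisy records for ``spec``.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  Each
    replicate is sampled on the same time grid; with
    ``dependence='per_individual'`` every replicate carries a distinct
    individual id so downstream population-mean fits treat it as one subject.
    """
    rng = np.random.default_rng(seed)
    t = spec.times()
    base = spec.curve(t)
    frames = []
    for r in range(spec.n_replicates):
        y = base + _noise(rng, spec, t.size)
        ind = f"{label}_{r + 1}" if spec.dependence == "per_individual" else None
        frames.append(
            pd.DataFrame({"test": label, "x": t, "y": y, "individual": ind})
        )
    return pd.concat(frames, ignore_index=True)


def generate_counts(spec: SignalSpec, seed, label: str = "counts") -> pd.DataFrame:
    """Generate Poisson counts whose log-intensity is the cosinor curve.

    The spec's ``mesor`` and amplitudes live on the log scale, matching a
    log-link count regression: counts at time t are Poisson with mean
    ``exp(curve(t))``.  ``noise_amplitude`` is ignored (Poisson sampling is
    the noise).
    """
    rng = np.random.default_rng(seed)
    t = spec.times()
    lam = np.exp(spec.curve(t))
    frames = []
    for r in range(spec.n_replicates):
        y = rng.poisson(lam).astype(float)
        ind = f"{label}_{r + 1}" if spec.dependence == "per_individual" else None
        frames.append(
            pd.DataFrame({"test": label, "x": t, "y": y, "individual": ind})
        )
    return pd.concat(frames, ignore_index=True)


#: The four benchmark scenarios: period 24 h, span 48 h, noise 0.5, 3 replicates;
#: test1/test2 use one harmonic sampled every 2 h with acrophase 0 / pi,
#: test3/test4 use three harmonics sampled every 1 h with acrophase 0 / pi.
BENCHMARK_SPECS: dict[str, SignalSpec] = {
    "test1": SignalSpec(n_components=1, step_hours=2.0, acrophase_rad=0.0),
    "test2": SignalSpec(n_components=1, step_hours=2.0, acrophase_rad=math.pi),
    "test3": SignalSpec(n_components=3, step_hours=1.0, acrophase_rad=0.0),
    "test4": SignalSpec(n_components=3, step_hours=1.0, acrophase_rad=math.pi),
}


def generate_benchmark_suite(seed: int, dependence: str = "independent") -> GeneratedSet:
    """Generate the four-scenario benchmark suite.

    Per-group substreams are spawned deterministically from the master seed,
    so regenerating with the same seed reproduces every value exactly and a
    group's draw does not depend on the other groups.
    """
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(BENCHMARK_SPECS))
    frames, truth = [], {}
    for child, (label, spec) in zip(children, BENCHMARK_SPECS.items()):
        spec = replace(spec, dependence=dependence)
        frames.append(generate_signal(spec, child, label=label))
        truth[label] = spec
    mset = MeasurementSet(pd.concat(frames, ignore_index=True))
    return GeneratedSet(measurements=mset, truth=truth, seed=int(seed))
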