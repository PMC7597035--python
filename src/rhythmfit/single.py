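"""Single-component cosinor with closed-form rhythm parameters.

With one harmonic the model is y(t) = M + A1*sin(wt) + A2*cos(wt) + e(t),
w = 2*pi/P, and the rhythm parameters have closed forms:

    amplitude  A   = sqrt(A1^2 + A2^2)
    acrophase  phi = atan2(-A1, A2) wrapped into (-2*pi, 0]

so that y(t) = M + A*cos(wt + phi) and the peak occurs at t = -phi*P/(2*pi).
The atan2 form is exactly the classical four-quadrant arctan case table for
the acrophase.

The module also provides the zero-amplitude F-test, confidence intervals for
(M, A, phi), a design-of-experiments sample-size calculator, and the
population-mean cosinor for dependent per-individual series (individual fits
averaged on the coefficient scale, never on angles, with a Hotelling-type
zero-amplitude test on the among-individual scatter of (A1, A2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from . import core
from .errors import FittingError, InfeasibleError, ValidationError

__all__ = [
    "polar_params",
    "SingleCosinorFit",
    "ParamCI",
    "fit_single",
    "zero_amplitude_test",
    "confidence_intervals",
    "required_sample_size",
    "PopulationFit",
    "fit_population",
    "fit_population_multicomponent",
]

TWO_PI = 2 * np.pi


def wrap_acrophase(phi: float) -> float:
    """Wrap an angle into the acrophase convention (-2*pi, 0]."""
    phi = float(phi) % TWO_PI  # in [0, 2*pi)
    out = phi - TWO_PI if phi > 0 else 0.0
    # guard the float boundary: a vanishingly small positive phi would
    # otherwise round to exactly -2*pi, which is outside (-2*pi, 0]
    return 0.0 if out <= -TWO_PI else out


def wrap_difference(dphi: float) -> float:
    """Wrap a phase difference into (-pi, pi]."""
    d = (float(dphi) + np.pi) % TWO_PI - np.pi
    return np.pi if d == -np.pi else d


def polar_params(a1: float, a2: float) -> tuple[float, float]:
    """Amplitude and acrophase from the sine/cosine coefficient pair.

    Total function: (0, 0) maps to amplitude 0 with acrophase 0 (the
    continuous limit of the first case).
    """
    amplitude = float(np.hypot(a1, a2))
    if amplitude == 0.0:
        return 0.0, 0.0
    return amplitude, wrap_acrophase(np.arctan2(-a1, a2))


@dataclass
class SingleCosinorFit:
    """A fitted single-component cosinor with closed-form rhythm parameters."""

    mesor: float
    a1: float
    a2: float
    amplitude: float
    acrophase_rad: float
    cov: np.ndarray
    ssr: float
    n_obs: int
    period_hours: float
    core_fit: core.CosinorFit = field(repr=False)

    @property
    def dof(self) -> int:
        return self.n_obs - 3

    def predict(self, times) -> np.ndarray:
        return self.core_fit.predict(times)


def fit_single(t, y, period_hours: float = 24.0) -> SingleCosinorFit:
    """Least-squares single-component cosinor fit.

    Delegates to the shared trigonometric-regression engine (one harmonic),
    then attaches the closed-form amplitude and acrophase.
    """
    t = np.asarray(t, float)
    if t.size < 4 or np.unique(t).size < 3:
        raise FittingError("single-component fit needs >= 4 points at >= 3 distinct times")
    fit = core.fit_model(t, y, core.CosinorModelSpec(period_hours, 1, core.GAUSSIAN))
    a1, a2 = fit.component_pair(1)
    amplitude, acrophase = polar_params(a1, a2)
    return SingleCosinorFit(
        mesor=fit.mesor,
        a1=a1,
        a2=a2,
        amplitude=amplitude,
        acrophase_rad=acrophase,
        cov=fit.cov,
        ssr=fit.ssr,
        n_obs=fit.n_obs,
        period_hours=period_hours,
        core_fit=fit,
    )


def zero_amplitude_test(fit: SingleCosinorFit) -> core.TestResult:
    """F-test of H0: amplitude = 0 (no rhythm).

    F = (model SS / 2) / (SSR / (n - 3)), df (2, n-3).  A flat noiseless
    input (no model SS, no residual SS) yields p = 1 by convention; a
    perfect rhythmic fit yields p = 0 with a note.
    """
    if fit.n_obs < 5:
        raise ValidationError("zero-amplitude test needs >= 5 observations")
    y = fit.core_fit.y
    tss = float(np.sum((y - y.mean()) ** 2))
    mss = max(tss - fit.ssr, 0.0)
    scale = max(tss, 1.0)
    if mss <= scale * 1e-12:
        return core.TestResult(0.0, (2, fit.dof), 1.0, "zero-amplitude F-test",
                               note="no rhythmic variation")
    if fit.ssr <= scale * 1e-12:
        return core.TestResult(np.inf, (2, fit.dof), 0.0, "zero-amplitude F-test",
                               note="perfect fit (SSR = 0)")
    f_stat = (mss / 2.0) / (fit.ssr / fit.dof)
    p = float(scipy.stats.f.sf(f_stat, 2, fit.dof))
    return core.TestResult(float(f_stat), (2, fit.dof), p, "zero-amplitude F-test")


@dataclass
class ParamCI:
    """Confidence intervals for MESOR, amplitude and acrophase.

    ``amplitude`` and ``acrophase`` come from projecting the joint elliptical
    confidence region of (A1, A2) onto the polar coordinates (conservative);
    the delta-method intervals are reported alongside.  When the region
    covers the origin the acrophase is unidentified and the interval spans
    the full circle, flagged via ``acrophase_full_circle``.
    """

    level: float
    mesor: tuple[float, float, float]
    amplitude: tuple[float, float, float]
    acrophase: tuple[float, float, float]
    amplitude_delta: tuple[float, float, float]
    acrophase_delta: tuple[float, float, float]
    acrophase_full_circle: bool = False


def _ellipse_polar_ci(mean2, cov2, radius2, estimate_amp, estimate_phi, level):
    """Project the ellipse (b-m)' C^-1 (b-m) <= r2 onto (amplitude, phase)."""
    mean2 = np.asarray(mean2, float)
    vals, vecs = np.linalg.eigh(np.asarray(cov2, float))
    vals = np.clip(vals, 0.0, None)
    L = vecs @ np.diag(np.sqrt(vals))
    theta = np.linspace(0, TWO_PI, 720, endpoint=False)
    boundary = mean2[:, None] + np.sqrt(radius2) * (L @ np.vstack([np.cos(theta), np.sin(theta)]))
    amps = np.hypot(boundary[0], boundary[1])
    try:
        cinv = np.linalg.inv(cov2)
        origin_inside = float(mean2 @ cinv @ mean2) <= radius2
    except np.linalg.LinAlgError:
        origin_inside = estimate_amp == 0.0
    amp_lo = 0.0 if origin_inside else float(amps.min())
    amp_hi = float(amps.max())
    if origin_inside:
        return (amp_lo, amp_hi), (estimate_phi - np.pi, estimate_phi + np.pi), True
    phis = np.arctan2(-boundary[0], boundary[1])
    dev = np.array([wrap_difference(p - estimate_phi) for p in phis])
    return (amp_lo, amp_hi), (estimate_phi + dev.min(), estimate_phi + dev.max()), False


def confidence_intervals(fit: SingleCosinorFit, level: float = 0.95) -> ParamCI:
    """Confidence intervals for M, A and phi at the requested level."""
    if fit.n_obs < 5:
        raise ValidationError("confidence intervals need >= 5 observations")
    if not (0 < level < 1):
        raise ValidationError("level must be in (0, 1)")
    df = fit.dof
    tcrit = scipy.stats.t.ppf(1 - (1 - level) / 2, df)
    se_m = float(np.sqrt(fit.cov[0, 0]))
    mesor_ci = (fit.mesor, fit.mesor - tcrit * se_m, fit.mesor + tcrit * se_m)

    cov2 = fit.cov[1:3, 1:3]
    a1, a2, A = fit.a1, fit.a2, fit.amplitude
    # delta method
    if A > 0:
        g_amp = np.array([a1 / A, a2 / A])
        g_phi = np.array([-a2, a1]) / (A * A)
        se_amp = float(np.sqrt(g_amp @ cov2 @ g_amp))
        se_phi = float(np.sqrt(g_phi @ cov2 @ g_phi))
    else:
        se_amp = float(np.sqrt(np.trace(cov2) / 2))
        se_phi = np.inf
    amp_delta = (A, A - tcrit * se_amp, A + tcrit * se_amp)
    phi_delta = (fit.acrophase_rad, fit.acrophase_rad - tcrit * se_phi,
                 fit.acrophase_rad + tcrit * se_phi)
    # joint-region projection: (b - bhat)' C^-1 (b - bhat) <= 2 F_{2,df}(level)
    radius2 = 2 * scipy.stats.f.ppf(level, 2, df)
    (amp_lo, amp_hi), (phi_lo, phi_hi), full = _ellipse_polar_ci(
        [a1, a2], cov2, radius2, A, fit.acrophase_rad, level
    )
    return ParamCI(
        level=level,
        mesor=mesor_ci,
        amplitude=(A, amp_lo, amp_hi),
        acrophase=(fit.acrophase_rad, phi_lo, phi_hi),
        amplitude_delta=amp_delta,
        acrophase_delta=phi_delta,
        acrophase_full_circle=full,
    )


def required_sample_size(
    target_ci_length: float,
    parameter: str = "amplitude",
    noise_sd: float = 0.5,
    level: float = 0.95,
    amplitude: float = 1.0,
    n_max: int = 10_000_000,
) -> int:
    """Smallest n whose predicted CI length meets the target.

    Assumes balanced sampling over whole periods, under which the amplitude
    standard error is sigma*sqrt(2/n) and the acrophase standard error is
    sigma*sqrt(2/n)/A at design amplitude A; the CI length is twice the
    two-sided t critical value times the standard error.  The floor is n=5
    (the smallest n with a usable residual df for the tests).
    """
    if parameter not in ("amplitude", "acrophase"):
        raise ValidationError("parameter must be 'amplitude' or 'acrophase'")
    if not (target_ci_length > 0 and noise_sd > 0 and 0 < level < 1):
        raise ValidationError("target, noise_sd must be positive and level in (0,1)")
    if parameter == "acrophase" and amplitude <= 0:
        raise InfeasibleError("acrophase precision is unreachable at zero amplitude")
    for n in range(5, n_max + 1):
        se = noise_sd * np.sqrt(2.0 / n)
        if parameter == "acrophase":
            se /= amplitude
        length = 2 * scipy.stats.t.ppf(1 - (1 - level) / 2, n - 3) * se
        if length <= target_ci_length:
            return n
    raise InfeasibleError(
        f"target CI length {target_ci_length} not reachable below n = {n_max}"
    )


@dataclass
class PopulationFit:
    """Population-mean single-component cosinor over k >= 3 individuals.

    Population coefficients are the arithmetic means of the individual
    (M, A1, A2); the population amplitude and acrophase derive from the mean
    coefficients (vector averaging, never angle averaging).
    """

    individual_fits: dict[str, SingleCosinorFit]
    mesor: float
    a1: float
    a2: float
    amplitude: float
    acrophase_rad: float
    coef_cov: np.ndarray  # among-individual covariance of (A1, A2)
    p_zero_amplitude: float
    f_zero_amplitude: float
    period_hours: float
    note: str | None = None

    @property
    def k(self) -> int:
        return len(self.individual_fits)

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, float)
        w = TWO_PI * t / self.period_hours
        return self.mesor + self.a1 * np.sin(w) + self.a2 * np.cos(w)

    def confidence_intervals(self, level: float = 0.95) -> ParamCI:
        """CIs of the population parameters from among-individual variability."""
        k = self.k
        df = k - 1
        tcrit = scipy.stats.t.ppf(1 - (1 - level) / 2, df)
        ms = [f.mesor for f in self.individual_fits.values()]
        se_m = float(np.std(ms, ddof=1) / np.sqrt(k))
        mesor_ci = (self.mesor, self.mesor - tcrit * se_m, self.mesor + tcrit * se_m)
        cov_mean = self.coef_cov / k
        m2 = np.array([self.a1, self.a2])
        A = self.amplitude
        if A > 0 and np.all(np.isfinite(cov_mean)):
            g_amp = m2 / A
            g_phi = np.array([-self.a2, self.a1]) / (A * A)
            se_amp = float(np.sqrt(g_amp @ cov_mean @ g_amp))
            se_phi = float(np.sqrt(g_phi @ cov_mean @ g_phi))
        else:
            se_amp, se_phi = np.nan, np.inf
        amp_delta = (A, A - tcrit * se_amp, A + tcrit * se_amp)
        phi_delta = (self.acrophase_rad, self.acrophase_rad - tcrit * se_phi,
                     self.acrophase_rad + tcrit * se_phi)
        if k >= 4 and np.linalg.matrix_rank(cov_mean) == 2:
            radius2 = (2.0 * (k - 1) / (k - 2)) * scipy.stats.f.ppf(level, 2, k - 2)
            (alo, ahi), (plo, phi_hi), full = _ellipse_polar_ci(
                m2, cov_mean, radius2, A, self.acrophase_rad, level
            )
        else:
            (alo, ahi), (plo, phi_hi), full = (
                (amp_delta[1], amp_delta[2]),
                (phi_delta[1], phi_delta[2]),
                False,
            )
        return ParamCI(level, mesor_ci, (A, max(alo, 0.0), ahi),
                       (self.acrophase_rad, plo, phi_hi), amp_delta, phi_delta, full)


def _split_individuals(t, y, individuals):
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    individuals = np.asarray(individuals, dtype=object)
    if individuals.size != t.size:
        raise ValidationError("individual labels must align with the records")
    out = {}
    for label in dict.fromkeys(individuals):
        mask = individuals == label
        out[str(label)] = (t[mask], y[mask])
    return out


def fit_population(t, y, individuals, period_hours: float = 24.0) -> PopulationFit:
    """Population-mean cosinor: fit each individual, then average coefficients.

    The zero-amplitude p-value is a Hotelling-type F on the mean individual
    (A1, A2) against their among-individual covariance:

        T^2 = k * m' S^-1 m,   F = (k-2)/(2(k-1)) * T^2,   df (2, k-2).

    Perfectly concordant individuals (singular S with non-zero mean rhythm)
    are reported as p = 0 with a note; a singular S around a zero mean gives
    p = 1.
    """
    groups = _split_individuals(t, y, individuals)
    if len(groups) < 3:
        raise ValidationError(
            f"population-mean cosinor requires at least 3 individuals, got {len(groups)}"
        )
    fits = {lab: fit_single(ti, yi, period_hours) for lab, (ti, yi) in groups.items()}
    coefs = np.array([[f.a1, f.a2] for f in fits.values()])
    k = len(fits)
    m = coefs.mean(axis=0)
    S = np.cov(coefs, rowvar=False, ddof=1)
    amplitude, acrophase = polar_params(m[0], m[1])
    note = None
    det = float(np.linalg.det(S))
    scale = max(float(np.trace(S)), float(m @ m), 1e-30)
    if det <= 1e-14 * scale**2:
        if amplitude > 1e-8 * max(1.0, np.sqrt(scale)):
            f_stat, p = np.inf, 0.0
            note = "individuals perfectly concordant (singular covariance)"
        else:
            f_stat, p = 0.0, 1.0
            note = "no rhythm and no dispersion"
    else:
        t2 = float(k * m @ np.linalg.inv(S) @ m)
        f_stat = (k - 2) / (2.0 * (k - 1)) * t2
        p = float(scipy.stats.f.sf(f_stat, 2, k - 2))
    return PopulationFit(
        individual_fits=fits,
        mesor=float(np.mean([f.mesor for f in fits.values()])),
        a1=float(m[0]),
        a2=float(m[1]),
        amplitude=amplitude,
        acrophase_rad=acrophase,
        coef_cov=S,
        p_zero_amplitude=p,
        f_zero_amplitude=float(f_stat),
        period_hours=period_hours,
        note=note,
    )


@dataclass
class PopulationMultiFit:
    """Population-mean multi-component cosinor (mean of individual models)."""

    individual_fits: dict[str, core.CosinorFit]
    mean_coefficients: np.ndarray
    spec: core.CosinorModelSpec
    params: core.RhythmParams
    coefficient_tests: list[core.TestResult]
    p_zero_amplitude: float

    @property
    def k(self) -> int:
        return len(self.individual_fits)

    def predict(self, times) -> np.ndarray:
        proto = next(iter(self.individual_fits.values()))
        saved = proto.coefficients
        try:
            proto.coefficients = self.mean_coefficients
            return proto.predict(times)
        finally:
            proto.coefficients = saved


def fit_population_multicomponent(
    t, y, individuals, spec: core.CosinorModelSpec
) -> PopulationMultiFit:
    """Multi-component population-mean cosinor.

    Each individual gets its own fit; the population curve is the mean of
    the individual curves (equivalently the curve of the mean coefficients,
    the model being linear).  Rhythm parameters come from that mean curve.
    Each rhythmic coefficient is tested across individuals with a one-sample
    t-test, and the model-level zero-amplitude F uses the fundamental
    (A_{1,1}, A_{1,2}) pair as in the single-component population test.
    """
    groups = _split_individuals(t, y, individuals)
    if len(groups) < 3:
        raise ValidationError(
            f"population-mean cosinor requires at least 3 individuals, got {len(groups)}"
        )
    fits = {lab: core.fit_model(ti, yi, spec) for lab, (ti, yi) in groups.items()}
    coefs = np.array([f.coefficients[: spec.n_params] for f in fits.values()])
    k = len(fits)
    mean_coef = coefs.mean(axis=0)
    tests = []
    names = ["M"] + [f"A_{i},{j}" for i in range(1, spec.n_components + 1) for j in (1, 2)]
    for j, name in enumerate(names):
        col = coefs[:, j]
        sd = np.std(col, ddof=1)
        if sd == 0:
            stat = np.inf if abs(mean_coef[j]) > 0 else 0.0
            p = 0.0 if abs(mean_coef[j]) > 0 else 1.0
        else:
            stat = mean_coef[j] / (sd / np.sqrt(k))
            p = float(2 * scipy.stats.t.sf(abs(stat), k - 1))
        tests.append(core.TestResult(float(stat), (k - 1,), p, f"t-test {name}"))
    # model-level zero-amplitude test on the fundamental pair
    pair = coefs[:, 1:3]
    m = pair.mean(axis=0)
    S = np.cov(pair, rowvar=False, ddof=1)
    det = float(np.linalg.det(S))
    scale = max(float(np.trace(S)), float(m @ m), 1e-30)
    if det <= 1e-14 * scale**2:
        p_zero = 0.0 if np.hypot(*m) > 1e-8 * max(1.0, np.sqrt(scale)) else 1.0
    else:
        t2 = float(k * m @ np.linalg.inv(S) @ m)
        p_zero = float(scipy.stats.f.sf((k - 2) / (2.0 * (k - 1)) * t2, 2, k - 2))
    proto = next(iter(fits.values()))
    mean_fit = core.CosinorFit(
        spec=spec,
        coefficients=mean_coef,
        cov=np.full((spec.n_params, spec.n_params), np.nan),
        ssr=np.nan,
        dof=proto.dof,
        n_obs=proto.n_obs,
        t=proto.t,
        y=proto.y,
    )
    params = core.rhythm_params(mean_fit)
    return PopulationMultiFit(
        individual_fits=fits,
        mean_coefficients=mean_coef,
        spec=spec,
        params=params,
        coefficient_tests=tests,
        p_zero_amplitude=p_zero,
    )
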