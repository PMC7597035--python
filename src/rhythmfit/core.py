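"""Multi-component cosinor regression and model selection.

A cosinor model with known period P and N harmonic components is linear in
its coefficients once each harmonic is expanded into a sine/cosine pair:

    y(t) = M + sum_{i=1}^{N} ( A_{i,1} sin(2*pi*i*t/P) + A_{i,2} cos(2*pi*i*t/P) ) + e(t)

Gaussian responses are fitted by ordinary least squares; count responses
(Poisson, generalized Poisson GP-1, negative binomial NB2) by maximum
likelihood with a log link on the same trigonometric design.  Rhythm
parameters of multi-component fits (amplitude, acrophase, peaks) are read
off the fitted curve on a dense grid, because no closed form exists beyond
one component.

Model selection across component counts uses the extra sum-of-squares
F-statistic

    F = ((SSR_1 - SSR_2)/SSR_2) / ((DoF_1 - DoF_2)/DoF_2)

comparing a simpler model (1) against a nested, more complex one (2); the
richer model is kept while the associated p-value stays below a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import (
    GeneralizedPoisson,
    NegativeBinomialP,
    Poisson,
)
from statsmodels.stats.multitest import multipletests

from .errors import FittingError, ResolutionError, ValidationError
from .io import MeasurementSet

__all__ = [
    "CosinorModelSpec",
    "CosinorFit",
    "RhythmParams",
    "TestResult",
    "build_design",
    "fit_model",
    "rhythm_params",
    "overall_significance",
    "lack_of_fit",
    "extra_ssr_test",
    "select_best_model",
    "estimate_period",
    "adjust_fdr",
    "analyze_all",
]

GAUSSIAN = "gaussian"
COUNT_FAMILIES = ("poisson", "generalized_poisson", "negative_binomial")


@dataclass(frozen=True)
class CosinorModelSpec:
    """One candidate cosinor model: period, harmonic count, response family."""

    period_hours: float = 24.0
    n_components: int = 1
    family: str = GAUSSIAN
    link: str | None = None

    def __post_init__(self):
        if not (self.period_hours > 0 and np.isfinite(self.period_hours)):
            raise ValidationError("period_hours must be a finite positive number")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if self.family not in (GAUSSIAN,) + COUNT_FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        # gaussian responses use the identity link, count families the log link
        expected = "identity" if self.family == GAUSSIAN else "log"
        if self.link is None:
            object.__setattr__(self, "link", expected)
        elif self.link != expected:
            raise ValidationError(
                f"family {self.family!r} requires the {expected!r} link"
            )

    @property
    def n_params(self) -> int:
        return 2 * self.n_components + 1


def build_design(times, spec: CosinorModelSpec) -> np.ndarray:
    """Trigonometric design matrix: intercept, then (sin_i, cos_i) per harmonic.

    Harmonic i has period ``P/i``.  Raises when there are too few
    observations to leave at least one residual degree of freedom.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValidationError("times must be one-dimensional")
    n_min = spec.n_params + 1
    if t.size < n_min:
        raise FittingError(
            f"{spec.n_components}-component fit needs >= {n_min} observations, got {t.size}"
        )
    cols = [np.ones_like(t)]
    for i in range(1, spec.n_components + 1):
        theta = 2 * np.pi * i * t / spec.period_hours
        cols.append(np.sin(theta))
        cols.append(np.cos(theta))
    return np.column_stack(cols)


@dataclass
class CosinorFit:
    """A fitted cosinor model for one group of measurements.

    ``coefficients`` are ordered ``[M, A_{1,1}, A_{1,2}, ..., A_{N,1}, A_{N,2}]``
    (intercept first, then the sine/cosine pair of each harmonic).
    """

    spec: CosinorModelSpec
    coefficients: np.ndarray
    cov: np.ndarray
    ssr: float
    dof: int
    n_obs: int
    t: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    p_overall: float = np.nan
    f_overall: float = np.nan
    df_overall: tuple = ()
    llf: float = np.nan
    perfect_fit: bool = False
    selection_trace: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, times) -> np.ndarray:
        """Noiseless fitted curve (mean response) at the given times."""
        t = np.asarray(times, dtype=float)
        cols = [np.ones_like(t)]
        for i in range(1, self.spec.n_components + 1):
            theta = 2 * np.pi * i * t / self.spec.period_hours
            cols.append(np.sin(theta))
            cols.append(np.cos(theta))
        eta = np.column_stack(cols) @ self.coefficients[: self.spec.n_params]
        if self.spec.link == "log":
            return np.exp(eta)
        return eta

    @property
    def mesor(self) -> float:
        """Intercept coefficient M (rhythm-adjusted mean for one component)."""
        return float(self.coefficients[0])

    def component_pair(self, i: int) -> tuple[float, float]:
        """(sine, cosine) coefficient pair of harmonic ``i`` (1-based)."""
        return float(self.coefficients[2 * i - 1]), float(self.coefficients[2 * i])


def _validate_group(t, y):
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if t.size != y.size:
        raise ValidationError("times and values must have the same length")
    if t.size == 0:
        raise ValidationError("empty group")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValidationError("times and values must be finite")
    return t, y


def fit_model(t, y, spec: CosinorModelSpec) -> CosinorFit:
    """Fit one cosinor model to a group of measurements.

    Gaussian family: OLS estimates minimising the SSR, with the overall
    regression F-test as model significance.  Count families: maximum
    likelihood with a log link; model significance from the likelihood-ratio
    test against the intercept-only model.
    """
    t, y = _validate_group(t, y)
    X = build_design(t, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FittingError(
            "rank-deficient design (too few distinct time points for "
            f"{spec.n_components} component(s))"
        )
    n = t.size
    dof = n - spec.n_params
    if spec.family == GAUSSIAN:
        res = sm.OLS(y, X).fit()
        ssr = float(res.ssr)
        tss = float(np.sum((y - y.mean()) ** 2))
        mss = max(tss - ssr, 0.0)
        perfect = ssr <= max(tss, 1.0) * 1e-12
        if perfect:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = (mss / (2 * spec.n_components)) / (ssr / dof)
            p = float(scipy.stats.f.sf(f_stat, 2 * spec.n_components, dof))
        return CosinorFit(
            spec=spec,
            coefficients=np.asarray(res.params, float),
            cov=np.asarray(res.cov_params(), float),
            ssr=ssr,
            dof=dof,
            n_obs=n,
            t=t,
            y=y,
            p_overall=p,
            f_overall=float(f_stat),
            df_overall=(2 * spec.n_components, dof),
            llf=float(res.llf),
            perfect_fit=perfect,
        )
    # count families: require non-negative integer responses
    if np.any(y < 0) or np.any(np.abs(y - np.round(y)) > 1e-9):
        raise ValidationError(
            f"family {spec.family!r} requires non-negative integer counts"
        )
    model_cls = {
        "poisson": Poisson,
        "generalized_poisson": GeneralizedPoisson,
        "negative_binomial": NegativeBinomialP,
    }[spec.family]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model_cls(y, X).fit(disp=0, maxiter=200)
        null = model_cls(y, np.ones((n, 1))).fit(disp=0, maxiter=200)
    lr = max(2.0 * (res.llf - null.llf), 0.0)
    df_lr = 2 * spec.n_components
    p = float(scipy.stats.chi2.sf(lr, df_lr))
    mu = np.exp(X @ np.asarray(res.params[: spec.n_params], float))
    return CosinorFit(
        spec=spec,
        coefficients=np.asarray(res.params, float),
        cov=np.asarray(res.cov_params(), float),
        ssr=float(np.sum((y - mu) ** 2)),
        dof=n - len(res.params),
        n_obs=n,
        t=t,
        y=y,
        p_overall=p,
        f_overall=lr,
        df_overall=(df_lr,),
        llf=float(res.llf),
    )


@dataclass
class RhythmParams:
    """Rhythm parameters read off a fitted curve over one period.

    ``mesor`` is the curve midline (max+min)/2, which coincides with the
    intercept for a single component but not for asymmetric multi-component
    curves; the intercept is reported separately as ``mesor_intercept``.
    ``acrophase_rad`` lies in (-2*pi, 0]; the corresponding peak time in
    hours is ``-acrophase_rad * P / (2*pi)``.
    """

    mesor: float
    mesor_intercept: float
    amplitude: float
    acrophase_rad: float
    peak_times_hours: list[float]
    trough_times_hours: list[float]
    period_hours: float

    @property
    def peak_time_hours(self) -> float:
        return -self.acrophase_rad * self.period_hours / (2 * np.pi)


def rhythm_params(fit: CosinorFit, grid_step_hours: float | None = None) -> RhythmParams:
    """Evaluate rhythm parameters from the fitted curve on a dense grid.

    The default grid step P/1000 keeps the phase quantisation error below
    0.36 degrees; steps of P/4 or coarser are rejected.
    """
    P = fit.spec.period_hours
    if grid_step_hours is None:
        grid_step_hours = P / 1000.0
    if grid_step_hours >= P / 4:
        raise ResolutionError("grid_step_hours must be finer than a quarter period")
    n = int(np.ceil(P / grid_step_hours))
    grid = np.arange(n) * (P / n)  # one period, endpoint excluded (periodic)
    curve = fit.predict(grid)
    hi, lo = float(curve.max()), float(curve.min())
    i_max = int(np.argmax(curve))
    acrophase = -2 * np.pi * grid[i_max] / P  # in (-2*pi, 0]
    prev, nxt = np.roll(curve, 1), np.roll(curve, -1)
    peaks = grid[(curve >= prev) & (curve > nxt)]
    troughs = grid[(curve <= prev) & (curve < nxt)]
    if peaks.size == 0:  # flat curve
        peaks, troughs = grid[:1], grid[:1]
    return RhythmParams(
        mesor=(hi + lo) / 2.0,
        mesor_intercept=fit.mesor,
        amplitude=(hi - lo) / 2.0,
        acrophase_rad=float(acrophase),
        peak_times_hours=[float(v) for v in peaks],
        trough_times_hours=[float(v) for v in troughs],
        period_hours=P,
    )


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    df: tuple
    p_value: float
    label: str
    note: str | None = None

    @property
    def applicable(self) -> bool:
        return not np.isnan(self.p_value)


def overall_significance(fit: CosinorFit) -> TestResult:
    """Model-significance test of the fitted cosinor.

    Gaussian: overall regression F-test, F = (model SS / 2N)/(SSR / DoF).
    Count families: likelihood-ratio chi-square against intercept-only.
    """
    if fit.dof < 1:
        raise ValidationError("model significance needs >= 1 residual df")
    note = "perfect fit (SSR = 0)" if fit.perfect_fit else None
    label = (
        "overall F-test" if fit.spec.family == GAUSSIAN else "likelihood-ratio test"
    )
    return TestResult(fit.f_overall, fit.df_overall, fit.p_overall, label, note)


def lack_of_fit(fit: CosinorFit, t=None, y=None) -> TestResult:
    """Goodness-of-fit F-test against pure replicate error.

    Splits the SSR into pure error (within replicated time points) and lack
    of fit; F = (SS_lof/(c-p)) / (SS_pure/(n-c)) with c distinct time points
    and p model parameters.  Requires replicated time points and c > p.
    """
    t = fit.t if t is None else np.asarray(t, float)
    y = fit.y if y is None else np.asarray(y, float)
    n = t.size
    uniq, inv = np.unique(t, return_inverse=True)
    c = uniq.size
    p = fit.spec.n_params
    if c == n:
        raise ValidationError(
            "goodness-of-fit test requires replicates (no time point is repeated)"
        )
    if c <= p:
        raise ValidationError(
            f"goodness-of-fit test needs more distinct time points ({c}) than model "
            f"parameters ({p})"
        )
    means = np.bincount(inv, weights=y) / np.bincount(inv)
    ss_pure = float(np.sum((y - means[inv]) ** 2))
    resid = y - fit.predict(t)
    ssr = float(np.sum(resid**2))
    ss_lof = max(ssr - ss_pure, 0.0)
    if ss_pure <= 1e-12 * max(ssr, 1.0):
        if ss_lof <= 1e-10:
            return TestResult(
                np.nan, (c - p, n - c), np.nan, "lack-of-fit F-test",
                note="not applicable: zero pure error and perfect fit",
            )
        return TestResult(
            np.inf, (c - p, n - c), 0.0, "lack-of-fit F-test",
            note="zero pure error with non-zero lack of fit",
        )
    f_stat = (ss_lof / (c - p)) / (ss_pure / (n - c))
    p_val = float(scipy.stats.f.sf(f_stat, c - p, n - c))
    return TestResult(float(f_stat), (c - p, n - c), p_val, "lack-of-fit F-test")


def extra_ssr_test(simple: CosinorFit, complex: CosinorFit) -> TestResult:
    """Extra sum-of-squares F-test between two nested cosinor fits.

    F = ((SSR_1 - SSR_2)/SSR_2) / ((DoF_1 - DoF_2)/DoF_2) with the simpler
    model as 1 and the richer as 2; p from F(DoF_1 - DoF_2, DoF_2).
    """
    s, x = simple, complex
    if s.n_obs != x.n_obs or not np.array_equal(s.t, x.t) or not np.array_equal(s.y, x.y):
        raise ValidationError("extra-SSR test requires both fits on the same data")
    if s.spec.period_hours != x.spec.period_hours or s.spec.family != x.spec.family:
        raise ValidationError("extra-SSR test requires the same period and family")
    if s.spec.n_components >= x.spec.n_components:
        raise ValidationError("models are not nested (simple must have fewer components)")
    if s.dof <= x.dof:
        raise ValidationError("simple model must have more residual df")
    if x.ssr <= 1e-12 * max(s.ssr, 1.0):
        return TestResult(
            np.inf, (s.dof - x.dof, x.dof), 0.0, "extra-SSR F-test",
            note="richer model fits perfectly (SSR_2 = 0)",
        )
    f_stat = max(((s.ssr - x.ssr) / x.ssr) / ((s.dof - x.dof) / x.dof), 0.0)
    p = float(scipy.stats.f.sf(f_stat, s.dof - x.dof, x.dof))
    return TestResult(float(f_stat), (s.dof - x.dof, x.dof), p, "extra-SSR F-test")


def select_best_model(
    t,
    y,
    periods,
    max_components: int = 3,
    alpha: float = 0.05,
    family: str = GAUSSIAN,
) -> CosinorFit:
    """Stepwise component selection per period, then best period by SSR.

    For each candidate period the component count grows from 1, keeping the
    richer model only while the extra-SSR test (adjacent counts) rejects at
    ``alpha``.  Among per-period winners the smallest SSR wins; near-ties
    (relative 1e-9) prefer fewer components, then the shorter period.  The
    full selection trace is attached as ``fit.selection_trace``.
    """
    periods = [float(p) for p in np.atleast_1d(periods)]
    if not periods:
        raise ValidationError("periods must be non-empty")
    if max_components < 1:
        raise ValidationError("max_components must be >= 1")
    winners, trace_rows, failures = [], [], []
    for P in periods:
        try:
            current = fit_model(t, y, CosinorModelSpec(P, 1, family))
            trace_rows.append((P, 1, np.nan, current.ssr, True))
        except Exception as exc:  # pragma: no cover - per-candidate isolation
            failures.append(f"period {P}: {exc}")
            continue
        for N in range(2, max_components + 1):
            try:
                richer = fit_model(t, y, CosinorModelSpec(P, N, family))
                test = extra_ssr_test(current, richer)
            except Exception as exc:
                failures.append(f"period {P}, {N} components: {exc}")
                break
            accept = test.p_value < alpha
            trace_rows.append((P, N, test.p_value, richer.ssr, accept))
            if not accept:
                break
            current = richer
        winners.append(current)
    if not winners:
        raise FittingError("all candidate fits failed: " + "; ".join(failures))
    ssr_min = min(w.ssr for w in winners)
    tol = 1e-9 * max(ssr_min, 1e-30)
    tied = [w for w in winners if w.ssr <= ssr_min + tol]
    best = min(tied, key=lambda w: (w.spec.n_components, w.spec.period_hours))
    best.selection_trace = pd.DataFrame(
        trace_rows, columns=["period", "n_components", "p_extra_ssr", "ssr", "accepted"]
    )
    return best


def estimate_period(t, y, period_range=(18.0, 30.0), n_grid: int = 25):
    """Rank candidate periods by Lomb-Scargle spectral power.

    ``period_range`` is either ``(low, high)``, scanned on an ``n_grid``-point
    linear grid, or an explicit sequence of candidate periods.  Returns a
    list of (period_hours, normalized power) sorted by descending power.
    Works with replicated (duplicate) time points.
    """
    t, y = _validate_group(t, y)
    period_range = np.asarray(period_range, dtype=float)
    if period_range.size < 2:
        raise ValidationError("period_range needs at least two values")
    if np.any(period_range <= 0):
        raise ValidationError("candidate periods must be positive")
    if period_range.size == 2:
        low, high = float(period_range[0]), float(period_range[1])
    else:
        low, high = float(period_range.min()), float(period_range.max())
    if not (0 < low < high):
        raise ValidationError("period_range must satisfy 0 < low < high")
    if t.size < 8:
        raise ValidationError("period estimation needs >= 8 observations")
    if t.max() - t.min() < low:
        raise ValidationError("time span must cover at least one candidate period")
    if period_range.size > 2:
        periods = np.sort(period_range)
    else:
        periods = np.linspace(low, high, int(n_grid))
    ang_freqs = 2 * np.pi / periods
    power = scipy.signal.lombscargle(t, y - y.mean(), ang_freqs, normalize=True)
    order = np.argsort(power)[::-1]
    return [(float(periods[i]), float(power[i])) for i in order]


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, each q >= p)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def analyze_all(
    mset: MeasurementSet,
    periods=(24.0,),
    max_components: int = 3,
    alpha: float = 0.05,
    family: str = GAUSSIAN,
) -> pd.DataFrame:
    """Batch driver: select and fit a model per group, BH-adjust across groups.

    Per-group failures are recorded in the row's ``error`` column and do not
    abort the remaining groups.
    """
    rows = []
    for label in mset.groups:
        t, y, _ = mset.group_arrays(label)
        row = {"test": label, "n_obs": t.size}
        try:
            fit = select_best_model(t, y, periods, max_components, alpha, family)
            params = rhythm_params(fit)
            row.update(
                period=fit.spec.period_hours,
                n_components=fit.spec.n_components,
                mesor=params.mesor,
                mesor_intercept=params.mesor_intercept,
                amplitude=params.amplitude,
                acrophase_rad=params.acrophase_rad,
                peak_time_hours=params.peak_time_hours,
                ssr=fit.ssr,
                p=fit.p_overall,
                error="",
            )
        except Exception as exc:
            row.update(error=str(exc), p=np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = adjust_fdr(table.loc[ok, "p"].to_numpy())
    return table
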