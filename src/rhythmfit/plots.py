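"""Figures for cosinor fits, group comparisons and acrophase polar plots.

Every plot function writes the figure (PNG/SVG/PDF by suffix) and returns a
metadata dict of the exact numbers drawn (curve endpoints, p-values, polar
ray angles).  For PNG and SVG the same dict is embedded as JSON under the
``rhythmfit`` metadata key, so figures can be audited against result tables
without pixel comparison.

Polar convention: angle 0 (time 0) at the top, time increasing clockwise;
an acrophase phi is drawn at the peak time -phi*P/(2*pi) hours.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ValidationError

__all__ = ["plot_fit", "plot_comparison", "plot_population", "save_figure"]


def save_figure(fig, path, metadata: dict) -> Path:
    """Write a figure, embedding ``metadata`` as JSON where the format allows."""
    path = Path(path)
    payload = json.dumps(metadata, default=float)
    kwargs = {}
    if path.suffix.lower() in (".png", ".svg"):
        kwargs["metadata"] = (
            {"rhythmfit": payload}
            if path.suffix.lower() == ".png"
            else {"Description": payload}
        )
    fig.savefig(path, dpi=150, **kwargs)
    plt.close(fig)
    return path


def _curve_grid(fits_period: float, t_max: float) -> np.ndarray:
    span = max(2 * fits_period, t_max)  # show at least two periods
    return np.linspace(0, span, 400)


def plot_fit(fit, t, y, path, title: str | None = None):
    """Scatter of raw points with the fitted cosinor curve over >= 2 periods.

    ``fit`` may be any object with ``predict`` and a ``spec``/``period_hours``
    attribute (CosinorFit, SingleCosinorFit).  Returns (path, metadata).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size == 0:
        raise ValidationError("cannot plot a fit with zero data points")
    period = getattr(getattr(fit, "spec", fit), "period_hours")
    grid = _curve_grid(period, float(t.max()))
    curve = fit.predict(grid)
    p_overall = getattr(fit, "p_overall", None)
    if p_overall is None and hasattr(fit, "core_fit"):
        p_overall = fit.core_fit.p_overall
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t, y, "o", ms=4, alpha=0.6, label="data")
    ax.plot(grid, curve, "-", color="crimson", label="cosinor fit")
    if p_overall is not None:
        ax.annotate(f"p = {p_overall:.3g}", xy=(0.02, 0.95), xycoords="axes fraction")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    meta = {
        "kind": "fit",
        "period_hours": float(period),
        "p_overall": None if p_overall is None else float(p_overall),
        "curve_first": float(curve[0]),
        "curve_last": float(curve[-1]),
        "n_points": int(t.size),
    }
    return save_figure(fig, path, meta), meta


def plot_population(pop, t, y, individuals, path, title: str | None = None):
    """Individual cosinor curves (black) with the population-mean curve (red)."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size == 0:
        raise ValidationError("cannot plot a population fit with zero data points")
    grid = _curve_grid(pop.period_hours, float(t.max()))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t, y, "o", ms=3, alpha=0.4, color="grey")
    for fit in pop.individual_fits.values():
        ax.plot(grid, fit.predict(grid), "-", color="black", lw=0.8, alpha=0.7)
    mean_curve = pop.predict(grid)
    ax.plot(grid, mean_curve, "-", color="red", lw=2, label="population mean")
    ax.annotate(f"p = {pop.p_zero_amplitude:.3g}", xy=(0.02, 0.95),
                xycoords="axes fraction")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    meta = {
        "kind": "population",
        "period_hours": float(pop.period_hours),
        "p_zero_amplitude": float(pop.p_zero_amplitude),
        "population_acrophase_rad": float(pop.acrophase_rad),
        "mean_curve_first": float(mean_curve[0]),
        "k_individuals": int(pop.k),
    }
    return save_figure(fig, path, meta), meta


def plot_comparison(result, pair, period_hours: float, path):
    """Two-panel comparison: data + fitted curves above, acrophase polar below.

    The polar panel draws one ray per group at its acrophase (angle 0 = time
    0 at the top, clockwise time) and, when standard errors are available,
    a +/- 1.96 SE arc around the group-b ray shift.
    """
    fig = plt.figure(figsize=(6, 8))
    ax = fig.add_subplot(2, 1, 1)
    omega = 2 * np.pi / period_hours
    grid = _curve_grid(period_hours, float(max(pair.t_a.max(), pair.t_b.max())))
    curves = {}
    for label, params, (t, y), color in (
        (pair.label_a, result.params_a, (pair.t_a, pair.y_a), "tab:blue"),
        (pair.label_b, result.params_b, (pair.t_b, pair.y_b), "tab:orange"),
    ):
        curve = params["mesor"] + params["amplitude"] * np.cos(
            omega * grid + params["acrophase_rad"]
        )
        curves[label] = curve
        ax.plot(t, y, "o", ms=3, alpha=0.4, color=color)
        ax.plot(grid, curve, "-", color=color, label=label)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("value")
    ax.legend(fontsize=8)
    ax.set_title(
        f"q(amplitude) = {_fmt_q(result.q_amplitude, result.p_amplitude)}, "
        f"q(acrophase) = {_fmt_q(result.q_acrophase, result.p_acrophase)}",
        fontsize=9,
    )
    axp = fig.add_subplot(2, 1, 2, projection="polar")
    axp.set_theta_zero_location("N")
    axp.set_theta_direction(-1)  # clockwise time
    angles = {}
    for label, params, color in (
        (pair.label_a, result.params_a, "tab:blue"),
        (pair.label_b, result.params_b, "tab:orange"),
    ):
        # acrophase phi -> peak time -phi*P/(2*pi) -> clockwise angle
        angle = -params["acrophase_rad"]
        angles[label] = float(angle)
        axp.plot([angle, angle], [0, 1], color=color, lw=2, label=label)
    se_phi = result.se.get("acrophase")
    if se_phi and np.isfinite(se_phi):
        center = -result.params_b["acrophase_rad"]
        arc = np.linspace(center - 1.96 * se_phi, center + 1.96 * se_phi, 50)
        axp.plot(arc, np.full_like(arc, 0.95), color="tab:orange", lw=1, alpha=0.7)
    axp.set_xticks(np.linspace(0, 2 * np.pi, 8, endpoint=False))
    axp.set_xticklabels([f"{h:g}h" for h in np.arange(0, period_hours, period_hours / 8)])
    axp.set_yticks([])
    axp.legend(fontsize=7, loc="lower left")
    meta = {
        "kind": "comparison",
        "labels": list(result.labels),
        "polar_angles_rad": angles,
        "acrophase_a": float(result.params_a["acrophase_rad"]),
        "acrophase_b": float(result.params_b["acrophase_rad"]),
        "d_amplitude": float(result.d_amplitude),
        "d_acrophase": float(result.d_acrophase),
        "p_amplitude": float(result.p_amplitude),
        "p_acrophase": float(result.p_acrophase),
        "curve_a_first": float(curves[pair.label_a][0]),
        "curve_b_first": float(curves[pair.label_b][0]),
    }
    return save_figure(fig, path, meta), meta


def _fmt_q(q, p):
    v = q if np.isfinite(q) else p
    if not np.isfinite(v):
        return "n/a"
    return "< 1e-6" if v < 1e-6 else f"{v:.3g}"
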