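"""Model-fit diagnostics: Cox–Snell residuals and trace export.

If the model is correctly specified, the Cox–Snell residuals
``r_i = exp(eta_i) * Lambda0(t_i)`` behave like a censored sample from the
unit exponential, so the Nelson–Aalen cumulative hazard of the residuals
plotted against the residuals should be a straight line of slope one
through the origin.  The slope of a zero-intercept least-squares fit to the
Nelson–Aalen points is reported as a quantitative surrogate for that visual
check.

Residuals are computed at the posterior mean of the unconstrained
parameters (a single plug-in state), which is standard for Cox–Snell
displays; a per-draw variant is available for research use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .likelihood import ParameterState, baseline_cumhaz, linear_predictor
from .mcmc import PosteriorSamples

__all__ = [
    "ResidualSet",
    "cox_snell",
    "cox_snell_per_draw",
    "residual_hazard_curve",
    "export_traces",
    "plot_residuals",
]


@dataclass
class ResidualSet:
    """Cox–Snell residuals with their censoring indicators."""

    residuals: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        self.status = np.asarray(self.status, dtype=float)
        if self.residuals.shape != self.status.shape:
            raise ValueError("residuals and status must have equal length")
        if np.any(self.residuals < 0):
            raise ValueError("Cox–Snell residuals must be nonnegative")


def cox_snell(cohort: Cohort, state: ParameterState) -> ResidualSet:
    """Plug-in Cox–Snell residuals r_i = exp(eta_i) * Lambda0(t_i)."""
    eta = linear_predictor(cohort, state)
    r = np.exp(eta) * baseline_cumhaz(state.baseline, cohort.time)
    return ResidualSet(residuals=r, status=cohort.status)


def cox_snell_per_draw(cohort: Cohort, samples: PosteriorSamples) -> np.ndarray:
    """Residual matrix (draws x records), one residual set per retained draw."""
    out = np.empty((samples.n_keep, cohort.n))
    for m in range(samples.n_keep):
        out[m] = cox_snell(cohort, samples.state_at(m)).residuals
    return out


def residual_hazard_curve(res: ResidualSet) -> tuple[np.ndarray, np.ndarray, float]:
    """Nelson–Aalen cumulative hazard of the residuals and its origin slope.

    Returns ``(r_event, H, slope)``: the ordered event residuals, the
    Nelson–Aalen estimate at each, and the zero-intercept least-squares
    slope of H against r (slope ≈ 1 indicates unit-exponential residuals,
    i.e. an adequate model).
    """
    n_events = int(res.status.sum())
    if n_events < 2:
        raise ValueError("need at least two events for the residual hazard curve")
    order = np.argsort(res.residuals, kind="stable")
    r_sorted = res.residuals[order]
    d_sorted = res.status[order]
    n = r_sorted.size
    at_risk = n - np.arange(n)
    increments = d_sorted / at_risk
    H_all = np.cumsum(increments)
    ev = d_sorted == 1
    r_event, H = r_sorted[ev], H_all[ev]
    denom = float(np.sum(r_event**2))
    slope = float(np.sum(r_event * H) / denom) if denom > 0 else float("nan")
    return r_event, H, slope


def export_traces(samples: PosteriorSamples, out_dir, plot: bool = True) -> Path:
    """Write per-parameter trace series (CSV) and a trace-plot figure.

    The CSV has one column per monitored parameter (baseline parameters on
    the natural scale, each coefficient under its covariate name, each
    frailty as ``w_<block>``, and sigma) and one row per retained draw.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = samples.to_frame()
    csv_path = out_dir / f"traces_{samples.family}.csv"
    frame.to_csv(csv_path, index=False)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ncol = 3
        nrow = int(np.ceil(len(frame.columns) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.0 * nrow))
        for ax, name in zip(np.ravel(axes), frame.columns):
            ax.plot(frame[name].to_numpy(), lw=0.5)
            ax.set_title(name, fontsize=8)
        for ax in np.ravel(axes)[len(frame.columns):]:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(out_dir / f"traces_{samples.family}.png", dpi=100)
        plt.close(fig)
    return csv_path


def plot_residuals(res: ResidualSet, path) -> float:
    """Cox–Snell residual plot (Nelson–Aalen vs residual, unit reference line)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r_event, H, slope = residual_hazard_curve(res)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.step(r_event, H, where="post", label="Nelson–Aalen of residuals")
    lim = float(max(r_event.max(), H.max()))
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="slope 1")
    ax.set_xlabel("Cox–Snell residual")
    ax.set_ylabel("cumulative hazard")
    ax.legend(fontsize=8)
    ax.set_title(f"slope = {slope:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return slope
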