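"""ThT aggregation-kinetics processing and half-time estimation.

Plate-reader Thioflavin T time courses are blank-subtracted, gated on a
2:1 signal-to-background ratio, normalized per condition to the maximum
mean amplitude, and fitted per replicate with a four-parameter Boltzmann
sigmoid

    y(t) = baseline + amplitude / (1 + exp((t_half - t) / tau_slope))

whose midpoint ``t_half`` (hours) is the aggregation half-time.  95%
confidence intervals on ``t_half`` come from the asymptotic parameter
covariance with a t-distribution on n - 4 degrees of freedom, or from a
seeded residual bootstrap.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ThTTrace",
    "SigmoidFit",
    "ConditionSummary",
    "boltzmann",
    "subtract_blank",
    "passes_signal_gate",
    "normalize_max",
    "fit_sigmoid",
    "summarize_condition",
    "read_plate_csv",
    "write_fits_tsv",
]


@dataclass
class ThTTrace:
    """A fluorescence time course from one well.

    Times are in hours on a strictly increasing grid (nominal spacing
    5 min); fluorescence in arbitrary units.
    """

    times: np.ndarray
    fluorescence: np.ndarray
    condition: str = ""
    replicate: str = ""
    is_blank: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class SigmoidFit:
    """Result of a Boltzmann-sigmoid fit to one blank-subtracted trace."""

    t_half: float = np.nan
    tau_slope: float = np.nan
    baseline: float = np.nan
    amplitude: float = np.nan
    ci95_t_half: tuple[float, float] = (np.nan, np.nan)
    converged: bool = False
    gate_passed: bool = True
    condition: str = ""
    replicate: str = ""
    message: str = ""


@dataclass
class ConditionSummary:
    condition: str
    n_replicates: int
    mean_t_half: float
    sd_t_half: float | None
    ci95: tuple[float, float] | None
    mean_curve_times: np.ndarray | None = None
    mean_curve: np.ndarray | None = None
    sd_curve: np.ndarray | None = None


def boltzmann(t, baseline, amplitude, t_half, tau_slope):
    """Four-parameter Boltzmann sigmoid."""
    return baseline + amplitude / (1.0 + np.exp((t_half - t) / tau_slope))


def _blank_mean_on_grid(blanks: Sequence[ThTTrace], times: np.ndarray) -> np.ndarray:
    if not blanks:
        raise ValueError("no blank traces supplied")
    stack = []
    for b in blanks:
        if b.times.shape == times.shape and np.allclose(b.times, times):
            stack.append(b.fluorescence)
        else:
            stack.append(np.interp(times, b.times, b.fluorescence))
    return np.mean(stack, axis=0)


def subtract_blank(trace: ThTTrace, blanks: Sequence[ThTTrace]) -> ThTTrace:
    """Subtract the pointwise mean blank signal (linear interpolation if the
    blank grid differs).  Negative values are retained."""
    blank_mean = _blank_mean_on_grid(blanks, trace.times)
    return replace(trace, fluorescence=trace.fluorescence - blank_mean)


def passes_signal_gate(
    trace: ThTTrace, blanks: Sequence[ThTTrace], ratio: float = 2.0
) -> bool:
    """True iff the raw trace maximum exceeds ``ratio`` times the mean blank
    background.  Conditions failing the gate show no detectable ThT signal
    change and are excluded from fitting."""
    blank_mean = _blank_mean_on_grid(blanks, trace.times)
    background = float(np.mean(blank_mean))
    if background <= 0:
        raise ValueError("invalid background: blank mean must be positive")
    return float(np.max(trace.fluorescence)) / background > ratio


def normalize_max(traces: Sequence[ThTTrace]) -> list[ThTTrace]:
    """Normalize to the per-condition maximum of the mean replicate curve.

    Each condition is scaled independently so that the maximum of its mean
    curve across replicates equals 1.
    """
    by_condition: dict[str, list[ThTTrace]] = {}
    for tr in traces:
        by_condition.setdefault(tr.condition, []).append(tr)
    out: list[ThTTrace] = []
    for cond, group in by_condition.items():
        grid = group[0].times
        curves = [
            tr.fluorescence
            if tr.times.shape == grid.shape and np.allclose(tr.times, grid)
            else np.interp(grid, tr.times, tr.fluorescence)
            for tr in group
        ]
        peak = float(np.max(np.mean(curves, axis=0)))
        if peak <= 0:
            raise ValueError(f"non-positive maximum for condition {cond!r}")
        out.extend(replace(tr, fluorescence=tr.fluorescence / peak) for tr in group)
    return out


def _initial_guess(times: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    baseline = float(np.min(y))
    amplitude = float(np.max(y) - np.min(y))
    # median-smooth to find the half-max crossing robustly
    k = 5
    if y.size >= k:
        pad = k // 2
        smoothed = np.array(
            [np.median(y[max(0, i - pad): i + pad + 1]) for i in range(y.size)]
        )
    else:
        smoothed = y
    half_level = baseline + 0.5 * amplitude
    above = np.nonzero(smoothed >= half_level)[0]
    t_half = float(times[above[0]]) if above.size else float(np.median(times))
    tau = 0.1 * float(times[-1] - times[0])
    return baseline, amplitude, t_half, tau


def fit_sigmoid(
    trace: ThTTrace,
    ci: Literal["asymptotic", "bootstrap"] = "asymptotic",
    bootstrap_b: int = 1000,
    seed: int | None = None,
) -> SigmoidFit:
    """Least-squares Boltzmann fit of one trace with a 95% CI on t_half.

    Non-convergence (including flat traces with no transition) returns a
    fit with ``converged=False`` and a diagnostic message rather than
    raising.
    """
    t, y = trace.times, trace.fluorescence
    if t.size < 10:
        return SigmoidFit(
            converged=False, condition=trace.condition, replicate=trace.replicate,
            message="fewer than 10 points",
        )
    p0 = _initial_guess(t, y)
    span = float(t[-1] - t[0])
    bounds = (
        [-np.inf, 1e-12, t[0] - span, 1e-6],
        [np.inf, np.inf, t[-1] + span, 10 * span],
    )
    try:
        popt, pcov = optimize.curve_fit(
            boltzmann, t, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        return SigmoidFit(
            converged=False, condition=trace.condition, replicate=trace.replicate,
            message=f"optimizer failure: {exc}",
        )
    baseline, amplitude, t_half, tau = (float(v) for v in popt)
    resid = y - boltzmann(t, *popt)
    # a fit is only meaningful when the transition lies inside the observed
    # window and the amplitude is resolved above the residual noise
    noise = float(np.std(resid))
    if not (t[0] <= t_half <= t[-1]) or amplitude < 3 * noise:
        return SigmoidFit(
            t_half=t_half, tau_slope=tau, baseline=baseline, amplitude=amplitude,
            converged=False, condition=trace.condition, replicate=trace.replicate,
            message="no resolvable transition in the observed window",
        )

    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        fitted = boltzmann(t, *popt)
        estimates = []
        for _ in range(bootstrap_b):
            y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
            try:
                popt_star, _ = optimize.curve_fit(
                    boltzmann, t, y_star, p0=popt, bounds=bounds, maxfev=5000
                )
                estimates.append(popt_star[2])
            except (RuntimeError, ValueError):
                continue
        if len(estimates) < max(10, bootstrap_b // 10):
            ci_low = ci_high = np.nan
        else:
            ci_low, ci_high = np.percentile(estimates, [2.5, 97.5])
    else:
        dof = max(t.size - 4, 1)
        se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
        tcrit = stats.t.ppf(0.975, dof)
        ci_low, ci_high = t_half - tcrit * se, t_half + tcrit * se

    return SigmoidFit(
        t_half=t_half,
        tau_slope=tau,
        baseline=baseline,
        amplitude=amplitude,
        ci95_t_half=(float(ci_low), float(ci_high)),
        converged=True,
        condition=trace.condition,
        replicate=trace.replicate,
    )


def summarize_condition(fits: Sequence[SigmoidFit]) -> ConditionSummary:
    """Aggregate replicate fits of one condition: mean t_half, replicate SD,
    and a pooled t-based 95% CI across replicates."""
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("zero converged fits")
    condition = good[0].condition
    vals = np.array([f.t_half for f in good])
    mean = float(np.mean(vals))
    if vals.size >= 2:
        sd = float(np.std(vals, ddof=1))
        half = stats.t.ppf(0.975, vals.size - 1) * sd / np.sqrt(vals.size)
        ci = (mean - half, mean + half)
    else:
        sd, ci = None, None
    return ConditionSummary(
        condition=condition, n_replicates=len(good), mean_t_half=mean,
        sd_t_half=sd, ci95=ci,
    )


# ---------------------------------------------------------------------------
# I/O

def read_plate_csv(path) -> list[ThTTrace]:
    """Read a long-format plate CSV with columns
    time_h, well, condition, replicate, fluorescence_au, is_blank."""
    df = pd.read_csv(path)
    required = {"time_h", "well", "condition", "replicate", "fluorescence_au", "is_blank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    traces = []
    for (well, cond, rep, blank), grp in df.groupby(
        ["well", "condition", "replicate", "is_blank"], sort=True
    ):
        grp = grp.sort_values("time_h")
        traces.append(
            ThTTrace(
                times=grp["time_h"].to_numpy(),
                fluorescence=grp["fluorescence_au"].to_numpy(),
                condition=str(cond),
                replicate=str(rep),
                is_blank=bool(blank),
            )
        )
    return traces


def write_plate_csv(traces: Sequence[ThTTrace], path) -> None:
    rows = []
    for i, tr in enumerate(traces):
        for t, y in zip(tr.times, tr.fluorescence):
            rows.append(
                {
                    "time_h": t,
                    "well": f"W{i:03d}",
                    "condition": tr.condition,
                    "replicate": tr.replicate,
                    "fluorescence_au": y,
                    "is_blank": int(tr.is_blank),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fits_tsv(fits: Sequence[SigmoidFit], path) -> None:
    rows = [
        {
            "condition": f.condition,
            "replicate": f.replicate,
            "t_half": f.t_half,
            "ci_low": f.ci95_t_half[0],
            "ci_high": f.ci95_t_half[1],
            "tau_slope": f.tau_slope,
            "baseline": f.baseline,
            "amplitude": f.amplitude,
            "converged": int(f.converged),
            "gate_passed": int(f.gate_passed),
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
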