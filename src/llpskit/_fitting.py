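"""Shared nonlinear least-squares machinery.

All model fits in this package go through :func:`multistart_curve_fit`, a thin
wrapper over :func:`scipy.optimize.curve_fit` that retries from a documented
set of perturbed starting points before giving up.  Tolerances are fixed at
1e-12 so that noiseless synthetic inputs are recovered to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class FitConvergenceError(RuntimeError):
    """Raised when a fit fails to converge from every starting point.

    Carries the best candidate parameters and their residuals so callers can
    inspect what the optimizer last saw.
    """

    def __init__(self, message: str, candidate=None, residuals=None):
        super().__init__(message)
        self.candidate = candidate
        self.residuals = residuals


@dataclass
class FitOutcome:
    params: np.ndarray
    residual_rms: float
    n_points: int
    n_starts_used: int
    warnings: list = field(default_factory=list)


def residual_rms(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(y) - np.asarray(yhat)) ** 2)))


def multistart_curve_fit(model, x, y, p0, bounds=(-np.inf, np.inf),
                         extra_starts=(), max_starts=3) -> FitOutcome:
    """Least-squares fit with documented multi-start fallback.

    Parameters
    ----------
    model : callable
        ``model(x, *params)``.
    p0 : sequence
        Primary starting point.
    extra_starts : sequence of sequences
        Alternative starting points tried in order if the primary start fails
        or converges poorly; at most ``max_starts`` total starts are used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    starts = [np.asarray(p0, dtype=float)]
    for s in extra_starts:
        if len(starts) >= max_starts:
            break
        starts.append(np.asarray(s, dtype=float))

    best = None
    last_err = None
    for i, start in enumerate(starts):
        try:
            lo, hi = bounds
            start_clipped = np.clip(start, lo, hi)
            popt, _ = curve_fit(
                model, x, y, p0=start_clipped, bounds=bounds,
                xtol=1e-12, ftol=1e-12, gtol=1e-12, maxfev=20000,
            )
        except (RuntimeError, ValueError) as err:  # non-convergence
            last_err = err
            continue
        rms = residual_rms(y, model(x, *popt))
        if best is None or rms < best.residual_rms:
            best = FitOutcome(params=popt, residual_rms=rms,
                              n_points=len(y), n_starts_used=i + 1)
        # A fit this good cannot be improved by restarting.
        if best.residual_rms <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
            break

    if best is None:
        raise FitConvergenceError(
            f"fit failed to converge after {len(starts)} starts: {last_err}",
            candidate=starts[-1],
            residuals=None,
        )
    return best
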