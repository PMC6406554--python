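"""Droplet-coalescence analysis from optical-tweezer force traces.

When two trapped condensate droplets are brought into contact they fuse and
relax toward a single sphere; the force on the moving trap relaxes as

    F(t) = a exp(-t / tau) + b t + c

where ``tau`` is the fusion relaxation time, the linear term accounts for the
constant trap velocity, and ``c`` is a force offset.  Because ``tau`` scales
with droplet size, each event's relaxation time is divided by the mean of the
two droplet radii before averaging across events of a condition (e.g. a
crowder concentration).  Events whose fitted ``tau`` reaches the trace
duration are marked incomplete (arrested fusion) and excluded from averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fitting import multistart_curve_fit

__all__ = [
    "FusionTrace", "FusionFit", "ConditionSummary", "fit_fusion_force",
    "scaled_relaxation_time", "aggregate_fusion_events", "decimate_trace",
    "fit_aspect_ratio_relaxation",
]


@dataclass
class FusionTrace:
    """Force-time record of one droplet fusion event, t = 0 at contact."""

    time: np.ndarray            # s
    force: np.ndarray           # pN
    sampling_rate: float        # Hz
    radius_1: float             # um
    radius_2: float             # um
    condition_label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.time) != len(self.force):
            raise ValueError("time and force lengths differ")
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.radius_1 <= 0 or self.radius_2 <= 0:
            raise ValueError("droplet radii must be > 0")


@dataclass
class FusionFit:
    amp_a: float                # pN
    tau: float                  # s
    drift_b: float              # pN/s
    offset_c: float             # pN
    residual_rms: float         # pN
    mean_radius: float          # um
    scaled_tau: float           # s/um
    complete: bool
    condition_label: str = ""
    warnings: list = field(default_factory=list)


@dataclass
class ConditionSummary:
    condition_label: str
    n_events: int
    mean_scaled_tau: float
    sem_scaled_tau: float | None
    incomplete_count: int


def _force_model(t, a, tau, b, c):
    return a * np.exp(-t / tau) + b * t + c


def decimate_trace(trace: FusionTrace, target_rate: float) -> FusionTrace:
    """Block-average a trace down to <= ``target_rate`` Hz.

    High-rate instrument streams (tens of kHz) carry no extra information for
    the relaxation fit, which is sampling-rate invariant; block averaging also
    suppresses white noise.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    factor = int(np.ceil(trace.sampling_rate / target_rate))
    if factor <= 1:
        return trace
    n = (len(trace.time) // factor) * factor
    t = trace.time[:n].reshape(-1, factor).mean(axis=1)
    f = trace.force[:n].reshape(-1, factor).mean(axis=1)
    return FusionTrace(time=t, force=f,
                       sampling_rate=trace.sampling_rate / factor,
                       radius_1=trace.radius_1, radius_2=trace.radius_2,
                       condition_label=trace.condition_label)


def fit_fusion_force(trace: FusionTrace, max_rate: float = 10e3) -> FusionFit:
    """Least-squares fit of ``F = a exp(-t/tau) + b t + c`` to one event.

    Traces sampled above ``max_rate`` are block-averaged first.  The force is
    normalized by its absolute maximum internally before fitting (the scale is
    restored on the reported ``a``, ``b``, ``c``; ``tau`` is unaffected).
    Fits whose ``tau`` reaches half the trace duration are marked
    ``complete=False`` (arrested fusion); traces shorter than 3 fitted ``tau``
    get a warning.
    """
    trace = decimate_trace(trace, max_rate)
    t, f = trace.time, trace.force
    warnings: list[str] = []
    if len(t) < 50:
        warnings.append("fewer than 50 samples")
    duration = float(t[-1] - t[0])

    # degenerate input: no relaxation component above the linear drift
    coeffs = np.polyfit(t, f, 1)
    lin_res = f - np.polyval(coeffs, t)
    scale = max(float(np.max(np.abs(f))), 1e-300)
    if float(np.max(np.abs(lin_res))) <= 1e-9 * scale:
        raise ValueError("no relaxation component detected (force is linear "
                         "in time)")

    fn = f / scale
    tail = slice(int(0.75 * len(t)), None)
    b0 = float(np.polyfit(t[tail], fn[tail], 1)[0])
    c0 = float(fn[tail].mean() - b0 * float(t[tail].mean()))
    a0 = float(fn[0] - c0)
    if a0 == 0.0:
        a0 = float(np.max(np.abs(fn - (b0 * t + c0)))) or 1e-3
    tau0 = duration / 5.0
    out = multistart_curve_fit(
        _force_model, t, fn, p0=[a0, tau0, b0, c0],
        bounds=([-np.inf, 1e-12, -np.inf, -np.inf],
                [np.inf, np.inf, np.inf, np.inf]),
        extra_starts=[[a0, tau0 / 5.0, b0, c0], [a0, tau0 * 5.0, b0, c0]],
    )
    a, tau, b, c = (float(v) for v in out.params)
    a, b, c = a * scale, b * scale, c * scale
    res_rms = out.residual_rms * scale

    complete = tau < 0.5 * duration
    if not complete:
        warnings.append("fitted tau reaches trace duration: incomplete "
                        "(arrested) fusion")
    elif duration < 3.0 * tau:
        warnings.append("trace shorter than 3 relaxation times: tau poorly "
                        "constrained")

    mean_radius = 0.5 * (trace.radius_1 + trace.radius_2)
    return FusionFit(
        amp_a=a, tau=tau, drift_b=b, offset_c=c, residual_rms=res_rms,
        mean_radius=mean_radius,
        scaled_tau=tau / mean_radius,
        complete=complete, condition_label=trace.condition_label,
        warnings=warnings,
    )


def scaled_relaxation_time(fit: FusionFit) -> float:
    """Relaxation time scaled by the mean droplet radius, s/um.

    Incomplete (arrested) events have no defined relaxation time and must be
    excluded, mirroring the 'n.d.' reported for non-fusing droplets.
    """
    if not fit.complete:
        raise ValueError("incomplete fusion event: scaled relaxation time "
                         "undefined; exclude this event")
    return fit.tau / fit.mean_radius


def aggregate_fusion_events(fits: list[FusionFit]) -> list[ConditionSummary]:
    """Mean and SEM of the scaled relaxation time per condition label.

    Incomplete events are counted per condition but never averaged.  SEM
    (sd / sqrt(n), sample sd) is defined only for n >= 2.
    """
    if not fits:
        raise ValueError("no fusion events supplied")
    rows = [{"condition": f.condition_label, "complete": f.complete,
             "scaled_tau": f.scaled_tau if f.complete else np.nan}
            for f in fits]
    df = pd.DataFrame(rows)
    out: list[ConditionSummary] = []
    for label, grp in df.groupby("condition", sort=True):
        done = grp[grp["complete"]]
        if done.empty:
            raise ValueError(f"condition {label!r} has no complete fusion "
                             "events")
        vals = done["scaled_tau"].to_numpy()
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else None
        out.append(ConditionSummary(
            condition_label=str(label), n_events=n,
            mean_scaled_tau=float(np.mean(vals)), sem_scaled_tau=sem,
            incomplete_count=int((~grp["complete"]).sum()),
        ))
    return out


def fit_aspect_ratio_relaxation(time: np.ndarray,
                                aspect_ratio: np.ndarray) -> float:
    """Relaxation time from a droplet aspect-ratio time series.

    Fits ``AR(t) = 1 + (AR0 - 1) exp(-t/tau)`` — the image-based cross-check
    of the force-trace relaxation time.  Intended for consistency testing on
    synthetic data; returns ``tau`` in seconds.
    """
    time = np.asarray(time, dtype=float)
    ar = np.asarray(aspect_ratio, dtype=float)

    def model(t, ar0, tau):
        return 1.0 + (ar0 - 1.0) * np.exp(-t / tau)

    tau0 = max(float(time[-1]) / 5.0, 1e-6)
    out = multistart_curve_fit(
        model, time, ar, p0=[max(float(ar[0]), 1.01), tau0],
        bounds=([1.0, 1e-12], [np.inf, np.inf]),
        extra_starts=[[max(float(ar[0]), 1.01), tau0 / 5.0]],
    )
    return float(out.params[1])
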