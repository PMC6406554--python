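"""FRAP (fluorescence recovery after photobleaching) quantification.

The analysis chain mirrors standard confocal FRAP practice for biomolecular
condensates:

1. background subtraction and photofading correction of the bleached-ROI
   intensity using a reference droplet ROI, ``Cf(t) = Ri / R(t)``;
2. shift-and-scale normalization of the post-bleach recovery so the immediate
   post-bleach point is 0 and the maximum recovery is 1;
3. single-exponential ``A(1 - exp(-t/tau))`` or two-exponential recovery fit,
   with the recovery half-time ``tau_half`` taken analytically (``tau ln 2``)
   for the single-exponential model and graphically (root of
   ``fit(t) = plateau/2``) for the two-exponential model;
4. effective bleach-radius estimation by fitting the post-bleach radial
   intensity profile with the exponential of a Gaussian laser profile,
   ``f(x) = exp(-K exp(-2 (x-b)^2 / r_e^2))``;
5. apparent diffusion coefficient ``D_app = (r_e^2 + r_n^2) / (8 tau_half)``,
   where ``r_n`` is the user-defined nominal bleach radius;
6. mobile fraction ``Mf = (I_inf - I_0) / (I_i - I_0)`` on photofade-corrected,
   unnormalized intensities.

Times are in seconds, lengths in micrometres, diffusion in um^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ._fitting import FitConvergenceError, multistart_curve_fit, residual_rms

__all__ = [
    "FrapTrace", "BleachProfile", "NormalizedRecovery", "RecoveryFit",
    "EffectiveRadiusFit", "FrapResult", "correct_photofading",
    "normalize_recovery", "fit_single_exponential", "fit_double_exponential",
    "fit_effective_radius", "apparent_diffusion", "mobile_fraction",
    "analyze_frap", "FrapStageError",
]


class FrapStageError(RuntimeError):
    """Error raised by :func:`analyze_frap`, naming the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FrapTrace:
    """Raw three-ROI FRAP time series (bleached droplet, reference droplet,
    background), plus the frame index at which the bleach was applied and the
    nominal (user-defined) bleach radius ``r_n`` in um."""

    time: np.ndarray
    intensity_bleach: np.ndarray
    intensity_ref: np.ndarray
    intensity_bg: np.ndarray
    bleach_frame_index: int
    nominal_radius_rn: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity_bleach = np.asarray(self.intensity_bleach, dtype=float)
        self.intensity_ref = np.asarray(self.intensity_ref, dtype=float)
        self.intensity_bg = np.asarray(self.intensity_bg, dtype=float)
        n = len(self.time)
        for name in ("intensity_bleach", "intensity_ref", "intensity_bg"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != time length")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not 0 <= self.bleach_frame_index < n:
            raise ValueError("bleach_frame_index out of range")
        if self.nominal_radius_rn <= 0:
            raise ValueError("nominal_radius_rn must be > 0")


@dataclass
class BleachProfile:
    """Radial (line) intensity profile across the bleached ROI taken from the
    immediate post-bleach frame; ``x_um`` in micrometres, intensity normalized
    so the unbleached plateau is ~1."""

    x_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.x_um) != len(self.intensity):
            raise ValueError("x_um and intensity lengths differ")
        if len(self.x_um) >= 2 and not np.all(np.diff(self.x_um) > 0):
            raise ValueError("x_um must be strictly increasing")


@dataclass
class NormalizedRecovery:
    """Post-bleach recovery curve after shift-and-scale normalization.

    ``shift_value`` and ``scale_value`` retain the affine map back to the
    corrected (unnormalized) intensity scale: ``corrected = shift_value +
    intensity_norm * scale_value``.
    """

    time_post_bleach: np.ndarray
    intensity_norm: np.ndarray
    correction_factors: np.ndarray | None = None
    shift_value: float = 0.0
    scale_value: float = 1.0


@dataclass
class RecoveryFit:
    model: str                    # "single_exp" | "double_exp"
    amp_a: float
    tau_a: float
    tau_half: float
    plateau: float
    residual_rms: float
    n_points: int
    amp_b: float | None = None
    tau_b: float | None = None
    warnings: list = field(default_factory=list)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        y = self.amp_a * (1.0 - np.exp(-t / self.tau_a))
        if self.model == "double_exp":
            y = y + self.amp_b * (1.0 - np.exp(-t / self.tau_b))
        return y


@dataclass
class EffectiveRadiusFit:
    depth_k: float
    center_b: float
    radius_re: float
    residual_rms: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return np.exp(-self.depth_k
                      * np.exp(-2.0 * (x - self.center_b) ** 2
                               / self.radius_re ** 2))


@dataclass
class FrapResult:
    d_app: float
    mobile_fraction: float
    tau_half: float
    radius_re: float
    radius_rn: float
    fit: RecoveryFit
    radius_fit: EffectiveRadiusFit | None = None
    intensity_pre: float = float("nan")
    intensity_post: float = float("nan")
    intensity_plateau: float = float("nan")
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "d_app_um2_per_s": self.d_app,
            "mobile_fraction": self.mobile_fraction,
            "tau_half_s": self.tau_half,
            "radius_re_um": self.radius_re,
            "radius_rn_um": self.radius_rn,
            "recovery_fit": {
                "model": self.fit.model,
                "amp_a": self.fit.amp_a,
                "tau_a_s": self.fit.tau_a,
                "amp_b": self.fit.amp_b,
                "tau_b_s": self.fit.tau_b,
                "plateau": self.fit.plateau,
                "residual_rms": self.fit.residual_rms,
                "n_points": self.fit.n_points,
                "warnings": list(self.fit.warnings),
            },
            "intensity_pre": self.intensity_pre,
            "intensity_post": self.intensity_post,
            "intensity_plateau": self.intensity_plateau,
            "warnings": list(self.warnings),
        }
        if self.radius_fit is not None:
            d["radius_fit"] = {
                "depth_k": self.radius_fit.depth_k,
                "center_b_um": self.radius_fit.center_b,
                "radius_re_um": self.radius_fit.radius_re,
                "residual_rms": self.radius_fit.residual_rms,
            }
        return d


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def correct_photofading(trace: FrapTrace) -> np.ndarray:
    """Background-subtract and photofade-correct the bleached-ROI series.

    Background is subtracted from both the bleached and reference series
    first; the correction factor is ``Cf(t) = Ri / R(t)`` with ``Ri`` the mean
    background-subtracted reference intensity over the pre-bleach frames (or
    the first frame when there are none).  Returns ``Cf(t) * I_bleached(t)``.
    """
    ref = trace.intensity_ref - trace.intensity_bg
    ble = trace.intensity_bleach - trace.intensity_bg
    bad = np.nonzero(ref <= 0)[0]
    if bad.size:
        raise ValueError(
            f"reference intensity non-positive after background subtraction "
            f"at frame {int(bad[0])} (t={trace.time[bad[0]]:.6g} s)")
    if trace.bleach_frame_index > 0:
        ri = float(np.mean(ref[:trace.bleach_frame_index]))
    else:
        ri = float(ref[0])
    cf = ri / ref
    return cf * ble


def correction_factors(trace: FrapTrace) -> np.ndarray:
    """The ``Cf(t) = Ri / R(t)`` series used by :func:`correct_photofading`."""
    ref = trace.intensity_ref - trace.intensity_bg
    if np.any(ref <= 0):
        raise ValueError("reference intensity non-positive after background "
                         "subtraction")
    if trace.bleach_frame_index > 0:
        ri = float(np.mean(ref[:trace.bleach_frame_index]))
    else:
        ri = float(ref[0])
    return ri / ref


def normalize_recovery(corrected: np.ndarray, time: np.ndarray,
                       bleach_frame_index: int,
                       correction_factors: np.ndarray | None = None,
                       noise_tol: float = 0.0) -> NormalizedRecovery:
    """Shift-and-scale the post-bleach window of a corrected series.

    The minimum over the post-bleach window is subtracted (shift) and the
    result divided by its maximum (scale), so the output spans [0, 1] by
    construction.  When the window minimum is not the immediate post-bleach
    point but differs from it by no more than ``noise_tol``, the zero is
    pinned to the immediate post-bleach point.
    Time is rebased so the first post-bleach frame is t = 0.
    """
    corrected = np.asarray(corrected, dtype=float)
    time = np.asarray(time, dtype=float)
    post = corrected[bleach_frame_index:]
    t_post = time[bleach_frame_index:] - time[bleach_frame_index]
    if len(post) < 3:
        raise ValueError("need at least 3 post-bleach frames")
    m = float(np.min(post))
    if post[0] - m <= noise_tol:
        m = float(post[0])
    shifted = post - m
    scale = float(np.max(shifted))
    if scale <= 0:
        raise ValueError("constant post-bleach series: nothing to normalize")
    cf_post = None
    if correction_factors is not None:
        cf_post = np.asarray(correction_factors, dtype=float)[bleach_frame_index:]
    return NormalizedRecovery(
        time_post_bleach=t_post,
        intensity_norm=shifted / scale,
        correction_factors=cf_post,
        shift_value=m,
        scale_value=scale,
    )


def _single_exp(t, a, tau):
    return a * (1.0 - np.exp(-t / tau))


def _double_exp(t, a, tau_a, b, tau_b):
    return (a * (1.0 - np.exp(-t / tau_a))
            + b * (1.0 - np.exp(-t / tau_b)))


def _tau_guess(t, y):
    """Time at which the curve first reaches (1 - 1/e) of its plateau."""
    plateau = float(np.max(y))
    if plateau <= 0:
        return max(float(t[-1]) / 3.0, 1e-6)
    target = (1.0 - math.exp(-1.0)) * plateau
    above = np.nonzero(y >= target)[0]
    if above.size and above[0] > 0:
        return max(float(t[above[0]]), float(t[1]) if len(t) > 1 else 1e-6)
    return max(float(t[-1]) / 3.0, 1e-6)


def fit_single_exponential(rec: NormalizedRecovery) -> RecoveryFit:
    """Fit ``y = A (1 - exp(-t/tau))``; ``tau_half = tau ln 2``."""
    t, y = rec.time_post_bleach, rec.intensity_norm
    if len(t) < 5:
        raise ValueError("need at least 5 points for a single-exponential fit")
    tau0 = _tau_guess(t, y)
    a0 = max(float(np.max(y)), 1e-6)
    out = multistart_curve_fit(
        _single_exp, t, y, p0=[a0, tau0],
        bounds=([0.0, 1e-9], [10.0, np.inf]),
        extra_starts=[[a0, tau0 / 5.0], [a0, tau0 * 5.0]],
    )
    a, tau = out.params
    return RecoveryFit(
        model="single_exp", amp_a=float(a), tau_a=float(tau),
        tau_half=float(tau) * math.log(2.0), plateau=float(a),
        residual_rms=out.residual_rms, n_points=out.n_points,
    )


def graphical_half_time(fit_curve, plateau: float, t_max: float) -> float:
    """Half-time of recovery found graphically: the bracketed root of
    ``fit_curve(t) = plateau / 2`` on (0, ~40 t_max]."""
    target = plateau / 2.0

    def g(t):
        return fit_curve(t) - target

    hi = t_max
    # recovery curves used here are monotone increasing from 0 toward plateau
    for _ in range(20):
        if g(hi) > 0:
            break
        hi *= 2.0
    else:
        raise FitConvergenceError("half-recovery level never reached")
    return float(brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-15))


def fit_double_exponential(rec: NormalizedRecovery) -> RecoveryFit:
    """Fit ``y = A (1-exp(-t/tauA)) + B (1-exp(-t/tauB))``.

    The half-time is obtained graphically (numeric root of
    ``fit(t) = plateau/2``).  Components are ordered so ``tau_a <= tau_b``;
    a warning is recorded when the two time constants are within a factor of
    1.5 (weak identifiability).
    """
    t, y = rec.time_post_bleach, rec.intensity_norm
    if len(t) < 8:
        raise ValueError("need at least 8 points for a two-exponential fit")
    tau0 = _tau_guess(t, y)
    a0 = max(float(np.max(y)), 1e-6)
    out = multistart_curve_fit(
        _double_exp, t, y,
        p0=[a0 / 2.0, tau0 / 3.0, a0 / 2.0, tau0 * 3.0],
        bounds=([0.0, 1e-9, 0.0, 1e-9], [10.0, np.inf, 10.0, np.inf]),
        extra_starts=[
            [a0 * 0.8, tau0, a0 * 0.2, tau0 * 10.0],
            [a0 / 2.0, tau0 / 10.0, a0 / 2.0, tau0],
        ],
    )
    a, tau_a, b, tau_b = (float(v) for v in out.params)
    if tau_a > tau_b:  # remove label-switching nonidentifiability
        a, tau_a, b, tau_b = b, tau_b, a, tau_a
    warnings = []
    if tau_b / max(tau_a, 1e-300) < 1.5:
        warnings.append("time constants within factor 1.5: "
                        "components weakly identifiable")
    plateau = a + b
    fit = RecoveryFit(
        model="double_exp", amp_a=a, tau_a=tau_a, amp_b=b, tau_b=tau_b,
        tau_half=float("nan"), plateau=plateau,
        residual_rms=out.residual_rms, n_points=out.n_points,
        warnings=warnings,
    )
    fit.tau_half = graphical_half_time(fit, plateau, float(t[-1]))
    return fit


def _gaussian_bleach(x, k, b, re):
    return np.exp(-k * np.exp(-2.0 * (x - b) ** 2 / re ** 2))


def fit_effective_radius(profile: BleachProfile) -> EffectiveRadiusFit:
    """Fit the post-bleach profile with the exponential of a Gaussian laser
    profile, ``f(x) = exp(-K exp(-2 (x-b)^2 / r_e^2))``.

    ``r_e`` is the effective bleach radius: the Gaussian 1/e^2 half-width of
    the bleach depth, accounting for diffusion during bleaching.  Initial
    guesses come from the data: ``b`` at the intensity minimum, ``K`` from the
    log of the minimum, ``r_e`` from the width at which the log-depth falls to
    ``exp(-2)`` of its central value.
    """
    x, y = profile.x_um, profile.intensity
    if len(x) < 15:
        raise ValueError("need at least 15 profile points")
    ymin = float(np.min(y))
    plateau = float(np.median(np.concatenate([y[:3], y[-3:]])))
    if ymin >= 0.98 * plateau:
        raise ValueError("no detectable bleach (profile minimum >= 98% of "
                         "the plateau)")
    imin = int(np.argmin(y))
    b0 = float(x[imin])
    k0 = max(-math.log(max(ymin, 1e-12)), 1e-3)
    # width at which the log-depth falls to e^-2 of the central depth
    depth = -np.log(np.clip(y, 1e-12, None))
    target = k0 * math.exp(-2.0)
    above = depth >= target
    if above.any():
        xs = x[above]
        re0 = max(float(xs[-1] - xs[0]) / 2.0, float(x[1] - x[0]))
    else:
        re0 = float(x[-1] - x[0]) / 6.0
    out = multistart_curve_fit(
        _gaussian_bleach, x, y, p0=[k0, b0, re0],
        bounds=([1e-9, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        extra_starts=[[k0, b0, re0 * 2.0], [k0, b0, re0 / 2.0]],
    )
    k, b, re = (float(v) for v in out.params)
    return EffectiveRadiusFit(depth_k=k, center_b=b, radius_re=abs(re),
                              residual_rms=out.residual_rms)


def apparent_diffusion(radius_re: float, radius_rn: float,
                       tau_half: float) -> float:
    """Apparent diffusion coefficient ``D = (r_e^2 + r_n^2) / (8 tau_half)``
    in um^2/s, from the effective and nominal bleach radii (um) and the
    recovery half-time (s)."""
    if radius_re <= 0 or radius_rn <= 0 or tau_half <= 0:
        raise ValueError("radius_re, radius_rn and tau_half must be > 0")
    return (radius_re ** 2 + radius_rn ** 2) / (8.0 * tau_half)


def mobile_fraction(intensity_pre: float, intensity_post_bleach: float,
                    intensity_recovered: float) -> float:
    """Mobile fraction ``Mf = (I_inf - I_0) / (I_i - I_0)`` computed on
    photofade-corrected, unnormalized intensities.

    ``I_i`` is the pre-bleach intensity, ``I_0`` the intensity immediately
    after the bleach and ``I_inf`` the recovered (plateau) intensity.  Values
    outside [0, 1.05] are returned as-is (flagged upstream, never clamped).
    """
    if intensity_pre == intensity_post_bleach:
        raise ValueError("zero bleach depth: I_i equals I_0")
    if intensity_pre < intensity_post_bleach:
        raise ValueError("pre-bleach intensity must exceed post-bleach "
                         "intensity")
    return ((intensity_recovered - intensity_post_bleach)
            / (intensity_pre - intensity_post_bleach))


def analyze_frap(trace: FrapTrace, profile: BleachProfile | None = None,
                 model: str = "single", noise_tol: float = 0.0) -> FrapResult:
    """Run the full FRAP chain and return a :class:`FrapResult` with all
    intermediates retained.

    ``model`` is ``"single"``, ``"double"`` or ``"both"`` (fit both, keep the
    model with the lower residual RMS; choice recorded in the result).  When
    ``profile`` is None the effective radius falls back to the nominal radius
    ``r_n`` and a warning is recorded.
    """
    if model not in ("single", "double", "both"):
        raise ValueError("model must be 'single', 'double' or 'both'")
    warnings: list[str] = []

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except FrapStageError:
            raise
        except Exception as err:
            raise FrapStageError(name, str(err)) from err

    corrected = stage("correct_photofading", correct_photofading, trace)
    cf = stage("correct_photofading", correction_factors, trace)
    rec = stage("normalize_recovery", normalize_recovery, corrected,
                trace.time, trace.bleach_frame_index, cf, noise_tol)

    if model == "single":
        fit = stage("fit_recovery", fit_single_exponential, rec)
    elif model == "double":
        fit = stage("fit_recovery", fit_double_exponential, rec)
    else:
        fit_s = stage("fit_recovery", fit_single_exponential, rec)
        fit_d = stage("fit_recovery", fit_double_exponential, rec)
        fit = fit_s if fit_s.residual_rms <= fit_d.residual_rms else fit_d
        warnings.append(f"model selected by residual RMS: {fit.model}")

    radius_fit = None
    if profile is not None:
        radius_fit = stage("fit_effective_radius", fit_effective_radius,
                           profile)
        radius_re = radius_fit.radius_re
    else:
        radius_re = trace.nominal_radius_rn
        warnings.append("no bleach profile supplied: r_e set to nominal r_n")

    d_app = stage("apparent_diffusion", apparent_diffusion, radius_re,
                  trace.nominal_radius_rn, fit.tau_half)

    # Eq.-3-style mobile fraction on the corrected, unnormalized scale:
    # I_inf estimated from the fitted plateau mapped back through the
    # normalization affine transform (robust to truncated recovery).
    i_pre = float(np.mean(corrected[:trace.bleach_frame_index])) \
        if trace.bleach_frame_index > 0 else float(corrected[0])
    i_post = rec.shift_value
    i_inf = rec.shift_value + fit.plateau * rec.scale_value
    mf = stage("mobile_fraction", mobile_fraction, i_pre, i_post, i_inf)
    if not 0.0 <= mf <= 1.05:
        warnings.append(f"mobile fraction {mf:.4g} outside [0, 1.05]")

    return FrapResult(
        d_app=d_app, mobile_fraction=mf, tau_half=fit.tau_half,
        radius_re=radius_re, radius_rn=trace.nominal_radius_rn, fit=fit,
        radius_fit=radius_fit, intensity_pre=i_pre, intensity_post=i_post,
        intensity_plateau=i_inf, warnings=warnings,
    )
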