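"""Ground-truth-known synthetic data for every analysis stage.

The measurements this package analyzes (confocal FRAP traces, post-bleach
radial profiles, optical-tweezer force traces, droplet fluorescence images,
turbidity grids) are not typically deposited with publications, so each
generator here emulates the statistical structure of the corresponding
measurement with known parameters.  All generators are deterministic under a
fixed seed, and each one is the exact inverse model of the matching analysis
stage: at zero noise the analysis recovers the generating parameters.

Conventions: time in s, lengths in um, intensities in arbitrary units with
the pre-bleach corrected level at 1, forces in pN.  Noise is i.i.d. Gaussian
unless an image generator is asked for Poisson (shot) noise; the analyses
only use means, so Gaussian is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .frap import BleachProfile, FrapTrace
from .fusion import FusionTrace
from .partition import DropletImage
from .phases import PhasePoint

__all__ = [
    "FrapGroundTruth", "ProfileGroundTruth", "FusionGroundTruth",
    "DropletImageGroundTruth", "BoundaryGroundTruth", "generate_frap_trace",
    "generate_bleach_profile", "generate_fusion_trace",
    "generate_droplet_image", "generate_turbidity_grid",
]


# ---------------------------------------------------------------------------
# ground-truth parameter sets
# ---------------------------------------------------------------------------

@dataclass
class FrapGroundTruth:
    """Generative parameters of a three-ROI FRAP trace.

    The recovery model is ``amp_a (1 - exp(-t/tau_a))`` plus an optional
    second component; ``mobile_fraction`` scales how much of the bleached
    depth ever recovers (the immobile remainder is a permanently dark floor);
    ``photofade_rate`` is the per-second decay of all imaged fluorescence;
    ``bleach_depth`` is the fraction of intensity removed by the bleach.
    Acquisition defaults (1 frame/s, ~300 s traces) are conventions typical
    of condensate FRAP, not constraints.
    """

    tau_a: float                      # s
    amp_a: float = 1.0
    tau_b: float | None = None        # s
    amp_b: float | None = None
    mobile_fraction: float = 1.0
    photofade_rate: float = 0.0       # 1/s
    noise_sd: float = 0.0
    pre_bleach_frames: int = 10
    frame_interval: float = 1.0       # s
    bleach_depth: float = 0.8         # in (0, 1]
    background_level: float = 0.1
    nominal_radius_rn: float = 2.0    # um

    def __post_init__(self):
        if self.tau_a <= 0 or (self.tau_b is not None and self.tau_b <= 0):
            raise ValueError("time constants must be > 0")
        amps = [self.amp_a] + ([self.amp_b] if self.amp_b is not None else [])
        if any(not 0.0 <= a <= 1.0 for a in amps) or sum(amps) > 1.0 + 1e-12:
            raise ValueError("amplitudes must lie in [0, 1] and sum to <= 1")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if self.photofade_rate < 0 or self.noise_sd < 0:
            raise ValueError("photofade_rate and noise_sd must be >= 0")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must lie in (0, 1]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def recovery(self, t_post):
        """Normalized recovery model evaluated at post-bleach times."""
        t = np.asarray(t_post, dtype=float)
        y = self.amp_a * (1.0 - np.exp(-t / self.tau_a))
        if self.amp_b is not None and self.tau_b is not None:
            y = y + self.amp_b * (1.0 - np.exp(-t / self.tau_b))
        return y


@dataclass
class ProfileGroundTruth:
    """Generative parameters of a post-bleach intensity profile: the
    exponential of a Gaussian laser profile with bleach depth K, center b and
    effective radius r_e."""

    depth_k: float                    # > 0
    center_b: float                   # um
    radius_re: float                  # um
    x_grid: np.ndarray                # um
    noise_sd: float = 0.0

    def __post_init__(self):
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        if self.depth_k <= 0:
            raise ValueError("depth_k must be > 0")
        if self.radius_re <= 0:
            raise ValueError("radius_re must be > 0")
        if not np.all(np.diff(self.x_grid) > 0):
            raise ValueError("x_grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        span_lo = self.center_b - 3.0 * self.radius_re
        span_hi = self.center_b + 3.0 * self.radius_re
        if self.x_grid[0] > span_lo or self.x_grid[-1] < span_hi:
            raise ValueError("x_grid must span [b - 3 r_e, b + 3 r_e]")


@dataclass
class FusionGroundTruth:
    """Generative parameters of a droplet-fusion force trace
    ``F = a exp(-t/tau) + b t + c`` plus droplet radii metadata.

    Traces are generated at kHz-scale sampling (the relaxation fit is
    sampling-rate invariant, so instrument-rate streams are unnecessary).
    """

    amp_a: float                      # pN
    tau: float                        # s
    drift_b: float = 0.0              # pN/s
    offset_c: float = 0.0             # pN
    sampling_rate: float = 1000.0     # Hz
    duration: float | None = None     # s; default 8 tau
    radius_1: float = 2.0             # um
    radius_2: float = 2.0             # um
    noise_sd: float = 0.0             # pN
    condition_label: str = ""

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.radius_1 <= 0 or self.radius_2 <= 0:
            raise ValueError("radii must be > 0")
        if self.duration is None:
            self.duration = 8.0 * self.tau
        if self.duration < 5.0 * self.tau:
            raise ValueError("duration must be >= 5 tau")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DropletImageGroundTruth:
    """Generative parameters of a droplet fluorescence image: disjoint discs
    of mean intensity ``dense_intensity`` on a background of mean
    ``background_intensity``."""

    image_shape: tuple[int, int] = (256, 256)     # px (rows, cols)
    pixel_size: float = 0.1                       # um/px
    droplet_centers_radii: Sequence[tuple[float, float, float]] = ()
    dense_intensity: float = 500.0                # counts
    background_intensity: float = 50.0            # counts
    noise_model: str = "none"                     # none|gaussian|poisson
    noise_sd: float = 0.0                         # counts, gaussian only
    seed: int = 0

    def __post_init__(self):
        if self.background_intensity <= 0:
            raise ValueError("background_intensity must be > 0")
        if self.dense_intensity <= self.background_intensity:
            raise ValueError("dense_intensity must exceed "
                             "background_intensity")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be none|gaussian|poisson")
        h, w = self.image_shape
        for x, y, r in self.droplet_centers_radii:
            if r <= 0:
                raise ValueError("droplet radii must be > 0")
            if (x - r < 0 or y - r < 0 or x + r > w * self.pixel_size
                    or y + r > h * self.pixel_size):
                raise ValueError("droplets must lie fully inside the frame")
        pts = list(self.droplet_centers_radii)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                xi, yi, ri = pts[i]
                xj, yj, rj = pts[j]
                if np.hypot(xi - xj, yi - yj) < ri + rj:
                    raise ValueError(
                        "overlapping droplet discs make per-droplet "
                        "statistics ambiguous")

    @property
    def true_partition(self) -> float:
        return self.dense_intensity / self.background_intensity


@dataclass
class BoundaryGroundTruth:
    """Generative parameters of a turbidity grid: a nonincreasing saturation
    boundary ``csat(crowder)`` separating low- from high-turbidity samples."""

    csat_function: Callable[[float], float]   # mg/mL -> uM, nonincreasing
    turbidity_high: float = 0.5               # A350
    turbidity_low: float = 0.01               # A350
    turbidity_noise_sd: float = 0.0           # A350

    def __post_init__(self):
        if self.turbidity_high <= self.turbidity_low:
            raise ValueError("turbidity_high must exceed turbidity_low")
        if self.turbidity_noise_sd < 0:
            raise ValueError("turbidity_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_frap_trace(gt: FrapGroundTruth, n_frames: int,
                        seed: int) -> FrapTrace:
    """Simulate a three-ROI FRAP trace.

    The underlying (background-free, fade-free) bleached-ROI intensity is 1
    before the bleach and, from the bleach frame on,

        I(t') = I0 + (1 - I0) * mobile_fraction * recovery(t')

    with ``I0 = 1 - bleach_depth`` — the immobile fraction is a permanently
    dark floor, matching the mobile-fraction definition.  Photofading
    ``exp(-photofade_rate t)`` multiplies both the bleached and reference
    ROIs identically (which is what makes the ratio correction exact), the
    background level is added to all three ROIs, and Gaussian noise of sd
    ``noise_sd`` is added i.i.d. to each series.
    """
    if n_frames <= gt.pre_bleach_frames + 3:
        raise ValueError("n_frames must exceed pre_bleach_frames + 3")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames, dtype=float) * gt.frame_interval
    t_bleach = t[gt.pre_bleach_frames]
    fade = np.exp(-gt.photofade_rate * t)

    i0 = 1.0 - gt.bleach_depth
    core = np.ones(n_frames)
    post = slice(gt.pre_bleach_frames, None)
    core[post] = i0 + (1.0 - i0) * gt.mobile_fraction \
        * gt.recovery(t[post] - t_bleach)

    bleach = gt.background_level + fade * core
    ref = gt.background_level + fade
    bg = np.full(n_frames, gt.background_level)
    if gt.noise_sd > 0:
        bleach = bleach + rng.normal(0.0, gt.noise_sd, n_frames)
        ref = ref + rng.normal(0.0, gt.noise_sd, n_frames)
        bg = bg + rng.normal(0.0, gt.noise_sd, n_frames)
    return FrapTrace(time=t, intensity_bleach=bleach, intensity_ref=ref,
                     intensity_bg=bg,
                     bleach_frame_index=gt.pre_bleach_frames,
                     nominal_radius_rn=gt.nominal_radius_rn)


def generate_bleach_profile(gt: ProfileGroundTruth,
                            seed: int) -> BleachProfile:
    """Simulate a post-bleach radial profile:
    ``I(x) = exp(-K exp(-2 (x-b)^2 / r_e^2)) + noise``."""
    rng = np.random.default_rng(seed)
    x = gt.x_grid
    intensity = np.exp(-gt.depth_k
                       * np.exp(-2.0 * (x - gt.center_b) ** 2
                                / gt.radius_re ** 2))
    if gt.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, gt.noise_sd, len(x))
    return BleachProfile(x_um=x.copy(), intensity=intensity)


def generate_fusion_trace(gt: FusionGroundTruth, seed: int) -> FusionTrace:
    """Simulate a fusion force trace ``F(t) = a exp(-t/tau) + b t + c`` at
    the stated sampling rate, radii attached as metadata."""
    rng = np.random.default_rng(seed)
    n = int(round(gt.duration * gt.sampling_rate)) + 1
    t = np.arange(n, dtype=float) / gt.sampling_rate
    force = gt.amp_a * np.exp(-t / gt.tau) + gt.drift_b * t + gt.offset_c
    if gt.noise_sd > 0:
        force = force + rng.normal(0.0, gt.noise_sd, n)
    return FusionTrace(time=t, force=force, sampling_rate=gt.sampling_rate,
                       radius_1=gt.radius_1, radius_2=gt.radius_2,
                       condition_label=gt.condition_label)


def generate_droplet_image(gt: DropletImageGroundTruth) -> DropletImage:
    """Render disjoint droplet discs on a uniform background.

    Pixels whose centers fall inside a disc have mean ``dense_intensity``,
    all others ``background_intensity``; noise per ``noise_model`` (Gaussian
    sd ``noise_sd``, or Poisson with the pixel mean as rate).  Deterministic
    under ``gt.seed``.
    """
    rng = np.random.default_rng(gt.seed)
    h, w = gt.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    # pixel centers in um
    xc = (xx + 0.5) * gt.pixel_size
    yc = (yy + 0.5) * gt.pixel_size
    img = np.full((h, w), gt.background_intensity, dtype=float)
    for x, y, r in gt.droplet_centers_radii:
        img[(xc - x) ** 2 + (yc - y) ** 2 <= r ** 2] = gt.dense_intensity
    if gt.noise_model == "gaussian" and gt.noise_sd > 0:
        img = img + rng.normal(0.0, gt.noise_sd, img.shape)
    elif gt.noise_model == "poisson":
        img = rng.poisson(img).astype(float)
    img = np.clip(img, 0.0, None)
    return DropletImage(pixels=img, pixel_size=gt.pixel_size, bit_depth=16)


def generate_turbidity_grid(gt: BoundaryGroundTruth,
                            protein_concs: Sequence[float],
                            crowder_concs: Sequence[float],
                            seed: int) -> list[PhasePoint]:
    """Simulate turbidity observations on a protein x crowder grid.

    A sample is phase-separated when its protein concentration is at or above
    the boundary ``csat(crowder)``; separated samples draw A350 near
    ``turbidity_high``, mixed samples near ``turbidity_low``; the microscopy
    droplet flag is set consistently with the ground truth.
    """
    protein_concs = list(protein_concs)
    crowder_concs = list(crowder_concs)
    if not protein_concs or not crowder_concs:
        raise ValueError("concentration lists must be nonempty")
    if any(p <= 0 for p in protein_concs) or any(c < 0 for c in crowder_concs):
        raise ValueError("protein concentrations must be > 0 and crowder "
                         "concentrations >= 0")
    csat_vals = [gt.csat_function(c) for c in sorted(crowder_concs)]
    if any(b - a > 1e-12 for a, b in zip(csat_vals, csat_vals[1:])):
        raise ValueError("csat_function must be nonincreasing in crowder "
                         "concentration")
    rng = np.random.default_rng(seed)
    points = []
    for c in crowder_concs:
        csat = gt.csat_function(c)
        for p in protein_concs:
            separated = p >= csat
            a350 = gt.turbidity_high if separated else gt.turbidity_low
            if gt.turbidity_noise_sd > 0:
                a350 = a350 + rng.normal(0.0, gt.turbidity_noise_sd)
            points.append(PhasePoint(
                protein_conc=p, crowder_conc=c,
                a350=max(float(a350), 0.0), droplet_flag=separated))
    return points
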