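"""Ternary protein-crowder-solvent thermodynamics of crowding-tuned LLPS.

The model is a Flory-Huggins ternary free energy of mixing per lattice site
(units of kT) augmented with a depletion-interaction coupling:

    f(phi_p, phi_c) = (phi_p/Np) ln phi_p + (phi_c/Nc) ln phi_c
                      + phi_s ln phi_s
                      + chi_ps phi_p phi_s + chi_cs phi_c phi_s
                      + chi_pc phi_p phi_c
                      - chi_dep phi_p phi_c (phi_p + phi_c)

with ``phi_s = 1 - phi_p - phi_c``.  The last term is an effective
(Asakura-Oosawa-style) excluded-volume correction: overlap of the depletion
layers around protein molecules frees volume to the crowder, producing a net
protein-protein attraction whose strength grows linearly with the crowder
volume fraction.  By default ``chi_dep`` is mapped from the contact parameter
``chi_pc`` scaled by the depletion-layer overlap-volume factor
``(1 + Rc/Rp)^3 - 1`` (equal radii assumed when unspecified), so an
interaction-free crowder (``chi_pc = 0``) contributes no depletion attraction.

Stability of the homogeneous mixture at fixed temperature and crowder
composition is governed by the curvature ``d^2 f / d phi_p^2`` (equivalently
the concentration derivative of the protein exchange chemical potential): the
solution is stable where it is positive and spinodally unstable where it is
negative.  Coexistence at fixed ``phi_c`` is found by a pseudo-binary
common-tangent construction (equal exchange chemical potential and equal
grand-potential density at the two compositions); the crowder is assumed not
to repartition between phases.

All compositions are volume fractions; energies are in kT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "TernaryModel", "SpinodalResult", "BinodalResult", "free_energy_density",
    "exchange_chemical_potential", "mu_derivative", "spinodal_at_crowder",
    "binodal_at_crowder", "crowding_sweep", "depletion_layer_ratio",
    "binary_critical_point", "DepletionGeometry",
]

_EPS = 1e-9


@dataclass
class TernaryModel:
    """Parameterization of the ternary mixture.

    ``n_protein``/``n_crowder`` are degrees of polymerization (>= 1);
    ``chi_ps``, ``chi_cs``, ``chi_pc`` the pairwise Flory interaction
    parameters.  ``chi_dep`` sets the depletion-coupling strength directly;
    when None it defaults to ``chi_pc * ((1 + Rc/Rp)^3 - 1)`` using the
    protein/crowder radii (equal radii, factor 7, when either is unset).
    """

    n_protein: float = 1.0
    n_crowder: float = 1.0
    chi_ps: float = 0.0
    chi_cs: float = 0.0
    chi_pc: float = 0.0
    chi_dep: float | None = None
    protein_radius_nm: float | None = None
    crowder_radius_nm: float | None = None

    def __post_init__(self):
        if self.n_protein < 1 or self.n_crowder < 1:
            raise ValueError("degrees of polymerization must be >= 1")
        for r in (self.protein_radius_nm, self.crowder_radius_nm):
            if r is not None and r <= 0:
                raise ValueError("radii must be > 0")

    @property
    def depletion_strength(self) -> float:
        if self.chi_dep is not None:
            return self.chi_dep
        if self.protein_radius_nm and self.crowder_radius_nm:
            q = self.crowder_radius_nm / self.protein_radius_nm
        else:
            q = 1.0
        return self.chi_pc * ((1.0 + q) ** 3 - 1.0)


class SpinodalResult(NamedTuple):
    crowder_level: float
    spinodal_phi: tuple[float, float] | None   # (low, high) in phi_p
    stable_everywhere: bool


@dataclass
class BinodalResult:
    crowder_level: float
    phi_dilute: float
    phi_dense: float
    predicted_partition: float
    mu_residual: float
    omega_residual: float


class DepletionGeometry(NamedTuple):
    layer_thickness: float     # proxy, == crowder hydrodynamic radius
    overlap_factor: float      # (1 + Rc/Rp)^3 - 1


def _check_interior(phi_p, phi_c):
    phi_p = np.asarray(phi_p, dtype=float)
    phi_c = np.asarray(phi_c, dtype=float)
    if np.any(phi_p <= 0) or np.any(phi_c < 0) \
            or np.any(phi_p + phi_c >= 1):
        raise ValueError("compositions must satisfy phi_p > 0, phi_c >= 0, "
                         "phi_p + phi_c < 1")
    return phi_p, phi_c


def free_energy_density(model: TernaryModel, phi_p, phi_c):
    """Mixing free energy per site, kT.  Errors on boundary compositions
    (logarithm domain); ``phi_c = 0`` is allowed (the crowder entropy term
    vanishes there by the x ln x -> 0 limit)."""
    phi_p, phi_c = _check_interior(phi_p, phi_c)
    phi_s = 1.0 - phi_p - phi_c
    if np.any(phi_s <= 0):
        raise ValueError("solvent fraction must be > 0")
    chi_dep = model.depletion_strength
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_c = np.where(phi_c > 0,
                         (phi_c / model.n_crowder)
                         * np.log(np.where(phi_c > 0, phi_c, 1.0)), 0.0)
    f = ((phi_p / model.n_protein) * np.log(phi_p)
         + ent_c
         + phi_s * np.log(phi_s)
         + model.chi_ps * phi_p * phi_s
         + model.chi_cs * phi_c * phi_s
         + model.chi_pc * phi_p * phi_c
         - chi_dep * phi_p * phi_c * (phi_p + phi_c))
    return f if f.ndim else float(f)


def exchange_chemical_potential(model: TernaryModel, phi_p, phi_c):
    """Exchange chemical potential ``mu = df/dphi_p`` at fixed ``phi_c``
    (protein replacing solvent), kT per site."""
    phi_p, phi_c = _check_interior(phi_p, phi_c)
    phi_s = 1.0 - phi_p - phi_c
    chi_dep = model.depletion_strength
    mu = ((np.log(phi_p) + 1.0) / model.n_protein
          - (np.log(phi_s) + 1.0)
          + model.chi_ps * (phi_s - phi_p)
          - model.chi_cs * phi_c
          + model.chi_pc * phi_c
          - chi_dep * (2.0 * phi_p * phi_c + phi_c ** 2))
    return mu if mu.ndim else float(mu)


def mu_derivative(model: TernaryModel, phi_p, phi_c):
    """Concentration derivative of the protein exchange chemical potential at
    fixed temperature and crowder composition: ``d^2 f / d phi_p^2``.

    Analytic form for the implemented free energy:

        1/(Np phi_p) + 1/phi_s - 2 chi_ps - 2 chi_dep phi_c

    Its sign is the stability criterion: positive -> stable homogeneous
    solution, negative -> spinodal decomposition into two liquids.  The
    depletion coupling makes it decrease linearly with crowder volume
    fraction (net inter-protein attraction grows with crowding); the solvent
    entropy term ``1/phi_s`` opposes this, so the decrease is monotone where
    ``2 chi_dep > 1/phi_s^2``.
    """
    phi_p, phi_c = _check_interior(phi_p, phi_c)
    phi_s = 1.0 - phi_p - phi_c
    out = (1.0 / (model.n_protein * phi_p) + 1.0 / phi_s
           - 2.0 * model.chi_ps
           - 2.0 * model.depletion_strength * phi_c)
    return out if out.ndim else float(out)


def grand_potential_density(model: TernaryModel, phi_p, phi_c):
    """``omega = f - phi_p * mu``; equal in coexisting phases at fixed
    phi_c."""
    return (free_energy_density(model, phi_p, phi_c)
            - np.asarray(phi_p)
            * exchange_chemical_potential(model, phi_p, phi_c))


def binary_critical_point(n_protein: float) -> tuple[float, float]:
    """Closed-form binary Flory-Huggins critical point:
    ``chi_c = (1 + 1/sqrt(Np))^2 / 2``, ``phi_crit = 1/(1 + sqrt(Np))``."""
    s = np.sqrt(n_protein)
    return float((1.0 + 1.0 / s) ** 2 / 2.0), float(1.0 / (1.0 + s))


def spinodal_at_crowder(model: TernaryModel, phi_c: float,
                        n_grid: int = 400) -> SpinodalResult:
    """Roots of ``d^2 f/d phi_p^2 = 0`` in ``phi_p`` at fixed ``phi_c``.

    The curvature is strictly convex in ``phi_p`` (sum of two convex terms
    plus a constant), so there are either zero or two roots; they bound the
    unstable composition interval.
    """
    if not 0.0 <= phi_c <= 0.5:
        raise ValueError("phi_c must lie in [0, 0.5]")
    lo, hi = _EPS, 1.0 - phi_c - _EPS
    grid = np.linspace(lo, hi, n_grid)
    vals = mu_derivative(model, grid, np.full_like(grid, phi_c))
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        return SpinodalResult(phi_c, None, True)
    roots = []
    for i in sign_change:
        roots.append(brentq(
            lambda p: mu_derivative(model, p, phi_c),
            grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16))
    if len(roots) == 1:
        # root at the very grid edge; treat as numerically stable
        return SpinodalResult(phi_c, None, True)
    return SpinodalResult(phi_c, (float(min(roots)), float(max(roots))),
                          False)


def binodal_at_crowder(model: TernaryModel, phi_c: float,
                       tol: float = 1e-10) -> BinodalResult:
    """Pseudo-binary common-tangent construction at fixed ``phi_c``.

    Solves for two protein volume fractions with equal exchange chemical
    potential and equal grand-potential density, started from the spinodal
    interval endpoints.  Raises if no spinodal exists (no coexistence) or the
    two-variable root-finding fails to reach ``|residual| <= 1e-8``.
    """
    sp = spinodal_at_crowder(model, phi_c)
    if sp.stable_everywhere:
        raise ValueError(f"no spinodal at phi_c={phi_c:g}: the homogeneous "
                         "solution is stable; no coexistence to construct")
    sp_lo, sp_hi = sp.spinodal_phi
    hi_max = 1.0 - phi_c - _EPS

    def residuals(z):
        x1, x2 = z
        mu1 = exchange_chemical_potential(model, x1, phi_c)
        mu2 = exchange_chemical_potential(model, x2, phi_c)
        w1 = grand_potential_density(model, x1, phi_c)
        w2 = grand_potential_density(model, x2, phi_c)
        return [mu1 - mu2, w1 - w2]

    starts = [
        (sp_lo * 0.5, sp_hi + 0.5 * (hi_max - sp_hi)),
        (sp_lo * 0.1, sp_hi + 0.9 * (hi_max - sp_hi)),
        (sp_lo * 0.8, sp_hi + 0.2 * (hi_max - sp_hi)),
    ]
    best = None
    for x0 in starts:
        sol = least_squares(
            residuals, x0=x0,
            bounds=([_EPS, sp_hi], [sp_lo, hi_max]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        res = np.abs(sol.fun)
        if best is None or res.max() < best[1]:
            best = (sol, float(res.max()))
        if res.max() <= tol:
            break
    sol, resmax = best
    if resmax > 1e-8:
        raise RuntimeError(
            f"binodal construction did not converge at phi_c={phi_c:g}: "
            f"max residual {resmax:.3e} (mu residual {sol.fun[0]:.3e}, "
            f"omega residual {sol.fun[1]:.3e})")
    x1, x2 = (float(v) for v in sol.x)
    return BinodalResult(
        crowder_level=phi_c, phi_dilute=x1, phi_dense=x2,
        predicted_partition=x2 / x1,
        mu_residual=float(abs(sol.fun[0])),
        omega_residual=float(abs(sol.fun[1])))


def crowding_sweep(model: TernaryModel, phi_c_grid) -> pd.DataFrame:
    """Binodal per crowder level: columns phi_c, csat (= dilute-branch
    protein fraction), phi_dense, partition, error.

    Failures at individual levels are recorded in the ``error`` column
    without aborting the sweep.  Monotonicity diagnostics are attached in
    ``DataFrame.attrs``: ``csat_decreasing`` and ``partition_increasing``
    (strict, over the converged levels).
    """
    rows = []
    for phi_c in np.asarray(phi_c_grid, dtype=float):
        try:
            b = binodal_at_crowder(model, float(phi_c))
            rows.append({"phi_c": phi_c, "csat": b.phi_dilute,
                         "phi_dense": b.phi_dense,
                         "partition": b.predicted_partition, "error": None})
        except (ValueError, RuntimeError) as err:
            rows.append({"phi_c": phi_c, "csat": np.nan,
                         "phi_dense": np.nan, "partition": np.nan,
                         "error": str(err)})
    df = pd.DataFrame(rows)
    ok = df[df["error"].isna()]
    df.attrs["csat_decreasing"] = bool(
        len(ok) >= 2 and np.all(np.diff(ok["csat"]) < 0))
    df.attrs["partition_increasing"] = bool(
        len(ok) >= 2 and np.all(np.diff(ok["partition"]) > 0))
    return df


def depletion_layer_ratio(protein_radius: float,
                          crowder_radius: float) -> DepletionGeometry:
    """Depletion-layer geometry for a protein of radius Rp in a crowder of
    hydrodynamic radius Rc (nm).

    The depletion-layer thickness is proportional to the crowder radius
    (proportionality constant 1 by convention); the Asakura-Oosawa
    overlap-volume factor ``(1 + Rc/Rp)^3 - 1`` maps crowder size to the
    strength of the crowder-mediated attraction (used for ``chi_dep``
    scaling).
    """
    if protein_radius <= 0 or crowder_radius <= 0:
        raise ValueError("radii must be > 0")
    q = crowder_radius / protein_radius
    return DepletionGeometry(layer_thickness=float(crowder_radius),
                             overlap_factor=float((1.0 + q) ** 3 - 1.0))
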