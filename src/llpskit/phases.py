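"""Phase-diagram construction from turbidity and microscopy observations.

Each sample (protein concentration x crowder concentration) is classified as
phase-separated or mixed by a simple binary criterion: turbidity at 350 nm
above a threshold, or droplets visible by microscopy.  When both readouts are
present and disagree, microscopy wins and a conflict is recorded.  The
liquid-liquid coexistence boundary is the saturation concentration ``csat``
per crowder level: the midpoint (geometric by default, since concentration
series in such titrations are log-spaced) between the highest mixed and the
lowest separated protein concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "PhasePoint", "PhaseLabel", "PhaseBoundary", "classify_phase",
    "build_phase_boundary",
]


@dataclass
class PhasePoint:
    """One observation on the protein x crowder grid."""

    protein_conc: float           # uM
    crowder_conc: float           # mg/mL
    a350: float                   # absorbance, 1 mm path
    droplet_flag: bool | None = None   # microscopy, when available
    label: str | None = None      # "separated" | "mixed", set by classify

    def __post_init__(self):
        if self.protein_conc < 0 or self.crowder_conc < 0:
            raise ValueError("concentrations must be >= 0")
        if self.a350 < 0:
            raise ValueError("a350 must be >= 0")


class PhaseLabel(NamedTuple):
    label: str        # "separated" | "mixed"
    conflict: bool    # turbidity and microscopy disagreed


@dataclass
class PhaseBoundary:
    crowder_levels: np.ndarray      # mg/mL
    csat: np.ndarray                # uM; NaN where censored
    censored: list                  # per level: None | "<x" | ">x"
    method: str
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "crowder_mg_ml": self.crowder_levels,
            "csat_uM": self.csat,
            "censored": self.censored,
        })


def classify_phase(point: PhasePoint,
                   turbidity_threshold: float) -> PhaseLabel:
    """Binary phase call for one sample.

    Separated iff turbidity >= threshold or droplets were seen.  Microscopy,
    when present, takes precedence over turbidity; a disagreement between the
    two is flagged as a conflict.
    """
    turbid = point.a350 >= turbidity_threshold
    if point.droplet_flag is None:
        return PhaseLabel("separated" if turbid else "mixed", False)
    label = "separated" if point.droplet_flag else "mixed"
    return PhaseLabel(label, conflict=(turbid != point.droplet_flag))


def build_phase_boundary(points: list[PhasePoint], turbidity_threshold: float,
                         midpoint: str = "geometric") -> PhaseBoundary:
    """Construct the saturation-concentration boundary over crowder levels.

    Per level, ``csat`` is the midpoint between the highest mixed and the
    lowest separated protein concentration.  Levels where every point shares
    one label are censored ("< lowest tested" when all separated, "> highest
    tested" when all mixed).  Non-monotone labels within a level (a mixed
    point above a separated one) produce a warning and ``csat`` falls back to
    the lowest separated concentration.
    """
    if midpoint not in ("geometric", "arithmetic"):
        raise ValueError("midpoint must be 'geometric' or 'arithmetic'")
    if not points:
        raise ValueError("no phase points supplied")

    rows = []
    for p in points:
        lab = classify_phase(p, turbidity_threshold)
        rows.append({"crowder": p.crowder_conc, "protein": p.protein_conc,
                     "separated": lab.label == "separated",
                     "conflict": lab.conflict})
    df = pd.DataFrame(rows)

    levels, csats, censored, warnings = [], [], [], []
    n_conflicts = int(df["conflict"].sum())
    if n_conflicts:
        warnings.append(f"{n_conflicts} turbidity/microscopy conflicts "
                        "(microscopy took precedence)")
    for crowder, grp in df.groupby("crowder", sort=True):
        levels.append(float(crowder))
        sep = grp.loc[grp["separated"], "protein"]
        mix = grp.loc[~grp["separated"], "protein"]
        if sep.empty:
            csats.append(np.nan)
            censored.append(f"> {grp['protein'].max():g}")
            continue
        if mix.empty:
            csats.append(np.nan)
            censored.append(f"< {grp['protein'].min():g}")
            continue
        lo_sep = float(sep.min())
        hi_mix = float(mix.max())
        censored.append(None)
        if hi_mix > lo_sep:
            warnings.append(
                f"non-monotone labels at crowder {crowder:g} mg/mL: mixed at "
                f"{hi_mix:g} uM above separated at {lo_sep:g} uM; csat taken "
                "from the lowest separated point")
            csats.append(lo_sep)
        elif midpoint == "geometric":
            csats.append(float(np.sqrt(hi_mix * lo_sep)))
        else:
            csats.append(0.5 * (hi_mix + lo_sep))

    return PhaseBoundary(
        crowder_levels=np.asarray(levels), csat=np.asarray(csats),
        censored=censored, method=f"{midpoint}-midpoint",
        warnings=warnings)
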