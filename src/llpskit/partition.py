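"""Partition-coefficient analysis of droplet fluorescence images.

The dense-phase partition coefficient of a labeled protein is estimated as the
mean fluorescence intensity inside a droplet divided by the mean background
(dilute-phase) intensity of the same image.  Droplets are segmented by global
Otsu thresholding followed by connected-component labeling, hole filling and
an area filter; the background excludes a 2-px dilation margin around every
droplet.  Conditions are compared pairwise with Welch's unequal-variance
t-test (Mann-Whitney available), with significance stars assigned by fixed
p-value bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk

__all__ = [
    "DropletImage", "SegmentationResult", "PartitionResult",
    "segment_droplets", "partition_coefficient", "compare_conditions",
    "DEFAULT_STAR_BINS",
]


@dataclass
class DropletImage:
    """2-D fluorescence image of phase-separated droplets."""

    pixels: np.ndarray          # 2-D, a.u.
    pixel_size: float           # um / px
    bit_depth: int = 16

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class SegmentationResult:
    labels: np.ndarray          # 0 = background margin or background
    droplets: pd.DataFrame      # label, area_um2, centroid_row/col, mean_intensity
    background_mask: np.ndarray
    background_mean: float
    warnings: list = field(default_factory=list)

    @property
    def n_droplets(self) -> int:
        return len(self.droplets)


@dataclass
class PartitionResult:
    per_droplet_partition: np.ndarray
    n_droplets: int
    mean: float
    sd: float
    condition_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition_label,
            "droplet": np.arange(1, self.n_droplets + 1),
            "partition": self.per_droplet_partition,
        })


def segment_droplets(image: DropletImage, min_area: float = 0.0,
                     max_area: float = np.inf) -> SegmentationResult:
    """Segment droplets by Otsu threshold + connected components.

    ``min_area``/``max_area`` are in um^2.  Background is the complement of
    the 2-px-dilated union of accepted droplets.  A saturated image (>= 1% of
    pixels at the bit-depth maximum) is flagged, not rejected.
    """
    px = image.pixels.astype(float)
    warnings: list[str] = []
    maxval = 2 ** image.bit_depth - 1
    if np.mean(image.pixels >= maxval) >= 0.01:
        warnings.append("saturated image: >=1% of pixels at the bit-depth "
                        "maximum")

    flat = px.ravel()
    if np.ptp(flat) <= 1e-12 * max(1.0, float(np.max(np.abs(flat)))):
        # blank (constant) image: no droplets, everything is background
        empty = pd.DataFrame(columns=["label", "area_um2", "centroid_row",
                                      "centroid_col", "mean_intensity"])
        return SegmentationResult(
            labels=np.zeros_like(px, dtype=int), droplets=empty,
            background_mask=np.ones_like(px, dtype=bool),
            background_mean=float(px.mean()), warnings=warnings)

    thr = threshold_otsu(px)
    mask = px > thr
    mask = ndimage.binary_fill_holes(mask)
    labeled = cc_label(mask)
    px_area = image.pixel_size ** 2

    rows = []
    keep = np.zeros_like(mask, dtype=bool)
    out_labels = np.zeros_like(labeled)
    next_label = 0
    for prop in regionprops(labeled, intensity_image=px):
        area_um2 = prop.area * px_area
        if not (min_area <= area_um2 <= max_area):
            continue
        next_label += 1
        region = labeled == prop.label
        keep |= region
        out_labels[region] = next_label
        rows.append({
            "label": next_label,
            "area_um2": area_um2,
            "centroid_row": prop.centroid[0],
            "centroid_col": prop.centroid[1],
            "mean_intensity": prop.intensity_mean,
        })
    droplets = pd.DataFrame(
        rows, columns=["label", "area_um2", "centroid_row", "centroid_col",
                       "mean_intensity"])

    background_mask = ~ndimage.binary_dilation(keep, structure=disk(2))
    if not background_mask.any():
        raise ValueError("no background pixels left after droplet dilation")
    return SegmentationResult(
        labels=out_labels, droplets=droplets,
        background_mask=background_mask,
        background_mean=float(px[background_mask].mean()),
        warnings=warnings)


def partition_coefficient(seg: SegmentationResult,
                          condition_label: str = "") -> PartitionResult:
    """Per-droplet partition = droplet mean intensity / background mean."""
    if seg.n_droplets < 1:
        raise ValueError("no droplets segmented")
    if seg.background_mean <= 0:
        raise ValueError("background mean intensity is zero")
    ratios = seg.droplets["mean_intensity"].to_numpy() / seg.background_mean
    return PartitionResult(
        per_droplet_partition=ratios, n_droplets=len(ratios),
        mean=float(np.mean(ratios)),
        sd=float(np.std(ratios, ddof=1)) if len(ratios) >= 2 else 0.0,
        condition_label=condition_label)


# p-value bins for significance stars, exactly as printed in the source
# figure convention: * (0.01, 0.1], ** (0.001, 0.01], *** (0.0001, 0.001],
# **** < 0.0001.
DEFAULT_STAR_BINS = ((0.1, "*"), (0.01, "**"), (0.001, "***"),
                     (0.0001, "****"))


def stars_for_p(p: float, bins=DEFAULT_STAR_BINS) -> str:
    if np.isnan(p):
        return "n.d."
    label = "ns"
    for upper, star in bins:
        if p <= upper:
            label = star
    return label


def compare_conditions(groups: list[PartitionResult], test: str = "welch",
                       holm: bool = False,
                       star_bins=DEFAULT_STAR_BINS) -> pd.DataFrame:
    """Pairwise two-sided comparison of partition distributions.

    ``test`` is ``"welch"`` (unequal-variance t-test, default) or
    ``"mannwhitney"``.  Optional Holm correction across the pairs.  Returns a
    DataFrame with columns condition_a, condition_b, p_value, stars.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n_droplets < 3:
            raise ValueError(f"group {g.condition_label!r} has n < 3")
    if test not in ("welch", "mannwhitney"):
        raise ValueError("test must be 'welch' or 'mannwhitney'")

    rows = []
    for ga, gb in combinations(groups, 2):
        a = ga.per_droplet_partition
        b = gb.per_droplet_partition
        if np.array_equal(np.sort(a), np.sort(b)) and np.ptp(a) == 0:
            # fully tied identical groups: no evidence of difference
            p = 1.0
        elif test == "welch":
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float(stats.mannwhitneyu(a, b,
                                         alternative="two-sided").pvalue)
        rows.append({"condition_a": ga.condition_label,
                     "condition_b": gb.condition_label, "p_value": p})
    df = pd.DataFrame(rows)
    if holm:
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        df["p_value"] = adj
    df["stars"] = [stars_for_p(p, star_bins) for p in df["p_value"]]
    return df
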