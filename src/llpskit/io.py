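"""File formats: CSV traces/grids, JSON sidecars and results, TIFF/PNG images.

All writes are atomic (temp file in the destination directory, then rename),
and every JSON result embeds the configuration, seed and package version that
produced it so outputs are self-describing.
"""

from __future__ import annotations

import json
import os
import tempfile
from io import BytesIO
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .frap import BleachProfile, FrapTrace
from .fusion import FusionTrace
from .partition import DropletImage
from .phases import PhasePoint

__all__ = [
    "atomic_write_text", "atomic_write_bytes", "write_json_result",
    "write_frap_trace", "read_frap_trace", "write_bleach_profile",
    "read_bleach_profile", "write_fusion_trace", "read_fusion_trace",
    "write_droplet_image", "read_droplet_image", "write_phase_points",
    "read_phase_points",
]


def _atomic(path, data: bytes):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_bytes(path, data: bytes) -> None:
    _atomic(path, data)


def atomic_write_text(path, text: str) -> None:
    _atomic(path, text.encode())


def write_json_result(path, payload: dict, config: dict | None = None,
                      seed: int | None = None) -> None:
    """Write a self-describing JSON result (embeds config, seed, version)."""
    doc = {"llpskit_version": __version__, "seed": seed,
           "config": config or {}, **payload}
    atomic_write_text(path, json.dumps(doc, indent=2, sort_keys=False,
                                       default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# FRAP traces and profiles
# ---------------------------------------------------------------------------

def write_frap_trace(path, trace: FrapTrace, sidecar: dict | None = None):
    """CSV with columns time_s, intensity_bleach, intensity_ref,
    intensity_bg; metadata (bleach frame, nominal radius) in a .json
    sidecar."""
    df = pd.DataFrame({
        "time_s": trace.time,
        "intensity_bleach": trace.intensity_bleach,
        "intensity_ref": trace.intensity_ref,
        "intensity_bg": trace.intensity_bg,
    })
    atomic_write_text(path, df.to_csv(index=False, float_format="%.10g"))
    meta = {"bleach_frame_index": int(trace.bleach_frame_index),
            "nominal_radius_rn_um": float(trace.nominal_radius_rn)}
    if sidecar:
        meta.update(sidecar)
    atomic_write_text(Path(path).with_suffix(".json"),
                      json.dumps(meta, indent=2, default=_jsonable) + "\n")


def read_frap_trace(path, bleach_frame_index: int | None = None,
                    nominal_radius_rn: float | None = None) -> FrapTrace:
    df = pd.read_csv(path)
    meta_path = Path(path).with_suffix(".json")
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    if bleach_frame_index is None:
        bleach_frame_index = meta["bleach_frame_index"]
    if nominal_radius_rn is None:
        nominal_radius_rn = meta["nominal_radius_rn_um"]
    return FrapTrace(
        time=df["time_s"].to_numpy(),
        intensity_bleach=df["intensity_bleach"].to_numpy(),
        intensity_ref=df["intensity_ref"].to_numpy(),
        intensity_bg=df["intensity_bg"].to_numpy(),
        bleach_frame_index=int(bleach_frame_index),
        nominal_radius_rn=float(nominal_radius_rn))


def write_bleach_profile(path, profile: BleachProfile):
    df = pd.DataFrame({"x_um": profile.x_um, "intensity": profile.intensity})
    atomic_write_text(path, df.to_csv(index=False, float_format="%.10g"))


def read_bleach_profile(path) -> BleachProfile:
    df = pd.read_csv(path)
    return BleachProfile(x_um=df["x_um"].to_numpy(),
                         intensity=df["intensity"].to_numpy())


# ---------------------------------------------------------------------------
# fusion traces
# ---------------------------------------------------------------------------

def write_fusion_trace(path, trace: FusionTrace):
    """CSV with columns time_s, force_pN; radii/rate/condition in a .json
    sidecar."""
    df = pd.DataFrame({"time_s": trace.time, "force_pN": trace.force})
    atomic_write_text(path, df.to_csv(index=False, float_format="%.10g"))
    meta = {"sampling_rate_hz": float(trace.sampling_rate),
            "radius_1_um": float(trace.radius_1),
            "radius_2_um": float(trace.radius_2),
            "condition_label": trace.condition_label}
    atomic_write_text(Path(path).with_suffix(".json"),
                      json.dumps(meta, indent=2) + "\n")


def read_fusion_trace(path) -> FusionTrace:
    df = pd.read_csv(path)
    meta = json.loads(Path(path).with_suffix(".json").read_text())
    return FusionTrace(
        time=df["time_s"].to_numpy(), force=df["force_pN"].to_numpy(),
        sampling_rate=meta["sampling_rate_hz"],
        radius_1=meta["radius_1_um"], radius_2=meta["radius_2_um"],
        condition_label=meta.get("condition_label", ""))


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_droplet_image(path, image: DropletImage):
    """16-bit TIFF; pixel size recorded in a .json sidecar."""
    px = np.clip(np.round(image.pixels), 0, 2 ** 16 - 1).astype(np.uint16)
    buf = BytesIO()
    tifffile.imwrite(buf, px)
    atomic_write_bytes(path, buf.getvalue())
    atomic_write_text(Path(path).with_suffix(".json"),
                      json.dumps({"pixel_size_um": image.pixel_size,
                                  "bit_depth": 16}, indent=2) + "\n")


def read_droplet_image(path, pixel_size: float | None = None) -> DropletImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    if px.ndim == 3:  # collapse RGB(A) PNGs to grayscale by channel mean
        px = px[..., :3].mean(axis=-1)
    meta_path = path.with_suffix(".json")
    bit_depth = 16 if px.dtype.itemsize > 1 else 8
    if pixel_size is None:
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            pixel_size = meta.get("pixel_size_um", 1.0)
            bit_depth = meta.get("bit_depth", bit_depth)
        else:
            pixel_size = 1.0
    return DropletImage(pixels=px.astype(float), pixel_size=float(pixel_size),
                        bit_depth=int(bit_depth))


# ---------------------------------------------------------------------------
# phase points
# ---------------------------------------------------------------------------

def write_phase_points(path, points: list[PhasePoint]):
    """CSV with columns protein_uM, crowder_mg_ml, a350, droplet_flag."""
    df = pd.DataFrame({
        "protein_uM": [p.protein_conc for p in points],
        "crowder_mg_ml": [p.crowder_conc for p in points],
        "a350": [p.a350 for p in points],
        "droplet_flag": ["" if p.droplet_flag is None else p.droplet_flag
                         for p in points],
    })
    atomic_write_text(path, df.to_csv(index=False, float_format="%.10g"))


def read_phase_points(path) -> list[PhasePoint]:
    df = pd.read_csv(path)
    points = []
    for _, row in df.iterrows():
        flag = row.get("droplet_flag", None)
        if flag is None or (isinstance(flag, float) and np.isnan(flag)) \
                or flag == "":
            flag = None
        else:
            flag = str(flag).strip().lower() in ("true", "1", "yes")
        points.append(PhasePoint(
            protein_conc=float(row["protein_uM"]),
            crowder_conc=float(row["crowder_mg_ml"]),
            a350=float(row["a350"]), droplet_flag=flag))
    return points
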