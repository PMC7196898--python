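"""File I/O: multi-page TIFF stacks with JSON sidecars, CSV traces/tables.

All on-disk formats are plain text or standard TIFF so that fixtures and
results can be inspected with any imaging or spreadsheet tool.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidArgumentError
from .image_quant import ImageStack, SpotSet, _SPOT_COLUMNS
from .kinetics import FrapTrace, LumTrace
from .photophysics import DecayHistogram

__all__ = [
    "write_stack",
    "read_stack",
    "write_decay_csv",
    "read_decay_csv",
    "write_frap_csv",
    "read_frap_csv",
    "write_lum_csv",
    "read_lum_csv",
    "write_spots_csv",
    "read_spots_csv",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as multi-page TIFF (one page per z) + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "pixel_size_xy_um": stack.pixel_size_xy,
        "z_step_um": stack.z_step,
        "channel_name": stack.channel_name,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path) -> ImageStack:
    path = Path(path)
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[None, :, :]
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ImageStack(
        voxels=np.asarray(voxels, dtype=float),
        pixel_size_xy=meta.get("pixel_size_xy_um", 0.1),
        z_step=meta.get("z_step_um", 0.5),
        channel_name=meta.get("channel_name", ""),
    )


def write_decay_csv(hist: DecayHistogram, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_ns": hist.bin_centers, "counts": hist.counts})
    df.attrs["repetition_period_ns"] = hist.repetition_period
    with open(path, "w") as fh:
        fh.write(f"# repetition_period_ns={hist.repetition_period}\n")
        df.to_csv(fh, index=False)
    return path


def read_decay_csv(path) -> DecayHistogram:
    path = Path(path)
    period = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "repetition_period_ns=" in first:
            period = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if not {"time_ns", "counts"} <= set(df.columns):
        raise InvalidArgumentError(f"{path} lacks time_ns/counts columns")
    t = df["time_ns"].to_numpy(dtype=float)
    if period is None:
        period = float(t[-1] - t[0] + (t[1] - t[0]))
    return DecayHistogram(bin_centers=t, counts=df["counts"].to_numpy(),
                          repetition_period=period)


def write_frap_csv(trace: FrapTrace, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "bleach_roi": trace.bleach_roi,
            "background_roi": trace.background_roi,
            "reference_roi": trace.reference_roi,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# bleach_frame_index={trace.bleach_frame_index}\n")
        df.to_csv(fh, index=False)
    return path


def read_frap_csv(path) -> FrapTrace:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "bleach_frame_index=" in first:
            k = int(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            raise InvalidArgumentError(f"{path} lacks bleach_frame_index header")
    return FrapTrace(
        time=df["time_s"].to_numpy(),
        bleach_roi=df["bleach_roi"].to_numpy(),
        background_roi=df["background_roi"].to_numpy(),
        reference_roi=df["reference_roi"].to_numpy(),
        bleach_frame_index=k,
    )


def write_lum_csv(traces, path) -> Path:
    """Write one or more luminescence traces in long format."""
    if isinstance(traces, LumTrace):
        traces = [traces]
    rows = []
    for tr in traces:
        for t, y in zip(tr.time, tr.rlu):
            rows.append(
                {"well_id": tr.well_id, "genotype": tr.genotype,
                 "treatment": tr.treatment, "time_min": t, "rlu": y}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_lum_csv(path) -> list:
    df = pd.read_csv(path)
    traces = []
    for well, sub in df.groupby("well_id", sort=False):
        sub = sub.sort_values("time_min")
        traces.append(
            LumTrace(
                time=sub["time_min"].to_numpy(),
                rlu=sub["rlu"].to_numpy(),
                well_id=str(well),
                treatment=str(sub["treatment"].iloc[0]),
                genotype=str(sub["genotype"].iloc[0]),
            )
        )
    return traces


def write_spots_csv(spots: SpotSet, path, image_id: str = "") -> Path:
    df = spots.spots.copy()
    df.insert(0, "image_id", image_id)
    df.to_csv(path, index=False)
    return Path(path)


def read_spots_csv(path) -> SpotSet:
    df = pd.read_csv(path)
    return SpotSet(df[_SPOT_COLUMNS].copy())
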