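"""File conventions for raw instrument artifacts.

Everything is plain text: CSV for traces and plates, two-column whitespace
text for spectra, multi-page TIFF plus a YAML sidecar for voxel volumes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .assay import PlateAssay
from .indentation import NanoPHCurve
from .mechanics import LoadDisplacementTrace
from .microct import VoxelVolume
from .spectra import Spectrum

__all__ = [
    "write_trace",
    "read_trace",
    "write_rpi",
    "read_rpi",
    "write_nano",
    "read_nano",
    "write_spectrum",
    "read_spectrum",
    "write_plate",
    "read_plate",
    "write_volume",
    "read_volume",
]


def write_trace(path, trace: LoadDisplacementTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "load_N": trace.load, "disp_mm": trace.displacement}
    ).to_csv(path, index=False, float_format="%.8g")


def read_trace(path, span: float = 19.0, preload: float = 10.0,
               rate: float = 10.0) -> LoadDisplacementTrace:
    df = pd.read_csv(path)
    return LoadDisplacementTrace(
        time=df["time_s"].to_numpy(),
        load=df["load_N"].to_numpy(),
        displacement=df["disp_mm"].to_numpy(),
        span=span,
        preload=preload,
        rate=rate,
    )


def write_rpi(path, force: np.ndarray, depth: np.ndarray, cycle: np.ndarray) -> None:
    pd.DataFrame(
        {"cycle": cycle, "force_N": force, "depth_um": depth}
    ).to_csv(path, index=False, float_format="%.8g")


def read_rpi(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (
        df["force_N"].to_numpy(),
        df["depth_um"].to_numpy(),
        df["cycle"].to_numpy(),
    )


def write_nano(path, curve: NanoPHCurve) -> None:
    pd.DataFrame(
        {"segment": curve.segment, "load_uN": curve.load, "depth_nm": curve.depth}
    ).to_csv(path, index=False, float_format="%.10g")


def read_nano(path, P_max: float = 1000.0) -> NanoPHCurve:
    df = pd.read_csv(path)
    return NanoPHCurve(
        load=df["load_uN"].to_numpy(),
        depth=df["depth_nm"].to_numpy(),
        segment=df["segment"].to_numpy(),
        P_max=P_max,
    )


def write_spectrum(path, s: Spectrum) -> None:
    np.savetxt(path, np.column_stack([s.x, s.y]), fmt="%.8g",
               header=f"kind: {s.kind}")


def read_spectrum(path, kind: str | None = None) -> Spectrum:
    text = Path(path).read_text().splitlines()
    if kind is None:
        kind = "ftir"
        for line in text:
            if line.startswith("#") and "kind:" in line:
                kind = line.split("kind:")[1].strip()
                break
    data = np.loadtxt(path)
    return Spectrum(x=data[:, 0], y=data[:, 1], kind=kind)


def write_plate(path, plate: PlateAssay) -> None:
    rows = [
        {"well": f"S{i+1}", "role": "standard", "concentration": c,
         "reading": r, "dilution": 1.0}
        for i, (c, r) in enumerate(plate.standards)
    ]
    rows += [
        {"well": sid, "role": "sample", "concentration": np.nan,
         "reading": r, "dilution": d}
        for sid, r, d in plate.samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def read_plate(path, mode: str = "fluorescence_360_460") -> PlateAssay:
    df = pd.read_csv(path)
    std = df[df["role"] == "standard"]
    smp = df[df["role"] == "sample"]
    return PlateAssay(
        standards=list(zip(std["concentration"], std["reading"])),
        samples=list(zip(smp["well"], smp["reading"], smp["dilution"])),
        mode=mode,
    )


def write_volume(path, v: VoxelVolume) -> None:
    """Multi-page TIFF (uint8 for binary, float32 for gray) + YAML sidecar."""
    path = Path(path)
    data = v.values
    arr = data.astype(np.uint8) if data.dtype == bool else data.astype(np.float32)
    tifffile.imwrite(path, arr)
    sidecar = {
        "voxel_size_um": float(v.voxel_size_um),
        "binary": bool(data.dtype == bool),
        "threshold": None if v.threshold is None else float(v.threshold),
        "roi": v.roi,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))


def read_volume(path) -> VoxelVolume:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    arr = tifffile.imread(path)
    if meta.get("binary", False):
        arr = arr.astype(bool)
    return VoxelVolume(
        values=arr,
        voxel_size_um=meta["voxel_size_um"],
        threshold=meta.get("threshold"),
        roi=meta.get("roi") or {},
    )
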