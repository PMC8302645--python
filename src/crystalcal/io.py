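"""Standard-format I/O: multi-page TIFF stacks, CSV tables, JSON reports.

Voxel sizes travel with a stack in two redundant places: ImageJ-convention
TIFF resolution metadata (XResolution/YResolution in pixels per micron,
plane spacing in the ImageJ description) and a JSON sidecar next to the
file.  On read the sources are checked against each other and an optional
override; any >1 % disagreement is an error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import ImageStack, ParticleSet

__all__ = [
    "write_stack",
    "read_stack",
    "write_particles",
    "read_particles",
    "write_spectrum",
    "read_spectrum",
    "write_json",
]

SIDE_SUFFIX = ".json"


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF with ImageJ resolution metadata
    plus a JSON sidecar carrying voxel sizes (nm) and the origin."""
    path = Path(path)
    dz, dy, dx = stack.voxel
    tifffile.imwrite(
        path,
        stack.data,
        imagej=stack.data.dtype in (np.dtype("uint8"), np.dtype("uint16"), np.dtype("float32")),
        resolution=(1e3 / dx, 1e3 / dy),  # pixels per micron
        metadata={"spacing": dz / 1e3, "unit": "um", "axes": "ZYX"},
    )
    sidecar = {
        "voxel_nm": [dz, dy, dx],
        "origin_nm": list(stack.origin),
        "axes": "ZYX",
    }
    path.with_suffix(path.suffix + SIDE_SUFFIX).write_text(json.dumps(sidecar, indent=1))
    return path


def _voxel_from_tags(tif: tifffile.TiffFile) -> tuple | None:
    page = tif.pages[0]
    tags = page.tags
    try:
        xres = tags["XResolution"].value
        yres = tags["YResolution"].value
    except KeyError:
        return None
    dx = 1e3 * xres[1] / xres[0]  # pixels/um -> nm/px
    dy = 1e3 * yres[1] / yres[0]
    dz = None
    if tif.imagej_metadata and "spacing" in tif.imagej_metadata:
        dz = float(tif.imagej_metadata["spacing"]) * 1e3
    if dz is None:
        return None
    return (dz, dy, dx)


def read_stack(path: str | Path, voxel_override: tuple | None = None) -> ImageStack:
    """Read a multi-page TIFF stack.

    Voxel sizes are taken from TIFF metadata, then the JSON sidecar, then
    ``voxel_override``, in that priority; sources that disagree by more
    than 1 % raise, and a stack with no voxel information at all raises.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tag_voxel = _voxel_from_tags(tif)
    if data.ndim == 2:
        data = data[None]

    sidecar_path = path.with_suffix(path.suffix + SIDE_SUFFIX)
    side_voxel = None
    origin = (0.0, 0.0, 0.0)
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        side_voxel = tuple(float(v) for v in meta["voxel_nm"])
        origin = tuple(float(v) for v in meta.get("origin_nm", origin))

    sources = [
        ("tiff-metadata", tag_voxel),
        ("sidecar", side_voxel),
        ("override", tuple(voxel_override) if voxel_override else None),
    ]
    present = [(n, v) for n, v in sources if v is not None]
    if not present:
        raise ValueError(f"{path}: no voxel size in TIFF tags, sidecar or override")
    for (na, va), (nb, vb) in zip(present, present[1:]):
        for ax, (a, b) in enumerate(zip(va, vb)):
            if abs(a - b) > 0.01 * max(abs(a), abs(b)):
                raise ValueError(
                    f"{path}: voxel size conflict on axis {'zyx'[ax]}: "
                    f"{na} says {a} nm but {nb} says {b} nm"
                )
    voxel = present[0][1]
    return ImageStack(data=data, voxel=voxel, origin=origin)


PARTICLE_COLUMNS = ["z_nm", "y_nm", "x_nm", "core_type", "core_diameter_nm", "layer_index"]


def write_particles(particles: ParticleSet, path: str | Path) -> Path:
    path = Path(path)
    n = len(particles)
    df = pd.DataFrame(
        {
            "z_nm": particles.centers[:, 0],
            "y_nm": particles.centers[:, 1],
            "x_nm": particles.centers[:, 2],
            "core_type": particles.core_type,
            "core_diameter_nm": particles.core_diameter,
            "layer_index": (
                particles.layer_index if particles.layer_index is not None else [-1] * n
            ),
        }
    )
    df.to_csv(path, index=False)
    return path


def read_particles(path: str | Path) -> ParticleSet:
    df = pd.read_csv(path)
    missing = [c for c in PARTICLE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    layer = None
    if "layer_index" in df.columns and not (df["layer_index"] < 0).all():
        layer = df["layer_index"].to_numpy()
    return ParticleSet(
        centers=df[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float),
        core_type=df["core_type"].to_numpy(dtype=object),
        core_diameter=df["core_diameter_nm"].to_numpy(dtype=float),
        layer_index=layer,
    )


def write_spectrum(wavenumber: np.ndarray, intensity: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"wavenumber_cm-1": wavenumber, "intensity": intensity}).to_csv(
        path, index=False
    )
    return path


def read_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: expected 2 columns (wavenumber, intensity)")
    return df[cols[0]].to_numpy(dtype=float), df[cols[1]].to_numpy(dtype=float)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=_default))
    return path
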