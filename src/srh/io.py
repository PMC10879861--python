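"""Readers and writers for cubes, spectra libraries, maps, and renders.

Formats are deliberately desk-scale and lossless: hyperspectral cubes are
multi-page grayscale TIFF stacks (one page per Raman shift, float32) paired
with a JSON sidecar carrying the wavenumber axis, pixel size and free-form
provenance; reference libraries are CSV with a ``wavenumber_cm1`` column and
one intensity column per component; concentration maps are one float32 TIFF
per component plus a JSON manifest recording λ, the normalization tag and
the channel subset, so every map is reproducible from its inputs; rendered
RGB images are 8-bit PNG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import (
    ChannelSubset,
    ConcentrationMaps,
    HyperspectralCube,
    ReferenceLibrary,
    WavenumberAxis,
)

__all__ = [
    "CubeSidecar",
    "read_cube",
    "write_cube",
    "read_library",
    "write_library",
    "write_maps",
    "read_maps",
    "write_rgb_png",
    "write_subset",
    "read_subset",
]


@dataclass
class CubeSidecar:
    """JSON metadata paired with a TIFF stack."""

    shifts_cm1: list[float]
    pixel_size_um: float = 0.5
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"shifts_cm1": self.shifts_cm1, "pixel_size_um": self.pixel_size_um,
             "provenance": self.provenance},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CubeSidecar":
        obj = json.loads(text)
        return cls(list(obj["shifts_cm1"]), float(obj.get("pixel_size_um", 0.5)),
                   dict(obj.get("provenance", {})))


def read_cube(stack_path, sidecar_path) -> HyperspectralCube:
    """Load a cube from a multi-page TIFF + JSON sidecar.

    Pages map to channels in sidecar order; data is promoted to float.
    """
    sidecar = CubeSidecar.from_json(Path(sidecar_path).read_text())
    pages = np.asarray(tifffile.imread(stack_path))
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.ndim != 3:
        raise ValueError("TIFF stack is not a stack of grayscale pages")
    if pages.shape[0] != len(sidecar.shifts_cm1):
        raise ValueError(
            f"page count {pages.shape[0]} does not match sidecar axis length "
            f"{len(sidecar.shifts_cm1)}"
        )
    data = np.moveaxis(pages.astype(float), 0, 2)
    axis = WavenumberAxis(sidecar.shifts_cm1)
    return HyperspectralCube(data, axis, sidecar.pixel_size_um, dict(sidecar.provenance))


def write_cube(cube: HyperspectralCube, stack_path, sidecar_path) -> None:
    """Persist a cube as float32 TIFF pages + JSON sidecar."""
    pages = np.moveaxis(cube.data, 2, 0).astype(np.float32)
    tifffile.imwrite(stack_path, pages, photometric="minisblack")
    sidecar = CubeSidecar(list(cube.axis.shifts), cube.pixel_size_um,
                          dict(cube.provenance))
    Path(sidecar_path).write_text(sidecar.to_json())


def read_library(csv_path) -> ReferenceLibrary:
    """Load a reference library from CSV (``wavenumber_cm1`` + one column per component).

    Spectra are unit-L2-normalized on read; column order is component order.
    """
    # round_trip parsing: the wavenumber axis must compare exactly equal to
    # the axis stored in a cube's JSON sidecar
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if df.columns[0] != "wavenumber_cm1":
        raise ValueError("first CSV column must be 'wavenumber_cm1'")
    if df.shape[1] < 2:
        raise ValueError("library CSV needs at least one component column")
    shifts = df["wavenumber_cm1"].to_numpy(dtype=float)
    if np.any(np.diff(shifts) <= 0):
        raise ValueError("wavenumber column must be strictly increasing")
    names = tuple(df.columns[1:])
    spectra = df[list(names)].to_numpy(dtype=float).T
    if np.any(spectra < 0):
        raise ValueError("negative reference intensity in CSV")
    return ReferenceLibrary.from_raw(names, spectra, WavenumberAxis(shifts))


def write_library(library: ReferenceLibrary, csv_path) -> None:
    df = pd.DataFrame({"wavenumber_cm1": library.axis.as_array()})
    for i, name in enumerate(library.names):
        df[name] = library.spectra[i]
    df.to_csv(csv_path, index=False, float_format="%.17g")


def write_maps(maps: ConcentrationMaps, out_dir) -> list[Path]:
    """Write one float32 TIFF per component plus ``manifest.json``.

    Refuses maps violating the non-negativity invariant.
    """
    if np.any(maps.data < 0):
        raise ValueError("refusing to write maps with negative abundances")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for i, name in enumerate(maps.names):
        path = out / f"{name}.tif"
        tifffile.imwrite(path, maps.data[:, :, i].astype(np.float32))
        written.append(path)
    manifest = {
        "names": list(maps.names),
        "lam": maps.meta.get("lam"),
        "normalization": maps.meta.get("normalization"),
        "channel_subset_cm1": list(maps.axis_used.shifts) if maps.axis_used else None,
        "meta": {k: v for k, v in maps.meta.items()
                 if isinstance(v, (int, float, str, bool, list, type(None)))},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written.append(manifest_path)
    return written


def read_maps(in_dir) -> ConcentrationMaps:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    names = tuple(manifest["names"])
    planes = [np.asarray(tifffile.imread(in_dir / f"{n}.tif"), dtype=float) for n in names]
    data = np.stack(planes, axis=2)
    return ConcentrationMaps(data, names, None, dict(manifest.get("meta", {})))


def write_rgb_png(rgb: np.ndarray, path) -> None:
    """Save an H×W×3 float image in [0,1] as 8-bit PNG."""
    arr = np.clip(np.asarray(rgb), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


def write_subset(subset: ChannelSubset, path) -> None:
    obj = {
        "indices": list(subset.indices),
        "shifts_cm1": list(subset.shifts),
        "trace": [{"eliminated_index": i, "mse": m} for i, m in subset.trace],
    }
    Path(path).write_text(json.dumps(obj, indent=2))


def read_subset(path) -> ChannelSubset:
    obj = json.loads(Path(path).read_text())
    trace = tuple((t["eliminated_index"], t["mse"]) for t in obj.get("trace", []))
    return ChannelSubset(tuple(obj["indices"]), tuple(obj["shifts_cm1"]), trace)
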