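"""Raster stack container and TIFF persistence.

A :class:`RasterStack` holds the co-registered 30-m grids the landscape
model consumes: a per-step binary surface-water mask, per-step temperature
and NDVI grids, and a static land-cover grid, plus geotransform/CRS
metadata.  Grids are written one single-band TIFF per variable per time
step, with the georeferencing and the step index stored as JSON in the TIFF
ImageDescription tag so the round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["RasterStack", "read_raster", "write_raster", "AlignmentError"]

#: land-cover codes used in the static grid
LAND_COVER_CODES = {0: "grassland", 1: "cropland"}


class AlignmentError(ValueError):
    """Grids in a stack are not co-registered."""


@dataclass(frozen=True)
class RasterStack:
    """Co-registered dynamic and static grids for one region and season.

    ``water_mask``, ``temperature`` and ``ndvi`` are ``(n_steps, ny, nx)``;
    ``land_cover`` is ``(ny, nx)`` with codes from :data:`LAND_COVER_CODES`.
    """

    water_mask: np.ndarray
    temperature: np.ndarray
    ndvi: np.ndarray
    land_cover: np.ndarray
    pixel_size: float = 30.0
    step_length_days: int = 14
    origin: tuple[float, float] = (0.0, 0.0)  # (x of left edge, y of top edge)
    crs: str = "EPSG:5070"

    def __post_init__(self) -> None:
        wm = np.asarray(self.water_mask)
        if wm.ndim != 3:
            raise AlignmentError("water_mask must be (n_steps, ny, nx)")
        shape = wm.shape
        for name in ("temperature", "ndvi"):
            g = np.asarray(getattr(self, name))
            if g.shape != shape:
                raise AlignmentError(
                    f"{name} shape {g.shape} != water_mask shape {shape}")
        if np.asarray(self.land_cover).shape != shape[1:]:
            raise AlignmentError("land_cover grid is not co-registered")

    @property
    def n_steps(self) -> int:
        return self.water_mask.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.water_mask.shape[1:]

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size**2

    def with_temperature(self, temperature: np.ndarray) -> "RasterStack":
        return replace(self, temperature=temperature)

    # ---- persistence -------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"pixel_size": self.pixel_size, "origin": list(self.origin),
                "crs": self.crs, "step_length_days": self.step_length_days}
        for s in range(self.n_steps):
            write_raster(self.water_mask[s].astype(np.uint8),
                         directory / f"water_{s:03d}.tif", step=s, **meta)
            write_raster(self.temperature[s].astype(np.float32),
                         directory / f"temperature_{s:03d}.tif", step=s, **meta)
            write_raster(self.ndvi[s].astype(np.float32),
                         directory / f"ndvi_{s:03d}.tif", step=s, **meta)
        write_raster(self.land_cover.astype(np.uint8),
                     directory / "land_cover.tif", **meta)

    @classmethod
    def load(cls, directory: str | Path) -> "RasterStack":
        directory = Path(directory)
        paths = sorted(directory.glob("water_*.tif"))
        if not paths:
            raise FileNotFoundError(f"no water_*.tif under {directory}")
        water, temp, ndvi = [], [], []
        meta = {}
        for p in paths:
            s = p.stem.split("_")[1]
            g, meta = read_raster(p)
            water.append(g)
            temp.append(read_raster(directory / f"temperature_{s}.tif")[0])
            ndvi.append(read_raster(directory / f"ndvi_{s}.tif")[0])
        lc, _ = read_raster(directory / "land_cover.tif")
        return cls(
            water_mask=np.stack(water), temperature=np.stack(temp),
            ndvi=np.stack(ndvi), land_cover=lc,
            pixel_size=meta["pixel_size"], origin=tuple(meta["origin"]),
            crs=meta["crs"], step_length_days=meta["step_length_days"],
        )


def write_raster(grid: np.ndarray, path: str | Path, *, pixel_size: float = 30.0,
                 origin: tuple[float, float] = (0.0, 0.0), crs: str = "EPSG:5070",
                 step: int | None = None, step_length_days: int = 14,
                 nodata: float | None = None) -> None:
    """Write one single-band grid as TIFF with JSON georeferencing metadata."""
    desc = {"pixel_size": pixel_size, "origin": list(origin), "crs": crs,
            "step_length_days": step_length_days}
    if step is not None:
        desc["step"] = int(step)
    if nodata is not None:
        desc["nodata"] = float(nodata)
    tifffile.imwrite(Path(path), np.asarray(grid), description=json.dumps(desc))


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a grid written by :func:`write_raster`; returns (array, metadata)."""
    with tifffile.TiffFile(Path(path)) as tf:
        page = tf.pages[0]
        grid = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return grid, meta
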