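"""Synthetic 30-m wetlandscape generator with known ground truth.

Places disjoint elliptical depressional wetlands on a grid, the size
distribution log-normal and dominated by sub-hectare basins as in the
prairie-pothole landscape.  Each wetland owns an exact, deterministic pixel
footprint (the ``area_px`` pixels of smallest normalized elliptical radius),
and a seasonal wetted-fraction trajectory: at each biweekly step the wettest
``round(frac * area_px)`` pixels — deepest first — are inundated, so wet
masks at any two steps are nested (a pixel wet in a dry step is wet in any
wetter step).  A global ``wetness`` multiplier scales all trajectories,
giving dry/wet "bookend" landscapes that share identical wetland objects.

NDVI is elevated in an emergent-vegetation ring around each wetland and
negative over open water; temperature follows a regional seasonal sinusoid
with a north-south gradient; land cover is a two-class (grassland/cropland)
mosaic from a smoothed random field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .rasters import RasterStack

__all__ = ["WetlandscapeConfig", "WetlandscapeTruth", "generate_wetlandscape"]


class PlacementError(RuntimeError):
    """Could not place the requested wetlands on the grid."""


@dataclass(frozen=True)
class WetlandscapeConfig:
    grid_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 30.0
    n_wetlands: int = 300
    #: log-normal size distribution (ha); majority of basins < 1 ha
    size_median_ha: float = 0.5
    size_log_sigma: float = 1.2
    #: explicit wetland sizes (ha) overriding the log-normal draw
    fixed_sizes_ha: tuple | None = None
    n_steps: int = 19  #: biweekly steps covering the frost-free season
    step_length_days: int = 14
    #: global multiplier on wetted fractions (dry/wet bookend lever)
    wetness: float = 1.0
    # wetted-fraction trajectory: base + amp * sin(pi s / (S-1))
    wet_frac_base: float = 0.55
    wet_frac_amp: float = 0.25
    wet_frac_size_coupling: float = 0.10  #: larger wetlands hold water longer
    wet_frac_sd: float = 0.08
    # temperature field
    temp_base: float = 6.0
    temp_amp: float = 12.0
    temp_step_sd: float = 0.8
    temp_ns_gradient: float = 3.0  #: degC from top (cool) to bottom (warm) row
    # NDVI
    ndvi_upland: float = 0.30
    ndvi_ring: float = 0.65
    ndvi_open_water: float = -0.20
    ndvi_noise_sd: float = 0.03
    land_cover_smoothing_px: float = 8.0
    max_place_attempts: int = 200

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 64:
            raise ValueError("grid must be at least 64x64")
        if self.n_steps < 2:
            raise ValueError("need at least two time steps")
        if not (0 < self.wetness <= 1.5):
            raise ValueError("wetness multiplier out of range")


@dataclass(frozen=True)
class WetlandscapeTruth:
    """Synthetic landscape with generating metadata.

    ``wetland_table`` has one row per wetland: id, centroid, exact maximum
    wet area, hydroperiod, season-mean NDVI and surrounding land cover.
    ``footprints`` maps wetland id -> (rows, cols) pixel indices in
    flooding order (deepest first), and ``wet_counts`` gives the number of
    inundated footprint pixels per (wetland, step).
    """

    wetland_table: pd.DataFrame
    rasters: RasterStack
    footprints: dict = field(repr=False)
    wet_counts: np.ndarray = field(repr=False)  # (n_wetlands, n_steps)
    config: WetlandscapeConfig = field(repr=False)
    seed: int = 0


def _ellipse_order(area_px: int, rng: np.random.Generator):
    """Relative pixel offsets of an elliptical footprint, deepest first.

    Returns exactly ``area_px`` (dr, dc) offsets sorted by normalized
    elliptical radius, so truncating the list at any count yields a nested
    family of wet masks.
    """
    q = rng.uniform(0.55, 1.0)             # axis ratio
    theta = rng.uniform(0.0, np.pi)        # orientation
    a = np.sqrt(area_px / (np.pi * q))     # semi-major axis, pixels
    b = q * a
    half = int(np.ceil(a)) + 1
    dr, dc = np.mgrid[-half:half + 1, -half:half + 1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    flat = np.argsort(r, axis=None, kind="stable")[:area_px]
    return dr.ravel()[flat], dc.ravel()[flat]


def generate_wetlandscape(config: WetlandscapeConfig | None = None,
                          seed: int = 0) -> WetlandscapeTruth:
    """Generate a synthetic wetlandscape; deterministic for (config, seed)."""
    cfg = config or WetlandscapeConfig()
    rng = np.random.default_rng(seed)
    ny, nx = cfg.grid_shape
    S = cfg.n_steps
    season = np.sin(np.pi * np.arange(S) / (S - 1))
    px_per_ha = 1e4 / cfg.pixel_size**2

    # --- land cover mosaic --------------------------------------------
    lc_field = ndimage.gaussian_filter(rng.normal(size=(ny, nx)),
                                       cfg.land_cover_smoothing_px)
    land_cover = (lc_field > np.median(lc_field)).astype(np.uint8)  # 1=cropland

    # --- wetland sizes and placement ----------------------------------
    if cfg.fixed_sizes_ha is not None:
        size_ha = np.asarray(cfg.fixed_sizes_ha, dtype=float)
        if len(size_ha) != cfg.n_wetlands:
            raise ValueError("fixed_sizes_ha length must equal n_wetlands")
    else:
        size_ha = np.exp(rng.normal(np.log(cfg.size_median_ha),
                                    cfg.size_log_sigma, cfg.n_wetlands))
    grid_capacity = 0.45 * ny * nx
    area_px = np.maximum(np.round(size_ha * px_per_ha), 1).astype(int)
    if area_px.sum() > grid_capacity:
        raise PlacementError(
            f"requested wetland area {area_px.sum()} px exceeds grid capacity "
            f"{int(grid_capacity)} px")
    order = np.argsort(-area_px)  # place large wetlands first

    occupied = np.zeros((ny, nx), dtype=bool)
    footprints: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    z_size = (np.log(size_ha) - np.log(cfg.size_median_ha)) / cfg.size_log_sigma
    for rank, w in enumerate(order):
        dr, dc = _ellipse_order(area_px[w], rng)
        placed = False
        for _ in range(cfg.max_place_attempts):
            r0 = rng.integers(0, ny)
            c0 = rng.integers(0, nx)
            rr, cc = r0 + dr, c0 + dc
            if rr.min() < 0 or cc.min() < 0 or rr.max() >= ny or cc.max() >= nx:
                continue
            # require a 1-pixel moat so neighbouring wetlands never touch
            rlo, rhi = rr.min() - 1, rr.max() + 2
            clo, chi = cc.min() - 1, cc.max() + 2
            if occupied[rlo:rhi, clo:chi].any():
                continue
            occupied[rr, cc] = True
            footprints[w + 1] = (rr, cc)  # labels are 1-based
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place wetland of {area_px[w]} px after "
                f"{cfg.max_place_attempts} attempts")

    # --- wetted-fraction trajectories and water masks ------------------
    base = np.clip(cfg.wet_frac_base + cfg.wet_frac_size_coupling * z_size
                   + rng.normal(0, cfg.wet_frac_sd, cfg.n_wetlands), 0.15, 1.0)
    frac = np.clip((base[:, None] + cfg.wet_frac_amp * season[None, :])
                   * cfg.wetness, 0.0, 1.0)
    wet_counts = np.maximum(np.round(frac * area_px[:, None]), 1).astype(int)

    water = np.zeros((S, ny, nx), dtype=np.uint8)
    for wid, (rr, cc) in footprints.items():
        w = wid - 1
        for s in range(S):
            k = min(wet_counts[w, s], rr.size)
            water[s, rr[:k], cc[:k]] = 1
            wet_counts[w, s] = k

    # --- temperature ---------------------------------------------------
    ns = np.linspace(-0.5, 0.5, ny)[None, :, None] * cfg.temp_ns_gradient
    temp = (cfg.temp_base + cfg.temp_amp * season[:, None, None] + ns
            + rng.normal(0, cfg.temp_step_sd, S)[:, None, None]
            + rng.normal(0, 0.3, (S, ny, nx))).astype(np.float32)

    # --- NDVI ------------------------------------------------------------
    ndvi = np.empty((S, ny, nx), dtype=np.float32)
    grow = 0.4 + 0.6 * season
    for s in range(S):
        f = cfg.ndvi_upland * grow[s] + rng.normal(0, cfg.ndvi_noise_sd, (ny, nx))
        ndvi[s] = f
    for wid, (rr, cc) in footprints.items():
        w = wid - 1
        npx = rr.size
        ring_start = int(0.6 * npx)  # outer 40% of the basin: emergent ring
        for s in range(S):
            k = wet_counts[w, s]
            open_w = slice(0, min(k, ring_start))
            ndvi[s, rr[open_w], cc[open_w]] = (cfg.ndvi_open_water
                                               + 0.05 * grow[s])
            ring = slice(ring_start, npx)
            ndvi[s, rr[ring], cc[ring]] = cfg.ndvi_ring * grow[s]
    ndvi += rng.normal(0, cfg.ndvi_noise_sd, (S, ny, nx)).astype(np.float32)
    ndvi = np.clip(ndvi, -1.0, 1.0)

    # --- truth table -----------------------------------------------------
    px_area = cfg.pixel_size**2
    recs = []
    for wid in sorted(footprints):
        w = wid - 1
        rr, cc = footprints[wid]
        max_wet = int(wet_counts[w].max())
        hydro = float(np.clip(
            wet_counts[w].sum(axis=0) / (rr.size * S), 0, 1) * 365.0)
        # surrounding land cover: majority class in the bounding box + margin
        rlo, rhi = max(rr.min() - 3, 0), min(rr.max() + 4, ny)
        clo, chi = max(cc.min() - 3, 0), min(cc.max() + 4, nx)
        ctx = land_cover[rlo:rhi, clo:chi]
        recs.append({
            "wetland_id": wid,
            "row": float(rr.mean()), "col": float(cc.mean()),
            "max_area_m2": max_wet * px_area,
            "footprint_area_m2": rr.size * px_area,
            "hydroperiod_days": hydro,
            "mean_ndvi": float(ndvi[:, rr, cc].mean()),
            "land_cover": "cropland" if ctx.mean() > 0.5 else "grassland",
        })
    table = pd.DataFrame(recs)

    stack = RasterStack(
        water_mask=water, temperature=temp, ndvi=ndvi, land_cover=land_cover,
        pixel_size=cfg.pixel_size, step_length_days=cfg.step_length_days,
    )
    return WetlandscapeTruth(wetland_table=table, rasters=stack,
                             footprints=footprints, wet_counts=wet_counts,
                             config=cfg, seed=seed)
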