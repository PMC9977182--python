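"""Synthetic chamber-flux dataset generator.

Emulates the statistical structure of a large static-chamber CH4 campaign in
a prairie-pothole wetlandscape: ~143 wetlands sampled along transects of
five chambers each, every ~2 weeks over a 26-step growing season, with
wetland sizes dominated by sub-hectare depressions, seasonal soil-temperature
sinusoids, wetland-specific water-filled-pore-space drawdown, an NDVI
greenness hump, and log-normal flux noise decomposed into wetland, chamber
and residual components around a known generating response
(:class:`~prairie_ch4.truth.TrueResponse`).

With the default configuration the generating signal explains roughly 60%
of the log-flux variance; the remainder is the three noise components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .truth import REFERENCE_COVARIATES, TrueResponse

__all__ = ["ChamberGeneratorConfig", "generate_chamber_dataset"]


@dataclass(frozen=True)
class ChamberGeneratorConfig:
    """Settings for :func:`generate_chamber_dataset`.

    Defaults mirror the emulated campaign: 143 wetlands x 5 chambers x 26
    biweekly steps x 1 sampled season per wetland = 18,590 rows (~19k).
    """

    n_wetlands: int = 143
    chambers_per_wetland: int = 5
    years: int = 1  #: sampled seasons per wetland
    n_steps: int = 26  #: biweekly steps per season
    step_length_days: int = 14
    truth: TrueResponse = field(default_factory=TrueResponse)
    # wetland size distribution (log-normal, most wetlands < 1 ha)
    size_median_ha: float = 0.5
    size_log_sigma: float = 1.4
    # seasonal soil temperature: base + amp * sin(pi * s / (S-1))
    temp_base: float = 6.0
    temp_amp: float = 12.0
    temp_wetland_sd: float = 1.0
    temp_step_sd: float = 1.5
    # WFPS drawdown
    wfps_step_sd: float = 2.0
    wfps_floor: float = 20.0
    # NDVI seasonality
    ndvi_base: float = -0.10
    ndvi_amp: float = 0.70
    ndvi_step_sd: float = 0.05
    #: coupling of NDVI step noise to WFPS step noise (correlation knob;
    #: the real campaign's covariate correlation structure is unknown)
    wfps_ndvi_corr: float = 0.3
    # per-chamber measurement-scale jitter
    chamber_wfps_sd: float = 3.0
    chamber_temp_sd: float = 0.5
    chamber_ndvi_sd: float = 0.04
    #: hold WFPS at 100% everywhere (saturated subset, e.g. for Q10 studies)
    saturated: bool = False
    #: freeze every covariate at its reference value (noise-only data)
    hold_at_reference: bool = False
    #: append a covariate column of pure noise (for selection tests)
    include_noise_covariate: bool = False

    def __post_init__(self) -> None:
        if self.n_wetlands < 2:
            raise ValueError("need at least two wetlands")
        if self.chambers_per_wetland < 1:
            raise ValueError("need at least one chamber per wetland")
        if self.n_steps < 2 or self.years < 1:
            raise ValueError("empty design")


def _season_profile(n_steps: int) -> np.ndarray:
    """Half-sine over the growing season, 0 at the ends, 1 at mid-season."""
    s = np.arange(n_steps, dtype=float)
    return np.sin(np.pi * s / (n_steps - 1))


def generate_chamber_dataset(
    config: ChamberGeneratorConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TrueResponse]:
    """Simulate a chamber campaign; returns (observation table, generating truth).

    One row per chamber x step x sampled season.  ``flux`` is
    ``exp(log_mean_true + wetland effect + chamber effect + residual)`` so is
    strictly positive; ``log_mean_true`` (the noise-free generating log mean)
    is included for oracle checks and must not be used as a model input.
    Deterministic for a fixed (config, seed).
    """
    cfg = config or ChamberGeneratorConfig()
    truth = cfg.truth
    rng = np.random.default_rng(seed)
    S, C, Y = cfg.n_steps, cfg.chambers_per_wetland, cfg.years
    season = _season_profile(S)

    # --- wetland-level attributes -------------------------------------
    n = cfg.n_wetlands
    size_ha = np.exp(rng.normal(np.log(cfg.size_median_ha), cfg.size_log_sigma, n))
    size_ha = np.clip(size_ha, 0.005, 500.0)
    z_size = (np.log(size_ha) - np.log(cfg.size_median_ha)) / cfg.size_log_sigma
    # larger wetlands hold water longer (hydroperiod increases with size)
    hydroperiod = np.clip(150 + 45 * z_size + rng.normal(0, 30, n), 10, 365)
    land_cover = np.where(rng.random(n) < 0.5, "grassland", "cropland")
    b_wetland = rng.normal(0.0, truth.sigma_wetland, n)

    rows: list[pd.DataFrame] = []
    for w in range(n):
        b_chamber = rng.normal(0.0, truth.sigma_chamber, C)
        for y in range(Y):
            year = 2003 + (w + y) % 13  # campaign spread over a 13-year span
            # shared wetland-year trajectories
            temp_off = rng.normal(0, cfg.temp_wetland_sd)
            temp_traj = (cfg.temp_base + cfg.temp_amp * season
                         + temp_off + rng.normal(0, cfg.temp_step_sd, S))
            # WFPS: near-saturated start, wetland-specific drawdown rate;
            # short-hydroperiod (small) wetlands dry down faster
            wfps0 = np.clip(92 + 8 * hydroperiod[w] / 365 + rng.normal(0, 3), 40, 100)
            rate = 2.6 * (1.0 - hydroperiod[w] / 365) + 0.3
            wfps_noise = rng.normal(0, cfg.wfps_step_sd, S)
            wfps_traj = np.clip(
                wfps0 - rate * np.arange(S) + np.cumsum(wfps_noise),
                cfg.wfps_floor, 100.0,
            )
            # NDVI: greenness hump, coupled to WFPS innovations via the knob
            ndvi_own = rng.normal(0, cfg.ndvi_step_sd, S)
            ndvi_traj = np.clip(
                cfg.ndvi_base + cfg.ndvi_amp * season
                + cfg.wfps_ndvi_corr * wfps_noise / max(cfg.wfps_step_sd, 1e-12)
                * cfg.ndvi_step_sd + ndvi_own,
                -0.3, 0.9,
            )
            for c in range(C):
                wfps = np.clip(wfps_traj + rng.normal(0, cfg.chamber_wfps_sd, S),
                               0.0, 100.0)
                temp = temp_traj + rng.normal(0, cfg.chamber_temp_sd, S)
                ndvi = np.clip(ndvi_traj + rng.normal(0, cfg.chamber_ndvi_sd, S),
                               -1.0, 1.0)
                if cfg.saturated:
                    wfps = np.full(S, 100.0)
                df = pd.DataFrame({
                    "wetland_id": f"W{w:04d}",
                    "chamber_id": f"W{w:04d}C{c}",
                    "year": year,
                    "step_index": np.arange(S),
                    "wfps": wfps,
                    "soil_temp": temp,
                    "ndvi": ndvi,
                    "wetland_size": size_ha[w] * 1e4,
                    "hydroperiod": hydroperiod[w],
                    "land_cover": land_cover[w],
                    "season_interval": np.where(np.arange(S) < S / 2, "early", "late"),
                })
                if cfg.hold_at_reference:
                    for k in ("wfps", "soil_temp", "ndvi", "wetland_size",
                              "hydroperiod", "land_cover", "season_interval"):
                        df[k] = REFERENCE_COVARIATES[k]
                # first-order lags; at the season's first step no prior
                # exists, so lags equal the current values
                for parent in ("wfps", "soil_temp", "ndvi"):
                    df[f"{parent}_lag"] = df[parent].shift(1).fillna(df[parent].iloc[0])
                df["_b"] = b_wetland[w] + b_chamber[c]
                rows.append(df)

    table = pd.concat(rows, ignore_index=True)
    if cfg.include_noise_covariate:
        table["noise_cov"] = rng.normal(0.0, 1.0, len(table))
    eta = truth.log_mean(table)
    eps = rng.normal(0.0, truth.sigma_resid, len(table))
    table["log_mean_true"] = eta
    table["flux"] = np.exp(eta + table.pop("_b").to_numpy() + eps)
    return table, truth
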