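"""Generating ("true") flux-response surface for synthetic chamber data.

The synthetic generator needs a known, closed-form response of log CH4 flux
to its covariates so that model-recovery tests have an exact oracle.  The
curves encode the qualitative biogeochemistry of depressional prairie
wetlands:

* **WFPS** — a logistic rise centred at 80% water-filled pore space: flux
  falls steeply once an oxic surface layer develops below ~80% saturation.
* **Soil temperature** — exponential (Arrhenius-like) with a fixed Q10, i.e.
  linear on the log-flux scale with slope ``ln(q10)/10`` per degC.
* **NDVI** — a smooth step across zero: emergent vegetation (positive NDVI)
  fuels methanogenesis and vents CH4 through plant stems.
* **Wetland size** — log-quadratic, peaking for medium wetlands near 3 ha
  ("goldilocks" wetlands: wetter than the smallest, fresher and more
  vegetated than the largest).
* **Hydroperiod** — saturating benefit of longer annual inundation.
* **Land cover** — wetlands ringed by grassland emit somewhat more than
  those nested in cropland; **season interval** — late growing season
  slightly above early.
* First-order **lags** of WFPS, temperature and NDVI from the previous
  biweekly step enter through down-weighted copies of the parent curves.

Every curve is exactly zero at its reference covariate value, so the
response at the all-reference record is ``exp(intercept)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["REFERENCE_COVARIATES", "TrueResponse", "evaluate_true_response"]

#: Covariate values at which every generating curve is zero.
REFERENCE_COVARIATES: dict = {
    "wfps": 80.0,
    "soil_temp": 10.0,
    "ndvi": 0.3,
    "wetland_size": 30_000.0,  # m^2 == 3 ha, the generating size-curve peak
    "hydroperiod": 180.0,
    "land_cover": "cropland",
    "season_interval": "early",
}

_SQM_PER_HA = 10_000.0


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class TrueResponse:
    """Closed-form generating response on the log-flux scale.

    ``log E[flux] = intercept + f_wfps + f_temp + f_ndvi + f_size + f_hydro
    + lc_offset + season_offset + lag terms``; observed log flux adds
    Gaussian wetland, chamber and residual noise with the given sigmas.
    """

    intercept: float = -1.20  # log mg m^-2 h^-1 at the reference record
    # WFPS: logistic centred at 80%, scale 6% WFPS
    wfps_amp: float = 2.5
    wfps_center: float = 80.0
    wfps_scale: float = 6.0
    # temperature: exp with Q10; reference 10 degC
    q10_true: float = 3.0
    temp_ref: float = 10.0
    # NDVI: smooth step at 0, scale 0.08
    ndvi_amp: float = 1.2
    ndvi_scale: float = 0.08
    # size: log-quadratic peaking at 3 ha
    size_peak_ha: float = 3.0
    size_curvature: float = 0.25
    # hydroperiod: saturating with e-folding 60 days
    hydro_amp: float = 0.8
    hydro_tau: float = 60.0
    lc_offset: dict = field(default_factory=lambda: {"grassland": 0.30, "cropland": 0.0})
    season_offset: dict = field(default_factory=lambda: {"early": 0.0, "late": 0.20})
    #: weights on the parent curves evaluated at the lagged covariates
    lag_weights: tuple = (0.30, 0.30, 0.30)  # (wfps, soil_temp, ndvi)
    sigma_wetland: float = 0.35
    sigma_chamber: float = 0.25
    sigma_resid: float = 1.64

    def __post_init__(self) -> None:
        if min(self.sigma_wetland, self.sigma_chamber, self.sigma_resid) < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.q10_true <= 0:
            raise ValueError("q10_true must be positive")
        if not (2.0 <= self.size_peak_ha <= 4.0):
            raise ValueError("generating size peak must lie in [2, 4] ha")

    # ---- single-covariate curves (all zero at their reference value) ----

    def f_wfps(self, wfps):
        z = (np.asarray(wfps, float) - self.wfps_center) / self.wfps_scale
        z0 = (REFERENCE_COVARIATES["wfps"] - self.wfps_center) / self.wfps_scale
        return self.wfps_amp * (_logistic(z) - _logistic(z0))

    def f_temp(self, soil_temp):
        slope = np.log(self.q10_true) / 10.0
        return slope * (np.asarray(soil_temp, float) - self.temp_ref)

    def f_ndvi(self, ndvi):
        z = np.asarray(ndvi, float) / self.ndvi_scale
        z0 = REFERENCE_COVARIATES["ndvi"] / self.ndvi_scale
        return self.ndvi_amp * (_logistic(z) - _logistic(z0))

    def f_size(self, size_m2):
        size_m2 = np.asarray(size_m2, float)
        if np.any(size_m2 <= 0):
            raise ValueError("wetland size must be positive")
        r = np.log(size_m2 / (self.size_peak_ha * _SQM_PER_HA))
        return -self.size_curvature * r**2

    def f_hydro(self, hydroperiod):
        h = np.asarray(hydroperiod, float)
        if np.any((h < 0) | (h > 365)):
            raise ValueError("hydroperiod must be within [0, 365] days")
        sat = 1.0 - np.exp(-h / self.hydro_tau)
        sat0 = 1.0 - np.exp(-REFERENCE_COVARIATES["hydroperiod"] / self.hydro_tau)
        return self.hydro_amp * (sat - sat0)

    # ---- assembled log-mean ----

    def log_mean(self, records: pd.DataFrame | dict) -> np.ndarray:
        """Noise-free log expected flux for a record table.

        ``records`` needs the ChamberObservation covariate columns (flux and
        IDs are ignored).  Lag columns default to the parent values when
        absent (the first-step rule).
        """
        if isinstance(records, dict):
            records = pd.DataFrame({k: np.atleast_1d(v) for k, v in records.items()})
        r = records
        wfps = np.asarray(r["wfps"], float)
        if np.any((wfps < 0) | (wfps > 100)):
            raise ValueError("wfps outside [0, 100]")
        ndvi = np.asarray(r["ndvi"], float)
        if np.any((ndvi < -1) | (ndvi > 1)):
            raise ValueError("ndvi outside [-1, 1]")

        eta = self.intercept + self.f_wfps(wfps) + self.f_temp(r["soil_temp"])
        eta = eta + self.f_ndvi(ndvi) + self.f_size(r["wetland_size"])
        eta = eta + self.f_hydro(r["hydroperiod"])
        eta = eta + np.asarray(r["land_cover"].map(self.lc_offset) if hasattr(r["land_cover"], "map")
                               else [self.lc_offset[v] for v in r["land_cover"]], float)
        eta = eta + np.asarray(r["season_interval"].map(self.season_offset) if hasattr(r["season_interval"], "map")
                               else [self.season_offset[v] for v in r["season_interval"]], float)
        w_wfps, w_temp, w_ndvi = self.lag_weights
        lag_wfps = np.asarray(r.get("wfps_lag", wfps), float)
        lag_temp = np.asarray(r.get("soil_temp_lag", r["soil_temp"]), float)
        lag_ndvi = np.asarray(r.get("ndvi_lag", ndvi), float)
        eta = eta + w_wfps * self.f_wfps(lag_wfps)
        eta = eta + w_temp * self.f_temp(lag_temp)
        eta = eta + w_ndvi * self.f_ndvi(lag_ndvi)
        return np.asarray(eta, float)

    @property
    def total_noise_variance(self) -> float:
        return self.sigma_wetland**2 + self.sigma_chamber**2 + self.sigma_resid**2


def evaluate_true_response(truth: TrueResponse, record) -> np.ndarray | float:
    """Noise-free expected flux (mg m^-2 h^-1): ``exp`` of the generating sum.

    Deterministic; a scalar for a single dict record, an array for a table.
    """
    scalar = isinstance(record, dict) and np.isscalar(record.get("wfps", 0.0))
    eta = truth.log_mean(record)
    out = np.exp(eta)
    return float(out[0]) if scalar else out
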