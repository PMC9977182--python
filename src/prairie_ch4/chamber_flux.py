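"""Static-chamber CH4 flux calculation, WFPS, and Q10 temperature sensitivity.

A static chamber is a closed enclosure placed over a wetland soil or water
surface; the linear change of headspace CH4 mixing ratio over the deployment,
the chamber geometry, and the ideal gas law give the areal mass flux.  The
companion helpers derive water-filled pore space (WFPS) from volumetric water
content and estimate Q10 coefficients (the multiplicative rate change per
10 degC) from paired temperature/flux records binned at 1 degC resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_GAS",
    "STANDARD_PRESSURE",
    "ConcentrationSeries",
    "ChamberGeometry",
    "FluxResult",
    "Q10Result",
    "compute_flux",
    "compute_wfps",
    "compute_q10",
]

#: Molar gas constant, J mol^-1 K^-1 (CODATA).
R_GAS = 8.314462618
#: Standard atmosphere, Pa.  Used when deployment pressure was not recorded.
STANDARD_PRESSURE = 101_325.0
#: Molar mass of CH4, g mol^-1.
MOLAR_MASS_CH4 = 16.04


@dataclass(frozen=True)
class ConcentrationSeries:
    """Headspace mixing ratios (ppm) at minutes since chamber closure.

    The first sample is the ambient air drawn at closure, so ``times[0]``
    must be 0 and times must strictly increase.
    """

    times_min: np.ndarray
    concentrations_ppm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.concentrations_ppm, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("need at least two samples (ambient + closed)")
        if t[0] != 0.0:
            raise ValueError("first sample must be the ambient draw at t=0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "concentrations_ppm", c)


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber height (m), volume (m^3) and basal area (m^2).

    Only the height enters the flux formula for a right cylinder/prism
    (volume/basal_area); volume and basal area are still validated for
    consistency so unit errors surface early.
    """

    height_m: float
    volume_m3: float
    basal_area_m2: float

    def __post_init__(self) -> None:
        if min(self.height_m, self.volume_m3, self.basal_area_m2) <= 0:
            raise ValueError("chamber dimensions must be positive")
        if not np.isclose(self.volume_m3, self.height_m * self.basal_area_m2,
                          rtol=1e-9, atol=0.0):
            raise ValueError("volume must equal height x basal_area")

    @classmethod
    def cylinder(cls, diameter_m: float, height_m: float) -> "ChamberGeometry":
        area = np.pi * (diameter_m / 2.0) ** 2
        return cls(height_m=height_m, volume_m3=height_m * area, basal_area_m2=area)


@dataclass(frozen=True)
class FluxResult:
    flux_mg_m2_h: float
    slope_ppm_h: float
    r_squared: float
    temperature_K: float
    pressure_Pa: float


@dataclass(frozen=True)
class Q10Result:
    q10: float
    temp_range: tuple[float, float]
    n_bins: int
    bin_midpoints: np.ndarray = field(repr=False)
    bin_means: np.ndarray = field(repr=False)


def compute_flux(
    series: ConcentrationSeries,
    geometry: ChamberGeometry,
    temperature_K: float = 293.15,
    pressure_Pa: float = STANDARD_PRESSURE,
    molar_mass_g_mol: float = MOLAR_MASS_CH4,
) -> FluxResult:
    """Areal gas flux (mg m^-2 h^-1) from a chamber concentration series.

    The concentration slope (ppm h^-1) comes from an ordinary least-squares
    fit of mixing ratio on time — for the two-sample protocol (ambient, then
    one sample after closure) this reduces exactly to the endpoint difference.
    One ppm of gas corresponds to ``molar_mass * P / (R * T) * 1e-6`` g m^-3
    (ideal gas law); multiplying the volumetric rate by the chamber height
    (volume per basal area) converts to an areal flux.

    Negative slopes (uptake) yield negative fluxes; exclusion of non-positive
    fluxes is a modelling choice made downstream, not here.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if pressure_Pa <= 0:
        raise ValueError("pressure must be positive")
    if molar_mass_g_mol <= 0:
        raise ValueError("molar mass must be positive")

    t_h = series.times_min / 60.0
    c = series.concentrations_ppm
    # OLS slope; with 2 points this is (c1-c0)/(t1-t0) exactly.
    t_c = t_h - t_h.mean()
    denom = float(t_c @ t_c)
    if denom == 0.0:
        raise ValueError("degenerate time axis (identical timestamps)")
    slope = float(t_c @ (c - c.mean())) / denom
    resid = c - (c.mean() + slope * t_c)
    ss_tot = float(((c - c.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float((resid**2).sum()) / ss_tot

    g_per_m3_per_ppm = molar_mass_g_mol * pressure_Pa / (R_GAS * temperature_K) * 1e-6
    flux_mg = slope * g_per_m3_per_ppm * geometry.height_m * 1e3  # g -> mg
    return FluxResult(
        flux_mg_m2_h=flux_mg,
        slope_ppm_h=slope,
        r_squared=r2,
        temperature_K=temperature_K,
        pressure_Pa=pressure_Pa,
    )


def compute_wfps(vwc_percent, porosity: float):
    """Water-filled pore space (%) = volumetric water content / porosity.

    Values exceeding 100% (possible when field VWC probes read above the
    assumed porosity) are clamped to 100 with a warning.
    Accepts scalars or arrays.
    """
    if porosity <= 0 or porosity > 1:
        raise ValueError("porosity must be in (0, 1]")
    vwc = np.asarray(vwc_percent, dtype=float)
    if np.any(vwc < 0) or np.any(vwc > 100):
        raise ValueError("VWC must be within [0, 100] percent")
    wfps = vwc / porosity
    if np.any(wfps > 100.0):
        warnings.warn("WFPS exceeded 100%; clamped", stacklevel=2)
        wfps = np.minimum(wfps, 100.0)
    return float(wfps) if np.isscalar(vwc_percent) else wfps


def compute_q10(
    temperatures_C,
    fluxes,
    temp_range: tuple[float, float] | str = "all",
    method: str = "regression",
) -> Q10Result:
    """Q10 from paired (temperature, flux) records.

    Records are binned into 1 degC increments; bin mean fluxes are regressed
    as log(mean flux) on bin midpoint temperature, and ``q10 = exp(10*slope)``.
    ``temp_range`` restricts to a half-open [low, high) degC window (the
    conventional 10-degree windows are (0,10), (10,20), (20,30)) or "all".
    ``method="endpoint"`` instead uses the ratio of the warmest and coolest
    bin means — identical to the regression when only two bins exist.
    """
    T = np.asarray(temperatures_C, dtype=float)
    F = np.asarray(fluxes, dtype=float)
    if T.shape != F.shape or T.ndim != 1:
        raise ValueError("temperatures and fluxes must be matching 1-D arrays")
    if temp_range != "all":
        lo, hi = temp_range
        keep = (T >= lo) & (T < hi)
        T, F = T[keep], F[keep]
        rng = (float(lo), float(hi))
    else:
        if T.size == 0:
            raise ValueError("no records supplied")
        rng = (float(np.floor(T.min())), float(np.ceil(T.max())))

    bins = np.floor(T).astype(int)
    uniq = np.unique(bins)
    if uniq.size < 2:
        raise ValueError("need records in at least two 1degC bins")
    mids = uniq + 0.5
    means = np.array([F[bins == b].mean() for b in uniq])
    if np.any(means <= 0):
        raise ValueError("non-positive bin mean flux: log-scale Q10 undefined")

    if method == "endpoint":
        slope = (np.log(means[-1]) - np.log(means[0])) / (mids[-1] - mids[0])
    elif method == "regression":
        slope = np.polyfit(mids, np.log(means), 1)[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    return Q10Result(
        q10=float(np.exp(10.0 * slope)),
        temp_range=rng,
        n_bins=int(uniq.size),
        bin_midpoints=mids,
        bin_means=means,
    )
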