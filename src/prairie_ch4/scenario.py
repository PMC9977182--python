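"""Warming x wetland-extent scenario projection.

Future predictor stacks are built from historical "bookend" landscapes (a
dry and a wet extent year) by the delta method: each ensemble member
supplies additive monthly temperature deltas (mapped to the biweekly step
containing each step's midpoint) and a longer frost-free season.  Season
extension prepends/appends shoulder steps that replicate the boundary
steps' water mask and NDVI (consistent with charging winter at boundary
rates); water masks and NDVI otherwise stay at the bookend year's values.
Each member runs the full landscape pipeline; ensemble statistics (mean,
CV, range) and fold changes against the historical baseline summarize the
projection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .landscape_model import (
    FrostFreeWindow,
    delineate_wetlands,
    derive_predictor_stack,
    predict_pixel_flux,
    rates_to_grid,
)
from .rasters import RasterStack
from .upscale import EmissionSummary, integrate_annual, summarize_region

__all__ = [
    "ScenarioMember",
    "ScenarioSpec",
    "ScenarioResult",
    "PATHWAY_WARMING",
    "make_ensemble_members",
    "apply_scenario",
    "run_ensemble",
    "fold_change",
]

#: regional mean warming (degC) by pathway: "moderate" tracks a
#: middle-of-the-road emission trajectory, "severe" an intensive one
PATHWAY_WARMING = {"moderate": 1.7, "severe": 2.7}
#: growing-season lengthening (days) by pathway, on the order of the ~50
#: extra frost-free days expected by end of century
PATHWAY_SEASON_EXTENSION = {"moderate": 57, "severe": 71}


@dataclass(frozen=True)
class ScenarioMember:
    """One ensemble member: monthly temperature deltas + frost-free window."""

    member_id: str
    monthly_deltas: dict  # month (1-12) -> degC
    frost_free: FrostFreeWindow

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.monthly_deltas.values()))):
            raise ValueError("temperature deltas must be finite")


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: str
    extent_bookend: str          # "dry" or "wet"
    pathway: str                 # "moderate" or "severe"
    members: tuple

    def __post_init__(self) -> None:
        if self.extent_bookend not in ("dry", "wet"):
            raise ValueError("extent_bookend must be 'dry' or 'wet'")
        if self.pathway not in PATHWAY_WARMING:
            raise ValueError(f"pathway must be one of {sorted(PATHWAY_WARMING)}")
        if not self.members:
            raise ValueError("need at least one ensemble member")


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    member_summaries: tuple
    mean_total_Gg: float
    cv_percent: float            # 100 * sd / mean across members
    member_range_Gg: tuple[float, float]
    fold_change_vs_baseline: float | None = None


def make_ensemble_members(pathway: str, historical_window: FrostFreeWindow,
                          n_members: int = 13, seed: int = 0,
                          member_sd: float = 0.6, month_sd: float = 0.4,
                          season_sd_days: float = 7.0) -> tuple:
    """Synthesize a climate-model ensemble for a warming pathway.

    Member mean deltas scatter around the pathway's regional warming;
    month-to-month variation adds structure; frost-free windows lengthen by
    the pathway's extension (jittered, never shorter than historical).
    """
    if pathway not in PATHWAY_WARMING:
        raise ValueError(f"unknown pathway {pathway!r}")
    rng = np.random.default_rng(seed)
    members = []
    for m in range(n_members):
        mean_delta = PATHWAY_WARMING[pathway] + rng.normal(0.0, member_sd)
        deltas = {month: mean_delta + rng.normal(0.0, month_sd)
                  for month in range(1, 13)}
        ext = max(int(round(PATHWAY_SEASON_EXTENSION[pathway]
                            + rng.normal(0.0, season_sd_days))), 0)
        pre = min(ext // 2, historical_window.start_day - 1)
        post = min(ext - pre, 365 - historical_window.end_day)
        window = FrostFreeWindow(historical_window.start_day - pre,
                                 historical_window.end_day + post)
        members.append(ScenarioMember(
            member_id=f"{pathway}-esm{m:02d}", monthly_deltas=deltas,
            frost_free=window))
    return tuple(members)


def _month_of_day(day: float) -> int:
    return int(np.clip(np.searchsorted(
        np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]),
        day, side="left") + 1, 1, 12))


def apply_scenario(stack: RasterStack, window: FrostFreeWindow,
                   member: ScenarioMember) -> tuple[RasterStack, FrostFreeWindow]:
    """Build one member's future stack from a historical bookend stack.

    Steps added by season extension replicate the first/last historical
    step's water mask, NDVI and temperature; every step's temperature grid
    is then shifted by the delta of the month containing its midpoint.
    Zero deltas with an unchanged window return an identical stack.
    """
    new_win = member.frost_free
    if new_win.length < window.length:
        raise ValueError("scenario frost-free window shorter than historical")
    sl = stack.step_length_days
    k_total = new_win.n_steps(sl) - window.n_steps(sl)
    k_pre = min(k_total, max(0, int(np.ceil((window.start_day
                                             - new_win.start_day) / sl))))
    k_post = k_total - k_pre

    def extend(grid):
        return np.concatenate([np.repeat(grid[:1], k_pre, axis=0), grid,
                               np.repeat(grid[-1:], k_post, axis=0)], axis=0)

    water = extend(stack.water_mask)
    ndvi = extend(stack.ndvi)
    temp = extend(stack.temperature).astype(float).copy()
    n_steps = temp.shape[0]
    step_mid = new_win.start_day + sl * (np.arange(n_steps) + 0.5)
    for s in range(n_steps):
        temp[s] += member.monthly_deltas[_month_of_day(step_mid[s])]
    return (replace(stack, water_mask=water, ndvi=ndvi, temperature=temp),
            new_win)


def _run_member(model, stack: RasterStack, window: FrostFreeWindow,
                member: ScenarioMember, region: str, scenario: str,
                dry_wfps: float = 50.0) -> EmissionSummary:
    future, win = apply_scenario(stack, window, member)
    wetlands = delineate_wetlands(future)
    predictors = derive_predictor_stack(future, wetlands, win, dry_wfps=dry_wfps)
    flux = predict_pixel_flux(model, predictors)
    rates = rates_to_grid(predictors, flux, future.n_steps, future.grid_shape)
    annual = integrate_annual(rates, future, win)
    return summarize_region(annual, rates, wetlands, future, win,
                            region=region, scenario=scenario)


def run_ensemble(model, bookend_stacks: dict, historical_window: FrostFreeWindow,
                 specs: list[ScenarioSpec], region: str = "synthetic",
                 dry_wfps: float = 50.0) -> list[ScenarioResult]:
    """Run every member of every scenario through the landscape pipeline.

    ``model`` is anything with ``predict_records`` (a fitted ensemble model
    or the true-response oracle); ``bookend_stacks`` maps "dry"/"wet" to
    historical RasterStacks.  Any member failure aborts with the member id
    — no silent partial ensembles.
    """
    if not specs:
        raise ValueError("no scenarios supplied")
    results = []
    for spec in specs:
        if spec.extent_bookend not in bookend_stacks:
            raise KeyError(f"{spec.scenario_id}: missing bookend "
                           f"{spec.extent_bookend!r} stack")
        stack = bookend_stacks[spec.extent_bookend]
        summaries = []
        for member in spec.members:
            try:
                summaries.append(_run_member(
                    model, stack, historical_window, member,
                    region=region, scenario=spec.scenario_id,
                    dry_wfps=dry_wfps))
            except Exception as exc:
                raise RuntimeError(
                    f"scenario {spec.scenario_id} member {member.member_id} "
                    f"failed: {exc}") from exc
        totals = np.array([s.total_emission_Gg for s in summaries])
        mean = float(totals.mean())
        if totals.max() == totals.min() or mean == 0.0:
            cv = 0.0  # identical members: exactly zero spread
        else:
            cv = float(100.0 * totals.std(ddof=0) / mean)
        results.append(ScenarioResult(
            spec=spec, member_summaries=tuple(summaries), mean_total_Gg=mean,
            cv_percent=cv, member_range_Gg=(float(totals.min()),
                                            float(totals.max()))))
    return results


def fold_change(future_results: list[ScenarioResult],
                historical_dry: EmissionSummary,
                historical_wet: EmissionSummary) -> dict:
    """Emission fold changes vs the historical dry/wet baseline.

    The headline ratio divides the ensemble-mean future total, averaged
    over the dry and wet extent bookends, by the mean of the two historical
    totals; per-bookend ratios are reported alongside so extent effects are
    never masked.
    """
    baseline = 0.5 * (historical_dry.total_emission_Gg
                      + historical_wet.total_emission_Gg)
    if baseline <= 0:
        raise ValueError("historical baseline total must be positive")
    by_pathway: dict[str, dict] = {}
    for res in future_results:
        d = by_pathway.setdefault(res.spec.pathway, {"per_bookend": {}})
        d["per_bookend"][res.spec.extent_bookend] = (
            res.mean_total_Gg / (historical_dry.total_emission_Gg
                                 if res.spec.extent_bookend == "dry"
                                 else historical_wet.total_emission_Gg))
        d.setdefault("_totals", []).append(res.mean_total_Gg)
    out = {}
    for pathway, d in by_pathway.items():
        out[pathway] = {
            "fold_change": float(np.mean(d["_totals"]) / baseline),
            "per_bookend": d["per_bookend"],
        }
    return out
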