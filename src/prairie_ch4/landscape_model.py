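"""Landscape-scale CH4 flux model on 30-m raster stacks.

Wetland objects are delineated as connected components of the any-step-wet
(union) water mask.  Per-(pixel, step) predictor records mirror the chamber
covariates with remotely-sensed surrogates: inundation stands in for WFPS
(wet pixels saturated at 100%, currently-dry wetland pixels at a
configurable intermediate value), per-pixel wet-step counts give
hydroperiod, component area gives wetland size, and first-order lags come
from the previous biweekly step (self-referential at the first step).

Flux is upscaled with a bootstrap ensemble of regression trees (random
forest) trained on ``log(flux)``: each tree sees a ~2/3 bootstrap sample
and a random feature subset at every split, and the withheld ~1/3 provides
the out-of-bag (OOB) evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestRegressor

from .truth import TrueResponse, evaluate_true_response

__all__ = [
    "FrostFreeWindow",
    "LabeledWetlands",
    "RandomForestConfig",
    "EnsembleModel",
    "TrueResponsePredictor",
    "delineate_wetlands",
    "derive_predictor_stack",
    "fit_landscape_model",
    "predict_pixel_flux",
    "rates_to_grid",
]

log = logging.getLogger(__name__)

#: predictor schema shared by chamber rows and landscape records
PREDICTOR_COLUMNS = (
    "wfps", "soil_temp", "ndvi", "wetland_size", "hydroperiod",
    "land_cover", "season_interval", "wfps_lag", "soil_temp_lag", "ndvi_lag",
)
_CAT_MAPS = {
    "land_cover": {"grassland": 0.0, "cropland": 1.0},
    "season_interval": {"early": 0.0, "late": 1.0},
}


@dataclass(frozen=True)
class FrostFreeWindow:
    """Growing-season window in day-of-year; winter is outside it."""

    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_day < self.end_day <= 365):
            raise ValueError("window must satisfy 1 <= start < end <= 365")

    @property
    def length(self) -> int:
        return self.end_day - self.start_day + 1

    @property
    def midpoint_day(self) -> float:
        return 0.5 * (self.start_day + self.end_day)

    def n_steps(self, step_length_days: int = 14) -> int:
        return -(-self.length // step_length_days)


@dataclass(frozen=True)
class LabeledWetlands:
    """Connected-component wetland objects from the union water mask."""

    labels: np.ndarray            # (ny, nx) int32, 0 = upland
    areas_m2: np.ndarray          # per label (1-based -> index 0)
    pixel_counts: np.ndarray
    connectivity: int
    pixel_size: float

    @property
    def n_wetlands(self) -> int:
        return len(self.areas_m2)

    def size_class(self, edges_ha: np.ndarray) -> np.ndarray:
        """Left-closed size-class index per wetland for 1-based ha edges."""
        return np.digitize(self.areas_m2 / 1e4, edges_ha, right=False)


def delineate_wetlands(stack, connectivity: int = 8) -> LabeledWetlands:
    """Label wetlands on the union (wet at any step) mask.

    8-connectivity is the default: depressional basins are roughly convex
    and diagonal splits are raster artifacts.  An empty mask yields an
    empty result with a warning, not an error.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    union = np.asarray(stack.water_mask).any(axis=0)
    structure = (np.ones((3, 3), dtype=int) if connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    labels, n = ndimage.label(union, structure=structure)
    if n == 0:
        warnings.warn("empty water mask: no wetlands delineated")
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return LabeledWetlands(
        labels=labels.astype(np.int32),
        areas_m2=counts * stack.pixel_area_m2,
        pixel_counts=counts,
        connectivity=connectivity,
        pixel_size=stack.pixel_size,
    )


def derive_predictor_stack(stack, wetlands: LabeledWetlands,
                           frost_free: FrostFreeWindow,
                           dry_wfps: float = 50.0) -> pd.DataFrame:
    """Per-(pixel, step) predictor records for all wetland pixels.

    WFPS surrogate: 100 for currently-wet pixels, ``dry_wfps`` for wetland
    pixels that are dry at the step.  Hydroperiod: per-pixel wet-step count
    x step length (days).  Season interval: early/late split at the
    frost-free-window midpoint.  Lags reference the previous step and are
    self-referential at step 0.
    """
    S = stack.n_steps
    if frost_free.n_steps(stack.step_length_days) > S:
        raise ValueError(
            f"frost-free window needs {frost_free.n_steps(stack.step_length_days)}"
            f" steps but stack has {S}")
    rows, cols = np.nonzero(wetlands.labels)
    if rows.size == 0:
        return pd.DataFrame(columns=("row", "col", "label", "step") + PREDICTOR_COLUMNS)
    lab = wetlands.labels[rows, cols]
    wet = stack.water_mask[:, rows, cols].astype(bool)          # (S, npx)
    hydro = wet.sum(axis=0) * float(stack.step_length_days)     # per pixel, days
    size = wetlands.areas_m2[lab - 1]
    lc = np.where(stack.land_cover[rows, cols] == 0, "grassland", "cropland")

    # day-of-year midpoint of each step -> early/late season halves
    step_mid = (frost_free.start_day + stack.step_length_days
                * (np.arange(S) + 0.5))
    season = np.where(step_mid < frost_free.midpoint_day, "early", "late")

    frames = []
    for s in range(S):
        sl = max(s - 1, 0)
        wfps = np.where(wet[s], 100.0, dry_wfps)
        frames.append(pd.DataFrame({
            "row": rows, "col": cols, "label": lab, "step": s,
            "wfps": wfps,
            "soil_temp": stack.temperature[s, rows, cols].astype(float),
            "ndvi": stack.ndvi[s, rows, cols].astype(float),
            "wetland_size": size.astype(float),
            "hydroperiod": hydro,
            "land_cover": lc,
            "season_interval": season[s],
            "wfps_lag": np.where(wet[sl], 100.0, dry_wfps),
            "soil_temp_lag": stack.temperature[sl, rows, cols].astype(float),
            "ndvi_lag": stack.ndvi[sl, rows, cols].astype(float),
        }))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# ensemble-tree model


@dataclass(frozen=True)
class RandomForestConfig:
    n_trees: int = 500
    #: features tried per split; None -> ceil(p/3) (regression convention)
    feature_subset: int | None = None
    bootstrap_fraction: float = 2 / 3
    min_samples_leaf: int = 1


def _encode(records: pd.DataFrame) -> np.ndarray:
    X = np.empty((len(records), len(PREDICTOR_COLUMNS)))
    for j, name in enumerate(PREDICTOR_COLUMNS):
        col = records[name]
        if name in _CAT_MAPS:
            col = col.map(_CAT_MAPS[name]) if hasattr(col, "map") else col
            if pd.isna(np.asarray(col, dtype=float)).any():
                raise ValueError(f"unknown categorical level in {name}")
        X[:, j] = np.asarray(col, dtype=float)
    return X


@dataclass
class EnsembleModel:
    """Fitted bootstrap tree ensemble for log-flux with OOB statistics."""

    forest: RandomForestRegressor
    config: RandomForestConfig
    feature_subset: int
    oob_variance_explained: float
    oob_mean_squared_residual: float
    n_training_rows: int

    @property
    def n_trees(self) -> int:
        return self.config.n_trees

    def predict_records(self, records: pd.DataFrame) -> np.ndarray:
        """Flux (mg m^-2 h^-1) for predictor records; always non-negative."""
        return np.exp(self.forest.predict(_encode(records)))


@dataclass
class TrueResponsePredictor:
    """Generating-truth stand-in for an EnsembleModel (oracle predictions)."""

    truth: TrueResponse

    def predict_records(self, records: pd.DataFrame) -> np.ndarray:
        return np.asarray(evaluate_true_response(self.truth, records))


def fit_landscape_model(training: pd.DataFrame,
                        config: RandomForestConfig | None = None,
                        seed: int = 0) -> EnsembleModel:
    """Fit the random-forest flux model on rows with positive flux.

    Trees are trained on ``log(flux)``; OOB variance explained and mean
    squared residual are reported on that training-response (log) scale.
    """
    config = config or RandomForestConfig()
    missing = set(PREDICTOR_COLUMNS) - set(training.columns)
    if missing:
        raise KeyError(f"training records missing {sorted(missing)}")
    training = training[training["flux"] > 0]
    if len(training) < 100:
        raise ValueError("need at least 100 positive-flux training rows")
    y = np.log(training["flux"].to_numpy(float))
    if np.allclose(y, y[0]):
        raise ValueError("degenerate fit: single-valued response")
    X = _encode(training)
    subset = config.feature_subset or -(-X.shape[1] // 3)
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=subset,
        max_samples=config.bootstrap_fraction,
        min_samples_leaf=config.min_samples_leaf,
        bootstrap=True,
        oob_score=True,
        random_state=int(seed) % 2**31,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # rows OOB in no tree
        forest.fit(X, y)
    oob = forest.oob_prediction_
    msr = float(np.mean((y - oob) ** 2))
    return EnsembleModel(
        forest=forest, config=config, feature_subset=subset,
        oob_variance_explained=float(forest.oob_score_),
        oob_mean_squared_residual=msr,
        n_training_rows=len(training),
    )


def predict_pixel_flux(model, predictors: pd.DataFrame,
                       tile_size: int | None = None) -> np.ndarray:
    """Predict flux for every (pixel, step) record, optionally in tiles.

    The prediction is row-wise, so the output is bit-identical for any tile
    partition; ``tile_size`` only bounds peak memory.
    """
    missing = set(PREDICTOR_COLUMNS) - set(predictors.columns)
    if missing:
        raise KeyError(f"predictor records missing {sorted(missing)}")
    if tile_size is None or tile_size >= len(predictors):
        return np.asarray(model.predict_records(predictors), dtype=float)
    out = np.empty(len(predictors))
    for start in range(0, len(predictors), tile_size):
        chunk = predictors.iloc[start:start + tile_size]
        out[start:start + tile_size] = model.predict_records(chunk)
    return out


def rates_to_grid(predictors: pd.DataFrame, values: np.ndarray,
                  n_steps: int, grid_shape: tuple[int, int]) -> np.ndarray:
    """Scatter per-record flux rates into a dense (n_steps, ny, nx) grid.

    Non-wetland cells are 0 (they contribute no emission).
    """
    grid = np.zeros((n_steps,) + tuple(grid_shape))
    grid[predictors["step"].to_numpy(int),
         predictors["row"].to_numpy(int),
         predictors["col"].to_numpy(int)] = values
    return grid
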