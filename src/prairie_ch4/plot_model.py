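"""Plot-scale additive model of chamber CH4 flux.

Positive fluxes are modelled as log-normal: a Gaussian additive model is fit
to ``log(flux)`` with a penalized B-spline (P-spline) smooth per continuous
covariate, unpenalized categorical effects, and ridge-penalized random
intercepts for wetland and chamber-within-wetland (the repeated-measures
grouping of a chamber campaign).

Smoothing parameters are chosen by restricted maximum likelihood (REML;
generalized cross-validation with an inflation factor is available as an
alternative, but REML shrinks spurious terms far more reliably).  When
``selection_penalty`` is on, each smooth additionally carries a penalty on
the null space of its curvature penalty (the "double penalty" device), so
the optimizer can shrink a term's effective degrees of freedom (EDF) to ~0
and thereby drop uninformative covariates entirely; categorical terms are
never subject to removal.

The fitted object exposes centred partial effects with pointwise 95%
intervals, population-level or group-level predictions (with boundary
clamping for covariates outside the training range, as needed when
projecting warmer futures), and Gaussian deviance explained on the log
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.interpolate import BSpline

__all__ = [
    "PlotModelConfig",
    "FittedPlotModel",
    "PartialEffect",
    "fit_plot_model",
    "predict_plot_flux",
    "partial_effect",
    "deviance_explained",
]

log = logging.getLogger(__name__)

DEFAULT_SMOOTHS = (
    "wfps", "soil_temp", "ndvi", "wetland_size", "hydroperiod",
    "wfps_lag", "soil_temp_lag", "ndvi_lag",
)
#: covariates smoothed on a log axis (wetland areas span 4+ orders of magnitude)
LOG_SCALE_TERMS = ("wetland_size",)
#: a term whose EDF falls below this is considered removed by selection
EDF_REMOVAL_THRESHOLD = 0.5


@dataclass(frozen=True)
class PlotModelConfig:
    smooth_terms: tuple[str, ...] = DEFAULT_SMOOTHS
    categorical_terms: tuple[str, ...] = ("land_cover", "season_interval")
    random_effect_terms: tuple[str, ...] = ("wetland_id", "chamber_id")
    basis_dim: int = 10
    selection_penalty: bool = True
    criterion: str = "reml"  #: "reml" or "gcv"
    #: complexity inflation; >1 favours smoother, sparser models in both criteria
    gamma: float = 2.5
    #: coordinate-descent sweeps over the smoothing parameters
    n_sweeps: int = 2

    def __post_init__(self) -> None:
        if self.basis_dim < 4:
            raise ValueError("basis_dim must be at least 4")
        if self.criterion not in ("reml", "gcv"):
            raise ValueError("criterion must be 'reml' or 'gcv'")


@dataclass
class _SmoothTerm:
    name: str
    knots: np.ndarray
    degree: int
    Z: np.ndarray          # constraint null-space basis (m x m-1)
    S: np.ndarray          # curvature penalty in constrained coordinates
    S0: np.ndarray | None  # null-space (selection) penalty, or None
    xmin: float
    xmax: float
    log_scale: bool
    sl: slice = field(default_factory=lambda: slice(0))

    def _prep(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.log_scale:
            if np.any(x <= 0):
                raise ValueError(f"{self.name}: log-scale covariate must be positive")
            x = np.log(x)
        return np.clip(x, self.xmin, self.xmax)

    def design(self, x) -> np.ndarray:
        B = BSpline.design_matrix(self._prep(x), self.knots, self.degree).toarray()
        return B @ self.Z


@dataclass
class _CategoricalTerm:
    name: str
    levels: tuple
    sl: slice = field(default_factory=lambda: slice(0))

    def design(self, values) -> np.ndarray:
        idx = pd.Categorical(values, categories=self.levels)
        if (idx.codes < 0).any():
            bad = sorted(set(np.asarray(values)[idx.codes < 0]))
            raise ValueError(f"unknown level(s) {bad} for {self.name}")
        # drop-first dummy coding
        out = np.zeros((len(idx), len(self.levels) - 1))
        for j in range(1, len(self.levels)):
            out[idx.codes == j, j - 1] = 1.0
        return out


@dataclass
class _RandomEffectTerm:
    name: str
    levels: tuple
    sl: slice = field(default_factory=lambda: slice(0))

    def design(self, values) -> np.ndarray:
        idx = pd.Categorical(values, categories=self.levels)
        out = np.zeros((len(idx), len(self.levels)))
        seen = idx.codes >= 0  # unseen groups get a zero row (population level)
        out[np.arange(len(idx))[seen], idx.codes[seen]] = 1.0
        return out


@dataclass
class PartialEffect:
    """Centred smooth effect on the log-flux scale with a 95% band."""

    covariate: str
    grid: np.ndarray
    effect: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


@dataclass
class FittedPlotModel:
    config: PlotModelConfig
    smooths: dict
    categoricals: dict
    random_effects: dict
    coef: np.ndarray
    cov: np.ndarray                  # Bayesian posterior covariance of coef
    lambdas: dict
    edf_by_term: dict
    edf_total: float
    sigma2: float
    rss: float
    tss: float
    n_obs: int
    n_dropped_nonpositive: int
    terms_removed: set
    train_means: dict

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.rss / self.tss if self.tss > 0 else 0.0

    @property
    def adjusted_r2(self) -> float:
        denom = self.tss / (self.n_obs - 1)
        return 1.0 - (self.rss / max(self.n_obs - self.edf_total, 1.0)) / denom


# --------------------------------------------------------------------------
# design construction


def _quantile_knots(x: np.ndarray, basis_dim: int, degree: int = 3):
    """Clamped knot vector with interior knots at quantiles of unique x."""
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("degenerate covariate (constant)")
    n_interior = basis_dim - degree - 1
    ux = np.unique(x)
    interior = np.unique(np.quantile(ux, np.linspace(0, 1, n_interior + 2)[1:-1]))
    interior = interior[(interior > lo) & (interior < hi)]
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return t, lo, hi


def _build_smooth(name: str, x: np.ndarray, basis_dim: int,
                  selection: bool, degree: int = 3) -> tuple[_SmoothTerm, np.ndarray]:
    log_scale = name in LOG_SCALE_TERMS
    xt = np.log(x) if log_scale else x.astype(float)
    t, lo, hi = _quantile_knots(xt, basis_dim, degree)
    B = BSpline.design_matrix(xt, t, degree).toarray()
    m = B.shape[1]
    # sum-to-zero constraint over the training rows: C beta = 0, C = colmeans
    C = B.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(C, full_matrices=True)
    Z = vt[1:].T                                # m x (m-1)
    D = np.diff(np.eye(m), n=2, axis=0)         # second-difference penalty
    S = Z.T @ (D.T @ D) @ Z
    S0 = None
    if selection:
        w, U = np.linalg.eigh(S)
        null = U[:, w < 1e-10 * max(w.max(), 1.0)]
        S0 = null @ null.T
    term = _SmoothTerm(name=name, knots=t, degree=degree, Z=Z, S=S, S0=S0,
                       xmin=lo, xmax=hi, log_scale=log_scale)
    return term, B @ Z


def _assemble(records: pd.DataFrame, config: PlotModelConfig):
    """Build terms and the full design matrix from training records."""
    n = len(records)
    cols: list[np.ndarray] = [np.ones((n, 1))]
    smooths: dict[str, _SmoothTerm] = {}
    cats: dict[str, _CategoricalTerm] = {}
    res: dict[str, _RandomEffectTerm] = {}
    penalties: list[tuple[slice, np.ndarray]] = []
    groups: list[tuple[slice, list[int]]] = []
    n_unpenalized = 1  # intercept
    pos = 1

    for name in config.categorical_terms:
        levels = tuple(sorted(pd.unique(records[name])))
        term = _CategoricalTerm(name=name, levels=levels)
        X = term.design(records[name])
        term.sl = slice(pos, pos + X.shape[1])
        pos += X.shape[1]
        n_unpenalized += X.shape[1]
        cols.append(X)
        cats[name] = term

    for name in config.smooth_terms:
        term, X = _build_smooth(name, records[name].to_numpy(float),
                                config.basis_dim, config.selection_penalty)
        term.sl = slice(pos, pos + X.shape[1])
        pos += X.shape[1]
        cols.append(X)
        smooths[name] = term
        idx = [len(penalties)]
        penalties.append((term.sl, term.S))
        if term.S0 is not None:
            idx.append(len(penalties))
            penalties.append((term.sl, term.S0))
        else:
            n_unpenalized += 1  # the unshrunk linear (null-space) direction
        groups.append((term.sl, idx))

    for name in config.random_effect_terms:
        levels = tuple(sorted(pd.unique(records[name])))
        term = _RandomEffectTerm(name=name, levels=levels)
        X = term.design(records[name])
        term.sl = slice(pos, pos + X.shape[1])
        pos += X.shape[1]
        cols.append(X)
        res[name] = term
        groups.append((term.sl, [len(penalties)]))
        penalties.append((term.sl, np.eye(X.shape[1])))

    return np.hstack(cols), smooths, cats, res, penalties, groups, n_unpenalized


# --------------------------------------------------------------------------
# penalized least squares + GCV


class _PenalizedLS:
    """Penalized least squares on precomputed cross-products, with the two
    smoothing-parameter criteria (REML and GCV) evaluated from one Cholesky.

    ``penalties`` is a flat list of (block slice, penalty matrix);
    ``groups`` collects, per penalized block, the indices into ``penalties``
    whose matrices sum to that block's total penalty (a smooth contributes
    its curvature penalty and, with selection on, its null-space penalty).
    ``n_unpenalized`` counts coefficient directions outside every penalty
    (intercept, categorical dummies, and smooth null spaces when the
    selection penalty is off) — the "fixed effect" dimension of REML.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 penalties: list[tuple[slice, np.ndarray]],
                 groups: list[tuple[slice, list[int]]],
                 n_unpenalized: int, criterion: str, gamma: float):
        self.A = X.T @ X
        self.b = X.T @ y
        self.yy = float(y @ y)
        self.n = len(y)
        self.p = X.shape[1]
        self.penalties = penalties
        self.groups = groups
        self.mp = n_unpenalized
        self.criterion = criterion
        self.gamma = gamma

    def _M(self, rho: np.ndarray) -> np.ndarray:
        M = self.A.copy()
        for lam, (sl, S) in zip(np.exp(rho), self.penalties):
            M[sl, sl] += lam * S
        return M

    def solve(self, rho: np.ndarray):
        M = self._M(rho)
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        beta = linalg.cho_solve(cf, self.b, check_finite=False)
        rss = self.yy - float(beta @ (2.0 * self.b - self.A @ beta))
        return beta, max(rss, 0.0), cf

    def edf_matrix(self, cf) -> np.ndarray:
        """M^-1 A, whose diagonal gives per-coefficient EDFs."""
        return linalg.cho_solve(cf, self.A, check_finite=False)

    def _log_det_penalty(self, rho: np.ndarray) -> float:
        """log of the product of positive eigenvalues of the total penalty."""
        lam = np.exp(rho)
        total = 0.0
        for sl, idx in self.groups:
            S = sum(lam[i] * self.penalties[i][1] for i in idx)
            w = np.linalg.eigvalsh(S)
            pos = w[w > 1e-10 * max(w[-1], 1e-300)]
            total += float(np.log(pos).sum())
        return total

    def objective(self, rho: np.ndarray) -> float:
        try:
            beta, rss, cf = self.solve(rho)
        except linalg.LinAlgError:
            return np.inf
        if self.criterion == "gcv":
            F = self.edf_matrix(cf)
            tau = float(np.trace(F))
            denom = self.n - self.gamma * tau
            if denom <= 1.0:
                return np.inf
            return self.n * rss / denom**2
        # profiled Gaussian REML (up to an additive constant); the likelihood
        # part is divided by gamma (>1 favours smoother, sparser fits)
        pen = sum(float(beta[sl] @ (self.penalties[i][1] @ beta[sl])) * np.exp(rho[i])
                  for i, (sl, _) in enumerate(self.penalties))
        prss = rss + pen
        nf = self.n - self.mp
        sigma2 = max(prss / nf, 1e-300)
        log_det_M = 2.0 * float(np.log(np.diag(cf[0])).sum())
        return (nf * (np.log(2.0 * np.pi * sigma2) + 1.0) / self.gamma
                + log_det_M - self._log_det_penalty(rho))


def _optimize_lambdas(prob: _PenalizedLS, n_lambda: int, n_sweeps: int) -> np.ndarray:
    rho = np.zeros(n_lambda)
    lo, hi = -12.0, 18.0
    for _ in range(n_sweeps):
        for i in range(n_lambda):
            def f(r, i=i):
                trial = rho.copy()
                trial[i] = r
                return prob.objective(trial)
            res = optimize.minimize_scalar(
                f, bounds=(lo, hi), method="bounded",
                options={"xatol": 0.15, "maxiter": 18},
            )
            if res.fun < prob.objective(rho):
                rho[i] = float(res.x)
    return rho


# --------------------------------------------------------------------------
# public API


def fit_plot_model(records: pd.DataFrame,
                   config: PlotModelConfig | None = None) -> FittedPlotModel:
    """Fit the penalized additive log-flux model to chamber observations.

    Rows with non-positive flux are dropped (their count is logged) before
    fitting, matching the positive-flux log-normal formulation.
    """
    config = config or PlotModelConfig()
    required = (set(config.smooth_terms) | set(config.categorical_terms)
                | set(config.random_effect_terms) | {"flux"})
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"records missing required columns: {sorted(missing)}")

    n0 = len(records)
    records = records[records["flux"] > 0].reset_index(drop=True)
    n_dropped = n0 - len(records)
    if n_dropped:
        log.info("dropped %d non-positive flux rows of %d", n_dropped, n0)

    X, smooths, cats, res, penalties, groups, n_unpen = _assemble(records, config)
    if len(records) <= X.shape[1]:
        raise ValueError(
            f"under-determined fit: {len(records)} rows for {X.shape[1]} coefficients")
    y = np.log(records["flux"].to_numpy(float))

    prob = _PenalizedLS(X, y, penalties, groups, n_unpen,
                        config.criterion, config.gamma)
    rho = _optimize_lambdas(prob, len(penalties), config.n_sweeps)
    beta, rss, cf = prob.solve(rho)
    F = prob.edf_matrix(cf)
    tau = float(np.trace(F))
    sigma2 = rss / max(prob.n - tau, 1.0)
    cov = sigma2 * linalg.cho_solve(cf, np.eye(prob.p), check_finite=False)

    edf = {}
    diagF = np.diag(F)
    for name, term in {**smooths, **cats, **res}.items():
        edf[name] = float(diagF[term.sl].sum())
    removed = {name for name in smooths if edf[name] < EDF_REMOVAL_THRESHOLD}

    lambdas = {i: float(np.exp(r)) for i, r in enumerate(rho)}
    tss = float(((y - y.mean()) ** 2).sum())
    train_means = {name: float(records[name].mean()) for name in config.smooth_terms}

    return FittedPlotModel(
        config=config, smooths=smooths, categoricals=cats, random_effects=res,
        coef=beta, cov=cov, lambdas=lambdas, edf_by_term=edf, edf_total=tau,
        sigma2=sigma2, rss=rss, tss=tss, n_obs=len(records),
        n_dropped_nonpositive=n_dropped, terms_removed=removed,
        train_means=train_means,
    )


def _design_for(model: FittedPlotModel, records: pd.DataFrame,
                include_random: bool) -> np.ndarray:
    n = len(records)
    X = np.zeros((n, model.coef.size))
    X[:, 0] = 1.0
    for term in model.categoricals.values():
        X[:, term.sl] = term.design(records[term.name])
    for term in model.smooths.values():
        x = records[term.name].to_numpy(float)
        if term.log_scale:
            xt = np.log(x)
        else:
            xt = x
        n_out = int(np.sum((xt < term.xmin) | (xt > term.xmax)))
        if n_out:
            log.info("%s: clamped %d value(s) outside training range", term.name, n_out)
        X[:, term.sl] = term.design(x)
    if include_random:
        for term in model.random_effects.values():
            X[:, term.sl] = term.design(records[term.name])
    return X


def predict_plot_flux(model: FittedPlotModel, records: pd.DataFrame,
                      include_random: bool = False,
                      with_interval: bool = False):
    """Predicted flux (mg m^-2 h^-1), strictly positive (exp of fitted log mean).

    With ``include_random`` off, predictions are population level (random
    intercepts set to zero).  Covariates outside the training range are
    clamped to the range boundary.  With ``with_interval``, returns
    ``(flux, lower, upper)`` from the pointwise 95% band on the log scale.
    """
    X = _design_for(model, records, include_random)
    eta = X @ model.coef
    flux = np.exp(eta)
    if not with_interval:
        return flux
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, model.cov, X), 0.0))
    return flux, np.exp(eta - 1.96 * se), np.exp(eta + 1.96 * se)


def partial_effect(model: FittedPlotModel, covariate: str,
                   grid: np.ndarray | None = None, n_grid: int = 101) -> PartialEffect:
    """Centred smooth effect of one covariate on the log-flux scale.

    The sum-to-zero constraint makes the effect average exactly zero over
    the training covariate distribution.  The 95% band comes from the
    coefficient posterior covariance.
    """
    if covariate in model.terms_removed:
        log.info("%s was removed by selection (EDF ~ 0); effect is ~flat", covariate)
    if covariate not in model.smooths:
        raise ValueError(f"{covariate!r} is not a fitted smooth term")
    term = model.smooths[covariate]
    if grid is None:
        lo, hi = term.xmin, term.xmax
        g = np.linspace(lo, hi, n_grid)
        grid = np.exp(g) if term.log_scale else g
    grid = np.asarray(grid, float)
    B = term.design(grid)
    eff = B @ model.coef[term.sl]
    se = np.sqrt(np.maximum(
        np.einsum("ij,jk,ik->i", B, model.cov[term.sl, term.sl], B), 0.0))
    return PartialEffect(covariate=covariate, grid=grid, effect=eff,
                         lower=eff - 1.96 * se, upper=eff + 1.96 * se)


def deviance_explained(model: FittedPlotModel) -> float:
    """1 - residual deviance / null deviance of the Gaussian log-scale fit."""
    return model.deviance_explained
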