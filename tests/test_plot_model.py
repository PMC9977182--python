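"""Penalized additive plot-scale model: fit, effects, prediction, selection."""

import numpy as np
import pandas as pd
import pytest

from prairie_ch4.plot_model import (
    PlotModelConfig,
    deviance_explained,
    fit_plot_model,
    partial_effect,
    predict_plot_flux,
)
from prairie_ch4.synthetic import ChamberGeneratorConfig, generate_chamber_dataset
from prairie_ch4.truth import TrueResponse

FIT_CFG = ChamberGeneratorConfig(n_wetlands=26, chambers_per_wetland=3, years=2)


@pytest.fixture(scope="module")
def fitted():
    """One moderate-size synthetic fit shared by the read-only checks."""
    df, truth = generate_chamber_dataset(FIT_CFG, seed=11)
    return fit_plot_model(df), df, truth


def test_deviance_explained_in_generator_band(fitted):
    model, _, _ = fitted
    assert 0.5 <= deviance_explained(model) <= 0.7
    assert 0.0 <= model.adjusted_r2 <= 1.0


def test_partial_effects_centred_over_training_rows(fitted):
    model, df, _ = fitted
    for name in ("wfps", "soil_temp", "ndvi"):
        pe = partial_effect(model, name, grid=df[name].to_numpy())
        assert abs(pe.effect.mean()) < 1e-8
        assert np.all(pe.lower <= pe.effect) and np.all(pe.effect <= pe.upper)


def test_temperature_effect_monotone_and_close_to_truth(fitted):
    model, _, truth = fitted
    pe = partial_effect(model, "soil_temp")
    assert np.all(np.diff(pe.effect) > -0.02)
    centred_true = truth.f_temp(pe.grid) - truth.f_temp(pe.grid).mean()
    rmse = np.sqrt(np.mean((pe.effect - pe.effect.mean() - centred_true) ** 2))
    assert rmse < 0.15


def test_grassland_predicts_above_cropland(fitted):
    """The generating land-cover offset favours grassland surroundings."""
    model, df, _ = fitted
    rec = df.iloc[[0]].copy()
    grass = rec.assign(land_cover="grassland")
    crop = rec.assign(land_cover="cropland")
    assert predict_plot_flux(model, grass)[0] >= predict_plot_flux(model, crop)[0]


def test_predictions_strictly_positive_with_intervals(fitted):
    model, df, _ = fitted
    flux, lo, hi = predict_plot_flux(model, df.head(50), with_interval=True)
    assert np.all(flux > 0) and np.all(lo > 0)
    assert np.all(lo <= flux) and np.all(flux <= hi)


def test_extrapolation_clamps_to_boundary(fitted):
    model, df, _ = fitted
    rec = df.iloc[[0]].copy()
    hot = rec.assign(soil_temp=100.0)
    edge = rec.assign(soil_temp=df["soil_temp"].max())
    assert predict_plot_flux(model, hot)[0] == pytest.approx(
        predict_plot_flux(model, edge)[0], rel=1e-9)


def test_noise_free_fit_reproduces_signal():
    truth = TrueResponse(sigma_wetland=0.0, sigma_chamber=0.0, sigma_resid=0.0)
    cfg = ChamberGeneratorConfig(n_wetlands=16, chambers_per_wetland=2,
                                 years=1, truth=truth)
    df, _ = generate_chamber_dataset(cfg, seed=4)
    # a richer basis and no complexity inflation: the question here is
    # approximation of a known deterministic signal, not selection
    model = fit_plot_model(df, PlotModelConfig(basis_dim=16, gamma=1.0))
    assert deviance_explained(model) >= 0.99
    pred = predict_plot_flux(model, df, include_random=True)
    assert np.allclose(pred, df["flux"], rtol=0.01)


def test_pure_noise_response_explains_nothing():
    df, _ = generate_chamber_dataset(
        ChamberGeneratorConfig(n_wetlands=14, chambers_per_wetland=2, years=2),
        seed=6)
    rng = np.random.default_rng(0)
    df = df.assign(flux=np.exp(rng.normal(0.0, 1.0, len(df))))
    assert deviance_explained(fit_plot_model(df)) <= 0.05


def test_constant_flux_flat_effects():
    df, _ = generate_chamber_dataset(
        ChamberGeneratorConfig(n_wetlands=8, chambers_per_wetland=2, years=1),
        seed=1)
    df = df.assign(flux=2.0)
    model = fit_plot_model(df)
    assert deviance_explained(model) == pytest.approx(0.0, abs=1e-9)
    pe = partial_effect(model, "wfps")
    assert np.max(np.abs(pe.effect)) < 1e-4


def test_invariance_to_row_order_and_id_relabeling():
    df, _ = generate_chamber_dataset(
        ChamberGeneratorConfig(n_wetlands=12, chambers_per_wetland=2, years=1),
        seed=8)
    m1 = fit_plot_model(df)
    shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    relabel = {w: f"X{i}" for i, w in enumerate(sorted(df["wetland_id"].unique()))}
    shuffled = shuffled.assign(
        wetland_id=shuffled["wetland_id"].map(relabel),
        chamber_id=shuffled["chamber_id"].map(
            lambda c: c.replace(c[:5], relabel[c[:5]])))
    m2 = fit_plot_model(shuffled)
    probe = df.head(100)
    probe2 = probe.assign(
        wetland_id=probe["wetland_id"].map(relabel),
        chamber_id=probe["chamber_id"].map(
            lambda c: c.replace(c[:5], relabel[c[:5]])))
    p1 = predict_plot_flux(m1, probe)
    p2 = predict_plot_flux(m2, probe2)
    assert np.allclose(p1, p2, rtol=1e-2)


def test_random_effects_improve_out_of_sample_likelihood():
    """With wetland-level noise present, dropping the random intercepts
    lowers the held-out Gaussian log-likelihood (median over replicates)."""
    no_re = PlotModelConfig(random_effect_terms=())
    strong_re = TrueResponse(sigma_wetland=1.0, sigma_chamber=0.8)
    deltas = []
    for seed in range(6):
        df, _ = generate_chamber_dataset(
            ChamberGeneratorConfig(n_wetlands=16, chambers_per_wetland=3,
                                   years=1, truth=strong_re), seed=30 + seed)
        train = df[df["step_index"] % 2 == 0]
        test = df[df["step_index"] % 2 == 1]

        def oos_loglik(model, include_random):
            mu = np.log(predict_plot_flux(model, test,
                                          include_random=include_random))
            resid = np.log(test["flux"].to_numpy()) - mu
            s2 = model.sigma2
            return float(-0.5 * np.sum(np.log(2 * np.pi * s2) + resid**2 / s2))

        with_re = oos_loglik(fit_plot_model(train), True)
        without = oos_loglik(fit_plot_model(train, no_re), False)
        deltas.append(with_re - without)
    assert np.median(deltas) > 0


def test_agrees_with_mgcv_reference_fit(tmp_path):
    """Independent cross-check: R's mgcv (REML, select=TRUE) on the same
    data gives a similar deviance explained and an essentially identical
    temperature partial effect."""
    import subprocess
    import textwrap

    df, _ = generate_chamber_dataset(
        ChamberGeneratorConfig(n_wetlands=14, chambers_per_wetland=2, years=1),
        seed=19)
    model = fit_plot_model(df)
    df.to_csv(tmp_path / "d.csv", index=False)
    grid = np.linspace(df["soil_temp"].min(), df["soil_temp"].max(), 41)
    pd.DataFrame({"soil_temp": grid}).to_csv(tmp_path / "grid.csv", index=False)
    rscript = textwrap.dedent(f"""
        library(mgcv)
        d <- read.csv("{tmp_path}/d.csv")
        d$y <- log(d$flux)
        for (col in c("wetland_id", "chamber_id", "land_cover",
                      "season_interval")) d[[col]] <- factor(d[[col]])
        fit <- gam(y ~ land_cover + season_interval + s(wfps) + s(soil_temp)
                   + s(ndvi) + s(log(wetland_size)) + s(hydroperiod)
                   + s(wfps_lag) + s(soil_temp_lag) + s(ndvi_lag)
                   + s(wetland_id, bs="re") + s(chamber_id, bs="re"),
                   data=d, method="REML", select=TRUE)
        writeLines(as.character(summary(fit)$dev.expl), "{tmp_path}/dev.txt")
        g <- read.csv("{tmp_path}/grid.csv")
        nd <- d[rep(1, nrow(g)), ]; nd$soil_temp <- g$soil_temp
        pt <- predict(fit, nd, type="terms")
        write.csv(data.frame(eff=pt[, "s(soil_temp)"]),
                  "{tmp_path}/eff.csv", row.names=FALSE)
    """)
    (tmp_path / "fit.R").write_text(rscript)
    subprocess.run(["Rscript", str(tmp_path / "fit.R")], check=True,
                   capture_output=True, timeout=600)
    mgcv_dev = float((tmp_path / "dev.txt").read_text().strip())
    assert abs(model.deviance_explained - mgcv_dev) < 0.08
    eff = pd.read_csv(tmp_path / "eff.csv")["eff"].to_numpy()
    pe = partial_effect(model, "soil_temp", grid=grid)
    a = pe.effect - pe.effect.mean()
    b = eff - eff.mean()
    assert np.corrcoef(a, b)[0, 1] > 0.95


def test_fit_errors():
    df, _ = generate_chamber_dataset(
        ChamberGeneratorConfig(n_wetlands=8, chambers_per_wetland=2, years=1),
        seed=1)
    with pytest.raises(KeyError, match="missing"):
        fit_plot_model(df.drop(columns=["ndvi"]))
    with pytest.raises(ValueError, match="under-determined"):
        fit_plot_model(df.head(80))
    with pytest.raises(ValueError):
        PlotModelConfig(basis_dim=3)
    with pytest.raises(ValueError):
        PlotModelConfig(criterion="aic")


def test_partial_effect_term_errors(fitted):
    model, _, _ = fitted
    with pytest.raises(ValueError, match="smooth term"):
        partial_effect(model, "land_cover")


def test_unknown_categorical_level_raises(fitted):
    model, df, _ = fitted
    bad = df.head(3).assign(land_cover="forest")
    with pytest.raises(ValueError, match="unknown level"):
        predict_plot_flux(model, bad)
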