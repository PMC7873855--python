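"""Synthetic designs: noise calibration, censoring families, closed-form
ground truth and the IPCW evaluation metrics."""

import numpy as np
import pytest
from scipy import stats

from srforest import (
    SimulationConfig,
    calibrate_sigma,
    eval_metrics,
    generate,
    restrict,
    toy_config,
    true_rmst,
)
from srforest.ipcw import censoring_survival, fit_cox_censoring


def test_calibrate_sigma_identity_analytic():
    """Identity link: σ² = Σαᵢ²·Var(h(U))/SNR on the unit covariate scale."""
    cfg = SimulationConfig(model=1, link="identity", p=5, snr=0.3)
    expected = 2 * 0.25**2 * (1 / 12) / 0.3
    assert calibrate_sigma(cfg) == pytest.approx(expected)
    cfg2 = SimulationConfig(model=2, link="identity", p=5, snr=0.3)
    assert calibrate_sigma(cfg2) == pytest.approx(2 * 0.25**2 * (4 / 45) / 0.3)


def test_calibrate_sigma_scaling_properties():
    base = SimulationConfig(model=1, link="identity", p=4, snr=0.3)
    high = SimulationConfig(model=1, link="identity", p=4, snr=3000.0)
    assert calibrate_sigma(high) < calibrate_sigma(base) / 1000
    doubled = SimulationConfig(
        model=1, link="identity", p=4, snr=0.3, alphas=(0.5, 0.5)
    )
    assert calibrate_sigma(doubled) == pytest.approx(4 * calibrate_sigma(base))


def test_calibrate_sigma_exp_link_monte_carlo():
    cfg = SimulationConfig(model=1, link="exp", p=5, snr=0.3)
    v1 = calibrate_sigma(cfg)
    assert v1 == calibrate_sigma(cfg)  # fixed internal seed
    assert v1 > 0


def test_observed_data_reconstruct_from_latents():
    s = generate(SimulationConfig(model=2, link="identity", p=3, n=500, seed=1))
    np.testing.assert_array_equal(s.data.Z, np.minimum(s.T, s.C))
    np.testing.assert_array_equal(s.data.delta, (s.T <= s.C).astype(int))
    assert ((s.true_mu >= 0) & (s.true_mu <= s.config.L)).all()


def test_seeded_reproducibility():
    cfg = SimulationConfig(model=1, link="identity", p=2, n=100, seed=5)
    a, b = generate(cfg), generate(cfg)
    np.testing.assert_array_equal(a.data.X, b.data.X)
    np.testing.assert_array_equal(a.data.Z, b.data.Z)


def test_exponential_censoring_distribution():
    """C·λ_C·2^{X₁} is standard exponential (gamma shape 1)."""
    cfg = SimulationConfig(model=1, link="identity", p=2, n=100_000, seed=2)
    s = generate(cfg)
    rate = cfg.lambda_C * np.exp(s.data.X[:, 0] * np.log(2))
    d, _ = stats.kstest(s.C * rate, "expon")
    assert d < 0.01


def test_gamma_censoring_parameterization():
    """Shape-α gamma with scale 1/(λ_C·2^{X₁}): C·rate ~ Γ(α, 1)."""
    cfg = SimulationConfig(
        model=1, link="identity", p=2, n=100_000, gamma_shape=0.5, seed=3
    )
    s = generate(cfg)
    rate = cfg.lambda_C * np.exp(s.data.X[:, 0] * np.log(2))
    d, _ = stats.kstest(s.C * rate, "gamma", args=(0.5,))
    assert d < 0.01


def test_true_mu_approaches_mean_for_large_L():
    cfg = SimulationConfig(model=1, link="identity", p=2, n=10, L=1000.0, seed=0)
    X = np.array([[0.5, -0.5], [0.0, 0.0]])
    mu = true_rmst(cfg, X)
    m = 5 + 0.25 * X[:, 0] + 0.25 * X[:, 1]
    np.testing.assert_allclose(mu, m, rtol=1e-8)


def test_true_mu_matches_monte_carlo(rng):
    cfg = SimulationConfig(model=2, link="identity", p=2, n=10, seed=0)
    sigma = float(np.sqrt(calibrate_sigma(cfg)))
    X = rng.uniform(-1, 1, (10, 2))
    mu = true_rmst(cfg, X)
    m = 5 + 0.25 * (X[:, 0] ** 2 + X[:, 1] ** 2)
    draws = 200_000
    eps = rng.normal(0, sigma, draws)
    for i in range(10):
        mc = np.minimum(m[i] + eps, cfg.L)
        se = mc.std() / np.sqrt(draws)
        assert abs(mu[i] - mc.mean()) < 3 * se


def test_operating_characteristics_at_coverage_defaults():
    """Uncensoring 60–70% and truncation 2–5% at λ_C=0.08, L=5.4, n=10^4."""
    cfg = SimulationConfig(model=1, link="identity", p=5, n=10_000, L=5.4, seed=8)
    s = generate(cfg)
    assert 0.60 <= s.data.delta.mean() <= 0.70
    trunc = np.mean(np.minimum(s.T, s.C) >= cfg.L)
    assert 0.02 <= trunc <= 0.05


def test_toy_preset_operating_rates():
    s = generate(toy_config(n=50_000, seed=4))
    L = s.config.L
    cens_rate = np.mean(s.C <= np.minimum(s.T, L))
    trunc_rate = np.mean(L <= np.minimum(s.T, s.C))
    assert abs(cens_rate - 0.33) < 0.02
    assert abs(trunc_rate - 0.11) < 0.02


# ------------------------------------------------------------- metrics
def test_metrics_zero_for_perfect_predictions(model1_sample):
    r = model1_sample.restricted()
    rep = eval_metrics(r, r.ZL)  # predicts ZL exactly for the uncensored
    assert rep.mae == 0.0 and rep.rmse == 0.0


def test_metrics_hand_case():
    from srforest import SurvivalDataset

    Z = np.array([1.0, 3.0])
    data = SurvivalDataset(np.zeros((2, 1)), Z, np.ones(2))
    r = restrict(data, 10.0)
    preds = Z + np.array([1.0, 3.0])  # absolute errors 1 and 3
    rep = eval_metrics(r, preds)
    assert rep.mae == pytest.approx(2.0)
    assert rep.rmse == pytest.approx(np.sqrt(5.0))


def test_metrics_match_independent_reimplementation(rng):
    cfg = SimulationConfig(model=1, link="identity", p=3, n=600, seed=33)
    s = generate(cfg)
    r = s.restricted()
    preds = rng.uniform(4, 5.3, r.n)
    rep = eval_metrics(r, preds)
    # longhand recomputation from first principles
    model = fit_cox_censoring(r.base)
    surv = censoring_survival(model, r.ZL, r.base.X)
    w = r.deltaL / np.maximum(surv, 0.05)
    mae = np.sum(w * np.abs(r.ZL - preds)) / r.n
    rmse = np.sqrt(np.sum(w * (r.ZL - preds) ** 2) / r.n)
    assert rep.mae == pytest.approx(mae)
    assert rep.rmse == pytest.approx(rmse)
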