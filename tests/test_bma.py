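"""MR-BMA: transform, marginal likelihood vs quadrature, posterior
identities, diagnostics oracles, and the iterative pruning loop."""
import numpy as np
import pytest
from scipy import stats

from bloodmr import BmaConfig, MRBMA, SyntheticGwasConfig, generate_summary_stats, harmonize
from bloodmr.bma import (
    bma_transform,
    cooks_distance,
    cooks_threshold,
    enumerate_posterior,
    iterative_prune,
    log_marginal_likelihood,
    snp_q_contributions,
)
from tests.conftest import single_cause_theta


def _toy_yx(seed=0, j=40, k=4, theta=None, noise=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(j, k))
    theta = np.zeros(k) if theta is None else np.asarray(theta, float)
    y = x @ theta + noise * rng.normal(size=j)
    return y, x


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------

def test_transform_identity_when_se_one(small_hset):
    hset = small_hset
    ones = np.ones_like(hset.beta_y)
    clone = type(hset)(hset.snp_ids, hset.exposures, hset.beta_x, hset.se_x,
                       hset.beta_y, ones)
    y, x = bma_transform(clone)
    np.testing.assert_array_equal(y, hset.beta_y)
    np.testing.assert_array_equal(x, hset.beta_x)


def test_transform_row_scaling(small_hset):
    hset = small_hset
    y1, x1 = bma_transform(hset)
    doubled = type(hset)(hset.snp_ids, hset.exposures, hset.beta_x, hset.se_x,
                         hset.beta_y, 2.0 * hset.se_y)
    y2, x2 = bma_transform(doubled)
    np.testing.assert_allclose(y2, y1 / 2)
    np.testing.assert_allclose(x2, x1 / 2)


def test_transform_equals_explicit_wls(small_hset):
    """Regression on the transformed pair equals inverse-variance weighted
    regression on the raw data."""
    y, x = bma_transform(small_hset)
    theta_t = np.linalg.lstsq(x, y, rcond=None)[0]
    w = 1.0 / small_hset.se_y ** 2
    xw = small_hset.beta_x * w[:, None]
    theta_w = np.linalg.solve(small_hset.beta_x.T @ xw, xw.T @ small_hset.beta_y)
    np.testing.assert_allclose(theta_t, theta_w, atol=1e-12)


# ---------------------------------------------------------------------------
# Marginal likelihood
# ---------------------------------------------------------------------------

def test_log_marginal_orders_signal_above_null():
    y, x = _toy_yx(seed=1, k=2, theta=[1.0, 0.0], noise=0.3)
    assert log_marginal_likelihood(y, x, [0], 0.25) > \
        log_marginal_likelihood(y, x, [1], 0.25)


def test_log_marginal_matches_numerical_quadrature():
    """Closed form equals 2-D numerical integration over the coefficient
    prior on a 6-observation, 2-predictor toy."""
    from scipy.integrate import dblquad

    rng = np.random.default_rng(7)
    x = rng.normal(size=(6, 2))
    y = rng.normal(size=6)
    sigma = 0.25

    def integrand(b2, b1):
        b = np.array([b1, b2])
        lik = np.exp(-0.5 * np.sum((y - x @ b) ** 2)) * (2 * np.pi) ** (-3.0)
        prior = np.exp(-0.5 * (b1 ** 2 + b2 ** 2) / sigma ** 2) / (2 * np.pi * sigma ** 2)
        return lik * prior

    val, _ = dblquad(integrand, -8 * sigma, 8 * sigma,
                     lambda _: -8 * sigma, lambda _: 8 * sigma,
                     epsabs=1e-13, epsrel=1e-11)
    assert log_marginal_likelihood(y, x, [0, 1], sigma) == pytest.approx(
        np.log(val), abs=1e-6)


def test_duplicated_columns_have_identical_marginals():
    y, x = _toy_yx(seed=2, k=2)
    x_dup = np.column_stack([x[:, 0], x[:, 0]])
    assert log_marginal_likelihood(y, x_dup, [0], 0.3) == pytest.approx(
        log_marginal_likelihood(y, x_dup, [1], 0.3), abs=1e-12)


# ---------------------------------------------------------------------------
# Posterior identities
# ---------------------------------------------------------------------------

def test_posterior_normalization_and_identities():
    y, x = _toy_yx(seed=3, j=60, k=5, theta=[0.5, 0, 0, 0, 0], noise=1.0)
    post = enumerate_posterior(y, x, list("ABCDE"), BmaConfig(max_model_size=5))
    assert post.models["pp"].sum() == pytest.approx(1.0, abs=1e-10)
    # MIP/MACE recomputed from the model table
    for k_i, name in enumerate(post.exposures):
        mip = sum(row["pp"] for _, row in post.models.iterrows()
                  if k_i in row["indices"])
        mace = sum(row["pp"] * row["estimates"][row["indices"].index(k_i)]
                   for _, row in post.models.iterrows() if k_i in row["indices"])
        assert post.mip[name] == pytest.approx(mip, abs=1e-12)
        assert post.mace[name] == pytest.approx(mace, abs=1e-12)
    # PP-sorted
    assert (np.diff(post.models["pp"].to_numpy()) <= 1e-15).all()


def test_identical_exposure_columns_share_mip():
    y, x = _toy_yx(seed=4, j=50, k=1, theta=[0.6], noise=0.5)
    x2 = np.column_stack([x[:, 0], x[:, 0]])
    post = enumerate_posterior(y, x2, ["A", "B"], BmaConfig(max_model_size=2))
    assert post.mip["A"] == pytest.approx(post.mip["B"], abs=1e-10)


def test_single_exposure_mace_equals_wls():
    y, x = _toy_yx(seed=5, j=30, k=1, theta=[0.4], noise=0.5)
    post = enumerate_posterior(y, x, ["A"], BmaConfig(max_model_size=1))
    wls = float(np.linalg.lstsq(x, y, rcond=None)[0][0])
    assert post.mace["A"] == pytest.approx(wls, abs=1e-12)
    assert post.mip["A"] == pytest.approx(1.0)


def test_posterior_invariant_to_row_order():
    y, x = _toy_yx(seed=6, j=40, k=3, theta=[0.3, 0, 0])
    perm = np.random.default_rng(0).permutation(40)
    p1 = enumerate_posterior(y, x, list("ABC"), BmaConfig(max_model_size=3))
    p2 = enumerate_posterior(y[perm], x[perm], list("ABC"),
                             BmaConfig(max_model_size=3))
    np.testing.assert_allclose(p1.mip.to_numpy(), p2.mip.to_numpy(), atol=1e-12)
    np.testing.assert_allclose(p1.mace.to_numpy(), p2.mace.to_numpy(), atol=1e-12)


def test_noiseless_single_cause_top_model_across_prior_sds():
    cfg = SyntheticGwasConfig(n_snps=80, n_exposures=4, sparsity=0.6,
                              causal_effects=single_cause_theta(4, 1, 0.4),
                              noise_scale=0.0, pleiotropy_frac=0.0,
                              missing_frac=0.0, seed=8)
    panels, out = generate_summary_stats(cfg)
    hset = harmonize(panels, out)
    y, x = bma_transform(hset)
    causal = hset.exposures[1]
    for sigma in (0.05, 0.1, 0.25, 0.5, 1.0):
        post = enumerate_posterior(y, x, hset.exposures,
                                   BmaConfig(prior_sd=sigma, max_model_size=4))
        assert post.models.iloc[0]["model"] == (causal,)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def test_q_contributions_perfect_fit_and_identity():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(20, 2))
    y_exact = x @ np.array([0.5, -0.2])
    assert snp_q_contributions(y_exact, x, [0, 1]).max() == pytest.approx(0, abs=1e-20)

    y = y_exact + rng.normal(size=20)
    q_j = snp_q_contributions(y, x, [0, 1])
    theta = np.linalg.lstsq(x, y, rcond=None)[0]
    rss = float(np.sum((y - x @ theta) ** 2))
    assert q_j.sum() == pytest.approx(rss, abs=1e-10)


def test_q_contributions_flag_planted_outlier():
    rng = np.random.default_rng(10)
    x = rng.normal(size=(60, 2))
    y = x @ np.array([0.5, -0.2]) + rng.normal(size=60)
    y[17] += 10.0  # 10-sigma outlier
    q_j = snp_q_contributions(y, x, [0, 1])
    assert int(np.argmax(q_j)) == 17
    assert q_j[17] > 10


def test_cooks_distance_matches_leave_one_out_refit():
    """Hat-matrix Cook's distance equals the leave-one-out refit
    definition Cd_j = sum_i (yhat_i - yhat_i(-j))^2 / (d s^2)."""
    rng = np.random.default_rng(11)
    x = rng.normal(size=(12, 2))
    y = x @ np.array([0.4, 0.1]) + rng.normal(size=12)
    cd = cooks_distance(y, x, [0, 1])
    theta_full = np.linalg.lstsq(x, y, rcond=None)[0]
    yhat = x @ theta_full
    s2 = np.sum((y - yhat) ** 2) / (12 - 2)
    for j in range(12):
        keep = [i for i in range(12) if i != j]
        theta_j = np.linalg.lstsq(x[keep], y[keep], rcond=None)[0]
        loo = np.sum((yhat - x @ theta_j) ** 2) / (2 * s2)
        assert cd[j] == pytest.approx(loo, abs=1e-10)


def test_cooks_threshold_is_f_median():
    assert cooks_threshold(1, 100) == pytest.approx(
        stats.f.ppf(0.5, 1, 99), abs=1e-12)
    assert cooks_threshold(1, 100) == pytest.approx(0.458, abs=0.005)


def test_duplicated_rows_get_equal_cooks_distance():
    x = np.tile(np.array([[1.0, 0.5], [0.3, -1.0], [0.8, 0.2]]), (4, 1))
    y = np.tile(np.array([0.6, -0.7, 0.5]), 4)
    y = y + 0.01 * np.arange(12) % 3  # break exact fit but keep row groups
    cd = cooks_distance(y + 0.0, x, [0, 1])
    assert cd.shape == (12,)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def _planted_outlier_set(seed, n_outliers=3, effect=0.3):
    cfg = SyntheticGwasConfig(n_snps=150, n_exposures=8,
                              causal_effects=single_cause_theta(8, 0, 0.4),
                              pleiotropy_frac=0.0, missing_frac=0.0,
                              flip_frac=0.0, seed=seed)
    panels, out = generate_summary_stats(cfg)
    hset = harmonize(panels, out)
    rng = np.random.default_rng(seed + 1000)
    chosen = rng.choice(hset.n_snps, size=n_outliers, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_outliers)
    hset.beta_y[chosen] += effect * signs
    return hset, {hset.snp_ids[i] for i in chosen}


def test_clean_data_needs_no_pruning():
    cfg = SyntheticGwasConfig(n_snps=150, n_exposures=4,
                              causal_effects=single_cause_theta(4, 0, 0.4),
                              pleiotropy_frac=0.0, missing_frac=0.0, seed=17)
    panels, out = generate_summary_stats(cfg)
    hset = harmonize(panels, out)
    res = MRBMA(hset, BmaConfig(max_model_size=4)).fit(prune=True)
    assert res.rounds_run == 0
    assert res.pruned == []


def test_planted_outliers_are_pruned():
    hset, planted = _planted_outlier_set(seed=17)
    res = MRBMA(hset, BmaConfig(max_model_size=8)).fit(prune=True)
    removed = {r.snp for r in res.pruned}
    assert planted <= removed
    assert max(r.round for r in res.pruned) <= 2
    assert res.posterior.models.iloc[0]["model"][0] == hset.exposures[0]


def test_pruning_is_idempotent():
    hset, _ = _planted_outlier_set(seed=23)
    config = BmaConfig(max_model_size=8)
    y, x = bma_transform(hset)
    keep, _, audit = iterative_prune(y, x, hset.snp_ids, hset.exposures, config)
    keep2, _, audit2 = iterative_prune(y[keep], x[keep],
                                       [hset.snp_ids[i] for i in keep],
                                       hset.exposures, config)
    assert audit2 == []
    assert len(keep2) == len(keep)


def test_pre_and_post_prune_results_reported_side_by_side():
    hset, _ = _planted_outlier_set(seed=29)
    res = MRBMA(hset, BmaConfig(max_model_size=8)).fit(prune=True)
    assert res.pre_prune.models["pp"].sum() == pytest.approx(1.0, abs=1e-10)
    assert res.posterior.models["pp"].sum() == pytest.approx(1.0, abs=1e-10)
    # directional consistency of the causal estimate before/after pruning
    causal = hset.exposures[0]
    assert res.posterior.mip.idxmax() == causal
    assert np.sign(res.pre_prune.mace[causal]) == np.sign(
        res.posterior.mace[causal])
    assert "MR-BMA" in res.summary()


def test_bma_config_validation():
    with pytest.raises(ValueError):
        BmaConfig(prior_inclusion=0.0).validate()
    with pytest.raises(ValueError):
        BmaConfig(prior_sd=-1).validate()
    with pytest.raises(ValueError):
        BmaConfig(max_model_size=20).validate(k=15)
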