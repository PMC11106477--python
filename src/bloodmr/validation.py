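"""Simulation studies validating the estimators against ground truth.

Each function runs a seeded Monte-Carlo experiment under the package's
default study conditions (blood-trait-scale exposure GWAS, IBD-scale
case-control outcome) and returns the measured quantities: oracle
agreement of the univariable estimators, MR-BMA causal-exposure recovery,
planted-outlier pruning recovery, IVW type-I error and power at the
Bonferroni threshold, and spline dose-response sanity checks.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .bma import BmaConfig, bma_transform, enumerate_posterior, iterative_prune, log_marginal_likelihood
from .instruments import harmonize, select_genomewide
from .simulate import SyntheticGwasConfig, generate_summary_stats
from .spline import RcsLogistic, find_crossings, harrell_knots
from .uvmr import UnivariableMR


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Estimator oracle agreement
# ---------------------------------------------------------------------------

def estimator_oracle_deviation(seed: int = 0, n_instances: int = 40) -> float:
    """Max |implementation - oracle| for IVW, Egger and median estimators
    on small (<= 10 SNP) random instances.

    Oracles use a different code path: IVW and Egger via numpy least
    squares on the sqrt-weight-scaled design, medians via brute-force
    minimisation of the weighted L1 objective over candidate ratios.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        j = int(rng.integers(4, 11))
        bx = rng.uniform(0.05, 0.5, j) * rng.choice([-1, 1], j)
        sx = rng.uniform(0.002, 0.01, j)
        sy = rng.uniform(0.01, 0.05, j)
        by = 0.3 * bx + rng.normal(0, sy)
        m = UnivariableMR(bx, sx, by, sy)

        # IVW: weighted least squares through the origin
        sw = 1.0 / sy
        slope = float(np.linalg.lstsq((bx * sw)[:, None], by * sw,
                                      rcond=None)[0][0])
        worst = max(worst, abs(m.fit("ivw_fe").estimate - slope),
                    abs(m.fit("ivw_re").estimate - slope))

        # Egger: weighted least squares with intercept, beta_x oriented >= 0
        sgn = np.where(bx < 0, -1.0, 1.0)
        design = np.column_stack([np.ones(j), bx * sgn]) * sw[:, None]
        coefs = np.linalg.lstsq(design, by * sgn * sw, rcond=None)[0]
        egger = m.fit("egger")
        worst = max(worst, abs(egger.egger_intercept - coefs[0]),
                    abs(egger.estimate - coefs[1]))

        # simple median: the ordinary sample median of the Wald ratios
        ratios = by / bx
        worst = max(worst, abs(m._median_point("simple_median")
                               - float(np.median(ratios))))

        # weighted median: exhaustive minimisation of the weighted L1
        # objective over candidate ratios (unique with continuous weights)
        weights = (bx / sy) ** 2
        objective = [float(np.sum(weights * np.abs(ratios - c)))
                     for c in ratios]
        oracle = ratios[int(np.argmin(objective))]
        worst = max(worst, abs(m._median_point("weighted_median") - oracle))

        # penalized median: same exhaustive check with the down-weighted
        # heterogeneity penalty applied to the oracle's weights
        est0 = ratios[int(np.argmin(objective))]
        q_j = weights * (ratios - est0) ** 2
        pen_w = weights * np.minimum(1.0, 20.0 * stats.chi2.sf(q_j, 1))
        pen_obj = [float(np.sum(pen_w * np.abs(ratios - c))) for c in ratios]
        pen_oracle = ratios[int(np.argmin(pen_obj))]
        worst = max(worst, abs(m._median_point("penalized_median") - pen_oracle))
    return worst


def logml_quadrature_deviation(seed: int = 7, sigma: float = 0.25) -> float:
    """|closed form - 2D quadrature| of the model marginal likelihood on a
    6-observation, 2-predictor toy."""
    from scipy.integrate import dblquad

    rng = np.random.default_rng(seed)
    x = rng.normal(size=(6, 2))
    y = rng.normal(size=6)

    def integrand(b2, b1):
        b = np.array([b1, b2])
        lik = np.exp(-0.5 * np.sum((y - x @ b) ** 2)) * (2 * np.pi) ** (-3.0)
        prior = np.exp(-0.5 * (b1 ** 2 + b2 ** 2) / sigma ** 2) \
            / (2 * np.pi * sigma ** 2)
        return lik * prior

    val, _ = dblquad(integrand, -8 * sigma, 8 * sigma,
                     lambda _: -8 * sigma, lambda _: 8 * sigma,
                     epsabs=1e-13, epsrel=1e-11)
    return abs(log_marginal_likelihood(y, x, [0, 1], sigma) - np.log(val))


# ---------------------------------------------------------------------------
# MR-BMA recovery and pruning
# ---------------------------------------------------------------------------

def _clean_multivariable_set(seed: int, n_instruments: int = 150, k: int = 8,
                             theta0: float = 0.4):
    """A harmonized set of ``n_instruments`` genome-wide-significant SNPs
    (the pooled instrument definition used by the multivariable stage)."""
    cfg = SyntheticGwasConfig(
        n_snps=3 * n_instruments, n_exposures=k,
        causal_effects=np.r_[[theta0], np.zeros(k - 1)],
        pleiotropy_frac=0.0, missing_frac=0.0, flip_frac=0.0,
        palindromic_frac=0.0, seed=seed,
    )
    panels, out = generate_summary_stats(cfg)
    selected = sorted(select_genomewide(panels),
                      key=lambda s: int(s.removeprefix("rs")))
    if len(selected) < n_instruments:
        raise RuntimeError("not enough significant SNPs; increase n_snps")
    return harmonize(panels, out, snps=selected[:n_instruments])


def bma_recovery(n_reps: int = 100, seed: int = 0, k: int = 8,
                 n_instruments: int = 150, theta0: float = 0.4) -> dict:
    """Fraction of replicates in which the single causal exposure attains
    the top MIP, and in which its MACE sign matches the true effect."""
    seeds = _spawn_seeds(seed, n_reps)
    config = BmaConfig(max_model_size=k)
    top_hits = sign_hits = 0
    pp_dev = 0.0
    for s in seeds:
        hset = _clean_multivariable_set(s, n_instruments=n_instruments,
                                        k=k, theta0=theta0)
        y, x = bma_transform(hset)
        post = enumerate_posterior(y, x, hset.exposures, config)
        causal = hset.exposures[0]
        if post.mip.idxmax() == causal:
            top_hits += 1
        if np.sign(post.mace[causal]) == np.sign(theta0):
            sign_hits += 1
        pp_dev = max(pp_dev, abs(post.models["pp"].sum() - 1.0))
    return {"top_mip_rate": top_hits / n_reps,
            "mace_sign_rate": sign_hits / n_reps,
            "pp_sum_max_deviation": pp_dev,
            "n_reps": n_reps}


def pruning_recovery(n_reps: int = 100, seed: int = 0, n_outliers: int = 3,
                     n_instruments: int = 150, k: int = 8,
                     outlier_effect: float = 0.3) -> dict:
    """Planted-outlier study: add large direct outcome effects to
    ``n_outliers`` SNPs and run the iterative Q / Cook's-distance loop.

    Reports the fraction of replicates where exactly the planted SNPs are
    removed within two rounds (exact recovery) and where all planted SNPs
    are among the removed (sensitivity).
    """
    seeds = _spawn_seeds(seed, n_reps)
    config = BmaConfig(max_model_size=k)
    exact = sensitive = 0
    for s in seeds:
        hset = _clean_multivariable_set(s, n_instruments=n_instruments, k=k)
        rng = np.random.default_rng(s + 1)
        chosen = rng.choice(hset.n_snps, size=n_outliers, replace=False)
        hset.beta_y[chosen] += outlier_effect * rng.choice([-1.0, 1.0],
                                                           n_outliers)
        planted = {hset.snp_ids[i] for i in chosen}
        y, x = bma_transform(hset)
        _, _, audit = iterative_prune(y, x, hset.snp_ids, hset.exposures,
                                      config)
        removed = {r.snp for r in audit}
        rounds = max((r.round for r in audit), default=0)
        if removed == planted and rounds <= 2:
            exact += 1
        if planted <= removed:
            sensitive += 1
    return {"exact_recovery_rate": exact / n_reps,
            "sensitivity_rate": sensitive / n_reps,
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# IVW calibration
# ---------------------------------------------------------------------------

def _univariable_replicate(seed: int, theta: float):
    """One single-exposure replicate at consortium-scale sample sizes, with
    ~60 genome-wide-significant instruments (the per-trait count implied by
    the pooled instrument set)."""
    cfg = SyntheticGwasConfig(
        n_snps=150, n_exposures=1, sparsity=0.4,
        causal_effects=np.array([theta]),
        missing_frac=0.0, flip_frac=0.0, palindromic_frac=0.0, seed=seed,
    )
    panels, out = generate_summary_stats(cfg)
    panel = panels[cfg.exposures()[0]]
    sig = panel["P"].to_numpy() < 5e-8
    out_idx = out.set_index("SNP")
    ids = panel.loc[sig, "SNP"]
    return UnivariableMR(
        panel.loc[sig, "BETA"].to_numpy(),
        panel.loc[sig, "SE"].to_numpy(),
        out_idx.loc[ids, "BETA"].to_numpy(),
        out_idx.loc[ids, "SE"].to_numpy(),
    )


def ivw_calibration(n_null: int = 1000, n_power: int = 200, seed: int = 0,
                    theta: float = 0.3,
                    bonferroni_alpha: float = 0.05 / 30) -> dict:
    """Type-I error of random-effects IVW at the Bonferroni threshold under
    no effect, and its power at a causal effect of ``theta``."""
    null_seeds = _spawn_seeds(seed, n_null)
    rejections = 0
    for s in null_seeds:
        m = _univariable_replicate(s, theta=0.0)
        if m.fit("ivw_re").pvalue < bonferroni_alpha:
            rejections += 1
    power_seeds = _spawn_seeds(seed + 1, n_power)
    detected = 0
    for s in power_seeds:
        m = _univariable_replicate(s, theta=theta)
        if m.fit("ivw_re").pvalue < bonferroni_alpha:
            detected += 1
    return {"type1_rate": rejections / n_null,
            "power": detected / n_power,
            "nominal_alpha": bonferroni_alpha,
            "n_null": n_null, "n_power": n_power}


# ---------------------------------------------------------------------------
# Spline dose-response checks
# ---------------------------------------------------------------------------

def rcs_validation(seed: int = 0, n_reps: int = 25, n: int = 300) -> dict:
    """Null-band coverage of zero, crossing agreement under 10x grid
    refinement, and case/control relabeling antisymmetry."""
    seeds = _spawn_seeds(seed, n_reps + 1)
    coverage = []
    for s in seeds[:-1]:
        rng = np.random.default_rng(s)
        x = rng.normal(10.0, 2.0, n)
        y = (rng.random(n) < 0.4).astype(float)
        fit = RcsLogistic(y, x).fit()
        coverage.append(float(((fit.ci_low <= 0) & (fit.ci_high >= 0)).mean()))

    rng = np.random.default_rng(seeds[-1])
    x = rng.normal(10.0, 2.0, 600)
    eta = 0.5 * (x - 10.0)
    y = (rng.random(600) < 1 / (1 + np.exp(-eta))).astype(float)
    knots = harrell_knots(x, 4)
    coarse = RcsLogistic(y, x, knots=knots, reference=10.0).fit(grid_size=200)
    fine = RcsLogistic(y, x, knots=knots, reference=10.0).fit(grid_size=2000)
    step = float(coarse.grid[1] - coarse.grid[0])
    dev = 0.0
    for band in ("ci_low", "ci_high"):
        c1 = find_crossings(coarse.grid, getattr(coarse, band), decimals=None)
        c2 = find_crossings(fine.grid, getattr(fine, band), decimals=None)
        if len(c1) != len(c2):
            dev = np.inf
        else:
            dev = max([dev] + [abs(a - b) for a, b in zip(c1, c2)])
    flipped = RcsLogistic(1.0 - y, x, knots=knots, reference=10.0).fit(
        grid_size=200)
    anti = float(np.max(np.abs(coarse.log_or + flipped.log_or)))
    return {"null_band_coverage": float(np.mean(coverage)),
            "crossing_refinement_max_dev": float(dev),
            "refinement_grid_step": step,
            "relabel_antisymmetry_max_abs": anti,
            "n_reps": n_reps}
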