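"""Univariable two-sample Mendelian randomization estimators.

Six estimators of the causal log-OR of one exposure on a binary outcome
from J harmonized instruments: fixed-effect and multiplicative
random-effects inverse-variance weighting (IVW), simple / weighted /
penalized weighted median, and MR-Egger regression. Heterogeneity
(Cochran's Q) and directional pleiotropy (Egger intercept) diagnostics are
attached to every fit. Ratio weights ignore exposure-side measurement
error (the NO Measurement Error assumption of the named estimators).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import HarmonizedInstrumentSet

METHODS = ("ivw_fe", "ivw_re", "simple_median", "weighted_median",
           "penalized_median", "egger")

#: Penalty constant for the penalized weighted median: weights are
#: multiplied by min(1, PENALTY * p_j) with p_j the chi-square(1) tail of
#: SNP j's heterogeneity contribution.
MEDIAN_PENALTY = 20.0


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Single-SNP causal estimate beta_y / beta_x with first-order
    (delta-method, NOME) standard error se_y / |beta_x|."""
    if beta_x == 0:
        raise ZeroDivisionError("wald_ratio undefined for beta_x = 0")
    if se_y <= 0 or se_x <= 0:
        raise ValueError("standard errors must be positive")
    return beta_y / beta_x, se_y / abs(beta_x)


def cochran_q(beta_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray,
              estimate: float) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q of the per-SNP Wald ratios around
    ``estimate`` with inverse-variance ratio weights; p from chi-square on
    J - 1 degrees of freedom."""
    beta_x = np.asarray(beta_x, float)
    beta_y = np.asarray(beta_y, float)
    se_y = np.asarray(se_y, float)
    if beta_x.size < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    ratios = beta_y / beta_x
    w = (beta_x / se_y) ** 2
    q = float(np.sum(w * (ratios - estimate) ** 2))
    df = beta_x.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def q_contributions(beta_x, beta_y, se_y, estimate) -> np.ndarray:
    """Per-SNP contributions to Cochran's Q at the given estimate."""
    beta_x = np.asarray(beta_x, float)
    ratios = np.asarray(beta_y, float) / beta_x
    w = (beta_x / np.asarray(se_y, float)) ** 2
    return w * (ratios - estimate) ** 2


def weighted_percentile(values: np.ndarray, weights: np.ndarray,
                        q: float = 0.5) -> float:
    """Exact weighted percentile (the L1 / minimum-weighted-absolute-
    deviation order statistic).

    Returns the smallest value whose cumulative weight fraction reaches
    ``q``; when the cumulative weight hits ``q`` exactly, the midpoint of
    the adjacent order statistics (so the equal-weight median of an even
    count matches the ordinary sample median). A SNP carrying more than
    half the total weight is always returned unchanged.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / np.sum(w)
    i = int(np.searchsorted(cum, q, side="left"))
    if i < v.size - 1 and abs(cum[i] - q) <= 1e-12:
        return float(0.5 * (v[i] + v[i + 1]))
    return float(v[min(i, v.size - 1)])


@dataclass
class UvmrResults:
    """One exposure-outcome causal estimate with its diagnostics.

    ``estimate`` is the log-OR for disease per SD increase of the exposure;
    ``or_scale`` exponentiates (OR, CI low, CI high).
    """

    exposure: str
    outcome: str
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pvalue: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    bonferroni_alpha: Optional[float] = None

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (float(np.exp(self.estimate)), float(np.exp(self.ci_low)),
                float(np.exp(self.ci_high)))

    @property
    def bonferroni_significant(self) -> Optional[bool]:
        if self.bonferroni_alpha is None:
            return None
        return bool(self.pvalue < self.bonferroni_alpha)

    def as_dict(self) -> dict:
        odds, lo, hi = self.or_scale
        d = {
            "exposure": self.exposure, "outcome": self.outcome,
            "method": self.method, "estimate": self.estimate, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue, "or": odds, "or_ci_low": lo,
            "or_ci_high": hi, "n_snps": self.n_snps,
            "q_stat": self.q_stat, "q_df": self.q_df, "q_pvalue": self.q_pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
            "bonferroni_alpha": self.bonferroni_alpha,
            "bonferroni_significant": self.bonferroni_significant,
        }
        return d

    def summary(self) -> str:
        odds, lo, hi = self.or_scale
        lines = [
            f"Univariable MR: {self.exposure} -> {self.outcome} [{self.method}]",
            f"  instruments: {self.n_snps}",
            f"  log-OR per SD: {self.estimate:+.4f} (SE {self.se:.4f})",
            f"  OR per SD:     {odds:.3f} (95% CI {lo:.3f}, {hi:.3f})",
            f"  p-value:       {self.pvalue:.3g}",
        ]
        if self.q_stat is not None:
            lines.append(f"  Cochran Q:     {self.q_stat:.2f} on {self.q_df} df"
                         f" (p = {self.q_pvalue:.3g})")
        if self.egger_intercept is not None:
            lines.append(f"  Egger intercept: {self.egger_intercept:+.4f}"
                         f" (p = {self.egger_intercept_p:.3g})")
        if self.bonferroni_alpha is not None:
            flag = "yes" if self.bonferroni_significant else "no"
            lines.append(f"  significant at Bonferroni alpha="
                         f"{self.bonferroni_alpha:.4g}: {flag}")
        return "\n".join(lines)


class UnivariableMR:
    """Univariable two-sample MR model for one exposure-outcome pair.

    Parameters
    ----------
    beta_x, se_x : per-SD instrument-exposure effects and standard errors.
    beta_y, se_y : instrument-outcome log-ORs and standard errors.

    ``fit(method)`` returns a :class:`UvmrResults`; ``fit_all()`` runs all
    six estimators.
    """

    def __init__(self, beta_x, se_x, beta_y, se_y,
                 exposure: str = "exposure", outcome: str = "outcome"):
        self.beta_x = np.asarray(beta_x, float).ravel()
        self.se_x = np.asarray(se_x, float).ravel()
        self.beta_y = np.asarray(beta_y, float).ravel()
        self.se_y = np.asarray(se_y, float).ravel()
        if not (self.beta_x.shape == self.se_x.shape == self.beta_y.shape
                == self.se_y.shape):
            raise ValueError("beta/SE vectors must share one length")
        if self.beta_x.size == 0:
            raise ValueError("no instruments supplied")
        if (self.se_x <= 0).any() or (self.se_y <= 0).any():
            raise ValueError("standard errors must be positive")
        self.exposure = exposure
        self.outcome = outcome

    @classmethod
    def from_instruments(cls, hset: HarmonizedInstrumentSet, exposure: str,
                         outcome: str = "outcome",
                         snps: Optional[list[str]] = None) -> "UnivariableMR":
        """Build the model from a harmonized set, optionally restricted to
        the instruments selected for this exposure."""
        sub = hset.subset(snps) if snps is not None else hset
        k = sub.exposure_index(exposure)
        return cls(sub.beta_x[:, k], sub.se_x[:, k], sub.beta_y, sub.se_y,
                   exposure=exposure, outcome=outcome)

    # -- internals ---------------------------------------------------------

    @property
    def n_snps(self) -> int:
        return self.beta_x.size

    def _ratios(self):
        if (self.beta_x == 0).any():
            raise ZeroDivisionError("ratio-based estimators need beta_x != 0")
        ratios = self.beta_y / self.beta_x
        weights = (self.beta_x / self.se_y) ** 2
        return ratios, weights

    def _ivw(self, random_effects: bool, alpha: float) -> UvmrResults:
        if self.n_snps < 2:
            raise ValueError("IVW needs >= 2 instruments; use wald_ratio for one")
        w = self.beta_x ** 2 / self.se_y ** 2
        est = float(np.sum(self.beta_x * self.beta_y / self.se_y ** 2) / np.sum(w))
        se_fixed = float(1.0 / np.sqrt(np.sum(w)))
        q, df, q_p = cochran_q(self.beta_x, self.beta_y, self.se_y, est)
        se = se_fixed
        if random_effects:
            se = se_fixed * max(1.0, float(np.sqrt(q / df)))
        z = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(est) / se)
        return UvmrResults(
            self.exposure, self.outcome,
            "ivw_re" if random_effects else "ivw_fe",
            est, se, est - z * se, est + z * se, float(p), self.n_snps,
            q_stat=q, q_df=df, q_pvalue=q_p,
        )

    def _median_point(self, variant: str, beta_x=None, beta_y=None) -> float:
        beta_x = self.beta_x if beta_x is None else beta_x
        beta_y = self.beta_y if beta_y is None else beta_y
        if (beta_x == 0).any():
            raise ZeroDivisionError("ratio-based estimators need beta_x != 0")
        ratios = beta_y / beta_x
        if variant == "simple_median":
            weights = np.ones_like(ratios)
            return weighted_percentile(ratios, weights)
        weights = (beta_x / self.se_y) ** 2
        if variant == "weighted_median":
            return weighted_percentile(ratios, weights)
        if variant == "penalized_median":
            est0 = weighted_percentile(ratios, weights)
            q_j = weights * (ratios - est0) ** 2
            penalty = np.minimum(1.0, MEDIAN_PENALTY * stats.chi2.sf(q_j, 1))
            return weighted_percentile(ratios, weights * penalty)
        raise ValueError(f"unknown median variant {variant!r}")

    def _median(self, variant: str, n_boot: int, seed: int, alpha: float) -> UvmrResults:
        if self.n_snps < 3:
            raise ValueError("median estimators need >= 3 instruments")
        est = self._median_point(variant)
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bx = rng.normal(self.beta_x, self.se_x)
            by = rng.normal(self.beta_y, self.se_y)
            bx = np.where(bx == 0, np.finfo(float).tiny, bx)
            boots[b] = self._median_point(variant, bx, by)
        se = float(np.std(boots, ddof=1))
        z = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else (0.0 if est else 1.0)
        q, df, q_p = cochran_q(self.beta_x, self.beta_y, self.se_y, est)
        return UvmrResults(self.exposure, self.outcome, variant, est, se,
                           est - z * se, est + z * se, float(p), self.n_snps,
                           q_stat=q, q_df=df, q_pvalue=q_p)

    def _egger(self, alpha: float) -> UvmrResults:
        if self.n_snps < 3:
            raise ValueError("MR-Egger needs >= 3 instruments")
        sign = np.where(self.beta_x < 0, -1.0, 1.0)  # orient all beta_x >= 0
        bx = self.beta_x * sign
        by = self.beta_y * sign
        if np.allclose(bx, bx[0]):
            raise ValueError("MR-Egger slope unidentifiable: all beta_x equal")
        w = 1.0 / self.se_y ** 2
        # weighted normal equations for [intercept, slope]
        s_w, s_wx = np.sum(w), np.sum(w * bx)
        s_wxx, s_wy, s_wxy = np.sum(w * bx * bx), np.sum(w * by), np.sum(w * bx * by)
        m = np.array([[s_w, s_wx], [s_wx, s_wxx]])
        rhs = np.array([s_wy, s_wxy])
        intercept, slope = np.linalg.solve(m, rhs)
        resid = by - intercept - slope * bx
        df = self.n_snps - 2
        sigma2 = float(np.sum(w * resid ** 2) / df)
        cov_unscaled = np.linalg.inv(m)
        scale = max(1.0, np.sqrt(sigma2))  # multiplicative residual inflation
        se_int = scale * float(np.sqrt(cov_unscaled[0, 0]))
        se_slope = scale * float(np.sqrt(cov_unscaled[1, 1]))
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        p_slope = 2 * stats.t.sf(abs(slope) / se_slope, df)
        p_int = 2 * stats.t.sf(abs(intercept) / se_int, df)
        q_egger = float(np.sum(w * resid ** 2))
        return UvmrResults(
            self.exposure, self.outcome, "egger", float(slope), se_slope,
            float(slope - tcrit * se_slope), float(slope + tcrit * se_slope),
            float(p_slope), self.n_snps,
            q_stat=q_egger, q_df=df, q_pvalue=float(stats.chi2.sf(q_egger, df)),
            egger_intercept=float(intercept), egger_intercept_se=se_int,
            egger_intercept_p=float(p_int),
        )

    # -- public API --------------------------------------------------------

    def fit(self, method: str = "ivw_re", alpha: float = 0.05,
            n_boot: int = 1000, seed: int = 0,
            bonferroni_alpha: Optional[float] = None) -> UvmrResults:
        """Fit one estimator and return its results.

        ``method`` is one of ``ivw_fe``, ``ivw_re``, ``simple_median``,
        ``weighted_median``, ``penalized_median``, ``egger``. Median
        standard errors come from ``n_boot`` seeded parametric bootstrap
        resamples of the summary statistics.
        """
        if method in ("ivw_fe", "ivw_re"):
            res = self._ivw(method == "ivw_re", alpha)
        elif method in ("simple_median", "weighted_median", "penalized_median"):
            res = self._median(method, n_boot, seed, alpha)
        elif method == "egger":
            res = self._egger(alpha)
        else:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        res.bonferroni_alpha = bonferroni_alpha
        return res

    def fit_all(self, alpha: float = 0.05, n_boot: int = 1000, seed: int = 0,
                bonferroni_alpha: Optional[float] = None) -> list[UvmrResults]:
        return [self.fit(m, alpha=alpha, n_boot=n_boot, seed=seed,
                         bonferroni_alpha=bonferroni_alpha) for m in METHODS]


def run_uvmr_grid(instrument_sets: dict[str, HarmonizedInstrumentSet],
                  instruments_by_exposure: Optional[dict[str, dict[str, list[str]]]] = None,
                  alpha: float = 0.05, n_boot: int = 1000, seed: int = 0,
                  ) -> pd.DataFrame:
    """All six estimators for every exposure-outcome pair.

    ``instrument_sets`` maps outcome name to its harmonized set. Unless
    per-exposure instrument lists are supplied, each exposure uses the SNPs
    genome-wide significant for it. The Bonferroni threshold is
    alpha / (K exposures x number of outcomes); per-cell failures are
    recorded in an ``error`` column and never abort the grid.
    """
    outcomes = list(instrument_sets)
    k = len(next(iter(instrument_sets.values())).exposures)
    n_tests = k * len(outcomes)
    bonf = alpha / n_tests
    rows = []
    for outcome, hset in instrument_sets.items():
        if instruments_by_exposure and outcome in instruments_by_exposure:
            per_exp = instruments_by_exposure[outcome]
        else:
            per_exp = hset.significant_instruments()
        for exposure in hset.exposures:
            snps = per_exp.get(exposure, [])
            for method in METHODS:
                try:
                    model = UnivariableMR.from_instruments(
                        hset, exposure, outcome=outcome, snps=snps)
                    res = model.fit(method, alpha=alpha, n_boot=n_boot,
                                    seed=seed, bonferroni_alpha=bonf)
                    row = res.as_dict()
                    row["error"] = ""
                except Exception as exc:  # isolate per-cell failures
                    row = {"exposure": exposure, "outcome": outcome,
                           "method": method, "estimate": np.nan, "se": np.nan,
                           "ci_low": np.nan, "ci_high": np.nan,
                           "pvalue": np.nan, "or": np.nan,
                           "or_ci_low": np.nan, "or_ci_high": np.nan,
                           "n_snps": len(snps), "q_stat": np.nan,
                           "q_df": np.nan, "q_pvalue": np.nan,
                           "egger_intercept": np.nan,
                           "egger_intercept_se": np.nan,
                           "egger_intercept_p": np.nan,
                           "bonferroni_alpha": bonf,
                           "bonferroni_significant": False,
                           "error": f"{type(exc).__name__}: {exc}"}
                rows.append(row)
    return pd.DataFrame(rows)
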