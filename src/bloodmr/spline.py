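"""Restricted-cubic-spline logistic dose-response curves and group tests.

For each blood-cell trait, case status (disease group vs healthy) is
regressed on a restricted (natural) cubic spline basis of the trait. The
fitted curve is reported as the log odds ratio relative to a reference
trait value (the healthy-group median by default) with a pointwise
delta-method 95% band; the trait values where a band boundary crosses
zero are candidate clinical decision thresholds. Descriptive group
comparisons use a rank-based two-sample test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

#: Harrell's default knot placement quantiles by knot count.
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def harrell_knots(x: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Knot locations at Harrell's default sample quantiles."""
    if n_knots not in KNOT_QUANTILES:
        raise ValueError(f"n_knots must be one of {sorted(KNOT_QUANTILES)}")
    knots = np.quantile(np.asarray(x, float), KNOT_QUANTILES[n_knots])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots are not strictly increasing; trait too discrete")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's parameterisation).

    For m strictly increasing knots t_1 < ... < t_m the basis has m - 1
    columns: the linear term and m - 2 truncated-cubic terms constrained so
    the function is linear beyond the boundary knots (zero second and third
    derivative outside [t_1, t_m]). Cubic terms are scaled by
    (t_m - t_1)^2 to keep coefficients comparable to the linear term.
    """
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    t = np.asarray(knots, float)
    m = t.size
    if m < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(m - 2):
        term = (cube(x - t[j])
                - cube(x - t[m - 2]) * (t[m - 1] - t[j]) / (t[m - 1] - t[m - 2])
                + cube(x - t[m - 1]) * (t[m - 2] - t[j]) / (t[m - 1] - t[m - 2]))
        cols.append(term / norm)
    return np.column_stack(cols)


def find_crossings(grid: np.ndarray, band: np.ndarray,
                   decimals: Optional[int] = 2) -> list[float]:
    """Trait values where a confidence-band boundary crosses zero.

    Sign changes between adjacent grid points are located by linear
    interpolation; exact zeros count as crossings. Values are rounded to
    ``decimals`` (pass None to disable) and deduplicated in order.
    """
    grid = np.asarray(grid, float)
    band = np.asarray(band, float)
    crossings: list[float] = []
    for i in range(band.size - 1):
        lo, hi = band[i], band[i + 1]
        if lo == 0.0:
            crossings.append(grid[i])
        elif lo * hi < 0:
            frac = lo / (lo - hi)
            crossings.append(grid[i] + frac * (grid[i + 1] - grid[i]))
    if band[-1] == 0.0:
        crossings.append(grid[-1])
    if decimals is not None:
        crossings = [round(float(c), decimals) for c in crossings]
    out: list[float] = []
    for c in crossings:
        if not out or out[-1] != c:
            out.append(float(c))
    return out


@dataclass
class RcsResults:
    """Fitted spline dose-response curve for one trait and outcome."""

    trait: str
    outcome: str
    knots: np.ndarray
    params: np.ndarray            # [intercept, basis coefficients]
    cov_params: np.ndarray
    reference_value: float
    grid: np.ndarray
    log_or: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_cases: int
    n_controls: int
    separation_flag: bool = False

    def crossings(self, decimals: Optional[int] = 2) -> dict[str, list[float]]:
        """Zero crossings of the lower and upper confidence boundaries."""
        return {
            "ci_low": find_crossings(self.grid, self.ci_low, decimals),
            "ci_high": find_crossings(self.grid, self.ci_high, decimals),
        }

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "log_or": self.log_or,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})

    def summary(self) -> str:
        cr = self.crossings()
        lines = [
            f"RCS logistic dose-response: {self.trait} vs {self.outcome}",
            f"  cases/controls: {self.n_cases}/{self.n_controls}",
            f"  knots: {np.round(self.knots, 3).tolist()}",
            f"  reference (logOR = 0 at): {self.reference_value:.3f}",
            f"  zero crossings, lower band: {cr['ci_low']}",
            f"  zero crossings, upper band: {cr['ci_high']}",
        ]
        if self.separation_flag:
            lines.append("  warning: quasi-separation detected; "
                         "standard errors are unreliable")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Curve with confidence band (matplotlib axis returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.log_or, color="crimson", label="logOR")
        ax.fill_between(self.grid, self.ci_low, self.ci_high,
                        color="crimson", alpha=0.2, label="95% CI")
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_xlabel(self.trait)
        ax.set_ylabel(f"logOR of {self.outcome}")
        ax.legend()
        return ax


class RcsLogistic:
    """Restricted-cubic-spline logistic dose-response model.

    ``y`` is binary case status, ``x`` the trait value. Knots default to
    Harrell's quantiles of the pooled trait distribution; the reference
    value (where the curve is anchored at logOR = 0) defaults to the
    control-group median.
    """

    def __init__(self, y, x, knots: Optional[Sequence[float]] = None,
                 n_knots: int = 4, reference: Optional[float] = None,
                 trait: str = "trait", outcome: str = "case",
                 covariates: Optional[np.ndarray] = None):
        self.y = np.asarray(y, float).ravel()
        self.x = np.asarray(x, float).ravel()
        if self.y.size != self.x.size:
            raise ValueError("y and x must have the same length")
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        if self.y.sum() == 0 or self.y.sum() == self.y.size:
            raise ValueError("both outcome groups must be non-empty")
        if np.var(self.x) == 0:
            raise ValueError("trait has zero variance")
        self.knots = (np.asarray(knots, float) if knots is not None
                      else harrell_knots(self.x, n_knots))
        if reference is None:
            controls = self.x[self.y == 0]
            reference = float(np.median(controls))
        self.reference = float(reference)
        self.trait = trait
        self.outcome = outcome
        self.covariates = (np.atleast_2d(np.asarray(covariates, float))
                           if covariates is not None else None)
        if self.covariates is not None and self.covariates.shape[0] != self.y.size:
            raise ValueError("covariates must have one row per subject")

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, trait: str, case_group: str,
                    control_group: str = "healthy", n_knots: int = 4,
                    knots: Optional[Sequence[float]] = None,
                    reference: Optional[float] = None,
                    adjust_age_sex: bool = False) -> "RcsLogistic":
        """Build the model from a cohort table (one row per subject)."""
        sub = cohort[cohort["group"].isin([case_group, control_group])]
        if sub.empty or (sub["group"] == case_group).sum() == 0 \
                or (sub["group"] == control_group).sum() == 0:
            raise ValueError("both groups must be non-empty")
        y = (sub["group"] == case_group).astype(float).to_numpy()
        x = sub[trait].to_numpy(dtype=float)
        covariates = None
        if adjust_age_sex:
            covariates = np.column_stack([
                sub["age"].to_numpy(dtype=float),
                (sub["sex"] == "F").astype(float).to_numpy(),
            ])
        return cls(y, x, knots=knots, n_knots=n_knots, reference=reference,
                   trait=trait, outcome=case_group, covariates=covariates)

    def fit(self, grid_size: int = 200, alpha: float = 0.05) -> RcsResults:
        """Fit the logistic regression and evaluate the curve and band.

        The curve is the linear-predictor difference from the reference
        value (covariates and intercept cancel), with a pointwise
        delta-method confidence band.
        """
        if grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        basis = rcs_basis(self.x, self.knots)
        design = [np.ones_like(self.x)[:, None], basis]
        if self.covariates is not None:
            design.append(self.covariates)
        design = np.hstack(design)

        separation = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(self.y, design, family=sm.families.Binomial())
            try:
                res = model.fit(maxiter=200)
            except Exception:
                separation = True
                res = model.fit_regularized(alpha=1e-6, maxiter=500)
        params = np.asarray(res.params)
        if not separation:
            if not np.all(np.isfinite(res.bse)) or np.abs(params).max() > 50:
                separation = True
        cov = np.asarray(res.cov_params()) if hasattr(res, "cov_params") else \
            np.full((design.shape[1],) * 2, np.nan)

        grid = np.linspace(self.x.min(), self.x.max(), grid_size)
        contrast = rcs_basis(grid, self.knots) - rcs_basis(
            np.full_like(grid, self.reference), self.knots)
        n_basis = basis.shape[1]
        beta = params[1:1 + n_basis]
        cov_b = cov[1:1 + n_basis, 1:1 + n_basis]
        log_or = contrast @ beta
        var = np.einsum("ij,jk,ik->i", contrast, cov_b, contrast)
        se = np.sqrt(np.clip(var, 0.0, None))
        z = stats.norm.ppf(1 - alpha / 2)
        return RcsResults(
            trait=self.trait, outcome=self.outcome, knots=self.knots,
            params=params, cov_params=cov, reference_value=self.reference,
            grid=grid, log_or=log_or, ci_low=log_or - z * se,
            ci_high=log_or + z * se,
            n_cases=int(self.y.sum()), n_controls=int((1 - self.y).sum()),
            separation_flag=separation,
        )


@dataclass
class GroupComparison:
    """Two-sample rank-test comparison of one trait between groups."""

    trait: str
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    statistic: float
    pvalue: float

    @property
    def direction(self) -> int:
        """Sign of the location difference (group_b relative to group_a)."""
        return int(np.sign(self.median_b - self.median_a))

    def as_dict(self) -> dict:
        return {"trait": self.trait, "group_a": self.group_a,
                "group_b": self.group_b, "median_a": self.median_a,
                "median_b": self.median_b, "statistic": self.statistic,
                "pvalue": self.pvalue, "direction": self.direction}


def group_compare(cohort: pd.DataFrame, trait: str,
                  groups: tuple[str, str] = ("healthy", "CD")) -> GroupComparison:
    """Mann-Whitney U comparison of a trait between two cohort groups."""
    a = cohort.loc[cohort["group"] == groups[0], trait].to_numpy(dtype=float)
    b = cohort.loc[cohort["group"] == groups[1], trait].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 members")
    if np.var(np.concatenate([a, b])) == 0:
        raise ValueError("degenerate (constant) trait values")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(trait, groups[0], groups[1],
                           float(np.median(a)), float(np.median(b)),
                           float(stat), float(p))
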