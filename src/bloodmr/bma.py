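"""Multivariable Mendelian randomization with Bayesian model averaging.

Exposure subsets (models) are scored by a closed-form Gaussian marginal
likelihood on the inverse-variance-weighted scale: the response is
beta_Y / se_Y, the design beta_X / se_Y (no intercept), residual variance
is fixed at 1 (the weighting already standardises the rows), and each
included causal coefficient carries an independent N(0, sigma^2) prior.
Combining the marginal likelihoods with an independent Bernoulli(p) prior
over exposure inclusion yields posterior model probabilities (PP),
per-exposure marginal inclusion probabilities (MIP) and model-averaged
causal estimates (MACE). Invalid or influential instruments are pruned
iteratively using per-SNP Cochran Q contributions (threshold 10) and
Cook's distance (threshold: median of F(d, J-d)) computed on every model
whose PP exceeds 0.02, and the posterior is re-estimated until no
offender remains.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .instruments import HarmonizedInstrumentSet


@dataclass
class BmaConfig:
    """Priors and pruning thresholds for the model-averaging analysis."""

    prior_inclusion: float = 0.1   # Bernoulli prior probability of inclusion
    prior_sd: float = 0.25         # N(0, sd^2) prior on each causal coefficient
    max_model_size: int = 12       # cap on enumerated subset size
    pp_threshold: float = 0.02     # "best model" cut for diagnostics
    q_threshold: float = 10.0      # per-SNP Cochran Q contribution cut
    cd_quantile: float = 0.5       # F-distribution quantile for Cook's distance
    max_prune_rounds: int = 10

    def validate(self, k: Optional[int] = None) -> None:
        if not 0.0 < self.prior_inclusion < 1.0:
            raise ValueError("prior_inclusion must be in (0, 1)")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.pp_threshold <= 0 or self.q_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.cd_quantile < 1.0:
            raise ValueError("cd_quantile must be in (0, 1)")
        if self.max_model_size < 1:
            raise ValueError("max_model_size must be >= 1")
        if k is not None and self.max_model_size > k:
            raise ValueError("max_model_size cannot exceed the number of exposures")
        if self.max_prune_rounds < 0:
            raise ValueError("max_prune_rounds must be >= 0")


def bma_transform(hset: HarmonizedInstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-variance-weighted response and design.

    response_j = beta_Y[j] / se_Y[j]; design[j, k] = beta_X[j, k] / se_Y[j];
    no intercept. A weighted regression on raw data with weights 1/se_Y^2
    is an ordinary regression on this transformed pair.
    """
    j, k = hset.beta_x.shape
    if j <= k:
        raise ValueError("need more instruments than exposures")
    y = hset.beta_y / hset.se_y
    x = hset.beta_x / hset.se_y[:, None]
    if (np.abs(x).sum(axis=0) == 0).any():
        raise ValueError("design contains an all-zero exposure column")
    return y, x


def log_marginal_likelihood(y: np.ndarray, x: np.ndarray,
                            subset: Sequence[int], sigma: float) -> float:
    """Closed-form log marginal likelihood of one exposure subset.

    Model: y ~ N(X_m theta, I) with theta ~ N(0, sigma^2 I_d); hence
    y ~ N(0, I + sigma^2 X_m X_m'). Evaluated in the d x d form via the
    Woodbury identity.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    xm = x[:, subset]
    j, d = xm.shape
    g = xm.T @ xm
    a = g + np.eye(d) / sigma ** 2
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular subset design")
    # |I + sigma^2 X'X| = |A| * sigma^(2d)
    logdet_v = logdet_a + 2 * d * np.log(sigma)
    b = xm.T @ y
    quad = float(y @ y - b @ np.linalg.solve(a, b))
    return float(-0.5 * (j * np.log(2 * np.pi) + logdet_v + quad))


def _subset_wls(y: np.ndarray, x: np.ndarray, subset: Sequence[int]) -> np.ndarray:
    """Least-squares causal estimates for one subset on the weighted scale."""
    theta, *_ = np.linalg.lstsq(x[:, list(subset)], y, rcond=None)
    return theta


@dataclass
class BmaPosterior:
    """Ranked model posterior with per-exposure summaries.

    ``models`` is PP-sorted with columns ``model`` (tuple of exposure
    names), ``indices``, ``pp`` and ``estimates`` (per-model WLS causal
    estimates, aligned with ``model``); ``mip``/``mace`` are per-exposure.
    """

    exposures: list[str]
    models: pd.DataFrame
    mip: pd.Series
    mace: pd.Series

    def best_models(self, pp_threshold: float) -> pd.DataFrame:
        best = self.models[self.models["pp"] > pp_threshold]
        return best if len(best) else self.models.head(1)

    def summary(self, top: int = 10) -> str:
        lines = ["Per-exposure model averaging (MIP-ranked):",
                 "  exposure   MIP      MACE"]
        for name in self.mip.sort_values(ascending=False).index:
            lines.append(f"  {name:<9}{self.mip[name]:7.3f}{self.mace[name]:+10.3f}")
        lines.append(f"Top {top} models by posterior probability:")
        for _, row in self.models.head(top).iterrows():
            model = ", ".join(row["model"])
            ests = ", ".join(f"{e:+.3f}" for e in row["estimates"])
            lines.append(f"  PP={row['pp']:.3f}  [{model}]  theta=({ests})")
        return "\n".join(lines)


def enumerate_posterior(y: np.ndarray, x: np.ndarray, exposures: Sequence[str],
                        config: Optional[BmaConfig] = None) -> BmaPosterior:
    """Exhaustive posterior over all non-empty exposure subsets up to
    ``max_model_size``.

    PP_m is proportional to p^|m| (1-p)^(K-|m|) exp(logML_m), normalised
    over the enumerated space; MIP_k sums PP over models containing k and
    MACE_k the PP-weighted per-model estimates of exposure k.
    """
    config = config or BmaConfig()
    k = x.shape[1]
    config.validate()
    if k > 20:
        raise ValueError("exhaustive enumeration supported for K <= 20")
    max_size = min(config.max_model_size, k)
    p = config.prior_inclusion

    # All subset quantities reduce to the K x K Gram matrix G = X'X, the
    # moment vector b = X'y and y'y, so enumeration cost is independent of
    # the number of instruments.
    g = x.T @ x
    b = x.T @ y
    yty = float(y @ y)
    j = x.shape[0]
    sigma = config.prior_sd
    base = -0.5 * j * np.log(2 * np.pi)

    subsets: list[tuple[int, ...]] = []
    log_scores: list[float] = []
    estimates: list[np.ndarray] = []
    for size in range(1, max_size + 1):
        log_prior = size * np.log(p) + (k - size) * np.log1p(-p)
        for subset in itertools.combinations(range(k), size):
            idx = list(subset)
            gm = g[np.ix_(idx, idx)]
            bm = b[idx]
            a = gm + np.eye(size) / sigma ** 2
            sign, logdet_a = np.linalg.slogdet(a)
            if sign <= 0:
                raise np.linalg.LinAlgError("singular subset design")
            logdet_v = logdet_a + 2 * size * np.log(sigma)
            quad = yty - float(bm @ np.linalg.solve(a, bm))
            log_ml = base - 0.5 * (logdet_v + quad)
            subsets.append(subset)
            log_scores.append(log_prior + log_ml)
            # lstsq tolerates exactly collinear exposure columns
            estimates.append(np.linalg.lstsq(gm, bm, rcond=None)[0])

    log_scores_arr = np.array(log_scores)
    pp = np.exp(log_scores_arr - logsumexp(log_scores_arr))

    mip = np.zeros(k)
    mace = np.zeros(k)
    for subset, weight, est in zip(subsets, pp, estimates):
        for pos, idx in enumerate(subset):
            mip[idx] += weight
            mace[idx] += weight * est[pos]

    order = np.argsort(-pp, kind="stable")
    models = pd.DataFrame({
        "model": [tuple(exposures[i] for i in subsets[j]) for j in order],
        "indices": [subsets[j] for j in order],
        "pp": pp[order],
        "estimates": [tuple(float(v) for v in estimates[j]) for j in order],
    })
    names = list(exposures)
    return BmaPosterior(names, models, pd.Series(mip, index=names, name="mip"),
                        pd.Series(mace, index=names, name="mace"))


def snp_q_contributions(y: np.ndarray, x: np.ndarray,
                        subset: Sequence[int]) -> np.ndarray:
    """Per-SNP Cochran Q contributions under one subset model: squared
    standardized residuals on the weighted scale (their sum is the model's
    Q / residual sum of squares)."""
    theta = _subset_wls(y, x, subset)
    resid = y - x[:, list(subset)] @ theta
    return resid ** 2


def cooks_distance(y: np.ndarray, x: np.ndarray,
                   subset: Sequence[int]) -> np.ndarray:
    """Classical leverage-based Cook's distance of each SNP under one
    subset model (through-origin regression on the weighted scale)."""
    xm = x[:, list(subset)]
    j, d = xm.shape
    if j <= d:
        raise ValueError("need more instruments than model size")
    theta, *_ = np.linalg.lstsq(xm, y, rcond=None)
    resid = y - xm @ theta
    # hat diagonal
    q, _ = np.linalg.qr(xm)
    h = np.sum(q * q, axis=1)
    s2 = float(resid @ resid) / (j - d)
    h = np.clip(h, 0.0, 1.0 - 1e-12)
    return (resid ** 2 / (d * s2)) * h / (1.0 - h) ** 2


def cooks_threshold(d: int, j: int, quantile: float = 0.5) -> float:
    """Influence cut-off: the ``quantile`` of the F(d, j-d) distribution."""
    if j <= d:
        raise ValueError("need more instruments than model size")
    return float(stats.f.ppf(quantile, d, j - d))


@dataclass
class PruneRecord:
    round: int
    snp: str
    reason: str        # "Q" or "Cd"
    value: float
    threshold: float
    model: tuple[str, ...]

    def as_dict(self) -> dict:
        return {"round": self.round, "snp": self.snp, "reason": self.reason,
                "value": self.value, "threshold": self.threshold,
                "model": list(self.model)}


def iterative_prune(y: np.ndarray, x: np.ndarray, snp_ids: Sequence[str],
                    exposures: Sequence[str], config: Optional[BmaConfig] = None,
                    ) -> tuple[list[int], BmaPosterior, list[PruneRecord]]:
    """Fit, flag, drop, refit until no instrument offends.

    In each round the posterior is enumerated and, on every model with
    PP above ``pp_threshold``, per-SNP Q contributions and Cook's distances
    are computed; a SNP offending either threshold in any of those models
    is dropped. Returns the kept row indices, the final posterior, and the
    audit trail of removals.
    """
    config = config or BmaConfig()
    keep = list(range(len(snp_ids)))
    audit: list[PruneRecord] = []
    posterior = enumerate_posterior(y, x, exposures, config)
    for rnd in range(1, config.max_prune_rounds + 1):
        best = posterior.best_models(config.pp_threshold)
        offenders: dict[int, PruneRecord] = {}
        for _, row in best.iterrows():
            subset = list(row["indices"])
            d = len(subset)
            q_j = snp_q_contributions(y[keep], x[keep], subset)
            cd_j = cooks_distance(y[keep], x[keep], subset)
            cd_cut = cooks_threshold(d, len(keep), config.cd_quantile)
            for pos, i in enumerate(keep):
                if i in offenders:
                    continue
                if q_j[pos] > config.q_threshold:
                    offenders[i] = PruneRecord(rnd, snp_ids[i], "Q",
                                               float(q_j[pos]),
                                               config.q_threshold, row["model"])
                elif cd_j[pos] > cd_cut:
                    offenders[i] = PruneRecord(rnd, snp_ids[i], "Cd",
                                               float(cd_j[pos]), cd_cut,
                                               row["model"])
        if not offenders:
            break
        audit.extend(offenders.values())
        keep = [i for i in keep if i not in offenders]
        if len(keep) <= x.shape[1]:
            raise RuntimeError("pruning removed too many instruments")
        posterior = enumerate_posterior(y[keep], x[keep], exposures, config)
    return keep, posterior, audit


@dataclass
class BMAResults:
    """Fitted MR-BMA analysis.

    ``posterior`` reflects the final (possibly pruned) instrument set;
    ``pre_prune`` keeps the posterior on the full set for the consistency
    check of reporting results before and after outlier exclusion.
    """

    exposures: list[str]
    posterior: BmaPosterior
    pre_prune: BmaPosterior
    snp_ids: list[str]
    pruned: list[PruneRecord] = field(default_factory=list)
    rounds_run: int = 0
    config: BmaConfig = field(default_factory=BmaConfig)

    @property
    def mip(self) -> pd.Series:
        return self.posterior.mip

    @property
    def mace(self) -> pd.Series:
        return self.posterior.mace

    def ranking(self) -> pd.DataFrame:
        """Per-exposure MIP/MACE table, MIP-ranked (strictly sorted)."""
        df = pd.DataFrame({"mip": self.mip, "mace": self.mace})
        return df.sort_values("mip", ascending=False)

    def top_models(self, n: int = 10) -> pd.DataFrame:
        return self.posterior.models.head(n)

    def pruning_audit(self) -> list[dict]:
        return [r.as_dict() for r in self.pruned]

    def summary(self) -> str:
        lines = [f"MR-BMA over {len(self.exposures)} exposures, "
                 f"{len(self.snp_ids)} instruments after pruning "
                 f"({len(self.pruned)} removed in {self.rounds_run} round(s))"]
        lines.append(self.posterior.summary())
        return "\n".join(lines)


class MRBMA:
    """Multivariable MR with Bayesian model averaging over exposure subsets.

    Built from a :class:`HarmonizedInstrumentSet` (or raw matrices via
    :meth:`from_matrices`); ``fit(prune=True)`` enumerates the model
    posterior, prunes invalid/influential instruments and returns a
    :class:`BMAResults`.
    """

    def __init__(self, hset: HarmonizedInstrumentSet,
                 config: Optional[BmaConfig] = None):
        self.hset = hset
        self.config = config or BmaConfig()
        self.config.validate()

    @classmethod
    def from_matrices(cls, beta_x, se_x, beta_y, se_y,
                      exposures: Optional[Sequence[str]] = None,
                      snp_ids: Optional[Sequence[str]] = None,
                      config: Optional[BmaConfig] = None) -> "MRBMA":
        beta_x = np.atleast_2d(np.asarray(beta_x, float))
        j, k = beta_x.shape
        exposures = list(exposures) if exposures is not None else [
            f"X{i + 1}" for i in range(k)]
        snp_ids = list(snp_ids) if snp_ids is not None else [
            f"snp{i + 1}" for i in range(j)]
        hset = HarmonizedInstrumentSet(snp_ids, exposures, beta_x,
                                       np.asarray(se_x, float), beta_y, se_y)
        return cls(hset, config)

    def fit(self, prune: bool = True) -> BMAResults:
        y, x = bma_transform(self.hset)
        pre = enumerate_posterior(y, x, self.hset.exposures, self.config)
        if not prune:
            return BMAResults(list(self.hset.exposures), pre, pre,
                              list(self.hset.snp_ids), [], 0, self.config)
        keep, post, audit = iterative_prune(y, x, self.hset.snp_ids,
                                            self.hset.exposures, self.config)
        rounds = max((r.round for r in audit), default=0)
        return BMAResults(list(self.hset.exposures), post, pre,
                          [self.hset.snp_ids[i] for i in keep], audit,
                          rounds, self.config)
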