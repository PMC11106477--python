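"""Synthetic GWAS summary statistics, LD structure, confounder catalogs and
an individual-level blood-count cohort with known ground truth.

The generator emulates the two-sample design used throughout the package:
a large exposure GWAS of K correlated blood-cell traits (effects per SD of
trait), a smaller binary-outcome case-control GWAS on the log-odds scale,
sparse per-SNP exposure effects, an optional fraction of SNPs with a direct
(pleiotropic) outcome effect, block-diagonal LD, and SNPs missing from the
outcome study so the proxy-lookup rule is exercisable. Every draw is
reproducible from the config seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .traits import (
    TRAITS,
    HEALTHY_REFERENCE,
    DEFAULT_GROUP_SHIFTS,
    EXPOSURE_STUDY_N,
    OUTCOME_STUDIES,
)

GENOME_WIDE_P = 5e-8

#: Column order of every summary-statistics panel.
PANEL_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P", "EAF", "N"]

_NON_PALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                          ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def snp_labels(n_snps: int) -> list[str]:
    """Synthetic variant identifiers rs1..rsN."""
    return [f"rs{i + 1}" for i in range(n_snps)]


def exchangeable_corr(k: int, rho: float = 0.3) -> np.ndarray:
    """Exchangeable K x K correlation matrix with off-diagonal rho."""
    c = np.full((k, k), rho)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class SyntheticGwasConfig:
    """Study conditions for one synthetic two-sample MR data set.

    Defaults mirror the real design the package targets: 15 blood-cell
    traits measured in 563,085 individuals as exposures and an ulcerative
    colitis case-control GWAS (6,968 cases / 20,464 controls) as outcome.
    ``causal_effects`` holds the ground-truth log-OR per SD of each trait.
    """

    n_snps: int = 1000
    n_exposures: int = 15
    causal_effects: Optional[np.ndarray] = None  # zeros if None
    exposure_corr: Optional[np.ndarray] = None   # exchangeable 0.3 if None
    effect_sd: float = 0.05        # SD of non-null per-allele exposure effects
    sparsity: float = 0.1          # fraction of SNPs affecting each exposure
    pleiotropy_frac: float = 0.05  # fraction of SNPs with a direct outcome effect
    pleiotropy_sd: float = 0.02    # SD of those direct effects (log-OR)
    n_exposure_study: int = EXPOSURE_STUDY_N
    n_cases: int = OUTCOME_STUDIES["UC"]["cases"]
    n_controls: int = OUTCOME_STUDIES["UC"]["controls"]
    missing_frac: float = 0.1      # fraction of SNPs absent from the outcome panel
    noise_scale: float = 1.0       # multiplies sampling noise; 0 = noiseless limit
    ld_block_size: int = 1         # SNPs per LD block (1 = independent SNPs)
    within_block_r2: float = 0.0   # r^2 between SNPs of the same block
    flip_frac: float = 0.3         # outcome rows reported on the swapped orientation
    palindromic_frac: float = 0.02  # fraction of A/T or C/G variants
    seed: int = 0

    def exposures(self) -> list[str]:
        if self.n_exposures <= len(TRAITS):
            return TRAITS[: self.n_exposures]
        return TRAITS + [f"X{i}" for i in range(len(TRAITS), self.n_exposures)]

    def corr(self) -> np.ndarray:
        if self.exposure_corr is None:
            return exchangeable_corr(self.n_exposures)
        return np.asarray(self.exposure_corr, dtype=float)

    def theta(self) -> np.ndarray:
        if self.causal_effects is None:
            return np.zeros(self.n_exposures)
        th = np.asarray(self.causal_effects, dtype=float)
        if th.shape != (self.n_exposures,):
            raise ValueError(
                f"causal_effects must have length {self.n_exposures}, got {th.shape}"
            )
        return th

    def validate(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if self.n_exposures <= 0:
            raise ValueError("n_exposures must be positive")
        for name in ("sparsity", "pleiotropy_frac", "missing_frac",
                     "flip_frac", "palindromic_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_exposure_study", "n_cases", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_sd <= 0 or self.pleiotropy_sd < 0:
            raise ValueError("effect_sd must be > 0 and pleiotropy_sd >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError("within_block_r2 must be in [0, 1]")
        if self.ld_block_size < 1 or self.ld_block_size > self.n_snps:
            raise ValueError("ld_block_size must be in [1, n_snps]")
        c = self.corr()
        if c.shape != (self.n_exposures, self.n_exposures):
            raise ValueError("exposure_corr has wrong shape")
        if not np.allclose(c, c.T):
            raise ValueError("exposure_corr must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("exposure_corr must be positive semi-definite")
        self.theta()  # length check


@dataclass
class GwasTruth:
    """Ground truth behind one synthetic data set (for tests and audits)."""

    snp_ids: list[str]
    exposures: list[str]
    beta_exposure: np.ndarray      # J x K true per-allele effects
    beta_outcome: np.ndarray       # length J true log-OR (incl. direct effects)
    direct_effects: np.ndarray     # length J pleiotropic component
    pleiotropic: np.ndarray        # boolean mask
    missing_from_outcome: list[str]
    theta: np.ndarray              # true causal log-OR per SD


@dataclass
class LdMatrix:
    """Squared-correlation (r^2) matrix over an ordered SNP list."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        j = len(self.snp_ids)
        if self.r2.shape != (j, j):
            raise ValueError("r2 shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def index(self, snp: str) -> int:
        try:
            return self._index[snp]
        except KeyError:
            raise KeyError(f"SNP {snp!r} not present in LD matrix") from None

    def between(self, a: str, b: str) -> float:
        return float(self.r2[self.index(a), self.index(b)])


def _draw_alleles(rng: np.random.Generator, n: int, palindromic_frac: float):
    pal = rng.random(n) < palindromic_frac
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for i in range(n):
        pool = _PALINDROMIC_PAIRS if pal[i] else _NON_PALINDROMIC_PAIRS
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    return ea, oa, pal


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta) / se
    return 2.0 * stats.norm.sf(z)


def generate_summary_stats(config: SyntheticGwasConfig, return_truth: bool = False):
    """Generate exposure and outcome GWAS summary-statistic panels.

    True per-allele exposure effects are sparse (independent Bernoulli mask
    per exposure) and correlated across exposures via the configured K x K
    correlation. The true outcome effect of SNP j is ``theta . beta_j`` plus
    a direct effect for pleiotropic SNPs. Observed effects add Gaussian
    sampling noise with the standard errors implied by the study sizes at
    the SNP's allele frequency; ``missing_frac`` of SNPs are withheld from
    the outcome panel. Within an LD block all SNPs tag the same underlying
    signal, attenuated by r (the block correlation), so block-mates are
    usable proxies.

    Returns ``(exposure_panels, outcome_panel)`` where ``exposure_panels``
    maps trait name to a DataFrame with columns SNP, EA, OA, BETA, SE, P,
    EAF, N; with ``return_truth=True`` a :class:`GwasTruth` is appended.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_snps, config.n_exposures
    ids = snp_labels(n)
    names = config.exposures()
    theta = config.theta()

    ea, oa, _ = _draw_alleles(rng, n, config.palindromic_frac)
    eaf = rng.uniform(0.05, 0.95, size=n)

    # Block structure: the first SNP of each block is the index variant; the
    # rest tag its signal with correlation r = sqrt(within_block_r2).
    block = np.arange(n) // config.ld_block_size
    n_blocks = int(block.max()) + 1
    is_index = np.r_[True, np.diff(block) > 0]
    r_tag = np.sqrt(config.within_block_r2)

    # Sparse, cross-trait-correlated index effects.
    chol = np.linalg.cholesky(config.corr() + 1e-12 * np.eye(k))
    z_index = (chol @ rng.standard_normal((k, n_blocks))).T * config.effect_sd
    mask_index = rng.random((n_blocks, k)) < config.sparsity
    b_index = z_index * mask_index
    scale = np.where(is_index, 1.0, r_tag)
    beta_exp_true = b_index[block] * scale[:, None]

    # Direct (pleiotropic) outcome effects.
    n_pleio = int(round(config.pleiotropy_frac * n))
    pleio_idx = rng.choice(n, size=n_pleio, replace=False) if n_pleio else np.array([], int)
    direct = np.zeros(n)
    if n_pleio:
        direct[pleio_idx] = rng.normal(0.0, config.pleiotropy_sd, size=n_pleio)
    beta_out_true = beta_exp_true @ theta + direct

    # Observed exposure panels.
    se_x = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_exposure_study)
    exposure_panels: dict[str, pd.DataFrame] = {}
    for j, name in enumerate(names):
        beta_obs = beta_exp_true[:, j] + config.noise_scale * rng.normal(0, se_x)
        exposure_panels[name] = pd.DataFrame({
            "SNP": ids, "EA": ea, "OA": oa,
            "BETA": beta_obs, "SE": se_x, "P": _two_sided_p(beta_obs, se_x),
            "EAF": eaf, "N": config.n_exposure_study,
        })[PANEL_COLUMNS]

    # Observed outcome panel (log-OR scale); SE from the standard log-OR
    # variance approximation at the allele frequency and case fraction.
    n_out = config.n_cases + config.n_controls
    v = config.n_cases / n_out
    se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_out * v * (1.0 - v))
    beta_y_obs = beta_out_true + config.noise_scale * rng.normal(0, se_y)

    out = pd.DataFrame({
        "SNP": ids, "EA": ea.copy(), "OA": oa.copy(),
        "BETA": beta_y_obs, "SE": se_y, "P": _two_sided_p(beta_y_obs, se_y),
        "EAF": eaf.copy(), "N": n_out,
    })[PANEL_COLUMNS]

    # Report a fraction of outcome rows on the swapped allele orientation.
    flip = rng.random(n) < config.flip_frac
    out.loc[flip, ["EA", "OA"]] = out.loc[flip, ["OA", "EA"]].to_numpy()
    out.loc[flip, "BETA"] = -out.loc[flip, "BETA"]
    out.loc[flip, "EAF"] = 1.0 - out.loc[flip, "EAF"]

    # Withhold SNPs from the outcome study. When LD blocks exist, keep at
    # least one member of each block present so a proxy is available.
    n_missing = int(round(config.missing_frac * n))
    missing: list[int] = []
    if n_missing:
        order = rng.permutation(n)
        removed_per_block: dict[int, int] = {}
        sizes = np.bincount(block)
        for i in order:
            b = int(block[i])
            if config.ld_block_size > 1 and removed_per_block.get(b, 0) >= sizes[b] - 1:
                continue
            missing.append(int(i))
            removed_per_block[b] = removed_per_block.get(b, 0) + 1
            if len(missing) >= n_missing:
                break
        # top up without the block constraint if blocks were exhausted
        for i in order:
            if len(missing) >= n_missing:
                break
            if int(i) not in missing:
                missing.append(int(i))
    missing_ids = [ids[i] for i in sorted(missing)]
    out = out[~out["SNP"].isin(missing_ids)].reset_index(drop=True)

    result = (exposure_panels, out)
    if return_truth:
        truth = GwasTruth(
            snp_ids=ids, exposures=names,
            beta_exposure=beta_exp_true, beta_outcome=beta_out_true,
            direct_effects=direct,
            pleiotropic=np.isin(np.arange(n), pleio_idx),
            missing_from_outcome=missing_ids, theta=theta,
        )
        return exposure_panels, out, truth
    return result


def generate_ld_matrix(n_snps: int, block_size: int, within_block_r2: float,
                       seed: int = 0) -> LdMatrix:
    """Block-diagonal r^2 matrix: ``within_block_r2`` inside consecutive
    blocks of ``block_size`` SNPs, zero across blocks, unit diagonal."""
    if not 0.0 <= within_block_r2 <= 1.0:
        raise ValueError("within_block_r2 must be in [0, 1]")
    if block_size < 1 or block_size > n_snps:
        raise ValueError("block_size must be in [1, n_snps]")
    block = np.arange(n_snps) // block_size
    r2 = (block[:, None] == block[None, :]).astype(float) * within_block_r2
    np.fill_diagonal(r2, 1.0)
    return LdMatrix(snp_labels(n_snps), r2)


_CONFOUNDER_PHENOTYPES = [
    "autoimmune disease", "metabolic disease", "cancer",
    "inflammatory bowel disease", "all-cause mortality",
]


def generate_confounder_catalog(snp_ids: list[str], confounder_frac: float,
                                seed: int = 0) -> dict[str, list[tuple[str, float]]]:
    """Variant-to-phenotype association catalog standing in for a lookup
    service: exactly ``round(confounder_frac * len(snp_ids))`` SNPs receive
    one confounder association at genome-wide significance (p < 5e-8)."""
    if not 0.0 <= confounder_frac <= 1.0:
        raise ValueError("confounder_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_conf = int(round(confounder_frac * len(snp_ids)))
    chosen = rng.choice(len(snp_ids), size=n_conf, replace=False) if n_conf else []
    catalog: dict[str, list[tuple[str, float]]] = {}
    for i in chosen:
        pheno = _CONFOUNDER_PHENOTYPES[rng.integers(len(_CONFOUNDER_PHENOTYPES))]
        logp = rng.uniform(np.log10(1e-20), np.log10(GENOME_WIDE_P * 0.99))
        catalog[snp_ids[int(i)]] = [(pheno, float(10.0 ** logp))]
    return catalog


def generate_cbc_cohort(n_healthy: int = 100, n_cd: int = 230, n_uc: int = 80,
                        effect_profile: Optional[dict] = None,
                        seed: int = 0) -> pd.DataFrame:
    """Individual-level complete-blood-count cohort.

    Trait values are lognormal; ``effect_profile[group][trait]`` gives
    ``(location shift in healthy-SD units on the log scale, SD scale)``.
    The default profile encodes the disease-group shifts the dose-response
    stage is meant to detect (e.g. lower LYM in CD, higher EOS in UC).
    """
    for name, val in (("n_healthy", n_healthy), ("n_cd", n_cd), ("n_uc", n_uc)):
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    profile = effect_profile if effect_profile is not None else DEFAULT_GROUP_SHIFTS
    rng = np.random.default_rng(seed)

    rows = []
    counts = {"healthy": n_healthy, "CD": n_cd, "UC": n_uc}
    sid = 1
    for group, n_g in counts.items():
        group_profile = profile.get(group, {})
        for _ in range(n_g):
            row = {
                "subject_id": f"S{sid:04d}",
                "group": group,
                "age": int(rng.integers(28, 55)),
                "sex": "F" if rng.random() < 0.5 else "M",
            }
            sid += 1
            for trait in TRAITS:
                m, s = HEALTHY_REFERENCE[trait]
                sigma2 = np.log1p((s / m) ** 2)
                sigma = np.sqrt(sigma2)
                mu = np.log(m) - sigma2 / 2.0
                shift, sd_scale = group_profile.get(trait, (0.0, 1.0))
                if sd_scale <= 0:
                    raise ValueError("SD scale in effect_profile must be positive")
                row[trait] = float(np.exp(
                    rng.normal(mu + shift * sigma, sigma * sd_scale)
                ))
            rows.append(row)
    return pd.DataFrame(rows)
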