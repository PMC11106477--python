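"""Genetic-instrument selection, proxying, harmonization and validation.

Implements the instrument funnel of a two-sample MR study: genome-wide
significant SNPs for any exposure, proxy substitution for SNPs absent from
the outcome study (r^2 >= 0.8 by default), greedy LD clumping at r^2 >
0.001 keeping the smallest exposure p-value, removal of SNPs associated
with potential confounders at genome-wide significance, and allele
harmonization onto a single effect-allele orientation. Also provides
instrument-strength (F) and power diagnostics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GENOME_WIDE_P, LdMatrix

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Minor-allele-frequency bound under which a palindromic SNP's strand can
#: be resolved from allele frequencies.
PALINDROMIC_MAF_MAX = 0.42


@dataclass
class SelectionLog:
    """Counts at each stage of the instrument-selection funnel."""

    n_genomewide: int = 0
    n_missing_outcome: int = 0
    n_proxied: int = 0
    n_post_clump: int = 0
    n_confounder_removed: int = 0
    n_final: int = 0
    n_dropped_harmonization: int = 0

    def reconciles(self) -> bool:
        return self.n_final == (self.n_post_clump - self.n_confounder_removed
                                - self.n_dropped_harmonization)

    def as_dict(self) -> dict:
        return {
            "genome_wide_significant": self.n_genomewide,
            "missing_in_outcome": self.n_missing_outcome,
            "proxied": self.n_proxied,
            "post_ld_pruning": self.n_post_clump,
            "confounder_removed": self.n_confounder_removed,
            "dropped_in_harmonization": self.n_dropped_harmonization,
            "final": self.n_final,
        }


@dataclass
class HarmonizedInstrumentSet:
    """Aligned effect matrices for J instruments and K exposures.

    ``beta_x[j, k]`` is the per-SD effect of instrument j on exposure k and
    ``beta_y[j]`` its log-OR on the outcome, all expressed on a shared
    effect-allele orientation. ``proxy_map`` records instruments whose
    outcome statistics came from an LD proxy.
    """

    snp_ids: list[str]
    exposures: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    proxy_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, float))
        self.beta_y = np.asarray(self.beta_y, float).ravel()
        self.se_y = np.asarray(self.se_y, float).ravel()
        j, k = self.beta_x.shape
        if len(self.snp_ids) != j or len(self.exposures) != k:
            raise ValueError("matrix shapes do not match snp/exposure labels")
        if self.se_x.shape != (j, k) or self.beta_y.shape != (j,) or self.se_y.shape != (j,):
            raise ValueError("inconsistent matrix shapes")
        if len(set(self.snp_ids)) != j:
            raise ValueError("duplicated snp_ids")
        if (self.se_x <= 0).any() or (self.se_y <= 0).any():
            raise ValueError("all standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def exposure_index(self, exposure: str) -> int:
        try:
            return self.exposures.index(exposure)
        except ValueError:
            raise KeyError(f"unknown exposure {exposure!r}") from None

    def subset(self, snps: Iterable[str]) -> "HarmonizedInstrumentSet":
        wanted = set(snps)
        idx = [i for i, s in enumerate(self.snp_ids) if s in wanted]
        return HarmonizedInstrumentSet(
            [self.snp_ids[i] for i in idx], list(self.exposures),
            self.beta_x[idx], self.se_x[idx],
            self.beta_y[idx], self.se_y[idx],
            {s: p for s, p in self.proxy_map.items() if s in wanted},
        )

    def pvalues_x(self) -> np.ndarray:
        """Exposure association p-values recomputed from beta/SE (J x K)."""
        z = np.abs(self.beta_x) / self.se_x
        return 2.0 * stats.norm.sf(z)

    def significant_instruments(self, p_threshold: float = GENOME_WIDE_P) -> dict[str, list[str]]:
        """For each exposure, the instruments significant at the threshold
        (the per-exposure instrument sets used in univariable MR)."""
        p = self.pvalues_x()
        out: dict[str, list[str]] = {}
        for k, name in enumerate(self.exposures):
            out[name] = [s for s, keep in zip(self.snp_ids, p[:, k] < p_threshold) if keep]
        return out


# ---------------------------------------------------------------------------
# Selection stages
# ---------------------------------------------------------------------------

def select_genomewide(panels: dict[str, pd.DataFrame],
                      p_threshold: float = GENOME_WIDE_P) -> set[str]:
    """SNPs reaching p < threshold in at least one exposure panel."""
    hits: set[str] = set()
    for panel in panels.values():
        hits |= set(panel.loc[panel["P"] < p_threshold, "SNP"])
    return hits


def min_exposure_pvalues(panels: dict[str, pd.DataFrame]) -> dict[str, float]:
    """Per SNP, the minimum association p-value across exposure panels."""
    best: dict[str, float] = {}
    for panel in panels.values():
        for snp, p in zip(panel["SNP"], panel["P"]):
            if snp not in best or p < best[snp]:
                best[snp] = float(p)
    return best


def clump(candidates: Iterable[str], ld: LdMatrix, pvalues: dict[str, float],
          r2_threshold: float = 0.001) -> set[str]:
    """Greedy LD clumping: repeatedly keep the remaining SNP with the
    smallest p-value and discard all others correlated with it at
    r^2 > threshold. No retained pair exceeds the threshold."""
    remaining = sorted(candidates, key=lambda s: (pvalues[s], s))
    for s in remaining:
        ld.index(s)  # raises if absent
    kept: list[str] = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        i = ld.index(lead)
        remaining = [s for s in remaining if ld.r2[i, ld.index(s)] <= r2_threshold]
    return set(kept)


def find_proxy(missing_snp: str, ld: LdMatrix, outcome_snps: Iterable[str],
               r2_min: float = 0.8) -> Optional[str]:
    """Best available LD proxy present in the outcome study, or None.

    Returns the outcome-present SNP with the largest r^2 to ``missing_snp``
    provided it reaches ``r2_min``; ties broken by SNP id for determinism.
    """
    i = ld.index(missing_snp)
    best: Optional[str] = None
    best_r2 = -1.0
    for s in sorted(outcome_snps):
        if s == missing_snp or s not in ld._index:
            continue
        r2 = float(ld.r2[i, ld.index(s)])
        if r2 > best_r2:
            best, best_r2 = s, r2
    if best is not None and best_r2 >= r2_min:
        return best
    return None


def filter_confounders(snps: Iterable[str], catalog: dict,
                       p_threshold: float = GENOME_WIDE_P) -> tuple[set[str], set[str]]:
    """Drop SNPs with any catalogued confounder association at p < threshold.

    Returns ``(retained, dropped)``.
    """
    retained, dropped = set(), set()
    for snp in snps:
        entries = catalog.get(snp, [])
        if any(p < p_threshold for _, p in entries):
            dropped.add(snp)
        else:
            retained.add(snp)
    return retained, dropped


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def _align_row(ea_ref: str, oa_ref: str, eaf_ref, ea: str, oa: str, eaf,
               palindromic_maf: float = PALINDROMIC_MAF_MAX) -> Optional[int]:
    """Orientation of one row relative to the reference alleles.

    Returns +1 (keep), -1 (flip the effect sign) or None (irreconcilable /
    ambiguous palindromic). Palindromic SNPs are resolved by allele
    frequency when both minor-allele frequencies are below
    ``palindromic_maf`` and concordant, otherwise dropped.
    """
    if _is_palindromic(ea_ref, oa_ref):
        if {ea, oa} != {ea_ref, oa_ref}:
            return None
        if eaf_ref is None or eaf is None or not np.isfinite(eaf_ref) or not np.isfinite(eaf):
            return None
        maf_ref = min(eaf_ref, 1.0 - eaf_ref)
        maf = min(eaf, 1.0 - eaf)
        if maf_ref >= palindromic_maf or maf >= palindromic_maf:
            return None
        return 1 if (eaf_ref < 0.5) == (eaf < 0.5) else -1
    if (ea, oa) == (ea_ref, oa_ref):
        return 1
    if (ea, oa) == (oa_ref, ea_ref):
        return -1
    # strand-complement reporting
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (cea, coa) == (ea_ref, oa_ref):
        return 1
    if (cea, coa) == (oa_ref, ea_ref):
        return -1
    return None


def harmonize(exposure_panels: dict[str, pd.DataFrame], outcome_panel: pd.DataFrame,
              snps: Optional[Iterable[str]] = None,
              proxy_map: Optional[dict[str, str]] = None,
              palindromic_maf: float = PALINDROMIC_MAF_MAX) -> HarmonizedInstrumentSet:
    """Align exposure and outcome panels onto one effect-allele orientation.

    The first exposure panel defines the reference orientation. Outcome rows
    reported on the swapped (or strand-complement) orientation have their
    effect sign flipped; palindromic SNPs are resolved by allele frequency
    or dropped; irreconcilable allele pairs are dropped. For instruments in
    ``proxy_map`` the outcome statistics of the proxy variant are used
    (aligned against the proxy's own exposure record).
    """
    proxy_map = proxy_map or {}
    exposures = list(exposure_panels)
    ref_panel = exposure_panels[exposures[0]].set_index("SNP")
    indexed = {name: p.set_index("SNP") for name, p in exposure_panels.items()}
    out_idx = outcome_panel.set_index("SNP")

    if snps is None:
        snps = [s for s in ref_panel.index if s in out_idx.index or s in proxy_map]
    wanted = list(dict.fromkeys(snps))

    kept_ids, bx, sx, by, sy = [], [], [], [], []
    used_proxies: dict[str, str] = {}
    for snp in wanted:
        if snp not in ref_panel.index:
            continue
        ref = ref_panel.loc[snp]
        ea_ref, oa_ref, eaf_ref = ref["EA"], ref["OA"], ref.get("EAF", np.nan)

        # exposure rows (shared orientation expected; re-align defensively)
        row_bx, row_sx, ok = [], [], True
        for name in exposures:
            panel = indexed[name]
            if snp not in panel.index:
                ok = False
                break
            r = panel.loc[snp]
            sign = _align_row(ea_ref, oa_ref, eaf_ref, r["EA"], r["OA"],
                              r.get("EAF", np.nan), palindromic_maf)
            if sign is None:
                ok = False
                break
            row_bx.append(sign * float(r["BETA"]))
            row_sx.append(float(r["SE"]))
        if not ok:
            continue

        # outcome row, possibly via proxy
        outcome_snp = proxy_map.get(snp, snp)
        if outcome_snp not in out_idx.index:
            continue
        orow = out_idx.loc[outcome_snp]
        if outcome_snp == snp:
            sign = _align_row(ea_ref, oa_ref, eaf_ref, orow["EA"], orow["OA"],
                              orow.get("EAF", np.nan), palindromic_maf)
        else:
            # align the proxy's outcome record against the proxy's own
            # exposure orientation (its LD with the instrument carries the
            # effect direction in the reference panels).
            if outcome_snp not in ref_panel.index:
                continue
            pref = ref_panel.loc[outcome_snp]
            sign = _align_row(pref["EA"], pref["OA"], pref.get("EAF", np.nan),
                              orow["EA"], orow["OA"], orow.get("EAF", np.nan),
                              palindromic_maf)
        if sign is None:
            continue

        kept_ids.append(snp)
        bx.append(row_bx)
        sx.append(row_sx)
        by.append(sign * float(orow["BETA"]))
        sy.append(float(orow["SE"]))
        if outcome_snp != snp:
            used_proxies[snp] = outcome_snp

    if not kept_ids:
        raise ValueError("no instruments survived harmonization")
    return HarmonizedInstrumentSet(
        kept_ids, exposures, np.array(bx), np.array(sx),
        np.array(by), np.array(sy), used_proxies,
    )


# ---------------------------------------------------------------------------
# Strength and power
# ---------------------------------------------------------------------------

def f_statistic(r2: float, n: int, k: int) -> float:
    """Overall instrument-strength F statistic.

    ``r2`` is the fraction of exposure variance explained by the k SNPs in
    a study of n individuals: F = (r2/k) / ((1-r2)/(n-k-1)). F >= 10 is the
    conventional bar for negligible weak-instrument bias.
    """
    if not 0.0 < r2 < 1.0:
        raise ValueError("r2 must be in (0, 1)")
    if n <= k + 1 or k < 1:
        raise ValueError("need n > k+1 and k >= 1")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def per_snp_f(beta: float, se: float) -> float:
    """Single-SNP instrument strength: the squared z-score (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def mr_power(n_outcome: int, case_ratio: float, r2_sum: float,
             odds_ratio: float, alpha: float = 0.05) -> float:
    """Approximate power of an MR analysis with a binary outcome.

    Normal-approximation non-centrality: the causal log-OR is estimated
    with standard error 1/sqrt(n * r2_sum * v * (1 - v)) where v is the
    case fraction and r2_sum the variance of the exposure explained by the
    instruments, giving

        power = Phi(|ln OR| * sqrt(n * r2_sum * v * (1 - v)) - z_{1-alpha/2}).
    """
    if not 0.0 < case_ratio < 1.0:
        raise ValueError("case_ratio must be in (0, 1)")
    if not 0.0 < r2_sum < 1.0:
        raise ValueError("r2_sum must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if n_outcome <= 0:
        raise ValueError("n_outcome must be positive")
    ncp = abs(np.log(odds_ratio)) * np.sqrt(
        n_outcome * r2_sum * case_ratio * (1.0 - case_ratio))
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit))


# ---------------------------------------------------------------------------
# Full funnel
# ---------------------------------------------------------------------------

def select_instruments(exposure_panels: dict[str, pd.DataFrame],
                       outcome_panel: pd.DataFrame,
                       ld: Optional[LdMatrix] = None,
                       catalog: Optional[dict] = None,
                       p_threshold: float = GENOME_WIDE_P,
                       clump_r2: float = 0.001,
                       proxy_r2: float = 0.8,
                       confounder_p: float = GENOME_WIDE_P,
                       ) -> tuple[HarmonizedInstrumentSet, SelectionLog]:
    """Run the whole instrument funnel and return the harmonized set.

    Order of operations: genome-wide selection, proxy lookup for SNPs
    missing from the outcome panel, LD clumping (skipped without an LD
    matrix), confounder screen (skipped without a catalog), harmonization.
    """
    log = SelectionLog()
    gw = select_genomewide(exposure_panels, p_threshold)
    log.n_genomewide = len(gw)

    outcome_present = set(outcome_panel["SNP"])
    missing = gw - outcome_present
    log.n_missing_outcome = len(missing)
    proxy_map: dict[str, str] = {}
    if ld is not None:
        for snp in sorted(missing):
            if snp not in ld._index:
                continue
            proxy = find_proxy(snp, ld, outcome_present, proxy_r2)
            if proxy is not None:
                proxy_map[snp] = proxy
    log.n_proxied = len(proxy_map)
    usable = (gw & outcome_present) | set(proxy_map)

    if ld is not None:
        pvals = min_exposure_pvalues(exposure_panels)
        clumpable = {s for s in usable if s in ld._index}
        usable = clump(clumpable, ld, pvals, clump_r2)
    log.n_post_clump = len(usable)

    if catalog is not None:
        usable, dropped = filter_confounders(usable, catalog, confounder_p)
        log.n_confounder_removed = len(dropped)

    hset = harmonize(exposure_panels, outcome_panel, sorted(usable), proxy_map)
    log.n_final = hset.n_snps
    log.n_dropped_harmonization = (log.n_post_clump - log.n_confounder_removed
                                   - log.n_final)
    return hset, log
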