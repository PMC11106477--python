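"""Instrument funnel: genome-wide selection, clumping, proxying,
confounder screening, harmonization, and strength/power metrics."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bloodmr import (
    SyntheticGwasConfig,
    clump,
    f_statistic,
    filter_confounders,
    find_proxy,
    generate_confounder_catalog,
    generate_ld_matrix,
    generate_summary_stats,
    harmonize,
    mr_power,
    per_snp_f,
    select_genomewide,
    select_instruments,
)
from bloodmr.simulate import LdMatrix, snp_labels


def _panel(snps, pvals, betas=None, ea="A", oa="C", eaf=0.3, se=0.01):
    n = len(snps)
    betas = betas if betas is not None else np.full(n, 0.05)
    return pd.DataFrame({
        "SNP": snps, "EA": [ea] * n, "OA": [oa] * n, "BETA": betas,
        "SE": [se] * n, "P": pvals, "EAF": [eaf] * n, "N": [1000] * n,
    })


# ---------------------------------------------------------------------------
# Genome-wide selection
# ---------------------------------------------------------------------------

def test_select_genomewide_threshold_and_empty():
    panel = _panel(["rs1", "rs2"], [1e-9, 1e-7])
    assert select_genomewide({"X": panel}) == {"rs1"}
    assert select_genomewide({"X": _panel(["rs1", "rs2"], [1.0, 1.0])}) == set()


def test_select_genomewide_matches_brute_force_scan():
    """Planted strong signals among nulls: selection equals a direct scan
    over every row of every panel."""
    rng = np.random.default_rng(0)
    panels = {}
    snps = snp_labels(200)
    for trait in ("A", "B"):
        p = rng.uniform(1e-6, 1.0, size=200)
        planted = rng.choice(200, 25, replace=False)
        p[planted] = rng.uniform(1e-30, 1e-10, size=25)
        panels[trait] = _panel(snps, p)
    expected = {s for panel in panels.values()
                for s, p in zip(panel["SNP"], panel["P"]) if p < 5e-8}
    assert select_genomewide(panels) == expected


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------

def test_clump_keeps_min_p_per_cluster():
    ld = LdMatrix(["A", "B", "C"], np.array([
        [1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]]))
    kept = clump(["A", "B", "C"], ld, {"A": 1e-10, "B": 1e-9, "C": 1e-8})
    assert kept == {"A", "C"}


def test_clump_identity_ld_keeps_everything():
    ld = generate_ld_matrix(10, 1, 0.0)
    pvals = {s: 1e-9 for s in ld.snp_ids}
    assert clump(ld.snp_ids, ld, pvals) == set(ld.snp_ids)


def test_clump_matches_explicit_greedy_oracle():
    """Random blocky LD: the result equals an independently coded greedy
    loop, and no retained pair exceeds the threshold."""
    rng = np.random.default_rng(4)
    ld = generate_ld_matrix(30, 3, 0.8, seed=1)
    pvals = {s: float(p) for s, p in zip(ld.snp_ids, rng.uniform(1e-12, 1e-4, 30))}

    # independent oracle: explicit loop over p-sorted candidates
    order = sorted(ld.snp_ids, key=lambda s: (pvals[s], s))
    kept, discarded = [], set()
    for s in order:
        if s in discarded:
            continue
        kept.append(s)
        for t in order:
            if t not in discarded and t != s and ld.between(s, t) > 0.001:
                discarded.add(t)
    assert clump(ld.snp_ids, ld, pvals) == set(kept)

    result = sorted(clump(ld.snp_ids, ld, pvals))
    for i, a in enumerate(result):
        for b in result[i + 1:]:
            assert ld.between(a, b) <= 0.001


def test_clump_missing_snp_raises():
    ld = generate_ld_matrix(3, 1, 0.0)
    with pytest.raises(KeyError):
        clump(["rs1", "rs99"], ld, {"rs1": 1e-9, "rs99": 1e-9})


# ---------------------------------------------------------------------------
# Proxy lookup
# ---------------------------------------------------------------------------

def _proxy_ld(r2_ab, r2_ac):
    m = np.array([[1.0, r2_ab, r2_ac], [r2_ab, 1.0, 0.0], [r2_ac, 0.0, 1.0]])
    return LdMatrix(["A", "B", "C"], m)


def test_find_proxy_threshold_and_argmax():
    assert find_proxy("A", _proxy_ld(0.85, 0.0), ["B", "C"]) == "B"
    assert find_proxy("A", _proxy_ld(0.5, 0.0), ["B", "C"]) is None
    assert find_proxy("A", _proxy_ld(0.9, 0.95), ["B", "C"]) == "C"


# ---------------------------------------------------------------------------
# Confounder screen
# ---------------------------------------------------------------------------

def test_filter_confounders_threshold():
    catalog = {"rs1": [("lipids", 1e-9)], "rs2": [("lipids", 1e-6)]}
    retained, dropped = filter_confounders(["rs1", "rs2", "rs3"], catalog)
    assert retained == {"rs2", "rs3"}
    assert dropped == {"rs1"}


def test_filter_confounders_with_generated_catalog():
    ids = snp_labels(100)
    catalog = generate_confounder_catalog(ids, 0.1, seed=3)
    retained, dropped = filter_confounders(ids, catalog)
    assert len(retained) == 90 and len(dropped) == 10


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def test_harmonize_flips_swapped_alleles():
    exp = _panel(["rs1"], [1e-9], betas=[0.5], ea="A", oa="C")
    out = _panel(["rs1"], [0.01], betas=[0.2], ea="C", oa="A")
    hset = harmonize({"X": exp}, out)
    assert hset.beta_y[0] == pytest.approx(-0.2)
    assert hset.beta_x[0, 0] == pytest.approx(0.5)


def test_harmonize_identical_orientation_unchanged():
    exp = _panel(["rs1"], [1e-9], betas=[0.5])
    out = _panel(["rs1"], [0.01], betas=[0.2])
    hset = harmonize({"X": exp}, out)
    assert hset.beta_y[0] == pytest.approx(0.2)


def test_harmonize_drops_ambiguous_palindromic():
    exp = _panel(["rs1", "rs2"], [1e-9, 1e-9], betas=[0.5, 0.5], ea="A", oa="T",
                 eaf=0.5)
    out = _panel(["rs1", "rs2"], [0.01, 0.01], betas=[0.2, 0.2], ea="A", oa="T",
                 eaf=0.5)
    with pytest.raises(ValueError):
        harmonize({"X": exp}, out)  # every SNP ambiguous -> none survive


def test_harmonize_resolves_palindromic_by_frequency():
    # A/T variant, minor allele A at 20%; the outcome study reports the
    # effect for T (frequency 80%), so the sign must flip on alignment.
    exp = _panel(["rs1"], [1e-9], betas=[0.5], ea="A", oa="T", eaf=0.2)
    out = _panel(["rs1"], [0.01], betas=[0.2], ea="T", oa="A", eaf=0.8)
    hset = harmonize({"X": exp}, out)
    assert hset.beta_y[0] == pytest.approx(-0.2)


def test_harmonize_strand_complement_reporting():
    exp = _panel(["rs1"], [1e-9], betas=[0.5], ea="A", oa="C")
    out = _panel(["rs1"], [0.01], betas=[0.2], ea="T", oa="G")  # complement strand
    hset = harmonize({"X": exp}, out)
    assert hset.beta_y[0] == pytest.approx(0.2)


def test_harmonize_is_involutive():
    """Re-harmonizing an already harmonized outcome panel changes nothing."""
    cfg = SyntheticGwasConfig(n_snps=80, n_exposures=2, missing_frac=0.0, seed=7)
    panels, out = generate_summary_stats(cfg)
    h1 = harmonize(panels, out)
    # rebuild the outcome panel on the harmonized orientation
    ref = panels[list(panels)[0]].set_index("SNP")
    out2 = pd.DataFrame({
        "SNP": h1.snp_ids,
        "EA": [ref.loc[s, "EA"] for s in h1.snp_ids],
        "OA": [ref.loc[s, "OA"] for s in h1.snp_ids],
        "BETA": h1.beta_y, "SE": h1.se_y,
        "P": 2 * stats.norm.sf(np.abs(h1.beta_y) / h1.se_y),
        "EAF": [ref.loc[s, "EAF"] for s in h1.snp_ids],
        "N": 1000,
    })
    h2 = harmonize(panels, out2, snps=h1.snp_ids)
    assert h2.snp_ids == h1.snp_ids
    np.testing.assert_array_equal(h2.beta_y, h1.beta_y)
    np.testing.assert_array_equal(h2.beta_x, h1.beta_x)


# ---------------------------------------------------------------------------
# Strength and power
# ---------------------------------------------------------------------------

def test_f_statistic_hand_values():
    assert f_statistic(0.5, 5, 1) == pytest.approx(3.0)
    assert f_statistic(0.01, 563085, 100) == pytest.approx(56.87, abs=0.005)


def test_f_statistic_monotone_in_r2_and_linear_in_n():
    values = [f_statistic(r2, 1000, 10) for r2 in (0.01, 0.05, 0.1, 0.5)]
    assert all(a < b for a, b in zip(values, values[1:]))
    # at fixed k, F grows linearly in n
    f1 = f_statistic(0.5, 1002, 1)
    f2 = f_statistic(0.5, 2002, 1)
    assert f2 / f1 == pytest.approx(2000 / 1000)


def test_f_statistic_domain():
    with pytest.raises(ValueError):
        f_statistic(0.0, 100, 1)
    with pytest.raises(ValueError):
        f_statistic(0.5, 2, 1)


def test_per_snp_f_values_and_pvalue_consistency():
    assert per_snp_f(0.01, 0.001) == pytest.approx(100.0)
    assert per_snp_f(0.0, 0.01) == 0.0
    # equals the squared inverse-normal z of a normal-consistent p-value
    beta, se = 0.042, 0.007
    p = 2 * stats.norm.sf(abs(beta) / se)
    z = stats.norm.isf(p / 2)
    assert per_snp_f(beta, se) == pytest.approx(z ** 2, rel=1e-10)
    with pytest.raises(ValueError):
        per_snp_f(0.1, 0.0)


def test_mr_power_null_and_monotonicity():
    assert mr_power(10000, 0.3, 0.02, 1.0) == pytest.approx(0.025)
    p_small = mr_power(5000, 0.3, 0.02, 1.2)
    p_large = mr_power(50000, 0.3, 0.02, 1.2)
    assert p_small < p_large
    assert mr_power(5000, 0.3, 0.02, 1.1) < mr_power(5000, 0.3, 0.02, 1.4)
    assert mr_power(5000, 0.3, 0.02, 1 / 1.4) == pytest.approx(
        mr_power(5000, 0.3, 0.02, 1.4))


def test_mr_power_matches_quadrature_oracle():
    """Power equals the tail mass of the non-central normal computed by
    numerical integration."""
    from scipy.integrate import quad

    n, ratio, r2, orr = 27432, 6968 / 27432, 0.02, 1.36
    ncp = abs(np.log(orr)) * np.sqrt(n * r2 * ratio * (1 - ratio))
    z_crit = stats.norm.ppf(0.975)
    tail, _ = quad(lambda z: stats.norm.pdf(z, loc=ncp), z_crit, np.inf)
    assert mr_power(n, ratio, r2, orr) == pytest.approx(tail, abs=1e-6)


# ---------------------------------------------------------------------------
# Full funnel bookkeeping
# ---------------------------------------------------------------------------

def test_selection_log_reconciles_on_synthetic_run():
    cfg = SyntheticGwasConfig(n_snps=150, n_exposures=3, ld_block_size=3,
                              within_block_r2=0.9, missing_frac=0.15, seed=21)
    panels, out = generate_summary_stats(cfg)
    ld = generate_ld_matrix(150, 3, 0.9)
    catalog = generate_confounder_catalog(ld.snp_ids, 0.1, seed=2)
    hset, log = select_instruments(panels, out, ld=ld, catalog=catalog)
    assert log.reconciles()
    assert log.n_final == hset.n_snps
    assert log.n_genomewide >= log.n_post_clump
    # proxied instruments recorded and resolve to present outcome SNPs
    present = set(out["SNP"])
    for snp, proxy in hset.proxy_map.items():
        assert snp not in present and proxy in present
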