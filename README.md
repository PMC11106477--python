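# bloodmr

Two-sample Mendelian randomization (MR) of blood-cell traits on
inflammatory bowel disease, as a tested, reusable Python pipeline.

## The problem

Observational associations between complete-blood-count (CBC) traits and
Crohn's disease (CD) or ulcerative colitis (UC) are confounded by
inflammation itself. MR sidesteps this by using genetic variants as
instrumental variables: a SNP that raises, say, eosinophil count (EOS) is
assigned at conception, so its association with UC reflects the causal
effect of the trait — provided the instrument assumptions hold. `bloodmr`
implements the full workflow for 15 CBC traits (RBC, HGB, HCT, MCV, MCH,
MCHC, RDW, WBC, NEU, LYM, MON, BAS, EOS, PLT, MPV) against two binary
outcomes:

1. **Instrument selection and validation** — genome-wide significance
   (p < 5×10⁻⁸), LD proxy substitution (r² ≥ 0.8) for SNPs missing from
   the outcome GWAS, greedy LD clumping (r² > 0.001, keep minimum p),
   confounder screening against a variant–phenotype catalog, allele
   harmonization (including frequency-resolved palindromic SNPs), the
   instrument-strength F statistic F = (R²/k)/((1−R²)/(n−k−1)), per-SNP
   F = (β/se)², and an analytic power calculation for binary outcomes.
2. **Six univariable estimators** — fixed-effect and multiplicative
   random-effects inverse-variance weighting (IVW), simple / weighted /
   penalized weighted median, and MR-Egger regression, with Cochran's Q
   heterogeneity and Egger-intercept pleiotropy diagnostics and a
   Bonferroni threshold of α/(15 traits × 2 outcomes) = 0.05/30 ≈ 0.0017.
3. **Multivariable MR via Bayesian model averaging (MR-BMA)** — every
   subset of exposures is scored by a closed-form Gaussian marginal
   likelihood on the inverse-variance-weighted scale; posterior model
   probabilities (PP) yield per-trait marginal inclusion probabilities
   (MIP) and model-averaged causal estimates (θ̂_MACE). Invalid or
   influential instruments are pruned iteratively by per-SNP Cochran Q
   contributions (Q > 10) and Cook's distance (Cd > median of F(d, J−d)).
4. **Dose-response curves** — restricted-cubic-spline logistic regression
   of case status on each trait in an individual-level cohort
   (100 healthy / 230 CD / 80 UC), reporting the logOR curve, its 95%
   band, and the trait values where a band boundary crosses zero
   (candidate clinical thresholds).

Because the consortium GWAS and the hospital cohort are not deposited,
the package ships a first-class synthetic-data module that emulates the
study design with known ground truth: sparse per-SNP effects correlated
across the 15 traits, a small causal subset driving the outcome log-odds,
configurable pleiotropy, block-diagonal LD, per-study sampling noise, and
a CBC cohort with the reported disease-group shifts.

## Worked example

```python
import numpy as np
from bloodmr import (SyntheticGwasConfig, generate_summary_stats,
                     generate_ld_matrix, generate_confounder_catalog,
                     select_instruments, UnivariableMR, MRBMA)

theta = np.zeros(15); theta[12] = 0.3          # true EOS -> UC effect (log-OR/SD)
cfg = SyntheticGwasConfig(n_snps=1500, causal_effects=theta,
                          ld_block_size=3, within_block_r2=0.9, seed=7)
panels, outcome = generate_summary_stats(cfg)
ld = generate_ld_matrix(1500, 3, 0.9, seed=7)
catalog = generate_confounder_catalog(ld.snp_ids, 0.1, seed=7)

hset, funnel = select_instruments(panels, outcome, ld=ld, catalog=catalog)
print(funnel.as_dict())

model = UnivariableMR.from_instruments(
    hset, "EOS", outcome="UC",
    snps=hset.significant_instruments()["EOS"])
print(model.fit("ivw_re", bonferroni_alpha=0.05/30).summary())

res = MRBMA(hset).fit()
print(res.ranking().head(3).round(3))
```

prints

```
{'genome_wide_significant': 1029, 'missing_in_outcome': 102, 'proxied': 102,
 'post_ld_pruning': 354, 'confounder_removed': 30,
 'dropped_in_harmonization': 1, 'final': 323}
Univariable MR: EOS -> UC [ivw_re]
  instruments: 41
  log-OR per SD: +0.3246 (SE 0.0616)
  OR per SD:     1.383 (95% CI 1.226, 1.561)
  p-value:       1.37e-07
  Cochran Q:     41.95 on 40 df (p = 0.386)
  significant at Bonferroni alpha=0.001667: yes
       mip   mace
EOS  1.000  0.320
MCV  0.346 -0.058
MPV  0.126  0.017
```

The funnel shows 1,029 genome-wide-significant SNPs reduced to 323
harmonized instruments; the random-effects IVW recovers the planted EOS
effect (true OR per SD = e^0.3 ≈ 1.35, estimated 1.38, CI 1.23–1.56)
well below the Bonferroni threshold, with no evidence of heterogeneity;
and MR-BMA ranks EOS first with MIP 1.0 and θ̂_MACE ≈ 0.32.

The same run end-to-end, from the shell:

```bash
bloodmr run-all --seed 7 --outdir results/run7        # full pipeline
bloodmr simulate --seed 7 --outdir data/              # or stage by stage
bloodmr select --indir data/ --outdir sel/
bloodmr rcs --cohort data/cohort.tsv --trait LYM --case-group CD --out lym_cd.tsv
```

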