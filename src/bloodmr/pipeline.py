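"""End-to-end orchestration: simulate or ingest data, select instruments,
run univariable MR, MR-BMA and the spline dose-response stage, and emit a
reproducible report.

A single master seed is fanned out into per-stage substreams
(numpy SeedSequence) so any stage can be rerun in isolation; all
intermediate artifacts are plain TSV/JSON.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as bio
from .bma import BmaConfig, MRBMA
from .instruments import SelectionLog, select_instruments
from .simulate import (
    GENOME_WIDE_P,
    SyntheticGwasConfig,
    generate_cbc_cohort,
    generate_confounder_catalog,
    generate_ld_matrix,
    generate_summary_stats,
)
from .spline import RcsLogistic, group_compare
from .traits import OUTCOME_STUDIES, TRAITS
from .uvmr import run_uvmr_grid

__version__ = "0.1.0"
log = logging.getLogger("bloodmr")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    mode: str = "synthetic"                 # "synthetic" | "user-data"
    seed: Optional[int] = 0                 # mandatory in synthetic mode
    outdir: Optional[str] = None

    # thresholds (documented defaults)
    p_threshold: float = GENOME_WIDE_P
    clump_r2: float = 0.001
    proxy_r2: float = 0.8
    confounder_p: float = GENOME_WIDE_P
    alpha: float = 0.05
    n_boot: int = 200                        # bootstrap resamples for median SEs

    # synthetic-mode generator settings
    n_snps: int = 1500
    n_exposures: int = 15
    causal_effects: dict = field(default_factory=lambda: {
        "CD": {"LYM": -0.2}, "UC": {"EOS": 0.3}})
    ld_block_size: int = 3
    within_block_r2: float = 0.9
    missing_frac: float = 0.1
    confounder_frac: float = 0.1
    cohort_sizes: tuple = (100, 230, 80)    # healthy, CD, UC

    # user-data mode paths
    exposure_paths: dict = field(default_factory=dict)   # trait -> TSV
    outcome_paths: dict = field(default_factory=dict)    # outcome -> TSV
    ld_path: Optional[str] = None
    catalog_path: Optional[str] = None
    cohort_path: Optional[str] = None

    # stage configs
    bma: BmaConfig = field(default_factory=BmaConfig)
    rcs_knots: int = 4

    def bonferroni_alpha(self) -> float:
        n_outcomes = len(self.causal_effects) if self.mode == "synthetic" \
            else max(len(self.outcome_paths), 1)
        return self.alpha / (self.n_exposures * n_outcomes)


class ConfigError(ValueError):
    """Aggregated configuration problems (never first-error-only)."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def validate_config(config: RunConfig | dict | None = None) -> RunConfig:
    """Normalise a config (dict or RunConfig), filling documented defaults
    and rejecting out-of-domain values with messages naming the field."""
    if config is None:
        config = RunConfig()
    elif isinstance(config, dict):
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(config) - known
        cfg = dict(config)
        if "bma" in cfg and isinstance(cfg["bma"], dict):
            cfg["bma"] = BmaConfig(**cfg["bma"])
        errors = [f"unknown field {k!r}" for k in sorted(unknown)]
        if errors:
            raise ConfigError(errors)
        config = RunConfig(**cfg)

    errors: list[str] = []
    unit = [("p_threshold", config.p_threshold), ("clump_r2", config.clump_r2),
            ("proxy_r2", config.proxy_r2), ("confounder_p", config.confounder_p),
            ("alpha", config.alpha), ("missing_frac", config.missing_frac),
            ("confounder_frac", config.confounder_frac),
            ("within_block_r2", config.within_block_r2)]
    for name, v in unit:
        if not 0.0 <= v <= 1.0:
            errors.append(f"{name} must be in [0, 1], got {v}")
    if config.mode not in ("synthetic", "user-data"):
        errors.append(f"mode must be 'synthetic' or 'user-data', got {config.mode!r}")
    if config.mode == "synthetic" and config.seed is None:
        errors.append("seed is mandatory in synthetic mode")
    if config.n_snps <= 0:
        errors.append(f"n_snps must be positive, got {config.n_snps}")
    if config.n_exposures <= 0:
        errors.append(f"n_exposures must be positive, got {config.n_exposures}")
    if config.n_boot < 2:
        errors.append(f"n_boot must be >= 2, got {config.n_boot}")
    if config.rcs_knots < 3:
        errors.append(f"rcs_knots must be >= 3, got {config.rcs_knots}")
    if config.mode == "synthetic":
        known_traits = set(TRAITS[:config.n_exposures]) if config.n_exposures > 0 else set()
        for outcome, effects in config.causal_effects.items():
            for trait in effects:
                if trait not in known_traits:
                    errors.append(
                        f"causal_effects[{outcome!r}]: trait {trait!r} is not "
                        f"among the first {config.n_exposures} exposures")
    try:
        config.bma.validate()
    except ValueError as exc:
        errors.append(f"bma: {exc}")
    if errors:
        raise ConfigError(errors)
    return config


@dataclass
class RunReport:
    """Everything one pipeline run produced, traceable to its seed."""

    selection_logs: dict            # outcome -> SelectionLog dict
    uvmr_table: pd.DataFrame
    bma_rankings: dict              # outcome -> DataFrame (MIP/MACE)
    bma_models: dict                # outcome -> DataFrame (top models)
    bma_audits: dict                # outcome -> list of prune records
    rcs_crossings: pd.DataFrame
    group_comparisons: pd.DataFrame
    provenance: dict

    def as_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "selection_logs": self.selection_logs,
            "uvmr": self.uvmr_table.to_dict(orient="records"),
            "bma_rankings": {o: df.reset_index().rename(
                columns={"index": "exposure"}).to_dict(orient="records")
                for o, df in self.bma_rankings.items()},
            "bma_models": {o: [
                {"model": list(r["model"]), "pp": r["pp"],
                 "estimates": list(r["estimates"])}
                for _, r in df.iterrows()] for o, df in self.bma_models.items()},
            "bma_audits": self.bma_audits,
            "rcs_crossings": self.rcs_crossings.to_dict(orient="records"),
            "group_comparisons": self.group_comparisons.to_dict(orient="records"),
        }

    def report_hash(self) -> str:
        """Stable digest of the scientific content (timing excluded)."""
        d = self.as_dict()
        d["provenance"] = {k: v for k, v in d["provenance"].items()
                           if k != "elapsed_s"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.uvmr_table.to_csv(outdir / "uvmr_results.tsv", sep="\t", index=False)
        for outcome, df in self.bma_rankings.items():
            df.to_csv(outdir / f"bma_ranking_{outcome}.tsv", sep="\t")
        self.rcs_crossings.to_csv(outdir / "rcs_crossings.tsv", sep="\t", index=False)
        self.group_comparisons.to_csv(outdir / "group_comparisons.tsv",
                                      sep="\t", index=False)
        bio.write_json(self.as_dict(), outdir / "report.json")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _synthetic_inputs(config: RunConfig):
    """Generate all synthetic inputs from the master seed."""
    seeds = _child_seeds(config.seed, 4)
    outcomes = list(config.causal_effects)
    names = TRAITS[:config.n_exposures]
    exposure_panels = None
    outcome_panels = {}
    for outcome in outcomes:
        theta = np.zeros(config.n_exposures)
        for trait, val in config.causal_effects[outcome].items():
            theta[names.index(trait)] = val
        study = OUTCOME_STUDIES.get(outcome, OUTCOME_STUDIES["UC"])
        gcfg = SyntheticGwasConfig(
            n_snps=config.n_snps, n_exposures=config.n_exposures,
            causal_effects=theta,
            n_cases=study["cases"], n_controls=study["controls"],
            missing_frac=config.missing_frac,
            ld_block_size=config.ld_block_size,
            within_block_r2=config.within_block_r2,
            # One seed for both outcomes: the exposure draw (which happens
            # before the outcome draw in the generator stream) is then
            # identical across outcome panels, as in a real two-sample
            # design where both diseases share the same exposure GWAS.
            seed=seeds[0],
        )
        panels, out = generate_summary_stats(gcfg)
        if exposure_panels is None:
            exposure_panels = panels
        outcome_panels[outcome] = out
    ld = generate_ld_matrix(config.n_snps, config.ld_block_size,
                            config.within_block_r2, seeds[1])
    catalog = generate_confounder_catalog(ld.snp_ids, config.confounder_frac,
                                          seeds[2])
    cohort = generate_cbc_cohort(*config.cohort_sizes, seed=seeds[3])
    return exposure_panels, outcome_panels, ld, catalog, cohort


def _user_inputs(config: RunConfig):
    exposure_panels = {t: bio.read_summary_stats(p)
                       for t, p in config.exposure_paths.items()}
    outcome_panels = {o: bio.read_summary_stats(p)
                      for o, p in config.outcome_paths.items()}
    ld = bio.read_ld_matrix(config.ld_path) if config.ld_path else None
    catalog = None
    if config.catalog_path:
        try:
            catalog = bio.read_confounder_catalog(config.catalog_path)
        except FileNotFoundError:
            log.warning("confounder catalog %s not found; filter skipped",
                        config.catalog_path)
    cohort = bio.read_cohort(config.cohort_path) if config.cohort_path else None
    return exposure_panels, outcome_panels, ld, catalog, cohort


def run_pipeline(config: RunConfig | dict | None = None) -> RunReport:
    """Execute selection -> proxies -> LD -> confounders -> uvMR / MR-BMA ->
    diagnostics -> dose-response and return the collected report.

    Stage failures are isolated: a failing exposure-outcome cell or trait
    curve is recorded with its error and the run continues.
    """
    config = validate_config(config)
    t0 = time.time()
    if config.mode == "synthetic":
        exposure_panels, outcome_panels, ld, catalog, cohort = _synthetic_inputs(config)
    else:
        exposure_panels, outcome_panels, ld, catalog, cohort = _user_inputs(config)

    selection_logs: dict = {}
    hsets = {}
    for outcome, panel in outcome_panels.items():
        hset, slog = select_instruments(
            exposure_panels, panel, ld=ld, catalog=catalog,
            p_threshold=config.p_threshold, clump_r2=config.clump_r2,
            proxy_r2=config.proxy_r2, confounder_p=config.confounder_p)
        hsets[outcome] = hset
        selection_logs[outcome] = slog.as_dict()
        log.info("instrument funnel for %s: %s", outcome, slog.as_dict())

    seed_uvmr = _child_seeds(config.seed or 0, 6)[4]
    uvmr_table = run_uvmr_grid(hsets, alpha=config.alpha,
                               n_boot=config.n_boot, seed=seed_uvmr)

    bma_rankings, bma_models, bma_audits = {}, {}, {}
    for outcome, hset in hsets.items():
        try:
            res = MRBMA(hset, config.bma).fit(prune=True)
            bma_rankings[outcome] = res.ranking()
            bma_models[outcome] = res.top_models(10)
            bma_audits[outcome] = res.pruning_audit()
        except Exception as exc:  # isolate per-outcome stage failures
            log.warning("MR-BMA failed for %s: %s", outcome, exc)
            bma_rankings[outcome] = pd.DataFrame(columns=["mip", "mace"])
            bma_models[outcome] = pd.DataFrame(
                columns=["model", "indices", "pp", "estimates"])
            bma_audits[outcome] = [{"error": f"{type(exc).__name__}: {exc}"}]

    rcs_rows, cmp_rows = [], []
    if cohort is not None:
        case_groups = [g for g in cohort["group"].unique() if g != "healthy"]
        for case_group in case_groups:
            for trait in TRAITS[:config.n_exposures]:
                if trait not in cohort.columns:
                    continue
                try:
                    fit = RcsLogistic.from_cohort(
                        cohort, trait, case_group,
                        n_knots=config.rcs_knots).fit()
                    cr = fit.crossings()
                    rcs_rows.append({
                        "trait": trait, "outcome": case_group,
                        "reference": fit.reference_value,
                        "crossings_ci_low": ",".join(map(str, cr["ci_low"])),
                        "crossings_ci_high": ",".join(map(str, cr["ci_high"])),
                        "separation": fit.separation_flag, "error": ""})
                except Exception as exc:
                    rcs_rows.append({"trait": trait, "outcome": case_group,
                                     "reference": np.nan,
                                     "crossings_ci_low": "",
                                     "crossings_ci_high": "",
                                     "separation": False,
                                     "error": f"{type(exc).__name__}: {exc}"})
                try:
                    cmp_rows.append(group_compare(
                        cohort, trait, ("healthy", case_group)).as_dict())
                except Exception as exc:
                    cmp_rows.append({"trait": trait, "group_a": "healthy",
                                     "group_b": case_group,
                                     "error": f"{type(exc).__name__}: {exc}"})

    report = RunReport(
        selection_logs=selection_logs,
        uvmr_table=uvmr_table,
        bma_rankings=bma_rankings,
        bma_models=bma_models,
        bma_audits=bma_audits,
        rcs_crossings=pd.DataFrame(rcs_rows),
        group_comparisons=pd.DataFrame(cmp_rows),
        provenance={
            "package": "bloodmr", "version": __version__,
            "mode": config.mode, "seed": config.seed,
            "bonferroni_alpha": config.bonferroni_alpha(),
            "confounder_filter_applied": catalog is not None,
            "elapsed_s": round(time.time() - t0, 2),
        },
    )
    if config.outdir:
        report.write(config.outdir)
    return report
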