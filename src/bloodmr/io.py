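"""Plain-text readers and writers for the package's interchange formats.

Summary-statistic panels, LD matrices and cohorts travel as tab-separated
files so every pipeline stage can be run, inspected and diffed in isolation.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import LdMatrix, PANEL_COLUMNS


def write_summary_stats(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype={"SNP": str, "EA": str, "OA": str})
    missing = set(PANEL_COLUMNS[:6]) - set(panel.columns)
    if missing:
        raise ValueError(f"summary-statistics file {path} lacks columns {sorted(missing)}")
    return panel


def write_ld_matrix(ld: LdMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")


def read_ld_matrix(path) -> LdMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LdMatrix(list(df.index), df.to_numpy(dtype=float))


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_confounder_catalog(catalog: dict, path) -> None:
    serialisable = {snp: [[str(p), float(v)] for p, v in entries]
                    for snp, entries in catalog.items()}
    Path(path).write_text(json.dumps(serialisable, indent=1, sort_keys=True))


def read_confounder_catalog(path) -> dict:
    raw = json.loads(Path(path).read_text())
    return {snp: [(p, float(v)) for p, v in entries] for snp, entries in raw.items()}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_default))


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
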