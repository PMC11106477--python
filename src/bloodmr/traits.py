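"""Blood-cell trait definitions shared across the package.

The 15 complete-blood-count (CBC) traits studied here, their reporting
units, and reference distributions for a healthy adult population used by
the cohort simulator. Reference means/SDs are mid-range values for healthy
adults; they parameterise lognormal draws, so all simulated counts are
strictly positive.
"""
from __future__ import annotations

#: Canonical trait order used everywhere (matrices, panels, reports).
TRAITS = [
    "RBC", "HGB", "HCT", "MCV", "MCH", "MCHC", "RDW",
    "WBC", "NEU", "LYM", "MON", "BAS", "EOS", "PLT", "MPV",
]

UNITS = {
    "RBC": "10^12/L", "HGB": "g/L", "HCT": "%", "MCV": "fL", "MCH": "pg",
    "MCHC": "g/L", "RDW": "%", "WBC": "10^9/L", "NEU": "10^9/L",
    "LYM": "10^9/L", "MON": "10^9/L", "BAS": "10^9/L", "EOS": "10^9/L",
    "PLT": "10^9/L", "MPV": "fL",
}

#: (mean, SD) of each trait in a healthy adult reference population.
HEALTHY_REFERENCE = {
    "RBC": (4.7, 0.4),
    "HGB": (140.0, 12.0),
    "HCT": (42.0, 3.5),
    "MCV": (90.0, 5.0),
    "MCH": (30.0, 2.0),
    "MCHC": (335.0, 8.0),
    "RDW": (13.0, 0.8),
    "WBC": (6.5, 1.5),
    "NEU": (3.8, 1.2),
    "LYM": (2.0, 0.5),
    "MON": (0.5, 0.15),
    "BAS": (0.04, 0.02),
    "EOS": (0.15, 0.08),
    "PLT": (250.0, 55.0),
    "MPV": (10.0, 0.9),
}

# Default disease-group location shifts, in units of the healthy log-scale SD.
# Directions follow the clinical picture of active inflammatory bowel
# disease: anaemia of chronic disease (low HGB/HCT and red-cell indices),
# reactive thrombocytosis and neutrophilia, raised RDW and monocytes;
# lymphopenia in Crohn's disease and eosinophilia in ulcerative colitis.
_CD_SHIFTS = {
    "RDW": +0.8, "NEU": +0.8, "MON": +0.8, "PLT": +0.8,
    "HGB": -0.8, "HCT": -0.8, "MCH": -0.8, "MCV": -0.8, "MCHC": -0.8,
    "LYM": -0.8, "MPV": -0.8,
}
_UC_SHIFTS = {
    "RDW": +0.8, "WBC": +0.8, "NEU": +0.8, "MON": +0.8, "EOS": +0.8,
    "HGB": -0.8, "MCH": -0.8, "MCV": -0.8, "MCHC": -0.8, "MPV": -0.8,
}

#: group -> trait -> (shift in healthy-SD units on the log scale, SD scale).
DEFAULT_GROUP_SHIFTS = {
    "healthy": {t: (0.0, 1.0) for t in TRAITS},
    "CD": {t: (_CD_SHIFTS.get(t, 0.0), 1.0) for t in TRAITS},
    "UC": {t: (_UC_SHIFTS.get(t, 0.0), 1.0) for t in TRAITS},
}

#: Outcome GWAS case/control sizes (IIBDGC summary statistics).
OUTCOME_STUDIES = {
    "CD": {"cases": 5956, "controls": 14927},
    "UC": {"cases": 6968, "controls": 20464},
}

#: Exposure GWAS sample size (Blood Cell Consortium phase 2).
EXPOSURE_STUDY_N = 563_085
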