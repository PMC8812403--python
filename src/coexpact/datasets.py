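"""Packaged reference fixtures.

Small plain-text fixtures shipped with the package:

* ``cohort_clinical.csv`` — a 27-patient clinical table (age, sex, disease
  duration, ESR, hs-CRP, IL-6, TNF-a, prednisone dose) with treatment and
  activity grouping.  Missing entries are encoded verbatim as an en-dash
  and parsed to NaN.  The ``table_header`` column preserves the original
  block headers (whose parenthetical counts are internally inconsistent
  with the listed patients); grouping in this package always follows the
  listed-order partition stored in ``activity``.
* ``closeness_components.csv`` — per-gene component counts of the
  three-metric TLR-closeness score for two conditions and two correlation
  methods.
* ``cluster_memberships.json`` — enumerated gene lists of the two largest
  cut-height clusters per condition (HGNC-style symbols).
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

MISSING_MARKER = "–"  # en-dash used for absent measurements

#: clinical covariate columns of the cohort fixture
CLINICAL_COLUMNS = [
    "age_years",
    "duration_months",
    "esr_mm_h",
    "hscrp_mg_l",
    "il6_pg_ml",
    "tnfa_pg_ml",
    "prednisone_mg_d",
]


def _data_path(name: str):
    return resources.files("coexpact.data").joinpath(name)


def load_cohort_clinical() -> pd.DataFrame:
    """Load the packaged 27-patient clinical table.

    Returns a DataFrame with one row per patient; numeric covariates are
    floats with NaN for missing entries.
    """
    with _data_path("cohort_clinical.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, na_values=[MISSING_MARKER])
    for col in CLINICAL_COLUMNS:
        df[col] = pd.to_numeric(df[col])
    return df


def load_closeness_components() -> pd.DataFrame:
    """Load per-gene closeness component counts (method x condition x gene)."""
    with _data_path("closeness_components.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_cluster_memberships() -> dict:
    """Load the enumerated cut-height cluster gene lists per condition."""
    with _data_path("cluster_memberships.json").open("r", encoding="utf-8") as fh:
        return json.load(fh)


def treated_subgroups(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the treated patients into the inactive / active subgroups.

    Uses the listed-order partition (patients 1-9 vs 10-20), which is
    invariant to the inconsistent header counts of the source table.
    """
    treated = df[df["condition"] == "treated"]
    return (
        treated[treated["activity"] == "inactive"],
        treated[treated["activity"] == "active"],
    )
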