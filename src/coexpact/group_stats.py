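"""Group-comparison statistics.

Mann-Whitney (default: normal approximation with tie and continuity
corrections), Pearson chi-square without continuity correction, one-sample
Kolmogorov-Smirnov normality screening against the fitted normal, and a
per-gene differential-expression wrapper.  Raw p-values throughout; an
optional Benjamini-Hochberg switch exists on the expression contrast only.

Missing values are dropped listwise within each single test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    ties: bool = False
    continuity: bool = False
    note: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise DataError("p-value outside [0,1]")


def _clean(values) -> np.ndarray:
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    return arr


def mann_whitney(a, b, mode: str = "asymptotic") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode="asymptotic"`` (default) uses the normal approximation with tie
    correction and continuity correction; ``mode="exact"`` enumerates the
    exact null distribution (valid without ties).  NAs are dropped per
    group.
    """
    a, b = _clean(a), _clean(b)
    if len(a) == 0 or len(b) == 0:
        raise DataError("a group is empty after NA removal")
    if mode not in ("asymptotic", "exact"):
        raise DataError(f"unknown mode {mode!r}")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=mode,
                             use_continuity=True)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n=(len(a), len(b)), method=f"mann-whitney-{mode}", ties=has_ties,
        continuity=(mode == "asymptotic"),
        note="exact p invalid under ties" if mode == "exact" and has_ties else "",
    )


def chi_square(table) -> TestResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise DataError("expected a 2x2 table")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise DataError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DataError("zero margin in the 2x2 table")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p),
                      n=(int(t[0].sum()), int(t[1].sum())),
                      method="chi-square", continuity=False)


def ks_normality(values) -> TestResult:
    """One-sample KS test against a normal with the sample mean/SD.

    The null parameters are estimated from the same data, so the nominal
    KS p is anti-conservative (Lilliefors caveat, recorded in the note).
    Use as a screening statistic, as in typical clinical-table workflows.
    """
    v = _clean(values)
    if len(v) < 5:
        raise DataError("KS normality screening needs >= 5 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DataError("constant input")
    res = stats.kstest(v, "norm", args=(v.mean(), sd))
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=(len(v),), method="ks-normality",
                      note="null parameters estimated from sample "
                           "(Lilliefors caveat)")


def differential_expression(expr: pd.DataFrame, samples: pd.DataFrame,
                            contrast: tuple[str, str],
                            group_col: str = "group",
                            adjust: bool = False) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney between two sample groups.

    ``contrast = (reference_group, comparison_group)``.  Returns per gene:
    U, raw p, group means, log2 fold (comparison/reference) and direction.
    No multiple-testing correction by default; ``adjust=True`` adds a
    Benjamini-Hochberg column.
    """
    for grp in contrast:
        if not (samples[group_col] == grp).any():
            raise DataError(f"contrast group {grp!r} absent from metadata")
    ids_a = samples.loc[samples[group_col] == contrast[0], "sample_id"]
    ids_b = samples.loc[samples[group_col] == contrast[1], "sample_id"]
    rows = []
    for gene in expr.index:
        a = expr.loc[gene, ids_a]
        b = expr.loc[gene, ids_b]
        res = mann_whitney(a, b)
        mean_a, mean_b = float(np.nanmean(a)), float(np.nanmean(b))
        with np.errstate(divide="ignore", invalid="ignore"):
            l2fc = float(np.log2(mean_b / mean_a))
        rows.append({
            "gene": gene, "statistic": res.statistic, "p_value": res.p_value,
            f"mean_{contrast[0]}": mean_a, f"mean_{contrast[1]}": mean_b,
            "log2_fold": l2fc, "direction": "up" if mean_b >= mean_a else "down",
            "n_a": res.n[0], "n_b": res.n[1],
        })
    out = pd.DataFrame(rows).set_index("gene")
    if adjust:
        from statsmodels.stats.multitest import multipletests
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def compare_clinical(table: pd.DataFrame, group_col: str, variables: list[str],
                     groups: tuple[str, str] | None = None) -> pd.DataFrame:
    """Mann-Whitney per continuous variable between two groups of a table."""
    if groups is None:
        uniq = table[group_col].dropna().unique()
        if len(uniq) != 2:
            raise DataError("need exactly two groups or an explicit pair")
        groups = tuple(uniq)
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    rows = []
    for var in variables:
        res = mann_whitney(a[var], b[var])
        rows.append({"variable": var, "statistic": res.statistic,
                     "p_value": res.p_value, "n_a": res.n[0], "n_b": res.n[1],
                     "method": res.method})
    return pd.DataFrame(rows).set_index("variable")
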