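"""Reference-gene stability and relative quantification for qPCR panels.

Implements the three classic stability measures on candidate reference
genes — pairwise-variation M (geNorm), the intra/intergroup variance
decomposition (NormFinder), and descriptive SD/CV plus index correlation
(BestKeeper) — an aggregate reference-pair selection rule, and plain
``2**-ddCq`` relative quantification with a fixed amplification efficiency
of 2 (no efficiency correction).

All stability computations operate on the Cq (log2-expression) scale:
the log2 ratio of expression of genes j and k in a sample equals
``Cq_k - Cq_j`` up to a per-gene constant, so per-gene constants (e.g.
abundance offsets) never affect the measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


# ---------------------------------------------------------------------------
# geNorm


@dataclass
class GenormResult:
    m_values: pd.Series            # full-panel M per gene
    exclusion_order: list[str]     # iteratively excluded worst genes
    final_pair: tuple[str, str]    # last two genes standing


def _genorm_m(cq: pd.DataFrame) -> pd.Series:
    genes = list(cq.index)
    m = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            diff = cq.loc[j] - cq.loc[k]   # = log2 ratio up to constants
            diff = diff.dropna()
            if len(diff) < 2:
                raise DataError(f"pair {j}/{k} has <2 complete samples")
            sds.append(diff.std(ddof=1))
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="genorm_m")


def genorm_stability(cq: pd.DataFrame) -> GenormResult:
    """Pairwise-variation stability M with stepwise worst-gene exclusion.

    M_j is the mean over partner genes k of the SD across samples of the
    log2 expression ratio j/k.  Lower M = more stable.  Requires >= 3
    candidate genes and >= 2 samples; genes entirely missing are rejected.
    """
    if cq.shape[0] < 3:
        raise DataError("geNorm needs >= 3 candidate genes")
    if cq.shape[1] < 2:
        raise DataError("geNorm needs >= 2 samples")
    if cq.isna().all(axis=1).any():
        bad = cq.index[cq.isna().all(axis=1)].tolist()
        raise DataError(f"gene(s) entirely missing: {bad}")

    full_m = _genorm_m(cq)
    remaining = cq.copy()
    order: list[str] = []
    while remaining.shape[0] > 2:
        m = _genorm_m(remaining)
        worst = m.sort_values(ascending=False, kind="stable").index[0]
        # deterministic tie rule: highest M, then reverse-lexicographic name
        ties = m.index[m == m[worst]]
        worst = sorted(ties)[-1]
        order.append(worst)
        remaining = remaining.drop(index=worst)
    pair = tuple(sorted(remaining.index))
    return GenormResult(m_values=full_m, exclusion_order=order, final_pair=pair)


# ---------------------------------------------------------------------------
# NormFinder


@dataclass
class NormfinderResult:
    stability: pd.Series
    intragroup_only: bool          # True when the single-group fallback ran


def normfinder_stability(cq: pd.DataFrame,
                         groups: pd.Series | list) -> NormfinderResult:
    """Model-based stability combining intergroup bias and intragroup variance.

    Follows the published variance-decomposition estimators: per gene and
    group, an unbiased intragroup variance from two-way (gene x sample)
    residuals; per gene, a shrunken intergroup deviation; stability is the
    group-averaged ``|d| + sqrt(var/n)``.  Lower = more stable.

    With a single group the intergroup term is undefined; the result falls
    back to the intragroup-only variant and flags it.
    """
    groups = pd.Series(list(groups), index=cq.columns)
    if cq.shape[0] < 3:
        raise DataError("NormFinder needs >= 3 candidate genes")
    labels = groups.unique().tolist()
    for g in labels:
        if (groups == g).sum() < 2:
            raise DataError(f"group {g!r} has < 2 samples")
    if cq.isna().any().any():
        raise DataError("NormFinder requires complete Cq data")

    k = cq.shape[0]
    z = cq.to_numpy(dtype=float)

    # intragroup variances (unbiased for the two-way residual contraction)
    sigma2 = np.zeros((k, len(labels)))
    n_g = np.zeros(len(labels), dtype=int)
    d = np.zeros((k, len(labels)))
    gene_mean = z.mean(axis=1)
    grand = z.mean()
    for gi, g in enumerate(labels):
        cols = (groups == g).to_numpy()
        zg = z[:, cols]
        n = zg.shape[1]
        n_g[gi] = n
        r = zg - zg.mean(axis=1, keepdims=True) - zg.mean(axis=0, keepdims=True) + zg.mean()
        v = (r ** 2).sum(axis=1) / (n - 1)
        s = v.sum() / (1.0 - 1.0 / k)
        sigma2[:, gi] = np.clip((v - s / k ** 2) / (1.0 - 2.0 / k), 0.0, None)
        d[:, gi] = zg.mean(axis=1) - gene_mean - (zg.mean() - grand)

    if len(labels) == 1:
        stab = pd.Series(np.sqrt(sigma2[:, 0]), index=cq.index,
                         name="normfinder_stability")
        return NormfinderResult(stability=stab, intragroup_only=True)

    samp_var = sigma2 / n_g            # sampling variance of each d estimate
    gamma2 = max(0.0, (d ** 2).sum() / ((k - 1) * (len(labels) - 1))
                 - samp_var.mean())
    denom = gamma2 + samp_var
    with np.errstate(invalid="ignore", divide="ignore"):
        d_shrunk = np.where(denom > 0, d * gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
    stab_vals = (np.abs(d_shrunk) + np.sqrt(samp_var)).mean(axis=1)
    stab = pd.Series(stab_vals, index=cq.index, name="normfinder_stability")
    return NormfinderResult(stability=stab, intragroup_only=False)


# ---------------------------------------------------------------------------
# BestKeeper

SD_ADVISORY_THRESHOLD = 1.0  # cycles; conventional inconsistency cutoff


def bestkeeper_stats(cq: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-gene SD/CV and correlation with the BestKeeper index.

    The index is the per-sample geometric-mean-equivalent of candidate Cq
    (arithmetic mean of Cq, since Cq is already log-scale).  Zero-variance
    genes get an undefined (NaN) index correlation.
    """
    if cq.shape[0] < 2:
        raise DataError("BestKeeper needs >= 2 candidate genes")
    index = cq.mean(axis=0)
    rows = []
    for gene in cq.index:
        row = cq.loc[gene]
        ok = row.notna() & index.notna()
        sd = float(row[ok].std(ddof=1))
        cv = float(100.0 * sd / row[ok].mean())
        if sd == 0 or index[ok].std(ddof=1) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(row[ok], index[ok])
        rows.append({"gene": gene, "bestkeeper_sd": sd, "bestkeeper_cv": cv,
                     "bestkeeper_r": r, "bestkeeper_p": p,
                     "sd_above_advisory": sd > SD_ADVISORY_THRESHOLD})
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# aggregate report and reference selection


def stability_report(cq: pd.DataFrame,
                     groups: pd.Series | list | None = None) -> pd.DataFrame:
    """Run all three stability methods and derive an aggregate rank.

    Aggregate rank = mean of the three per-method ranks (geNorm M,
    NormFinder stability, BestKeeper SD; all ascending = better), converted
    to a 1..n permutation with ties broken by geNorm M, then gene name.
    """
    gen = genorm_stability(cq)
    if groups is None:
        nf = normfinder_stability(cq, ["all"] * cq.shape[1])
    else:
        nf = normfinder_stability(cq, groups)
    bk = bestkeeper_stats(cq)

    report = pd.DataFrame({
        "genorm_m": gen.m_values,
        "normfinder_stability": nf.stability,
        "bestkeeper_sd": bk["bestkeeper_sd"],
        "bestkeeper_r": bk["bestkeeper_r"],
    })
    mean_rank = (
        report["genorm_m"].rank() + report["normfinder_stability"].rank()
        + report["bestkeeper_sd"].rank()
    ) / 3.0
    order = sorted(report.index,
                   key=lambda g: (mean_rank[g], report.loc[g, "genorm_m"], g))
    report["aggregate_rank"] = pd.Series(
        {g: i + 1 for i, g in enumerate(order)})
    report.attrs["normfinder_intragroup_only"] = nf.intragroup_only
    return report


def select_reference_pair(report: pd.DataFrame) -> tuple[str, str]:
    """The two candidates with best aggregate rank.

    Ties were already resolved deterministically (geNorm M, then
    lexicographic gene name) when the 1..n aggregate rank was assigned.
    """
    if report.shape[0] < 3:
        raise DataError("need a stability report over >= 3 candidates")
    ordered = report["aggregate_rank"].sort_values().index
    return tuple(sorted(ordered[:2]))


# ---------------------------------------------------------------------------
# relative quantification


def relative_expression(cq: pd.DataFrame, targets: list[str],
                        reference_pair: tuple[str, str],
                        calibrator_samples: list[str]) -> pd.DataFrame:
    """Relative expression ``2**-ddCq`` of target genes.

    dCq = Cq_target - mean(Cq of the two reference genes);
    ddCq = dCq - mean dCq over the calibrator samples (per gene);
    value = 2**-ddCq.  Samples missing a reference Cq get all-NA values
    with a warning.  Output carries the references and calibrator in
    ``DataFrame.attrs``.
    """
    for ref in reference_pair:
        if ref not in cq.index:
            raise DataError(f"reference gene {ref!r} absent from Cq matrix")
    if not calibrator_samples:
        raise DataError("calibrator sample set is empty")
    missing_t = [t for t in targets if t not in cq.index]
    if missing_t:
        raise DataError(f"target gene(s) absent: {missing_t}")

    ref_cq = cq.loc[list(reference_pair)].mean(axis=0, skipna=False)
    bad = ref_cq.index[ref_cq.isna()].tolist()
    if bad:
        warnings.warn(
            f"missing reference Cq; samples set to NA: {bad}", stacklevel=2)
    dcq = cq.loc[targets].sub(ref_cq, axis=1)
    calib_mean = dcq[calibrator_samples].mean(axis=1)
    ddcq = dcq.sub(calib_mean, axis=0)
    expr = np.power(2.0, -ddcq)
    expr.attrs["reference_genes"] = tuple(sorted(reference_pair))
    expr.attrs["calibrator_samples"] = list(calibrator_samples)
    return expr


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
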