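"""Regression-residual disease-activity scoring.

Highly co-expressed gene pairs of a reference (fit) group define
least-squares lines; each patient's departure from a line is the relative
error M = |(y_pred - y_obs) / y_obs|.  Per-pair Youden thresholds turn
M-values into binary scores (1 = reference-group-like, M below threshold),
summed into a total score whose own Youden threshold classifies patients.
ROC metrics use the rank-probability AUC (ties count 1/2), which equals
the normalized Mann-Whitney U.

Thresholds are strict Youden maximizers (ties: higher sensitivity, then
lower threshold) evaluated in-sample; a manual override hook exists
because published thresholds are occasionally hand-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import CorrelationResult
from .errors import DataError


@dataclass
class PairModel:
    """OLS line y = slope*x + intercept for a gene pair, fit on one group."""

    x_gene: str
    y_gene: str
    slope: float
    intercept: float
    fit_group: str
    r: float
    p: float
    n_fit: int

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass
class MValueRecord:
    sample_id: str
    pair: tuple[str, str]          # (x_gene, y_gene)
    y_predicted: float
    y_observed: float

    @property
    def absolute_error(self) -> float:
        return abs(self.y_predicted - self.y_observed)

    @property
    def m(self) -> float:
        return self.absolute_error / abs(self.y_observed)


@dataclass
class RocSummary:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


# ---------------------------------------------------------------------------
# pair selection and regression


def select_pairs(correlations: list[CorrelationResult], r_min: float = 0.73,
                 alpha: float = 0.01) -> list[tuple[str, str]]:
    """Pairs with ``|r| > r_min`` and ``p < alpha``, ordered by |r| desc."""
    kept = [c for c in correlations
            if not np.isnan(c.r) and abs(c.r) > r_min and c.p < alpha]
    kept.sort(key=lambda c: (-abs(c.r), c.pair))
    return [c.pair for c in kept]


def fit_pair_regression(expr: pd.DataFrame, pair: tuple[str, str],
                        fit_samples: list[str],
                        fit_group: str = "") -> PairModel:
    """Ordinary least squares of the second-named gene on the first.

    The pair is read as (x_gene, y_gene): the model relates the second
    gene's level to the first's.  Needs >= 3 complete observations and
    non-degenerate x.
    """
    x_gene, y_gene = pair
    x = expr.loc[x_gene, fit_samples].astype(float)
    y = expr.loc[y_gene, fit_samples].astype(float)
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    if len(x) < 3:
        raise DataError(f"pair {pair}: <3 complete observations in fit group")
    if np.var(x) == 0:
        raise DataError(f"pair {pair}: zero variance in x gene {x_gene!r}")
    slope, intercept = np.polyfit(x, y, 1)
    r, p = stats.pearsonr(x, y)
    return PairModel(x_gene=x_gene, y_gene=y_gene, slope=float(slope),
                     intercept=float(intercept), fit_group=fit_group,
                     r=float(r), p=float(p), n_fit=len(x))


def m_value(model: PairModel, expr: pd.DataFrame,
            sample: str) -> MValueRecord | None:
    """Relative-error record for one sample; None (with warning) if y = 0."""
    x_obs = expr.loc[model.x_gene, sample]
    y_obs = expr.loc[model.y_gene, sample]
    if np.isnan(x_obs) or np.isnan(y_obs):
        raise DataError(f"sample {sample!r} missing {model.x_gene}/"
                        f"{model.y_gene} expression")
    if y_obs == 0:
        warnings.warn(f"observed y = 0 for sample {sample!r}; M undefined",
                      stacklevel=2)
        return None
    return MValueRecord(sample_id=sample, pair=(model.x_gene, model.y_gene),
                        y_predicted=model.predict(float(x_obs)),
                        y_observed=float(y_obs))


def m_values(model: PairModel, expr: pd.DataFrame,
             samples: list[str]) -> pd.Series:
    """M-values for many samples (NaN where expression is missing/zero)."""
    out = {}
    for s in samples:
        x_obs = expr.loc[model.x_gene, s]
        y_obs = expr.loc[model.y_gene, s]
        if np.isnan(x_obs) or np.isnan(y_obs) or y_obs == 0:
            out[s] = np.nan
        else:
            out[s] = abs(model.predict(float(x_obs)) - float(y_obs)) / abs(y_obs)
    return pd.Series(out, name=f"M[{model.x_gene}->{model.y_gene}]")


# ---------------------------------------------------------------------------
# thresholds and ROC


def _as_binary(labels, positive) -> np.ndarray:
    y = np.asarray([1 if v == positive else 0 for v in labels])
    if y.all() or not y.any():
        raise DataError("both classes must be present")
    return y


def _confusion(scores: np.ndarray, y: np.ndarray, threshold: float,
               direction: str) -> tuple[float, float, float, float]:
    if direction == "greater":
        pred = scores > threshold
    elif direction == "less":
        pred = scores < threshold
    else:
        raise DataError(f"unknown direction {direction!r}")
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return sens, spec, ppv, npv


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.array([])
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def youden_threshold(scores, labels, positive,
                     direction: str = "greater"
                     ) -> tuple[float, float, RocSummary]:
    """Threshold maximizing Youden's J over all cutpoint midpoints.

    ``direction="greater"`` calls a sample positive when its score exceeds
    the threshold.  Ties on J prefer higher sensitivity, then the lower
    threshold.  Returns (threshold, J, summary-at-threshold).
    """
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise DataError("NaN scores not allowed in threshold search")
    y = _as_binary(labels, positive)
    best = None
    for thr in _candidate_thresholds(scores):
        sens, spec, ppv, npv = _confusion(scores, y, thr, direction)
        j = sens + spec - 1.0
        key = (-j, -sens, thr)
        if best is None or key < best[0]:
            best = (key, thr, j, (sens, spec, ppv, npv))
    _, thr, j, (sens, spec, ppv, npv) = best
    summary = RocSummary(auc=roc_auc(scores, labels, positive, direction),
                         threshold=thr, sensitivity=sens, specificity=spec,
                         ppv=ppv, npv=npv)
    return thr, j, summary


def roc_auc(scores, labels, positive, direction: str = "greater") -> float:
    """Rank-probability AUC with ties counting 1/2 (= U / (n1*n2))."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels, positive)
    if direction == "less":
        scores = -scores
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (len(pos) * len(neg)))


def roc_summary(scores, labels, positive, direction: str = "greater",
                threshold: float | None = None) -> RocSummary:
    """AUC plus confusion metrics at a supplied (or Youden) threshold."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels, positive)
    if threshold is None:
        _, _, summary = youden_threshold(scores, labels, positive, direction)
        return summary
    sens, spec, ppv, npv = _confusion(scores, y, threshold, direction)
    return RocSummary(auc=roc_auc(scores, labels, positive, direction),
                      threshold=threshold, sensitivity=sens, specificity=spec,
                      ppv=ppv, npv=npv)


# ---------------------------------------------------------------------------
# combined scoring


@dataclass
class ScoreCard:
    """Per-sample per-pair binary scores and the summed total.

    ``scores`` is a samples x pairs frame of {0, 1, NaN}; totals sum the
    available pairs per sample (missing pairs flagged via n_available).
    """

    scores: pd.DataFrame
    pair_thresholds: dict[tuple[str, str], float]
    total_threshold: float | None = None

    @property
    def total(self) -> pd.Series:
        return self.scores.sum(axis=1, skipna=True)

    @property
    def n_available(self) -> pd.Series:
        return self.scores.notna().sum(axis=1)

    def classify(self, total_threshold: float | None = None) -> pd.Series:
        """'inactive' when total >= threshold (reference-group-like)."""
        thr = total_threshold if total_threshold is not None \
            else self.total_threshold
        if thr is None:
            raise DataError("no total threshold set")
        return pd.Series(
            np.where(self.total >= thr, "inactive", "active"),
            index=self.scores.index)


def combined_score(models: list[PairModel],
                   pair_thresholds: dict[tuple[str, str], float],
                   expr: pd.DataFrame, samples: list[str],
                   total_threshold: float | None = None) -> ScoreCard:
    """Per-pair score 1 when M < pair threshold; totals over available pairs."""
    if not models:
        raise DataError("no fitted pair models")
    columns = {}
    for model in models:
        pair = (model.x_gene, model.y_gene)
        if pair not in pair_thresholds:
            raise DataError(f"no threshold for pair {pair}")
        m = m_values(model, expr, samples)
        scored = pd.Series(np.where(m.isna(), np.nan,
                                    (m < pair_thresholds[pair]).astype(float)),
                           index=m.index)
        if scored.isna().any():
            warnings.warn(
                f"pair {pair} skipped for samples "
                f"{list(scored.index[scored.isna()])}", stacklevel=2)
        columns[pair] = scored
    scores = pd.DataFrame(columns)
    return ScoreCard(scores=scores, pair_thresholds=dict(pair_thresholds),
                     total_threshold=total_threshold)
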