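"""Synthetic cohort generation.

Generates complete synthetic study inputs — Cq tables, sample metadata,
clinical covariates, and miRNA target maps — with the statistical structure
the downstream analyses assume: two functional gene blocks with positive
within-block correlation, a per-condition between-block correlation (strongly
negative in one condition by default), candidate reference genes of
controlled stability, and clinical covariates with configurable
per-condition distributions.

Correlations are induced on the dCq (log-expression) scale.  Pearson
correlation of the derived ``2**-ddCq`` values is then monotone-related and
Spearman correlation is invariant, so downstream analyses see the planted
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .mirna_network import MirnaTargetMap

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# defaults

#: default block of pattern-recognition / NF-kB axis genes
DEFAULT_BLOCK_A = [
    "TLR1", "TLR2", "TLR4", "TLR6", "TLR8", "BCL6", "TIGIT", "NR4A1",
    "IkBa", "P50", "TNF", "CD83", "PD-1", "PD-L1", "TIM3",
]
#: default block of T-cell activation / differentiation genes
DEFAULT_BLOCK_B = [
    "TCR", "CD28", "T-bet", "GATA3", "FOXP3", "CCL5", "CD3", "CD40L",
    "CTLA4", "PD-L2",
]
#: panel genes assigned to neither block (drawn independently)
DEFAULT_INDEPENDENT = ["CD40", "LAG3", "P65", "RORC"]

DEFAULT_GROUP_SIZES = {
    "HC": 10,
    "untreated-inactive": 3,
    "untreated-active": 4,
    "treated-inactive": 9,
    "treated-active": 11,
}

DEFAULT_WITHIN_R = {
    "HC": 0.5,
    "untreated-inactive": 0.5,
    "untreated-active": 0.5,
    # the strongly anti-correlated condition needs tight blocks to keep the
    # implied correlation matrix positive semi-definite without repair
    "treated-inactive": 0.9,
    "treated-active": 0.75,
}

DEFAULT_BETWEEN_R = {
    "HC": 0.0,
    "untreated-inactive": 0.0,
    "untreated-active": 0.0,
    "treated-inactive": -0.85,
    "treated-active": 0.4,
}

#: "block": constant within-block correlation (tight co-expression modules);
#: "serial": correlation decays with within-block gene distance
#: (``r ** |i-j|``), yielding the sparse, chain-like networks typical of
#: control groups
DEFAULT_CORRELATION_STYLE = {
    "HC": "serial",
    "untreated-inactive": "serial",
    "untreated-active": "serial",
    "treated-inactive": "block",
    "treated-active": "block",
}

#: candidate reference genes with their per-sample Cq standard deviations
DEFAULT_REFERENCES = [
    ("ACTB", 0.60), ("GUSB", 0.80), ("B2M", 0.10), ("GAPDH", 0.70),
    ("HPRT1", 0.25), ("PGK1", 0.45), ("RPL13A", 0.55), ("SDHA", 0.30),
    ("YWHAZ", 0.15),
]

ACTIVE_CONDITIONS = frozenset({"untreated-active", "treated-active"})
INACTIVE_CONDITIONS = frozenset({"untreated-inactive", "treated-inactive"})


def _default_clinical_spec() -> dict:
    """Per-covariate, per-condition sampling distributions.

    Keys are covariate column names; values map condition (or ``"*"`` as a
    fallback) to a ``{"dist": ..., **params}`` mapping.
    """
    return {
        "age_years": {"*": {"dist": "normal", "mean": 37.0, "sd": 9.0,
                            "low": 18.0, "round": 0}},
        "duration_months": {
            "HC": {"dist": "na"},
            "*": {"dist": "lognormal", "mu": 3.5, "sigma": 1.3, "round": 0},
        },
        "esr_mm_h": {
            "HC": {"dist": "lognormal", "mu": 2.0, "sigma": 0.5, "round": 0},
            "untreated-active": {"dist": "lognormal", "mu": 4.3, "sigma": 0.5,
                                 "round": 0},
            "*": {"dist": "lognormal", "mu": 2.5, "sigma": 0.6, "round": 0},
        },
        "hscrp_mg_l": {
            "HC": {"dist": "lognormal", "mu": -1.0, "sigma": 1.0},
            "untreated-active": {"dist": "lognormal", "mu": 4.0, "sigma": 1.0},
            "treated-active": {"dist": "lognormal", "mu": 1.2, "sigma": 1.2},
            "*": {"dist": "lognormal", "mu": -0.3, "sigma": 1.0},
        },
        "il6_pg_ml": {
            "untreated-active": {"dist": "lognormal", "mu": 2.2, "sigma": 0.8},
            "*": {"dist": "lognormal", "mu": 0.9, "sigma": 0.5},
        },
        "tnfa_pg_ml": {"*": {"dist": "lognormal", "mu": 1.8, "sigma": 0.4}},
        "prednisone_mg_d": {
            "HC": {"dist": "na"},
            "untreated-inactive": {"dist": "constant", "value": 0.0},
            "untreated-active": {"dist": "constant", "value": 0.0},
            "*": {"dist": "lognormal", "mu": 2.5, "sigma": 0.8, "round": 1},
        },
        "sex": {
            "HC": {"dist": "choice", "values": ["F", "M"], "p": [0.8, 0.2]},
            "*": {"dist": "choice", "values": ["F", "M"], "p": [0.9, 0.1]},
        },
    }


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CohortConfig:
    """Configuration for a synthetic cohort.

    ``within_block_r`` and ``between_block_r`` may be scalars (applied to
    every condition) or per-condition mappings.  Correlation matrices implied
    by the block structure are repaired by eigenvalue clipping when not
    positive semi-definite; a repair that moves any pairwise correlation by
    more than ``max_repair_delta`` rejects the config.
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    gene_blocks: dict = field(default_factory=lambda: {
        "block_a": list(DEFAULT_BLOCK_A), "block_b": list(DEFAULT_BLOCK_B)})
    independent_genes: list = field(
        default_factory=lambda: list(DEFAULT_INDEPENDENT))
    within_block_r: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WITHIN_R))
    between_block_r: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_R))
    correlation_style: str | Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATION_STYLE))
    signal_sd: float = 2.0     # dCq-scale SD of the correlated signal, cycles
    noise_sd: float = 0.25     # independent technical noise added to Cq
    baseline_cq: float = 22.0  # arbitrary but fixed for reproducibility
    reference_gene_spec: list = field(
        default_factory=lambda: list(DEFAULT_REFERENCES))
    clinical_spec: dict = field(default_factory=_default_clinical_spec)
    missing_rate: float = 0.0
    max_repair_delta: float = 0.1
    seed: int = 0

    def __post_init__(self):
        # normalize YAML round-trips (lists -> tuples)
        self.reference_gene_spec = [
            (str(name), float(sd)) for name, sd in self.reference_gene_spec]
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for cond, n in self.group_sizes.items():
            if n < 2:
                raise ConfigError(f"group size for {cond!r} must be >= 2")
        seen: set[str] = set()
        for name, genes in self.gene_blocks.items():
            if not genes:
                raise ConfigError(f"gene block {name!r} is empty")
            overlap = seen.intersection(genes)
            if overlap:
                raise ConfigError(f"gene blocks overlap: {sorted(overlap)}")
            seen.update(genes)
        if seen.intersection(self.independent_genes):
            raise ConfigError("independent genes overlap a block")
        for cond in self.group_sizes:
            w = self.within_r(cond)
            b = self.between_r(cond)
            if not 0.0 <= w <= 1.0:
                raise ConfigError(f"within_block_r for {cond!r} not in [0,1]")
            if not -1.0 <= b <= 1.0:
                raise ConfigError(f"between_block_r for {cond!r} not in [-1,1]")
        if self.noise_sd < 0 or self.signal_sd <= 0:
            raise ConfigError("signal_sd must be > 0 and noise_sd >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate not in [0,1]")

    # -- accessors ---------------------------------------------------------
    def within_r(self, condition: str) -> float:
        if isinstance(self.within_block_r, Mapping):
            return float(self.within_block_r.get(condition, 0.5))
        return float(self.within_block_r)

    def between_r(self, condition: str) -> float:
        if isinstance(self.between_block_r, Mapping):
            return float(self.between_block_r.get(condition, 0.0))
        return float(self.between_block_r)

    def style(self, condition: str) -> str:
        if isinstance(self.correlation_style, Mapping):
            s = self.correlation_style.get(condition, "block")
        else:
            s = self.correlation_style
        if s not in ("block", "serial"):
            raise ConfigError(f"unknown correlation style {s!r}")
        return s

    @property
    def target_genes(self) -> list[str]:
        genes: list[str] = []
        for block in self.gene_blocks.values():
            genes.extend(block)
        genes.extend(self.independent_genes)
        return genes

    @property
    def reference_genes(self) -> list[str]:
        return [name for name, _ in self.reference_gene_spec]

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


# ---------------------------------------------------------------------------
# correlation matrix assembly


def condition_correlation(config: CohortConfig, condition: str) -> pd.DataFrame:
    """Target-gene correlation matrix implied by the block structure.

    Within each named block the off-diagonal is ``within_block_r``; between
    the first two blocks it is the condition's ``between_block_r``; any
    additional blocks and all independent genes are uncorrelated with
    everything else.  The matrix is PSD-repaired by eigenvalue clipping if
    needed (logged); the config is rejected if the repair moves any entry by
    more than ``config.max_repair_delta``.
    """
    genes = config.target_genes
    n = len(genes)
    corr = np.eye(n)
    index = {g: i for i, g in enumerate(genes)}
    blocks = list(config.gene_blocks.values())
    w = config.within_r(condition)
    style = config.style(condition)
    for block in blocks:
        idx = [index[g] for g in block]
        for pos_a, a in enumerate(idx):
            for pos_b, b in enumerate(idx):
                if a != b:
                    corr[a, b] = (w if style == "block"
                                  else w ** abs(pos_a - pos_b))
    if len(blocks) >= 2:
        b_r = config.between_r(condition)
        ia = [index[g] for g in blocks[0]]
        ib = [index[g] for g in blocks[1]]
        for a in ia:
            for b in ib:
                corr[a, b] = corr[b, a] = b_r
    repaired, delta = _repair_psd(corr)
    if delta > 0:
        log.warning(
            "correlation matrix for %s repaired by eigenvalue clipping; "
            "max pairwise delta %.4g", condition, delta)
    if delta > config.max_repair_delta:
        raise ConfigError(
            f"PSD repair for condition {condition!r} moved a correlation by "
            f"{delta:.4g} > max_repair_delta={config.max_repair_delta}")
    return pd.DataFrame(repaired, index=genes, columns=genes)


def _repair_psd(corr: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues and renormalize to unit diagonal.

    Returns the repaired matrix and the max absolute change of any entry.
    """
    w, v = np.linalg.eigh(corr)
    if w.min() >= -1e-10:
        return corr, 0.0
    w_clipped = np.clip(w, 0.0, None)
    fixed = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, float(np.abs(fixed - corr).max())


# ---------------------------------------------------------------------------
# generators


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a Cq matrix (genes x samples) and a sample table.

    Per condition, target-gene dCq values are drawn from a multivariate
    normal with the condition's block-structured correlation matrix
    (``signal_sd`` per gene); Cq = baseline + dCq + technical noise.
    Reference genes are drawn independently with their configured stability
    SDs.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.target_genes
    all_genes = genes + config.reference_genes

    sample_ids: list[str] = []
    conditions: list[str] = []
    columns: list[np.ndarray] = []
    for condition in config.group_sizes:
        n = config.group_sizes[condition]
        corr = condition_correlation(config, condition).to_numpy()
        w, v = np.linalg.eigh(corr)
        factor = v * np.sqrt(np.clip(w, 0.0, None))
        z = rng.standard_normal((len(genes), n))
        dcq = config.signal_sd * (factor @ z)
        cq_t = (config.baseline_cq + dcq
                + rng.normal(0.0, config.noise_sd, size=dcq.shape))
        ref_rows = []
        for j, (ref, sd) in enumerate(config.reference_gene_spec):
            base = config.baseline_cq - 4.0 + 0.5 * j  # abundant, gene-offset
            ref_rows.append(base + rng.normal(0.0, sd, size=n))
        block = np.vstack([cq_t, np.array(ref_rows)]) if ref_rows else cq_t
        columns.append(block)
        code = condition.replace("-", "_")
        sample_ids.extend(f"{code}_{i + 1:02d}" for i in range(n))
        conditions.extend([condition] * n)

    cq = pd.DataFrame(np.hstack(columns), index=all_genes, columns=sample_ids)
    cq.index.name = "gene"
    activity = [
        "active" if c in ACTIVE_CONDITIONS
        else "inactive" if c in INACTIVE_CONDITIONS
        else "not-applicable"
        for c in conditions
    ]
    base_condition = [c.split("-")[0] for c in conditions]
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "condition": base_condition,
        "activity": activity,
        "group": conditions,
    })
    return cq, samples


def generate_clinical(config: CohortConfig, samples: pd.DataFrame,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Attach clinical covariates drawn from per-condition distributions.

    Unknown covariate names in ``config.clinical_spec`` raise ConfigError.
    Missingness is applied cell-wise at ``config.missing_rate``.
    """
    known = set(CLINICAL_COLUMNS_SYNTH)
    unknown = set(config.clinical_spec) - known
    if unknown:
        raise ConfigError(f"unknown covariate name(s): {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    out = samples.copy()
    for cov, per_cond in config.clinical_spec.items():
        values = []
        for group in out["group"]:
            spec = per_cond.get(group, per_cond.get("*"))
            if spec is None:
                values.append(np.nan)
                continue
            values.append(_draw(spec, rng))
        out[cov] = values
        if config.missing_rate > 0 and cov != "sex":
            mask = rng.random(len(out)) < config.missing_rate
            out.loc[mask, cov] = np.nan
    return out


CLINICAL_COLUMNS_SYNTH = [
    "age_years", "duration_months", "esr_mm_h", "hscrp_mg_l", "il6_pg_ml",
    "tnfa_pg_ml", "prednisone_mg_d", "sex",
]


def _draw(spec: Mapping, rng: np.random.Generator):
    dist = spec.get("dist", "normal")
    if dist == "na":
        return np.nan
    if dist == "constant":
        return spec["value"]
    if dist == "choice":
        return rng.choice(spec["values"], p=spec.get("p"))
    if dist == "normal":
        x = rng.normal(spec["mean"], spec["sd"])
    elif dist == "lognormal":
        x = rng.lognormal(spec["mu"], spec["sigma"])
    elif dist == "gamma":
        x = rng.gamma(spec["shape"], spec["scale"])
    else:
        raise ConfigError(f"unknown distribution {dist!r}")
    if "low" in spec:
        x = max(x, spec["low"])
    if "high" in spec:
        x = min(x, spec["high"])
    if "round" in spec:
        x = round(x, int(spec["round"])) if spec["round"] else float(round(x))
    return x


def generate_mirna_targets(n_mirnas: int, n_genes: int,
                           family_spec: Mapping[str, int] | None = None,
                           seed: int = 0,
                           degree: int | tuple[int, int] = (1, 4),
                           genes: Sequence[str] | None = None) -> MirnaTargetMap:
    """Generate a random miRNA -> target-gene map.

    ``family_spec`` maps family names to member counts; family members are
    named ``<family>-m<i>``.  Remaining miRNAs (up to ``n_mirnas`` total) are
    singleton-family.  Each miRNA receives a target set of size drawn
    uniformly from ``degree`` (or exactly ``degree`` if an int).
    """
    if n_mirnas <= 0 or n_genes <= 0:
        raise ConfigError("n_mirnas and n_genes must be positive")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    else:
        genes = list(genes)
        if len(genes) != n_genes:
            raise ConfigError("len(genes) != n_genes")

    names: list[str] = []
    families: dict[str, str] = {}
    family_spec = dict(family_spec or {})
    for fam, count in family_spec.items():
        if count <= 0:
            raise ConfigError(f"family {fam!r} member count must be positive")
        for i in range(count):
            name = f"{fam}-m{i + 1}"
            names.append(name)
            families[name] = fam
    if len(names) > n_mirnas:
        raise ConfigError("family members exceed n_mirnas")
    i = 0
    while len(names) < n_mirnas:
        i += 1
        name = f"miR-x{i:03d}"
        names.append(name)
        families[name] = name

    if isinstance(degree, int):
        lo = hi = degree
    else:
        lo, hi = degree
    if lo < 1 or hi < lo:
        raise ConfigError("invalid degree specification")
    hi = min(hi, n_genes)
    lo = min(lo, hi)

    targets = {}
    for name in names:
        k = int(rng.integers(lo, hi + 1))
        targets[name] = set(rng.choice(genes, size=k, replace=False))
    return MirnaTargetMap(targets=targets, families=families)


# ---------------------------------------------------------------------------
# file I/O


def write_cq_tsv(cq: pd.DataFrame, path) -> None:
    """Write a Cq matrix as TSV, genes as rows, first column ``gene``."""
    cq.to_csv(path, sep="\t", index_label="gene")
    log.info("wrote Cq matrix %s (%d genes x %d samples)",
             path, cq.shape[0], cq.shape[1])


def read_cq_tsv(path) -> pd.DataFrame:
    cq = pd.read_csv(path, sep="\t", index_col="gene")
    if cq.index.duplicated().any() or cq.columns.duplicated().any():
        raise ConfigError("duplicate gene or sample names in Cq table")
    return cq


def write_samples_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)
    log.info("wrote sample table %s (%d samples)", path, len(samples))


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["–"])
    if df["sample_id"].duplicated().any():
        raise ConfigError("duplicate sample_id in sample table")
    return df
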