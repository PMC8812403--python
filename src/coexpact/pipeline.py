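"""End-to-end pipeline orchestration.

Runs simulate -> quantify -> stats -> networks -> clusters -> scoring ->
closeness -> miRNA from one RunConfig, writing every artifact with a
sha256 checksum into a JSON run manifest.  Reruns with the same config and
seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import activity_score as act
from . import clustering as clu
from . import coexpression as coexpr
from . import group_stats as gs
from . import mirna_network as mir
from . import qpcr_quant as qp
from . import synthetic_data as synth
from . import tlr_closeness as tc
from .errors import ConfigError, StageError

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    outdir: str = "coexpact_run"
    seed: int = 0
    alpha: float = 0.05
    alpha_strict: float = 0.01
    r_min: float = 0.73
    cut_height: float = 1.0
    cut_height_coarse: float = 2.0
    min_degree: int = 3
    correlation_method: str = "pearson"
    correlation_scale: str = "expression"   # or "log2" (-dCq scale)
    fit_group: str = "treated-inactive"
    eval_groups: tuple = ("treated-inactive", "treated-active")
    calibrator_group: str = "HC"
    reference_policy: str = "auto"      # "auto" or "NAME,NAME"
    cohort: dict = dataclasses.field(default_factory=dict)
    mirna: dict = dataclasses.field(
        default_factory=lambda: {"n_mirnas": 40, "n_genes": 13,
                                 "family_spec": {"miR-900": 3}})

    def __post_init__(self):
        if not 0 < self.alpha <= 1 or not 0 < self.alpha_strict <= 1:
            raise ConfigError("alpha levels must be in (0,1]")
        if not 0 <= self.r_min < 1:
            raise ConfigError("r_min must be in [0,1)")
        if self.cut_height < 0 or self.min_degree < 1:
            raise ConfigError("invalid cut height or min_degree")
        if self.correlation_scale not in ("expression", "log2"):
            raise ConfigError("correlation_scale must be expression|log2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest = {"version": __version__, "seed": config.seed,
                "config": dataclasses.asdict(config), "stages": {},
                "artifacts": artifacts}

    def emit(name: str, path: Path):
        artifacts[name] = _sha256(path)

    # --- simulate ---------------------------------------------------------
    try:
        cohort_cfg = synth.CohortConfig(**{**config.cohort,
                                           "seed": config.seed})
        cq, samples = synth.generate_cohort(cohort_cfg)
        samples = synth.generate_clinical(cohort_cfg, samples)
        cq_path, sm_path = outdir / "cq.tsv", outdir / "samples.csv"
        synth.write_cq_tsv(cq, cq_path)
        synth.write_samples_csv(samples, sm_path)
        cohort_cfg.to_yaml(outdir / "cohort_config.yaml")
        emit("cq", cq_path)
        emit("samples", sm_path)
        manifest["stages"]["simulate"] = {
            "n_samples": len(samples), "n_genes": len(cohort_cfg.target_genes)}
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    # --- quantify ---------------------------------------------------------
    try:
        candidates = cq.loc[cohort_cfg.reference_genes]
        report = qp.stability_report(candidates, groups=samples["group"])
        report.to_csv(outdir / "stability_report.csv")
        emit("stability_report", outdir / "stability_report.csv")
        if config.reference_policy == "auto":
            refs = qp.select_reference_pair(report)
        else:
            refs = tuple(config.reference_policy.split(","))
        calibrators = samples.loc[samples["group"] == config.calibrator_group,
                                  "sample_id"].tolist()
        expr = qp.relative_expression(cq, cohort_cfg.target_genes, refs,
                                      calibrators)
        qp.write_expression_tsv(expr, outdir / "expression.tsv")
        emit("expression", outdir / "expression.tsv")
        manifest["stages"]["quantify"] = {"reference_pair": list(refs)}
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc

    # --- stats ------------------------------------------------------------
    try:
        stats_df = gs.compare_clinical(
            samples, "group",
            ["age_years", "duration_months", "esr_mm_h", "hscrp_mg_l"],
            groups=(config.fit_group, "treated-active"))
        stats_df.to_csv(outdir / "clinical_stats.csv")
        emit("clinical_stats", outdir / "clinical_stats.csv")
        manifest["stages"]["stats"] = {
            "variables": stats_df.index.tolist()}
    except Exception as exc:
        raise StageError("stats", str(exc)) from exc

    # --- networks ---------------------------------------------------------
    corr_data = (np.log2(expr) if config.correlation_scale == "log2"
                 else expr)
    try:
        networks = {}
        topo_rows = []
        for group in cohort_cfg.group_sizes:
            ids = samples.loc[samples["group"] == group, "sample_id"].tolist()
            corr = coexpr.pairwise_correlation(
                corr_data, method=config.correlation_method,
                condition_samples=ids)
            net = coexpr.build_network(corr, alpha=config.alpha,
                                       nodes=sorted(expr.index),
                                       condition=group)
            networks[group] = (corr, net)
            coexpr.write_sif(net, outdir / f"network_{group}.sif")
            emit(f"network_{group}", outdir / f"network_{group}.sif")
            t = coexpr.topology(net)
            topo_rows.append({"condition": group,
                              **dataclasses.asdict(t)})
        pd.DataFrame(topo_rows).to_csv(outdir / "topology.csv", index=False)
        emit("topology", outdir / "topology.csv")
        manifest["stages"]["network"] = {"conditions": list(networks)}
    except Exception as exc:
        raise StageError("network", str(exc)) from exc

    # --- clusters ---------------------------------------------------------
    try:
        assignments = {}
        for group, (corr, _net) in networks.items():
            ids = samples.loc[samples["group"] == group, "sample_id"].tolist()
            dist = clu.correlation_distance(corr_data[ids],
                                            method=config.correlation_method)
            tree = clu.hierarchical_cluster(dist)
            assignment = clu.cut_tree(tree, config.cut_height)
            assignments[group] = assignment
            clu.write_assignment_tsv(assignment,
                                     outdir / f"clusters_{group}.tsv")
            emit(f"clusters_{group}", outdir / f"clusters_{group}.tsv")
        manifest["stages"]["cluster"] = {
            g: a.n_clusters for g, a in assignments.items()}
    except Exception as exc:
        raise StageError("cluster", str(exc)) from exc

    # --- scoring ----------------------------------------------------------
    try:
        fit_ids = samples.loc[samples["group"] == config.fit_group,
                              "sample_id"].tolist()
        eval_mask = samples["group"].isin(config.eval_groups)
        eval_ids = samples.loc[eval_mask, "sample_id"].tolist()
        labels = samples.set_index("sample_id").loc[eval_ids, "activity"]
        corr_fit, _ = networks[config.fit_group]
        pairs = act.select_pairs(corr_fit, r_min=config.r_min,
                                 alpha=config.alpha_strict)[:4]
        score_info: dict = {"pairs": [list(p) for p in pairs]}
        if pairs:
            models = [act.fit_pair_regression(expr, p, fit_ids,
                                              config.fit_group)
                      for p in pairs]
            thresholds = {}
            for model in models:
                m = act.m_values(model, expr, eval_ids)
                thr, _, _ = act.youden_threshold(m.dropna(),
                                                 labels[m.dropna().index],
                                                 positive="inactive",
                                                 direction="less")
                thresholds[(model.x_gene, model.y_gene)] = thr
            card = act.combined_score(models, thresholds, expr, eval_ids)
            thr_total, _, summary = act.youden_threshold(
                card.total, labels, positive="inactive", direction="greater")
            card.total_threshold = thr_total
            flat = card.scores.copy()
            flat.columns = [f"{a}:{b}" for a, b in flat.columns]
            flat.assign(total=card.total).to_csv(outdir / "scorecard.csv")
            emit("scorecard", outdir / "scorecard.csv")
            score_info.update({
                "total_threshold": thr_total,
                "roc": dataclasses.asdict(summary),
            })
        manifest["stages"]["score"] = score_info
    except Exception as exc:
        raise StageError("score", str(exc)) from exc

    # --- closeness --------------------------------------------------------
    try:
        _, net_fit = networks[config.fit_group]
        tlr_present = tc.DEFAULT_TLR_SET & set(net_fit.nodes)
        closeness_info = {}
        if tlr_present:
            table = tc.closeness_table(net_fit, assignments[config.fit_group],
                                       tlr_set=tlr_present)
            pd.DataFrame(tc.closeness_to_rows(table)).to_csv(
                outdir / "closeness.csv", index=False)
            emit("closeness", outdir / "closeness.csv")
            closeness_info = {"top": table[0].gene if table else None}
        manifest["stages"]["closeness"] = closeness_info
    except Exception as exc:
        raise StageError("closeness", str(exc)) from exc

    # --- miRNA ------------------------------------------------------------
    try:
        cluster1 = assignments[config.fit_group].members(1)
        mcfg = dict(config.mirna)
        tmap = synth.generate_mirna_targets(
            n_mirnas=int(mcfg.get("n_mirnas", 40)),
            n_genes=len(cluster1) or int(mcfg.get("n_genes", 13)),
            family_spec=mcfg.get("family_spec"),
            seed=config.seed, genes=cluster1 or None)
        pooled = mir.pool_families(mir.filter_multi_target(tmap))
        ranking = mir.rank_by_target_count(pooled)
        net = mir.build_network(pooled, min_degree=config.min_degree)
        mir.write_network_sif(net, outdir / "mirna_network.sif")
        emit("mirna_network", outdir / "mirna_network.sif")
        manifest["stages"]["mirna"] = {"ranking": ranking[:10]}
    except Exception as exc:
        raise StageError("mirna", str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                        default=str))
    return manifest


def report(manifest: dict) -> str:
    """Human-readable run summary; sections absent from the manifest are
    omitted gracefully."""
    lines = [f"coexpact run report (seed={manifest.get('seed')})", ""]
    stages = manifest.get("stages", {})
    if "simulate" in stages:
        s = stages["simulate"]
        lines.append(f"cohort: {s['n_samples']} samples, "
                     f"{s['n_genes']} target genes")
    if "quantify" in stages:
        lines.append("reference pair: "
                     + ", ".join(stages["quantify"]["reference_pair"]))
    if "network" in stages:
        lines.append("")
        lines.append("topology (per condition): nodes / edges / avg "
                     "neighbors / diameter / clustering / path length")
        outdir = Path(manifest["config"]["outdir"])
        topo = pd.read_csv(outdir / "topology.csv")
        for _, row in topo.iterrows():
            lines.append(
                f"  {row['condition']}: {int(row['nodes'])} / "
                f"{int(row['edges'])} / {row['average_neighbors']:.3f} / "
                f"{row['diameter']:.0f} / "
                f"{row['clustering_coefficient']:.3f} / "
                f"{row['characteristic_path_length']:.3f}")
    if "score" in stages and stages["score"].get("roc"):
        roc = stages["score"]["roc"]
        lines.append("")
        lines.append(
            f"activity score ROC: AUC={roc['auc']:.3f} "
            f"sens={roc['sensitivity']:.3f} spec={roc['specificity']:.3f}")
    if "closeness" in stages and stages["closeness"]:
        lines.append(f"closest gene to probe set: "
                     f"{stages['closeness'].get('top')}")
    if "mirna" in stages:
        top = stages["mirna"]["ranking"][:4]
        lines.append("top miRNA nodes: "
                     + ", ".join(f"{m} ({n})" for m, n in top))
    return "\n".join(lines) + "\n"
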