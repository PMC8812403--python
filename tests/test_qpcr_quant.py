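import math

import numpy as np
import pandas as pd
import pytest

from coexpact import qpcr_quant as qp
from coexpact.errors import DataError


def cq_frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# geNorm


def genorm_oracle(cq: pd.DataFrame) -> dict:
    """Brute-force mean-of-SD-of-log-ratio evaluation (loops only)."""
    out = {}
    for j in cq.index:
        sds = []
        for k in cq.index:
            if k == j:
                continue
            ratios = [cq.loc[j, s] - cq.loc[k, s] for s in cq.columns]
            mean = sum(ratios) / len(ratios)
            var = sum((x - mean) ** 2 for x in ratios) / (len(ratios) - 1)
            sds.append(math.sqrt(var))
        out[j] = sum(sds) / len(sds)
    return out


class TestGenorm:
    def test_constant_offsets_give_zero_m(self):
        base = np.linspace(20, 25, 6)
        cq = cq_frame([base, base + 1.5, base - 3.0])
        res = qp.genorm_stability(cq)
        assert np.allclose(res.m_values, 0.0)

    def test_matches_bruteforce_oracle(self, rng):
        cq = cq_frame(rng.normal(22, 1.5, size=(4, 6)))
        res = qp.genorm_stability(cq)
        oracle = genorm_oracle(cq)
        for gene, m in oracle.items():
            assert res.m_values[gene] == pytest.approx(m)

    def test_noisy_gene_excluded_first(self):
        hits = 0
        for seed in range(100):
            local = np.random.default_rng(seed)
            rows = [22 + local.normal(0, 0.1, 8) for _ in range(3)]
            rows.append(22 + local.normal(0, 2.0, 8))
            cq = cq_frame(rows, genes=["a", "b", "c", "noisy"])
            res = qp.genorm_stability(cq)
            hits += res.exclusion_order[0] == "noisy"
        assert hits >= 95

    def test_shift_invariance(self, rng):
        cq = cq_frame(rng.normal(22, 1, size=(4, 6)))
        shifted = cq.add(pd.Series([1.0, -2.5, 0.3, 7.0], index=cq.index),
                         axis=0)
        m1 = qp.genorm_stability(cq).m_values
        m2 = qp.genorm_stability(shifted).m_values
        assert np.allclose(m1, m2)

    def test_too_few_candidates_refused(self, rng):
        with pytest.raises(DataError):
            qp.genorm_stability(cq_frame(rng.normal(size=(2, 6))))


# ---------------------------------------------------------------------------
# NormFinder


def normfinder_oracle(cq: pd.DataFrame, groups) -> dict:
    """Independent loop-based evaluation of the variance decomposition."""
    genes = list(cq.index)
    k = len(genes)
    labels = []
    for g in groups:
        if g not in labels:
            labels.append(g)
    cols = {g: [s for s, lab in zip(cq.columns, groups) if lab == g]
            for g in labels}

    v = {}
    sigma2 = {}
    d = {}
    grand = float(np.mean([cq.loc[i, s] for i in genes for s in cq.columns]))
    for g in labels:
        n = len(cols[g])
        group_vals = [[cq.loc[i, s] for s in cols[g]] for i in genes]
        gene_means = [sum(row) / n for row in group_vals]
        sample_means = [sum(group_vals[i][j] for i in range(k)) / k
                        for j in range(n)]
        gmean = sum(gene_means) / k
        for gi, gene in enumerate(genes):
            resid = [group_vals[gi][j] - gene_means[gi] - sample_means[j]
                     + gmean for j in range(n)]
            v[(gene, g)] = sum(x ** 2 for x in resid) / (n - 1)
        s_total = sum(v[(gene, g)] for gene in genes) / (1 - 1 / k)
        for gene in genes:
            sigma2[(gene, g)] = max(
                0.0, (v[(gene, g)] - s_total / k ** 2) / (1 - 2 / k))
        for gene in genes:
            gene_overall = float(np.mean([cq.loc[gene, s]
                                          for s in cq.columns]))
            d[(gene, g)] = (sum(cq.loc[gene, s] for s in cols[g])
                            / len(cols[g]) - gene_overall - (gmean - grand))

    samp_var = {key: sigma2[key] / len(cols[key[1]]) for key in sigma2}
    gamma2 = max(0.0,
                 sum(val ** 2 for val in d.values())
                 / ((k - 1) * (len(labels) - 1))
                 - sum(samp_var.values()) / len(samp_var))
    out = {}
    for gene in genes:
        terms = []
        for g in labels:
            den = gamma2 + samp_var[(gene, g)]
            shrunk = d[(gene, g)] * gamma2 / den if den > 0 else 0.0
            terms.append(abs(shrunk) + math.sqrt(samp_var[(gene, g)]))
        out[gene] = sum(terms) / len(labels)
    return out


class TestNormfinder:
    def test_matches_formula_oracle(self, rng):
        cq = cq_frame(rng.normal(22, 1.0, size=(4, 12)))
        groups = ["a"] * 6 + ["b"] * 6
        res = qp.normfinder_stability(cq, groups)
        oracle = normfinder_oracle(cq, groups)
        for gene in cq.index:
            assert res.stability[gene] == pytest.approx(oracle[gene])

    def test_zero_variance_gene_is_most_stable(self, rng):
        rows = [np.full(8, 20.0)] + [rng.normal(22, 0.8, 8) for _ in range(3)]
        cq = cq_frame(rows, genes=["flat", "a", "b", "c"])
        res = qp.normfinder_stability(cq, ["x"] * 4 + ["y"] * 4)
        assert res.stability["flat"] == res.stability.min()

    def test_intergroup_shift_ranked_least_stable(self):
        hits = 0
        for seed in range(100):
            local = np.random.default_rng(seed)
            rows = [22 + local.normal(0, 0.3, 12) for _ in range(4)]
            rows[0] = rows[0] + np.r_[np.zeros(6), np.full(6, 2.0)]
            cq = cq_frame(rows, genes=["shifted", "a", "b", "c"])
            res = qp.normfinder_stability(cq, ["x"] * 6 + ["y"] * 6)
            hits += res.stability.idxmax() == "shifted"
        assert hits >= 95

    def test_single_group_fallback_flagged(self, rng):
        cq = cq_frame(rng.normal(22, 1, size=(4, 6)))
        res = qp.normfinder_stability(cq, ["only"] * 6)
        assert res.intragroup_only
        assert (res.stability >= 0).all()

    def test_small_group_rejected(self, rng):
        cq = cq_frame(rng.normal(size=(3, 5)))
        with pytest.raises(DataError):
            qp.normfinder_stability(cq, ["a", "a", "a", "a", "b"])


# ---------------------------------------------------------------------------
# BestKeeper


class TestBestkeeper:
    def test_identical_rows(self):
        row = np.array([20.0, 21.0, 22.5, 19.5, 23.0])
        cq = cq_frame([row, row, row])
        bk = qp.bestkeeper_stats(cq)
        expected_sd = pd.Series(row).std(ddof=1)
        assert np.allclose(bk["bestkeeper_sd"], expected_sd)
        assert np.allclose(bk["bestkeeper_r"], 1.0)

    def test_matches_arithmetic_oracle(self, rng):
        cq = cq_frame(rng.normal(22, 1.2, size=(5, 10)))
        bk = qp.bestkeeper_stats(cq)
        index = [sum(cq.loc[g, s] for g in cq.index) / 5 for s in cq.columns]
        for gene in cq.index:
            vals = [cq.loc[gene, s] for s in cq.columns]
            mean = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 9)
            assert bk.loc[gene, "bestkeeper_sd"] == pytest.approx(sd)
            r = np.corrcoef(vals, index)[0, 1]
            assert bk.loc[gene, "bestkeeper_r"] == pytest.approx(r)

    def test_high_sd_flagged(self, rng):
        cq = cq_frame([rng.normal(22, 3.0, 30), rng.normal(22, 0.2, 30)],
                      genes=["wild", "tame"])
        bk = qp.bestkeeper_stats(cq)
        assert bool(bk.loc["wild", "sd_above_advisory"])
        assert not bool(bk.loc["tame", "sd_above_advisory"])

    def test_zero_variance_gene_reports_na_correlation(self, rng):
        cq = cq_frame([np.full(6, 20.0), rng.normal(22, 1, 6)],
                      genes=["flat", "a"])
        bk = qp.bestkeeper_stats(cq)
        assert np.isnan(bk.loc["flat", "bestkeeper_r"])


# ---------------------------------------------------------------------------
# reference selection


class TestSelectReferencePair:
    def test_planted_stable_pair_selected(self):
        hits = 0
        for seed in range(100):
            local = np.random.default_rng(seed)
            rows = {
                "calm1": 20 + local.normal(0, 0.02, 10),
                "calm2": 21 + local.normal(0, 0.02, 10),
                "noisy1": 22 + local.normal(0, 1.5, 10),
                "noisy2": 23 + local.normal(0, 1.5, 10),
                "noisy3": 24 + local.normal(0, 1.5, 10),
            }
            report = qp.stability_report(pd.DataFrame(rows).T)
            hits += qp.select_reference_pair(report) == ("calm1", "calm2")
        assert hits >= 95

    def test_all_equal_ties_break_lexicographically(self):
        base = np.linspace(20, 24, 8)
        cq = cq_frame([base, base, base, base],
                      genes=["delta", "alpha", "charlie", "bravo"])
        report = qp.stability_report(cq)
        assert qp.select_reference_pair(report) == ("alpha", "bravo")

    def test_candidate_panel_membership(self):
        # default nine-candidate panel: selection must come from the panel
        from coexpact import synthetic_data as synth
        cfg = synth.CohortConfig(seed=3)
        cq, samples = synth.generate_cohort(cfg)
        report = qp.stability_report(cq.loc[cfg.reference_genes],
                                     groups=samples["group"])
        pair = qp.select_reference_pair(report)
        panel = {"ACTB", "GUSB", "B2M", "GAPDH", "HPRT1", "PGK1", "RPL13A",
                 "SDHA", "YWHAZ"}
        assert set(pair) <= panel

    def test_aggregate_rank_is_permutation(self, rng):
        cq = cq_frame(rng.normal(22, 1, size=(6, 10)))
        report = qp.stability_report(cq)
        assert sorted(report["aggregate_rank"]) == [1, 2, 3, 4, 5, 6]

    def test_single_noise_carrier_ranked_last_by_all_methods(self, rng):
        rows = [22 + rng.normal(0, 0.05, 12) for _ in range(3)]
        rows.append(22 + rng.normal(0, 2.5, 12))
        cq = cq_frame(rows, genes=["a", "b", "c", "noisy"])
        report = qp.stability_report(cq)
        assert report["genorm_m"].idxmax() == "noisy"
        assert report["normfinder_stability"].idxmax() == "noisy"
        assert report["bestkeeper_sd"].idxmax() == "noisy"


# ---------------------------------------------------------------------------
# relative expression


class TestRelativeExpression:
    def refs(self):
        samples = [f"s{i}" for i in range(4)]
        cq = cq_frame(
            [[20, 21, 22, 23],     # ref1
             [22, 23, 24, 25],     # ref2
             [21, 22, 23, 24],     # target == mean of refs
             [20, 22, 21, 25]],    # target2
            genes=["ref1", "ref2", "t1", "t2"], samples=samples)
        return cq, samples

    def test_target_equal_to_reference_mean_gives_ones(self):
        cq, samples = self.refs()
        expr = qp.relative_expression(cq, ["t1"], ("ref1", "ref2"), samples)
        assert np.allclose(expr.loc["t1"], 1.0)

    def test_one_cycle_below_calibrator_doubles(self):
        samples = ["cal", "probe"]
        cq = cq_frame([[20, 20], [20, 20], [25, 24]],
                      genes=["r1", "r2", "t"], samples=samples)
        expr = qp.relative_expression(cq, ["t"], ("r1", "r2"), ["cal"])
        assert expr.loc["t", "probe"] == pytest.approx(2.0)
        assert expr.loc["t", "cal"] == pytest.approx(1.0)

    def test_matches_spreadsheet_oracle(self, rng):
        samples = [f"s{i}" for i in range(4)]
        cq = cq_frame(rng.normal(22, 2, size=(5, 4)),
                      genes=["r1", "r2", "a", "b", "c"], samples=samples)
        expr = qp.relative_expression(cq, ["a", "b", "c"], ("r1", "r2"),
                                      calibrator_samples=["s0", "s1"])
        for gene in ["a", "b", "c"]:
            dcq = [cq.loc[gene, s]
                   - (cq.loc["r1", s] + cq.loc["r2", s]) / 2 for s in samples]
            calib = (dcq[0] + dcq[1]) / 2
            for j, s in enumerate(samples):
                assert expr.loc[gene, s] == pytest.approx(
                    2 ** -(dcq[j] - calib))

    def test_reference_swap_invariance(self, rng):
        cq, samples = self.refs()
        e1 = qp.relative_expression(cq, ["t2"], ("ref1", "ref2"), samples)
        e2 = qp.relative_expression(cq, ["t2"], ("ref2", "ref1"), samples)
        assert np.allclose(e1.loc["t2"], e2.loc["t2"])

    def test_missing_reference_nans_sample_with_warning(self):
        cq, samples = self.refs()
        cq.loc["ref1", "s2"] = np.nan
        with pytest.warns(UserWarning, match="missing reference"):
            expr = qp.relative_expression(cq, ["t1", "t2"], ("ref1", "ref2"),
                                          ["s0"])
        assert expr["s2"].isna().all()
        assert expr[["s0", "s1", "s3"]].notna().all().all()

    def test_empty_calibrator_rejected(self):
        cq, _ = self.refs()
        with pytest.raises(DataError):
            qp.relative_expression(cq, ["t1"], ("ref1", "ref2"), [])
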