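import math

import numpy as np
import pandas as pd
import pytest

from genefamkit.expression_stats import (
    anova_duncan, cluster_genes, correlate, ddct, ddct_summary,
    duncan_critical_range, normalize_expression, pearson_p_from_r,
    significance_mark,
)
from genefamkit.io_formats import ValidationError
from genefamkit.synthetic_data import (
    SimulationConfig, simulate_expression, simulate_qpcr,
)


class TestNormalize:
    def test_lg_closed_forms(self):
        tpm = pd.DataFrame({"t1": [0.0, 99.0], "t2": [9.0, 999.0]},
                           index=["g1", "g2"])
        em = normalize_expression(tpm)
        assert em.lg.loc["g1", "t1"] == 0.0
        assert em.lg.loc["g2", "t1"] == pytest.approx(2.0)
        assert em.lg.loc["g1", "t2"] == pytest.approx(1.0)

    def test_z_row_standardized(self):
        tpm = pd.DataFrame({"t1": [0.0], "t2": [99.0]}, index=["g"])
        em = normalize_expression(tpm)
        assert em.z.loc["g"].tolist() == pytest.approx([-1.0, 1.0])
        rng = np.random.default_rng(0)
        tpm2 = pd.DataFrame(rng.uniform(0, 50, size=(6, 8)))
        z = normalize_expression(tpm2).z
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_constant_rows_flagged(self):
        tpm = pd.DataFrame({"t1": [5.0], "t2": [5.0]}, index=["g"])
        em = normalize_expression(tpm)
        assert em.constant_genes == ("g",)
        assert (em.z.loc["g"] == 0).all()

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValidationError):
            normalize_expression(pd.DataFrame({"t": [-1.0]}))


class TestClustering:
    def test_two_identical_groups_recovered(self):
        rows = [[10, 0, 10, 0]] * 3 + [[0, 10, 0, 10]] * 4
        tpm = pd.DataFrame(rows, index=[f"g{i}" for i in range(7)])
        cl = cluster_genes(normalize_expression(tpm), k=2)
        assert len({cl[f"g{i}"] for i in range(3)}) == 1
        assert len({cl[f"g{i}"] for i in range(3, 7)}) == 1
        assert cl["g0"] != cl["g3"]

    def test_k1_single_cluster(self):
        tpm = pd.DataFrame([[1.0, 2.0], [3.0, 1.0]], index=["a", "b"])
        assert set(cluster_genes(normalize_expression(tpm), k=1).values()) == {1}

    def test_k_exceeding_genes_rejected(self):
        tpm = pd.DataFrame([[1.0, 2.0]], index=["a"])
        with pytest.raises(ValidationError):
            cluster_genes(normalize_expression(tpm), k=3)

    def test_planted_clusters_recovered(self):
        """Planted high/low labels recovered with Rand index >= 0.9."""
        tpm, labels = simulate_expression(SimulationConfig(seed=2))
        cl = cluster_genes(normalize_expression(tpm), k=2)
        genes = list(tpm.index)
        same_true = same_pred = agree = 0
        n_pairs = 0
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                t = labels[genes[i]] == labels[genes[j]]
                p = cl[genes[i]] == cl[genes[j]]
                agree += t == p
                n_pairs += 1
        assert agree / n_pairs >= 0.9
        # cluster 1 is the high-expression cluster by construction
        high = [g for g in genes if labels[g] == "high"]
        assert sum(cl[g] == 1 for g in high) >= 0.9 * len(high)


class TestDdct:
    def _table(self, dcts):
        rows = []
        for treatment, values in dcts.items():
            for i, v in enumerate(values):
                rows.append(dict(gene="g", cultivar="c", treatment=treatment,
                                 replicate=i + 1, ct_target=20.0 + v,
                                 ct_reference=20.0))
        return pd.DataFrame(rows)

    def test_equal_dct_gives_unit_folds(self):
        folds = ddct(self._table({"control": [5, 5, 5], "Zn": [5, 5, 5]}))
        assert folds["fold"].tolist() == pytest.approx([1.0] * 6)

    def test_one_cycle_below_control_doubles(self):
        folds = ddct(self._table({"control": [5, 5, 5], "Zn": [4, 4, 4]}))
        zn = folds[folds.treatment == "Zn"]["fold"]
        assert zn.tolist() == pytest.approx([2.0] * 3)

    def test_control_geometric_mean_is_one(self):
        folds = ddct(self._table({"control": [5.2, 4.7, 5.1], "Zn": [3, 3, 3]}))
        ctrl = folds[folds.treatment == "control"]["fold"]
        assert math.prod(ctrl) ** (1 / len(ctrl)) == pytest.approx(1.0)
        assert ctrl.mean() >= 1.0  # arithmetic mean exceeds 1 unless constant

    def test_missing_control_named(self):
        with pytest.raises(ValidationError, match="control"):
            ddct(self._table({"Zn": [1, 2, 3]}))

    def test_planted_log2fc_recovered(self):
        qpcr, _, fc = simulate_qpcr(SimulationConfig(seed=3))
        summary = ddct_summary(ddct(qpcr))
        merged = summary.merge(fc, on=["gene", "cultivar", "treatment"])
        zn = merged[(merged.log2fc == 2.0)]
        assert np.allclose(zn["mean_fold"], 4.0, rtol=0.35)
        assert abs(np.log2(zn["mean_fold"]).mean() - 2.0) < 0.15


class TestAnovaDuncan:
    def test_identical_groups_share_one_letter(self):
        res = anova_duncan({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res.f_statistic is None
        assert res.letters == {"a": "a", "b": "a"}

    def test_extreme_separation(self):
        res = anova_duncan({"lo": [0.0, 0.1, -0.1], "hi": [100.0, 100.1, 99.9]})
        assert res.letters["hi"] == "a" and res.letters["lo"] == "b"
        assert res.p_value < 1e-6

    def test_critical_range_factors_match_published_table(self):
        """Duncan 5% significant-range factors for df=10 (published values)."""
        for span, factor in ((2, 3.151), (3, 3.293), (4, 3.376), (5, 3.430)):
            got = duncan_critical_range(0.05, span, 10, 1.0, 1.0)
            assert got == pytest.approx(factor, abs=5e-3)

    def test_four_group_fixture_frozen_letters(self):
        """Overlapping middle groups share a letter (hand-computed ranges).

        Pooled MS_error = 0.01 on 8 df, n = 3: the least significant range
        for adjacent means is 3.261 * sqrt(0.01/3) = 0.188, so the gap of
        0.15 between g2 and g3 is not significant while all other gaps are.
        """
        groups = {
            "g1": [9.9, 10.0, 10.1],
            "g2": [12.9, 13.0, 13.1],
            "g3": [13.05, 13.15, 13.25],
            "g4": [29.9, 30.0, 30.1],
        }
        res = anova_duncan(groups)
        assert res.letters == {"g4": "a", "g3": "b", "g2": "b", "g1": "c"}

    def test_letters_transitively_consistent(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            groups = {f"g{i}": list(rng.normal(rng.uniform(0, 3), 1.0, size=4))
                      for i in range(5)}
            res = anova_duncan(groups)
            order = sorted(groups, key=lambda g: -res.means[g])
            # shared letters form contiguous runs in mean order
            for letter in set("".join(res.letters.values())):
                idx = [i for i, g in enumerate(order) if letter in res.letters[g]]
                assert idx == list(range(min(idx), max(idx) + 1))

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValidationError):
            anova_duncan({"a": [1.0], "b": [1.0, 2.0]})


class TestCorrelate:
    def test_perfectly_linear(self):
        e = pd.DataFrame({"g": [1.0, 2.0, 3.0, 4.0]})
        t = pd.DataFrame({"zn": [2.0, 4.0, 6.0, 8.0]})
        row = correlate(e, t).iloc[0]
        assert row.r == pytest.approx(1.0) and row.mark == "**"

    @pytest.mark.parametrize("r,n,mark", [
        (0.534, 24, "**"),   # p < 0.01
        (0.283, 24, ""),     # not significant
        (0.430, 24, "*"),    # 0.01 <= p < 0.05
    ])
    def test_marks_at_study_sample_size(self, r, n, mark):
        assert significance_mark(pearson_p_from_r(r, n)) == mark

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = 0.6 * x + rng.normal(size=20)
        e = pd.DataFrame({"g": x})
        r1 = correlate(e, pd.DataFrame({"t": y})).iloc[0].r
        r2 = correlate(e, pd.DataFrame({"t": 5.0 - 3.0 * y})).iloc[0].r
        assert abs(r1) == pytest.approx(abs(r2))
        r3 = correlate(pd.DataFrame({"g": 2 * x + 7}),
                       pd.DataFrame({"t": y})).iloc[0].r
        assert r1 == pytest.approx(r3)

    def test_constant_vector_flagged(self):
        e = pd.DataFrame({"g": [1.0, 1.0, 1.0]})
        t = pd.DataFrame({"zn": [1.0, 2.0, 3.0]})
        row = correlate(e, t).iloc[0]
        assert math.isnan(row.r) and row.mark == "nd"

    def test_planted_expression_metal_correlation(self):
        """Zn-induced genes correlate with root Zn at p < 0.01 (n = 24)."""
        from genefamkit.synthetic_data import ZN_INDUCED

        qpcr, metals, _ = simulate_qpcr(SimulationConfig(seed=6))
        folds = ddct(qpcr)
        key = ["cultivar", "treatment", "replicate"]
        expr = folds.pivot_table(index=key, columns="gene", values="fold")
        traits = metals.set_index(key).loc[expr.index][["zn_root"]]
        corr = correlate(expr, traits)
        assert (corr.n == 24).all()
        sub = corr[corr.gene.isin(ZN_INDUCED)]
        assert (sub.p < 0.01).all() and (sub.mark == "**").all()
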