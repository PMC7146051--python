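"""Moderated t, BH adjustment, and DE feature selection."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omicsig as og
from omicsig.diffexpr import fit_variance_prior


def make_matrix(rng, p=50, n0=10, n1=12, shift_first=0):
    vals = rng.normal(size=(p, n0 + n1)) * rng.uniform(0.5, 2.0, size=(p, 1))
    if shift_first:
        vals[:shift_first, n0:] += 1.5
    groups = np.array(["good"] * n0 + ["poor"] * n1)
    mat = og.ExpressionMatrix("l", [f"f{i:03d}" for i in range(p)],
                              [f"s{i}" for i in range(n0 + n1)], vals)
    return mat, groups


class TestModeratedT:
    def test_d0_zero_reduces_to_pooled_t(self, rng):
        mat, groups = make_matrix(rng)
        res = og.moderated_t(mat, groups, d0_override=0.0)
        t_ref, p_ref = stats.ttest_ind(mat.values[:, groups == "poor"].T,
                                       mat.values[:, groups == "good"].T,
                                       equal_var=True)
        np.testing.assert_allclose(res.table["t_mod"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p_value"], p_ref, atol=1e-10)

    def test_identical_variances_shrink_to_themselves(self):
        # within-group deviations identical across features → common s²;
        # with the prior variance at that common value, shrinkage is a
        # no-op and the statistic equals the ordinary pooled t for any d0
        rng = np.random.default_rng(3)
        base0 = rng.normal(size=5)
        base1 = rng.normal(size=6)
        vals = np.vstack([
            np.concatenate([base0 + m0, base1 + m1])
            for m0, m1 in rng.normal(size=(20, 2))
        ])
        groups = np.array(["good"] * 5 + ["poor"] * 6)
        mat = og.ExpressionMatrix("l", [f"f{i}" for i in range(20)],
                                  [f"s{i}" for i in range(11)], vals)
        n0, n1 = 5, 6
        common_s2 = (((vals[:, :5] - vals[:, :5].mean(1, keepdims=True)) ** 2).sum()
                     / 20 + ((vals[:, 5:] - vals[:, 5:].mean(1, keepdims=True)) ** 2).sum()
                     / 20) / (n0 + n1 - 2)
        t_ref, _ = stats.ttest_ind(vals[:, 5:].T, vals[:, :5].T)
        for d0 in (1.0, 4.0, 100.0):
            res = og.moderated_t(mat, groups, d0_override=d0,
                                 s0_sq_override=common_s2)
            np.testing.assert_allclose(res.table["t_mod"], t_ref, atol=1e-8)

    def test_matches_limma_ebayes(self, rng, tmp_path):
        """Dual route: compare hyperparameters, t and p with Bioconductor
        limma on the same matrix."""
        mat, groups = make_matrix(rng, p=40, n0=6, n1=7, shift_first=5)
        res = og.moderated_t(mat, groups)
        csv = tmp_path / "expr.csv"
        pd.DataFrame(mat.values, index=mat.feature_ids).to_csv(csv)
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.csv("{csv}", row.names=1))\n'
            'design <- cbind(Intercept=1, poor=c(rep(0,6), rep(1,7)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(t=fit$t[,"poor"], p=fit$p.value[,"poor"],\n'
            '                  d0=fit$df.prior, s0sq=fit$s2.prior)\n'
            f'write.csv(out, "{tmp_path / "out.csv"}")\n'
        )
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv")
        assert abs(res.d0 - ref["d0"][0]) < 1e-6
        assert abs(res.s0_sq - ref["s0sq"][0]) < 1e-8
        np.testing.assert_allclose(res.table["t_mod"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(res.table["p_value"], ref["p"], atol=1e-8)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(size=(1000, 100)) * rng.uniform(0.5, 2, (1000, 1))
        groups = np.array(["good"] * 50 + ["poor"] * 50)
        mat = og.ExpressionMatrix("l", [f"f{i}" for i in range(1000)],
                                  [f"s{i}" for i in range(100)], vals)
        res = og.moderated_t(mat, groups)
        ks = stats.kstest(res.table["p_value"], "uniform").statistic
        assert ks < 0.05
        reject = (res.table["p_value"] < 0.05).mean()
        assert abs(reject - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_invariant_to_relabeling_and_feature_order(self, rng):
        mat, groups = make_matrix(rng, p=20)
        res = og.moderated_t(mat, groups)
        # permute samples within groups
        idx = np.arange(mat.n_samples)
        g0 = np.nonzero(groups == "good")[0]
        rng.shuffle(g0)
        idx[np.nonzero(groups == "good")[0]] = g0
        mat2 = og.ExpressionMatrix("l", mat.feature_ids,
                                   [mat.sample_ids[i] for i in idx],
                                   mat.values[:, idx])
        res2 = og.moderated_t(mat2, groups[idx])
        np.testing.assert_allclose(res2.table["t_mod"], res.table["t_mod"],
                                   atol=1e-10)
        # reverse feature order
        mat3 = og.ExpressionMatrix("l", mat.feature_ids[::-1],
                                   mat.sample_ids, mat.values[::-1])
        res3 = og.moderated_t(mat3, groups)
        np.testing.assert_allclose(res3.table["t_mod"].to_numpy()[::-1],
                                   res.table["t_mod"], atol=1e-10)

    def test_small_group_rejected(self, rng):
        mat, _ = make_matrix(rng, p=5, n0=1, n1=5)
        groups = np.array(["good"] + ["poor"] * 5)
        with pytest.raises(ValueError, match="at least 2"):
            og.moderated_t(mat, groups)

    def test_homogeneous_variances_give_infinite_d0(self, rng):
        s_sq = np.full(100, 2.0)
        d0, s0 = fit_variance_prior(s_sq, df=10)
        assert np.isinf(d0)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(og.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_equal_p_values_unchanged(self):
        np.testing.assert_allclose(og.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            q = og.bh_adjust(p)
            # quadratic-time step-up definition
            m = len(p)
            order = np.argsort(p)
            brute = np.empty(m)
            for rank, i in enumerate(order, start=1):
                candidates = [p[j] * m / (list(order).index(j) + 1)
                              for j in order[rank - 1:]]
                brute[i] = min(1.0, min(candidates))
            np.testing.assert_allclose(q, brute, atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_monotone_in_p_order(self, rng):
        p = np.sort(rng.random(30))
        q = og.bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            og.bh_adjust([0.5, 1.2])


class TestSelectDE:
    def test_alpha_zero_selects_nothing(self, rng):
        mat, groups = make_matrix(rng)
        res = og.moderated_t(mat, groups)
        assert og.select_de_features(res, alpha=0.0) == []

    def test_top_k_mode_caps_size_by_strength(self, rng):
        mat, groups = make_matrix(rng, p=30, shift_first=10)
        res = og.moderated_t(mat, groups)
        top5 = og.select_de_features(res, top_k=5)
        assert len(top5) == 5
        tab = res.table.set_index("feature_id")
        strengths = tab.loc[top5, "t_mod"].abs().to_numpy()
        assert strengths.min() >= tab["t_mod"].abs().sort_values()[::-1].iloc[5]

    def test_recovers_planted_features_with_fdr_control(self):
        """Strong shifts at n=100: high sensitivity, controlled FDR."""
        sens, fdr = [], []
        for seed in range(5):
            cfg = og.SimConfig(n_samples=100, features_per_layer={"m": 100},
                               de_fraction=0.1, de_effect=2.0,
                               edge_effect_range=(0.0, 0.0), seed=seed)
            cohort, truth = og.simulate_cohort(cfg)
            res = og.moderated_t(cohort.layers["m"], truth.group_labels)
            picked = set(og.select_de_features(res, alpha=0.05))
            true_set = set(truth.de_features["m"])
            sens.append(len(picked & true_set) / len(true_set))
            fdr.append(len(picked - true_set) / max(len(picked), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr) <= 0.1

    def test_all_null_selects_almost_nothing(self):
        counts = []
        for seed in range(5):
            cfg = og.SimConfig(n_samples=100, features_per_layer={"m": 200},
                               de_fraction=0.0, edge_effect_range=(0.0, 0.0),
                               seed=seed)
            cohort, truth = og.simulate_cohort(cfg)
            res = og.moderated_t(cohort.layers["m"], truth.group_labels)
            counts.append(len(og.select_de_features(res, alpha=0.05)))
        assert np.mean(counts) < 2
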