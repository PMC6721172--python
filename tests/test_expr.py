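"""Expression preprocessing, moderated DE, sPLS-DA, rCCA and integration."""

import numpy as np
import pandas as pd
import pytest

from fenet.expr import (
    assign_fe_groups,
    de_trend_test,
    integrate_candidates,
    preprocess_expression,
    rcca_fit,
    splsda_fit,
)


def _meta(n, groups=None, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "group": groups if groups is not None else ["none"] * n,
        "batch": rng.integers(1, 3, n),
        "laboratory": rng.integers(1, 3, n),
    }, index=[f"s{i}" for i in range(n)])


class TestPreprocess:
    def test_detection_threshold_boundary(self):
        n = 104
        raw = pd.DataFrame(np.ones((2, n)) * 6.0, index=["p_keep", "p_drop"],
                           columns=[f"s{i}" for i in range(n)])
        det = pd.DataFrame(False, index=raw.index, columns=raw.columns)
        det.iloc[0, :30] = True      # 30/104 = 28.8% detected -> kept
        det.iloc[1, :20] = True      # 19.2% -> dropped
        probe_map = pd.Series({"p_keep": "gA", "p_drop": "gB"})
        out = preprocess_expression(raw, det, probe_map)
        assert list(out.index) == ["gA"]

    def test_probe_collapse_averages(self):
        raw = pd.DataFrame({"s0": [4.0, 6.0, 5.0]}, index=["p1", "p2", "p3"])
        det = pd.DataFrame(True, index=raw.index, columns=raw.columns)
        probe_map = pd.Series({"p1": "gA", "p2": "gA", "p3": "gB"})
        out = preprocess_expression(raw, det, probe_map)
        assert out.loc["gA", "s0"] == pytest.approx(5.0)

    def test_toy_filter_and_collapse_matches_hand_result(self):
        n = 8
        rng = np.random.default_rng(1)
        probes = [f"p{i}" for i in range(10)]
        raw = pd.DataFrame(rng.normal(6, 1, size=(10, n)), index=probes,
                           columns=[f"s{i}" for i in range(n)])
        det = pd.DataFrame(True, index=probes, columns=raw.columns)
        det.loc["p3"] = False                      # undetected everywhere
        det.loc["p4", :] = [True] + [False] * 7    # 12.5% < 25%
        probe_map = pd.Series(
            {"p0": "gA", "p1": "gA", "p2": "gB", "p3": "gB", "p4": "gC",
             "p5": "gC", "p6": np.nan, "p7": "gD", "p8": "gD", "p9": "gE"})
        out = preprocess_expression(raw, det, probe_map,
                                    control_probes=["p9"])
        assert sorted(out.index) == ["gA", "gB", "gC", "gD"]
        assert np.allclose(out.loc["gA"], raw.loc[["p0", "p1"]].mean())
        assert np.allclose(out.loc["gB"], raw.loc["p2"])   # p3 filtered
        assert np.allclose(out.loc["gC"], raw.loc["p5"])   # p4 filtered
        # control probe p9 removes gE entirely
        assert "gE" not in out.index


class TestDeTrend:
    def _data(self, n_genes=400, n=20, delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        groups = ["HFE"] * (n // 2) + ["LFE"] * (n // 2)
        meta = _meta(n, groups, seed)
        base = rng.normal(7, 1.5, n_genes)
        vals = base[:, None] + rng.normal(0, 0.5, size=(n_genes, n))
        vals[:20, np.array(groups) == "LFE"] += delta
        values = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                              columns=meta.index)
        return values, meta

    def test_prior_df_zero_equals_ordinary_t(self):
        from scipy import stats

        values, meta = self._data(seed=3)
        res = de_trend_test(values, meta, prior_df=0)
        # ordinary per-gene least-squares t for the group contrast
        X = np.column_stack([
            np.ones(len(meta)),
            (meta["group"] == "LFE").to_numpy(float),
            (meta["batch"] == 2).to_numpy(float),
            (meta["laboratory"] == 2).to_numpy(float),
        ])
        XtXi = np.linalg.inv(X.T @ X)
        for g in [0, 7, 123]:
            y = values.iloc[g].to_numpy()
            beta = XtXi @ X.T @ y
            r = y - X @ beta
            df = len(y) - X.shape[1]
            se = np.sqrt(r @ r / df * XtXi[1, 1])
            t = beta[1] / se
            assert res.table["t"].iloc[g] == pytest.approx(t, abs=1e-10)
            assert res.table["p"].iloc[g] == pytest.approx(
                2 * stats.t.sf(abs(t), df), abs=1e-10)

    def test_fold_change_scale(self):
        values, meta = self._data(delta=2.3046, seed=5)
        res = de_trend_test(values, meta)
        fc = res.table["fc"].iloc[:20]
        assert fc.mean() == pytest.approx(2 ** 2.3046, rel=0.1)
        assert 2 ** 2.3046 == pytest.approx(4.94, abs=0.005)
        # sign convention: positive FC = higher in LFE
        assert (fc > 0).all()

    def test_planted_effect_detected(self):
        values, meta = self._data(delta=1.2, seed=6)
        res = de_trend_test(values, meta)
        called = set(res.table.loc[res.table["de"], "gene"])
        assert len(called & {f"g{i}" for i in range(20)}) >= 15
        false_calls = called - {f"g{i}" for i in range(20)}
        assert len(false_calls) <= 3

    def test_null_pvalues_uniform(self):
        pooled = []
        for s in range(5):
            values, meta = self._data(seed=100 + s)
            pooled.append(de_trend_test(values, meta).table["p"].to_numpy())
        from scipy import stats

        ks = stats.kstest(np.concatenate(pooled), "uniform")
        assert ks.pvalue > 0.01


class TestSplsda:
    def _data(self, n=20, p=200, signal=10, effect=3.0, seed=0):
        rng = np.random.default_rng(seed)
        labels = pd.Series(["HFE"] * (n // 2) + ["LFE"] * (n // 2),
                           index=[f"s{i}" for i in range(n)])
        vals = rng.normal(size=(p, n))
        vals[:signal, (labels == "LFE").to_numpy()] += effect
        expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(p)],
                            columns=labels.index)
        return expr, labels

    def test_keepx_equals_p_matches_dense_pls(self):
        """With no sparsity the first weight vector is the dominant left
        singular vector of X'Y (dense PLS-DA)."""
        expr, labels = self._data(seed=2)
        res = splsda_fit(expr, labels, ncomp=1, keepX=[len(expr)], reps=2, seed=0)
        X = expr.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = np.column_stack([(labels == c).astype(float) for c in ("HFE", "LFE")])
        Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        u, s, vt = np.linalg.svd(Xs.T @ Ys, full_matrices=False)
        w_ref = u[:, 0]
        w = res.loadings["comp1"].to_numpy()
        sign = np.sign(w @ w_ref)
        assert np.allclose(w, sign * w_ref, atol=1e-6)

    def test_selected_count_equals_keepx(self):
        expr, labels = self._data(seed=3)
        res = splsda_fit(expr, labels, ncomp=2, keepX=[15, 7], reps=2, seed=0)
        assert len(res.selected[1]) == 15
        assert len(res.selected[2]) == 7

    def test_planted_signal_recovered(self):
        hits, bers = [], []
        for s in range(8):
            expr, labels = self._data(p=500, seed=50 + s)
            res = splsda_fit(expr, labels, ncomp=1, keepX=[10], reps=3, seed=s)
            sel = set(res.selected[1])
            hits.append(len(sel & {f"g{i}" for i in range(10)}))
            bers.append(res.ber[1])
        assert np.mean(hits) >= 8
        assert np.mean(bers) <= 0.15

    def test_permuted_labels_give_chance_ber(self):
        rng = np.random.default_rng(0)
        bers = []
        for s in range(5):
            expr, labels = self._data(signal=0, seed=200 + s)
            perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            res = splsda_fit(expr, perm, ncomp=1, keepX=[20], reps=4, seed=s)
            bers.append(res.ber[1])
        assert np.mean(bers) == pytest.approx(0.5, abs=0.12)

    def test_sign_contract_lfe_up_genes_load_negative(self):
        expr, labels = self._data(signal=10, effect=3.0, seed=9)
        res = splsda_fit(expr, labels, ncomp=1, keepX=[10], reps=2, seed=0)
        planted = res.loadings.loc[[f"g{i}" for i in range(10)], "comp1"]
        nonzero = planted[planted != 0]
        assert (nonzero < 0).all()

    def test_keepx_too_large(self):
        expr, labels = self._data()
        with pytest.raises(ValueError, match="keepX"):
            splsda_fit(expr, labels, keepX=[10_000], reps=2)


class TestRcca:
    def test_single_trait_lambda_zero_equals_multiple_correlation(self):
        rng = np.random.default_rng(1)
        n, p = 40, 10
        genes = rng.normal(size=(p, n))
        w = rng.normal(size=p)
        trait = genes.T @ w + rng.normal(size=n)
        expr = pd.DataFrame(genes, index=[f"g{i}" for i in range(p)],
                            columns=[f"s{i}" for i in range(n)])
        traits = pd.DataFrame({"RFI": trait}, index=expr.columns)
        res = rcca_fit(expr, traits, lambda1=0.0, lambda2=0.0)
        # least-squares oracle: sqrt(R^2) of the trait on all genes
        X = np.column_stack([np.ones(n), genes.T])
        yhat = X @ np.linalg.lstsq(X, trait, rcond=None)[0]
        r2 = 1 - ((trait - yhat) ** 2).sum() / ((trait - trait.mean()) ** 2).sum()
        assert res.canonical_correlations[0] == pytest.approx(np.sqrt(r2), abs=1e-8)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        n = 30
        X = rng.normal(size=(n, 3))
        traits = pd.DataFrame(X, columns=["a", "b", "c"],
                              index=[f"s{i}" for i in range(n)])
        expr = pd.DataFrame(X.T, index=["ga", "gb", "gc"], columns=traits.index)
        res = rcca_fit(expr, traits, lambda1=0.0, lambda2=0.0)
        assert np.allclose(res.canonical_correlations, 1.0, atol=1e-6)

    def test_canonical_correlations_properties(self):
        rng = np.random.default_rng(3)
        n, p = 50, 120
        expr = pd.DataFrame(rng.normal(size=(p, n)),
                            index=[f"g{i}" for i in range(p)],
                            columns=[f"s{i}" for i in range(n)])
        traits = pd.DataFrame(rng.normal(size=(n, 4)),
                              columns=["RFI", "FCR", "ADG", "ADFI"],
                              index=expr.columns)
        res = rcca_fit(expr, traits)
        cc = res.canonical_correlations
        assert ((cc >= 0) & (cc <= 1)).all()
        assert (np.diff(cc) <= 1e-10).all()
        # invariance to gene reordering
        perm = rng.permutation(p)
        res2 = rcca_fit(expr.iloc[perm], traits,
                        lambda1=res.lambdas[0], lambda2=res.lambdas[1])
        assert np.allclose(cc, res2.canonical_correlations, atol=1e-8)

    def test_planted_genes_pass_median_rule(self):
        passes = []
        for s in range(10):
            rng = np.random.default_rng(300 + s)
            n, p, planted = 104, 600, 30
            trait = rng.normal(size=n)
            vals = rng.normal(size=(p, n))
            # planted genes correlate ~0.5 with the RFI-like trait
            vals[:planted] = (0.577 * trait + rng.normal(size=(planted, n))) / 1.155
            expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(p)],
                                columns=[f"s{i}" for i in range(n)])
            traits = pd.DataFrame({
                "RFI": trait, "FCR": 0.7 * trait + 0.7 * rng.normal(size=n),
                "ADG": rng.normal(size=n), "ADFI": rng.normal(size=n),
            }, index=expr.columns)
            res = rcca_fit(expr, traits, key_trait="RFI",
                           select_population="all")
            sel = set(res.selected[1])
            passes.append(len(sel & {f"g{i}" for i in range(planted)}) / planted)
        assert np.mean(passes) >= 0.7

    def test_invalid_inputs(self):
        expr = pd.DataFrame(np.ones((3, 2)), columns=["s0", "s1"])
        traits = pd.DataFrame({"RFI": [1.0, 2.0]}, index=["s0", "s1"])
        with pytest.raises(ValueError, match="3 samples"):
            rcca_fit(expr, traits)
        traits4 = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)),
                               columns=["RFI", "FCR"],
                               index=[f"s{i}" for i in range(5)])
        expr4 = pd.DataFrame(np.random.default_rng(1).normal(size=(4, 5)),
                             columns=traits4.index)
        with pytest.raises(ValueError, match="nonnegative"):
            rcca_fit(expr4, traits4, lambda1=-0.1, lambda2=0.1)


class TestIntegrate:
    def _mk(self, de_genes, spls_genes, rcca_genes, universe):
        from fenet.expr import DEResult, MultivariateResult

        table = pd.DataFrame({
            "gene": universe,
            "de": [g in de_genes for g in universe],
            "p": 0.5, "q": 0.5, "fc": 1.0, "delta": 0.0, "t": 0.0,
        })
        de = DEResult(table=table, prior_df=1.0, prior_var=np.ones(len(universe)))
        rng = np.random.default_rng(0)
        load = pd.DataFrame({"comp1": rng.normal(size=len(universe))},
                            index=universe)
        spls = MultivariateResult(loadings=load, selected={1: spls_genes})
        rcca = MultivariateResult(loadings=load.rename(columns={"comp1": "cc1"}),
                                  selected={1: rcca_genes})
        return de, spls, rcca

    def test_set_logic(self):
        uni = [f"g{i}" for i in range(1, 6)]
        de, spls, rcca = self._mk({"g1", "g2", "g3"}, ["g2", "g3", "g4"],
                                  ["g3", "g5"], uni)
        table, _ = integrate_candidates(de, spls, rcca, min_methods=2)
        assert set(table.loc[table["candidate"], "gene"]) == {"g2", "g3"}
        assert set(table.loc[table["n_methods"] == 3, "gene"]) == {"g3"}

    def test_identical_loadings_concordance_one(self):
        uni = [f"g{i}" for i in range(10)]
        de, spls, rcca = self._mk(set(), uni[:5], uni[:5], uni)
        _, conc = integrate_candidates(de, spls, rcca)
        assert conc == pytest.approx(1.0)


def test_assign_fe_groups_extremes():
    rfi = pd.Series(np.arange(30, dtype=float), index=[f"p{i}" for i in range(30)])
    g = assign_fe_groups(rfi, n_per_group=5)
    assert (g.iloc[:5] == "HFE").all()      # lowest RFI = most efficient
    assert (g.iloc[-5:] == "LFE").all()
    assert (g.iloc[5:-5] == "none").all()
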