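"""Piecewise SEM (paths, d-separation, Fisher's C) and RF importance."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenoflux import attribution, synthetic
from phenoflux.attribution import (SEMSpec, basis_set,
                                   direct_vs_indirect_effects,
                                   fit_piecewise_sem, rf_importance)
from phenoflux.errors import ConfigError, GraphError
from phenoflux.synthetic import CLIMATE_VARS, SiteConfig


def _panel(coef_overrides, n_sites=100, years=10, seed=0, edges=None):
    edges = edges or synthetic.default_flux_edges()
    coefs = {e: 0.0 for e in edges}
    coefs.update(coef_overrides)
    sites = [SiteConfig(f"F{i}", 45, 5, years, 2000) for i in range(n_sites)]
    panel, truths = synthetic.generate_flux_site_panel(sites, coefs,
                                                       seed=seed, edges=edges)
    return panel, truths


class TestSEMSpec:
    def test_default_graph_shape(self):
        spec = SEMSpec.default()
        assert set(spec.endogenous) == {"gppmax", "sos"}
        assert len(spec.edges) == 11
        assert spec.parents("sos") == sorted([*CLIMATE_VARS, "gppmax"])

    def test_cycle_rejected(self):
        with pytest.raises(GraphError):
            SEMSpec(("a", "b"), (("a", "b"), ("b", "a")))

    def test_saturated_graph_has_empty_basis_set(self):
        assert basis_set(SEMSpec.default()) == []

    def test_pruned_graph_basis_claims(self):
        spec = SEMSpec(("t", "g", "s"), (("t", "g"), ("g", "s")))
        claims = basis_set(spec)
        assert claims == [("t", "s", ("g", "t"))] or \
            claims == [("t", "s", ("g",))]


class TestPiecewiseSEM:
    def test_standardized_paths_recovered(self):
        truth = {("temperature", "gppmax"): 0.6,
                 ("radiation", "gppmax"): 0.3,
                 ("gppmax", "sos"): -0.5,
                 ("temperature", "sos"): 0.15}
        panel, truths = _panel(truth, n_sites=200, years=10, seed=1)
        res = fit_piecewise_sem(panel)
        for (u, v), want in truths[0].true_paths.items():
            assert res.coef(u, v) == pytest.approx(want, abs=0.05), (u, v)

    def test_single_predictor_equation_equals_pearson_r(self):
        spec = SEMSpec(("temperature", "gppmax"),
                       (("temperature", "gppmax"),))
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"temperature": rng.normal(size=300)})
        df["gppmax"] = 0.4 * df["temperature"] + rng.normal(size=300)
        res = fit_piecewise_sem(df, spec)
        r = sps.pearsonr(df["temperature"], df["gppmax"])[0]
        assert res.coef("temperature", "gppmax") == pytest.approx(r, abs=1e-10)

    def test_saturated_graph_fisher_degenerate(self):
        panel, _ = _panel({("gppmax", "sos"): -0.5}, n_sites=50, seed=3)
        res = fit_piecewise_sem(panel)
        assert res.fisher_c == 0.0
        assert res.fisher_df == 0
        assert res.accepted

    def test_true_pruned_graph_usually_accepted(self):
        """Data generated from a pruned DAG should pass d-separation."""
        edges = [(c, "gppmax") for c in CLIMATE_VARS] + [("gppmax", "sos")]
        spec = SEMSpec((*CLIMATE_VARS, "gppmax", "sos"), tuple(edges))
        accepted = 0
        for rep in range(20):
            panel, _ = _panel({("temperature", "gppmax"): 0.6,
                               ("gppmax", "sos"): -0.5},
                              n_sites=40, years=5, seed=100 + rep,
                              edges=edges)
            res = fit_piecewise_sem(panel, spec)
            assert res.fisher_df == 2 * len(basis_set(spec))
            accepted += res.accepted
        assert accepted >= 16

    def test_omitted_strong_edge_detected(self):
        """Fitting a graph that omits a strong real edge should be rejected
        by the d-separation test in most replicates."""
        pruned_edges = [(c, "gppmax") for c in CLIMATE_VARS] + \
            [("gppmax", "sos")]
        spec = SEMSpec((*CLIMATE_VARS, "gppmax", "sos"), tuple(pruned_edges))
        rejected = 0
        for rep in range(20):
            panel, _ = _panel({("temperature", "gppmax"): 0.5,
                               ("gppmax", "sos"): -0.4,
                               ("temperature", "sos"): 0.5},
                              n_sites=40, years=5, seed=200 + rep)
            res = fit_piecewise_sem(panel, spec)
            rejected += not res.accepted
        assert rejected >= 18

    def test_cyclic_or_missing_variables_rejected(self):
        panel, _ = _panel({}, n_sites=5, years=3)
        with pytest.raises(ConfigError):
            fit_piecewise_sem(panel.drop(columns=["co2"]))


class TestEffectDecomposition:
    def test_arithmetic_example(self):
        paths = pd.DataFrame([
            {"source": "temperature", "target": "gppmax", "coef": 0.6,
             "se": 0.1, "p": 0.001},
            {"source": "temperature", "target": "sos", "coef": 0.2,
             "se": 0.1, "p": 0.05},
            {"source": "gppmax", "target": "sos", "coef": -0.5,
             "se": 0.1, "p": 0.001},
        ])
        sem = attribution.SEMResult(paths, {}, 0.0, 0, 1.0)
        dec = direct_vs_indirect_effects(sem)
        row = dec[dec.driver == "temperature"].iloc[0]
        assert row.indirect == pytest.approx(-0.3)
        assert row.total == pytest.approx(-0.1)

    def test_zero_mediator_path_kills_indirect(self):
        panel, _ = _panel({("temperature", "gppmax"): 0.6}, n_sites=100,
                          seed=4)
        res = fit_piecewise_sem(panel)
        dec = direct_vs_indirect_effects(res)
        assert np.all(np.abs(dec["indirect"]) <=
                      np.abs(res.coef("gppmax", "sos")))

    def test_totals_match_marginal_regressions(self):
        truth = {("temperature", "gppmax"): 0.6,
                 ("gppmax", "sos"): -0.5,
                 ("temperature", "sos"): 0.2}
        panel, _ = _panel(truth, n_sites=500, years=10, seed=5)
        res = fit_piecewise_sem(panel)
        dec = direct_vs_indirect_effects(res)
        z = (panel - panel.mean(numeric_only=True)) / \
            panel.std(numeric_only=True, ddof=1)
        marg = sps.linregress(z["temperature"], z["sos"]).slope
        row = dec[dec.driver == "temperature"].iloc[0]
        assert row.total == pytest.approx(marg, abs=0.05)


class TestRFImportance:
    def test_planted_dominant_predictor_ranked_first(self):
        rng = np.random.default_rng(6)
        n = 300
        df = pd.DataFrame({c: rng.normal(size=n) for c in CLIMATE_VARS})
        df["gppmax"] = rng.normal(size=n)
        df["sos"] = 0.9 * df["gppmax"] + 0.2 * rng.normal(size=n)
        res = rf_importance(df, ntree=300, mtry=4, seed=0)
        assert res.top() == "gppmax"
        assert res.shares.sum() == pytest.approx(100.0, abs=1e-6)

    def test_null_response_near_uniform_shares(self):
        """With a pure-noise response no predictor's share should exceed
        three times the uniform share in most replicates."""
        rng = np.random.default_rng(7)
        uniform = 100.0 / 6
        ok = 0
        for rep in range(10):
            n = 200
            df = pd.DataFrame({c: rng.normal(size=n) for c in CLIMATE_VARS})
            df["gppmax"] = rng.normal(size=n)
            df["sos"] = rng.normal(size=n)
            res = rf_importance(df, ntree=500, mtry=4, seed=rep)
            ok += res.shares.max() <= 3 * uniform
        assert ok >= 7

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        n = 100
        df = pd.DataFrame({c: rng.normal(size=n) for c in CLIMATE_VARS})
        df["gppmax"] = rng.normal(size=n)
        df["sos"] = 0.5 * df["temperature"] + rng.normal(size=n)
        a = rf_importance(df, ntree=100, mtry=4, seed=3)
        b = rf_importance(df, ntree=100, mtry=4, seed=3)
        pd.testing.assert_series_equal(a.shares, b.shares)

    def test_duplicated_predictor_splits_importance(self):
        rng = np.random.default_rng(9)
        n = 400
        df = pd.DataFrame({c: rng.normal(size=n) for c in CLIMATE_VARS})
        df["gppmax"] = rng.normal(size=n)
        df["sos"] = 0.8 * df["gppmax"] + 0.3 * rng.normal(size=n)
        base = rf_importance(df, ntree=300, mtry=3, seed=2,
                             predictors=("gppmax", "temperature",
                                         "radiation"))
        df["gppmax_copy"] = df["gppmax"]
        dup = rf_importance(df, ntree=300, mtry=3, seed=2,
                            predictors=("gppmax", "gppmax_copy",
                                        "temperature", "radiation"))
        combined = dup.importance["gppmax"] + dup.importance["gppmax_copy"]
        assert combined == pytest.approx(base.importance["gppmax"], rel=0.5)

    def test_mtry_exceeding_predictors_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)),
                          columns=["sos", "gppmax", "temperature"])
        with pytest.raises(ConfigError):
            rf_importance(df, predictors=("gppmax", "temperature"), mtry=4)


class TestFisherCalibration:
    def test_fisher_c_chi_square_under_true_graph(self):
        """On data generated from a pruned true DAG, Fisher's C follows
        chi-square with 2k df: the empirical CDF at the 0.95 quantile stays
        within 0.03 of nominal over many basis-set draws."""
        edges = [(c, "gppmax") for c in CLIMATE_VARS] + [("gppmax", "sos")]
        spec = SEMSpec((*CLIMATE_VARS, "gppmax", "sos"), tuple(edges))
        k = len(basis_set(spec))
        crit = sps.chi2.ppf(0.95, 2 * k)
        coefs = {e: 0.0 for e in edges}
        coefs.update({("temperature", "gppmax"): 0.6,
                      ("radiation", "gppmax"): 0.3,
                      ("gppmax", "sos"): -0.5})
        cs = []
        for rep in range(500):
            sites = [SiteConfig(f"F{i}", 45, 5, 10, 2000) for i in range(20)]
            panel, _ = synthetic.generate_flux_site_panel(
                sites, coefs, seed=rep, edges=edges)
            cs.append(fit_piecewise_sem(panel, spec).fisher_c)
        frac = float(np.mean(np.asarray(cs) <= crit))
        assert frac == pytest.approx(0.95, abs=0.03)
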