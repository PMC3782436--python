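"""SEM engine: implied covariance, ML fitting, fit statistics, effects."""

import numpy as np
import pandas as pd
import pytest

from seasonfire.sem import (
    Covariance,
    Edge,
    PathModel,
    aic,
    bcc,
    chisq_pvalue,
    effects,
    effects_table,
    fit_ml,
    implied_covariance,
    model_spec_text,
    parse_model_spec,
    sample_covariance,
    significance_tier,
)
from seasonfire.simulate import sample_from_path_model


class TestPathModelValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathModel(["a", "b"], [Edge("a", "b"), Edge("b", "a")])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PathModel(["a", "b"], [Edge("a", "b"), Edge("a", "b")])

    def test_endogenous_covariance_rejected(self):
        with pytest.raises(ValueError, match="endogenous"):
            PathModel(["a", "b"], [Edge("a", "b")], [Covariance("a", "b")])

    def test_parameter_counting(self):
        m = PathModel(["x", "z", "y"], [Edge("x", "y"), Edge("z", "y", value=0.3)])
        # 1 free edge + 2 exogenous variances + 1 error variance
        assert m.q == 4
        assert m.df == 6 - 4
        assert m.exogenous == ["x", "z"] and m.endogenous == ["y"]


class TestImpliedCovariance:
    def test_edgeless_unit_variance_model_gives_identity(self):
        m = PathModel(["a", "b", "c"], [])
        theta = {"var:a": 1.0, "var:b": 1.0, "var:c": 1.0}
        assert np.allclose(implied_covariance(m, theta), np.eye(3))

    def test_single_edge_hand_algebra(self):
        m = PathModel(["x", "y"], [Edge("x", "y")])
        theta = {"beta:x->y": 0.8, "var:x": 1.0, "err:y": 0.5}
        sigma = implied_covariance(m, theta)
        assert sigma[0, 0] == pytest.approx(1.0)
        assert sigma[0, 1] == pytest.approx(0.8)
        assert sigma[1, 1] == pytest.approx(0.8**2 + 0.5)

    def test_matches_monte_carlo_draws(self):
        # independent simulation oracle: draw the structural system directly
        m = PathModel(
            ["u", "v", "w", "y"],
            [Edge("u", "w"), Edge("v", "w"), Edge("w", "y"), Edge("u", "y")],
            [Covariance("u", "v")],
        )
        theta = {
            "beta:u->w": 0.6, "beta:v->w": -0.4, "beta:w->y": 0.7, "beta:u->y": -0.3,
            "var:u": 1.3, "var:v": 0.9, "cov:u~~v": 0.35, "err:w": 0.8, "err:y": 0.6,
        }
        sigma = implied_covariance(m, theta)
        rng = np.random.default_rng(12)
        n = 1_000_000
        L = np.linalg.cholesky(np.array([[1.3, 0.35], [0.35, 0.9]]))
        uv = rng.standard_normal((n, 2)) @ L.T
        u, v = uv[:, 0], uv[:, 1]
        w = 0.6 * u - 0.4 * v + rng.normal(0, np.sqrt(0.8), n)
        y = 0.7 * w - 0.3 * u + rng.normal(0, np.sqrt(0.6), n)
        S_mc = np.cov(np.column_stack([u, v, w, y]), rowvar=False)
        assert np.allclose(sigma, S_mc, atol=0.012)


class TestFitML:
    def test_saturated_model_fits_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 3)) @ rng.uniform(0.5, 1.5, (3, 3))
        S = np.cov(X, rowvar=False)
        m = PathModel(
            ["a", "b", "c"],
            [Edge("a", "b"), Edge("a", "c"), Edge("b", "c")],
        )
        fit = fit_ml(S, m, 200)
        assert fit.df == 0
        assert fit.chisq == pytest.approx(0.0, abs=1e-6)
        assert fit.pvalue is None

    def test_simple_regression_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2.0, 500)
        y = 1.4 * x + rng.normal(0, 1.0, 500)
        df = pd.DataFrame({"x": x, "y": y})
        S = sample_covariance(df)
        fit = fit_ml(S, PathModel(["x", "y"], [Edge("x", "y")]), 500)
        assert fit.estimates["beta:x->y"] == pytest.approx(S[0, 1] / S[0, 0], abs=1e-6)
        r = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        assert fit.standardized["x->y"] == pytest.approx(r, abs=1e-6)
        assert fit.r2_endogenous("y") == pytest.approx(r**2, abs=1e-6)

    def test_parameter_recovery_on_five_variable_model(self, dry_best, dry_best_skeleton):
        data = sample_from_path_model(dry_best, 10_000, seed=99)
        fit = fit_ml(sample_covariance(data), dry_best_skeleton, 10_000)
        true = {e.name: e.value for e in dry_best.model.edges}
        for name, value in fit.standardized.items():
            assert value == pytest.approx(true[name], abs=0.04)

    def test_standardized_invariant_to_rescaling(self, dry_best, dry_best_skeleton):
        data = sample_from_path_model(dry_best, 800, seed=5)
        fit1 = fit_ml(sample_covariance(data), dry_best_skeleton, 800)
        scaled = data.copy()
        scaled["rainfall"] *= 13.0
        scaled["nino"] *= 0.2
        fit2 = fit_ml(sample_covariance(scaled), dry_best_skeleton, 800)
        for name in fit1.standardized:
            assert fit2.standardized[name] == pytest.approx(fit1.standardized[name], abs=1e-5)
        assert fit2.chisq == pytest.approx(fit1.chisq, abs=1e-5)

    def test_nesting_monotonicity_adding_edge_never_raises_chisq(self, dry_best):
        data = sample_from_path_model(dry_best, 300, seed=17)
        S = sample_covariance(data)
        smaller = PathModel(
            dry_best.model.variables,
            [Edge("onset", "duration"), Edge("duration", "rainfall"), Edge("rainfall", "tc")],
        )
        bigger = PathModel(
            dry_best.model.variables,
            smaller.edges + [Edge("nino", "rainfall")],
        )
        f_small = fit_ml(S, smaller, 300)
        f_big = fit_ml(S, bigger, 300)
        assert f_big.chisq <= f_small.chisq + 1e-6

    def test_non_pd_covariance_rejected(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError, match="positive definite"):
            fit_ml(S, PathModel(["x", "y"], [Edge("x", "y")]), 50)

    def test_r2_limits(self):
        # near-deterministic relation drives R^2 toward 1
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        y = 2.0 * x + rng.normal(0, 0.01, 400)
        S = sample_covariance(pd.DataFrame({"x": x, "y": y}))
        fit = fit_ml(S, PathModel(["x", "y"], [Edge("x", "y")]), 400)
        assert fit.r2_endogenous("y") > 0.99
        with pytest.raises(ValueError):
            fit.r2_endogenous("x")


class TestFitStatistics:
    @pytest.mark.parametrize(
        "chisq, df, expected, places",
        [(2.0, 3, 0.57, 2), (18.2, 5, 0.003, 3)],
    )
    def test_published_chisq_pvalues(self, chisq, df, expected, places):
        assert round(chisq_pvalue(chisq, df), places) == expected

    @pytest.mark.parametrize("df", [1, 4, 10])
    def test_zero_statistic_gives_p_one(self, df):
        assert chisq_pvalue(0.0, df) == pytest.approx(1.0)

    def test_df_zero_is_undefined(self):
        with pytest.raises(ValueError):
            chisq_pvalue(1.0, 0)

    def test_bcc_worked_value_and_penalty(self):
        assert bcc(10.0, 5, 58, 5) == pytest.approx(10 + 10 * 57 / 51, abs=1e-9)
        assert bcc(7.0, 0, 58, 5) == pytest.approx(7.0)
        # per-parameter penalty always exceeds AIC's
        for n, p in [(30, 5), (58, 5), (1000, 8)]:
            assert bcc(0.0, 1, n, p) - 0.0 > aic(0.0, 1) - 0.0 - 2 + 2 * 0  # 2(n-1)/(n-p-2) > 2
            assert 2 * (n - 1) / (n - p - 2) > 2
        with pytest.raises(ValueError):
            bcc(1.0, 2, 7, 5)

    def test_significance_tiers_match_figure_coding(self):
        assert significance_tier(0.0005) == "thick"
        assert significance_tier(0.005) == "medium"
        assert significance_tier(0.03) == "thin"
        assert significance_tier(0.08) == "gray"
        assert significance_tier(0.5) == "dashed"


class TestEffects:
    def test_edgeless_model_has_all_zero_effects(self):
        table = effects_table(PathModel(["a", "b", "c"], []))
        assert (table[["direct", "indirect", "total"]] == 0).all().all()

    def test_total_is_direct_plus_indirect_everywhere(self, dry_best):
        table = effects_table(dry_best.model)
        assert np.allclose(table["total"], table["direct"] + table["indirect"], atol=1e-12)

    def test_two_edge_path_is_product_of_coefficients(self, dry_best):
        row = effects(dry_best.model, "onset", "rainfall")
        assert row["direct"] == 0.0
        assert row["indirect"] == pytest.approx(-0.69 * 0.46, abs=1e-12)

    def test_matches_exhaustive_path_enumeration(self):
        import itertools
        import networkx as nx

        rng = np.random.default_rng(21)
        names = list("abcdef")
        edges = []
        for i, j in itertools.combinations(range(6), 2):
            if rng.random() < 0.5:
                edges.append(Edge(names[i], names[j], value=float(rng.uniform(-0.6, 0.6))))
        model = PathModel(names, edges)
        table = effects_table(model)
        g = nx.DiGraph()
        g.add_nodes_from(names)
        weights = {}
        for e in edges:
            g.add_edge(e.source, e.target)
            weights[(e.source, e.target)] = e.value
        for src in names:
            for tgt in names:
                if src == tgt:
                    continue
                total = 0.0
                for path in nx.all_simple_paths(g, src, tgt):
                    prod = 1.0
                    for a, b in zip(path, path[1:]):
                        prod *= weights[(a, b)]
                    total += prod
                assert table.loc[(src, tgt), "total"] == pytest.approx(total, abs=1e-10)

    def test_unknown_variable_raises(self, dry_best):
        with pytest.raises(ValueError):
            effects(dry_best.model, "onset", "nope")


class TestModelSpecFormat:
    def test_round_trip(self, dry_best):
        text = model_spec_text(dry_best.model, role="fitted-best")
        model, meta = parse_model_spec(text, name="roundtrip")
        assert model.variables == dry_best.model.variables
        assert [(e.source, e.target, e.value) for e in model.edges] == [
            (e.source, e.target, e.value) for e in dry_best.model.edges
        ]
        assert meta["role"] == "fitted-best"

    def test_bad_line_raises(self):
        with pytest.raises(ValueError):
            parse_model_spec("vars a b\na => b free\n")
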