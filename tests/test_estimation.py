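"""Midpoint imputation, pair building and multinomial-logit estimation."""

import numpy as np
import pandas as pd
import pytest

import multistate_aging as ma
from multistate_aging.estimation import (
    COG_FORBIDDEN,
    COGNITIVE,
    FUN_FORBIDDEN,
    FUNCTIONAL,
    MissingOriginError,
    TransitionModelCoefficients,
    build_rate_table,
    build_transition_pairs,
    fit_transition_model,
    impute_midpoint_state,
    predict_transition_probs,
)
from multistate_aging.mnlogit import fit_mnlogit, softmax_reference
from multistate_aging.states import Cognition


def _alive_survey(n, cog="INTACT", fun="ACTIVE", cog2=None, fun2=None, age=70):
    return pd.DataFrame(
        {
            "respondent_id": [f"r{i}" for i in range(n)],
            "sex": ["female"] * n,
            "age_w1": age,
            "weight": 1.0,
            "cog_w1": cog,
            "fun_w1": fun,
            "cog_w2": cog2 or cog,
            "fun_w2": fun2 or fun,
            "dead_w2": 0,
        }
    )


class TestMidpointImputation:
    def test_identical_waves_are_carried_through(self):
        rng = np.random.default_rng(0)
        for s in (Cognition.MILD, "ACTIVE"):
            assert impute_midpoint_state(s, s, rng) == s

    def test_differing_waves_split_fifty_fifty(self):
        """The 50/50 rule, checked by Monte Carlo against a counting oracle."""
        rng = np.random.default_rng(123)
        draws = [impute_midpoint_state("INTACT", "MILD", rng) for _ in range(10_000)]
        freq = draws.count("INTACT") / 10_000
        assert abs(freq - 0.5) < 0.02

    def test_death_is_an_admissible_midpoint(self):
        rng = np.random.default_rng(5)
        draws = {impute_midpoint_state("SEVERE", "DEAD", rng) for _ in range(100)}
        assert draws == {"SEVERE", "DEAD"}


class TestPairBuilding:
    def test_stable_respondents_give_two_identity_pairs(self):
        pairs = build_transition_pairs(
            _alive_survey(1), COGNITIVE, np.random.default_rng(0)
        )
        assert len(pairs) == 2
        assert (pairs["origin"] == pairs["dest"]).all()
        assert sorted(pairs["age"]) == [70, 71]

    def test_alive_survey_yields_exactly_2n_pairs(self):
        n = 500
        survey = _alive_survey(n, cog2="MILD")
        pairs = build_transition_pairs(survey, COGNITIVE, np.random.default_rng(1))
        assert len(pairs) == 2 * n

    def test_dead_midpoint_truncates_to_one_pair(self):
        survey = _alive_survey(200)
        survey["dead_w2"] = 1
        survey["cog_w2"] = ""
        survey["fun_w2"] = ""
        pairs = build_transition_pairs(survey, COGNITIVE, np.random.default_rng(2))
        per_resp = pairs.groupby("respondent_id").size()
        # midpoint death (p=1/2) leaves a single wave1->DEAD pair
        assert set(per_resp) == {1, 2}
        assert abs((per_resp == 1).mean() - 0.5) < 0.12
        dead_idx = 4
        assert (pairs.groupby("respondent_id")["dest"].max() == dead_idx).all()

    def test_functional_ci_uses_interval_start_cognition(self):
        # wave1 intact, wave2 mild: first interval must carry ci=0
        survey = _alive_survey(300, cog2="MILD", fun2="ADL12")
        pairs = build_transition_pairs(survey, FUNCTIONAL, np.random.default_rng(3))
        first = pairs[pairs["age"] == 70]
        second = pairs[pairs["age"] == 71]
        assert (first["ci"] == 0).all()
        assert 0.3 < second["ci"].mean() < 0.7  # midpoint cognition is the coin

    def test_empty_survey_warns_and_returns_empty(self, caplog):
        empty = _alive_survey(0)
        with caplog.at_level("WARNING"):
            pairs = build_transition_pairs(empty, COGNITIVE, np.random.default_rng(0))
        assert pairs.empty

    def test_determinism_bit_identical(self, realistic):
        survey = ma.generate_survey(realistic, ma.GeneratorConfig(n_respondents=400), seed=9)
        a = build_transition_pairs(survey, FUNCTIONAL, np.random.default_rng(7))
        b = build_transition_pairs(survey, FUNCTIONAL, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_lost_to_followup_dropped_with_count(self, caplog):
        survey = _alive_survey(10)
        survey.loc[3, "cog_w2"] = ""
        with caplog.at_level("WARNING"):
            pairs = build_transition_pairs(survey, COGNITIVE, np.random.default_rng(0))
        assert "1 respondents lost to follow-up" in caplog.text
        assert pairs["respondent_id"].nunique() == 9


class TestMNLogit:
    def test_binary_intercept_equals_empirical_logit(self):
        """Closed-form weighted-MLE oracle for a stay/die toy."""
        rng = np.random.default_rng(0)
        n = 4000
        y = (rng.random(n) < 0.23).astype(int)
        w = rng.uniform(0.5, 2.0, size=n)
        res = fit_mnlogit(np.ones((n, 1)), y, weights=w)
        d = w[y == 1].sum() / w.sum()
        assert res.converged
        assert abs(res.coef[0, 0] - np.log(d / (1 - d))) < 1e-6

    def test_against_sklearn_reference(self):
        """Independent cross-check of the solver on a 3-class problem."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(1)
        n = 3000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
        beta = np.array([[-1.0, 0.5, -0.3], [-2.0, -0.4, 0.8]])
        p = softmax_reference(X @ beta.T)
        y = (rng.random(n)[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
        ours = fit_mnlogit(X, y, n_classes=3)
        sk = sklearn.LogisticRegression(
            C=np.inf, tol=1e-10, max_iter=2000
        ).fit(X[:, 1:], y)
        # sklearn's symmetric softmax: reference-category form is the difference
        sk_coef = np.column_stack(
            [sk.intercept_[1:] - sk.intercept_[0], sk.coef_[1:] - sk.coef_[0]]
        )
        assert np.allclose(ours.coef, sk_coef, atol=1e-4)

    def test_symmetric_softmax_under_null_truth(self):
        """With all coefficients zero and 4 destinations, p is 1/5 everywhere."""
        rng = np.random.default_rng(2)
        n = 20_000
        y = rng.integers(0, 5, size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        res = fit_mnlogit(X, y, n_classes=5)
        p = softmax_reference(np.zeros((1, 4)) + res.coef[:, 0])[0]
        assert np.all(np.abs(p - 0.2) < 0.02)


class TestFittedModels:
    def test_rate_table_rows_and_structural_zeros(self, fitted_models):
        _, cog, fun = fitted_models
        table = build_rate_table(cog, fun)
        table.validate(atol=1e-12)
        assert np.all(table.cog[..., COG_FORBIDDEN] == 0.0)
        assert np.all(table.fun[..., FUN_FORBIDDEN] == 0.0)

    def test_prediction_matches_bruteforce_softmax(self, fitted_models):
        """Direct re-evaluation oracle at age 80, female."""
        _, cog, _ = fitted_models
        oc = cog.origins["MILD"]
        x = np.array([1.0, 0.0, 0.0, 1.0])  # age 80 centred, female
        eta = oc.coef @ x
        expected = np.exp(eta) / (1 + np.exp(eta).sum())
        got = predict_transition_probs(cog, "MILD", 80, sex=1)
        for d, dest in enumerate(oc.destinations):
            assert got[dest] == pytest.approx(expected[d], abs=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)
        assert got["MILD"] == pytest.approx(1 - expected.sum(), abs=1e-12)

    def test_structurally_forbidden_destinations_exactly_zero(self, fitted_models):
        _, cog, fun = fitted_models
        assert predict_transition_probs(cog, "SEVERE", 75, sex=0)["INTACT"] == 0.0
        assert predict_transition_probs(fun, "ADL3", 75, sex=0, ci=1)["ACTIVE"] == 0.0

    def test_age_open_interval_capped_at_100(self, fitted_models):
        _, cog, fun = fitted_models
        table = build_rate_table(cog, fun)
        p100 = predict_transition_probs(cog, "INTACT", 100, sex=1)
        p120 = predict_transition_probs(cog, "INTACT", 120, sex=1)
        pd.testing.assert_series_equal(p100, p120)
        np.testing.assert_allclose(
            table.cog[1, -1, 0, :4].sum() + table.cog[1, -1, 0, 4],
            p100.sum(),
            atol=1e-12,
        )

    def test_table_row_is_definitionally_the_prediction(self, fitted_models):
        _, cog, fun = fitted_models
        table = build_rate_table(cog, fun)
        pred = predict_transition_probs(cog, "INTACT", 65, sex=1)
        row = table.cog[1, 0, 0]
        labels = ("INTACT", "MILD", "MODERATE", "SEVERE", "DEAD")
        np.testing.assert_allclose(row, [pred[l] for l in labels], atol=1e-15)

    def test_predict_rejects_unknown_origin_and_young_age(self, fitted_models):
        _, cog, _ = fitted_models
        with pytest.raises(ValueError, match="unknown origin"):
            predict_transition_probs(cog, "ACTIVE", 70, sex=0)
        with pytest.raises(ValueError, match="age"):
            predict_transition_probs(cog, "INTACT", 60, sex=0)

    def test_missing_origin_is_an_explicit_error(self):
        pairs = pd.DataFrame(
            {
                "respondent_id": ["a", "b"],
                "origin": [0, 0],
                "dest": [0, 1],
                "age": [70, 70],
                "sex": [0, 1],
                "ci": [-1, -1],
                "weight": [1.0, 1.0],
            }
        )
        with pytest.raises(MissingOriginError, match="MILD"):
            fit_transition_model(pairs, COGNITIVE)

    def test_unobserved_destination_pinned_near_zero(self, caplog):
        # INTACT pairs that only ever stay or die: MILD/MODERATE/SEVERE unseen
        rng = np.random.default_rng(0)
        n = 800
        dest = np.where(rng.random(n) < 0.1, 4, 0)
        pairs = pd.DataFrame(
            {
                "respondent_id": [f"r{i}" for i in range(n)],
                "origin": 0,
                "dest": dest,
                "age": rng.integers(65, 100, n),
                "sex": rng.integers(0, 2, n),
                "ci": -1,
                "weight": 1.0,
            }
        )
        # give the other origins a token pair so the model is estimable
        extra = pd.DataFrame(
            {
                "respondent_id": ["x1", "x2", "x3"],
                "origin": [1, 2, 3],
                "dest": [1, 2, 3],
                "age": [70, 70, 70],
                "sex": [0, 0, 0],
                "ci": [-1, -1, -1],
                "weight": [1.0, 1.0, 1.0],
            }
        )
        with caplog.at_level("WARNING"):
            model = fit_transition_model(pd.concat([pairs, extra]), COGNITIVE)
        assert "pinned" in caplog.text
        probs = predict_transition_probs(model, "INTACT", 80, sex=0)
        assert probs["MILD"] < 1e-6
        assert probs["DEAD"] > 0.05

    def test_natural_scale_roundtrip(self, fitted_models):
        """Natural-scale CSV coefficients reproduce the same probabilities."""
        _, cog, fun = fitted_models
        frame = pd.concat([cog.natural_frame(), fun.natural_frame()])
        cog2 = TransitionModelCoefficients.from_natural_frame(frame, COGNITIVE)
        fun2 = TransitionModelCoefficients.from_natural_frame(frame, FUNCTIONAL)
        t1 = build_rate_table(cog, fun)
        t2 = build_rate_table(cog2, fun2)
        np.testing.assert_allclose(t1.cog, t2.cog, atol=1e-9)
        np.testing.assert_allclose(t1.fun, t2.fun, atol=1e-9)

    def test_fit_determinism(self, realistic):
        survey = ma.generate_survey(realistic, ma.GeneratorConfig(n_respondents=1000), seed=3)
        coefs = []
        for _ in range(2):
            rng = np.random.default_rng(21)
            model = fit_transition_model(
                build_transition_pairs(survey, COGNITIVE, rng), COGNITIVE
            )
            coefs.append(np.concatenate([model.origins[o].coef.ravel() for o in model.origins]))
        assert np.array_equal(coefs[0], coefs[1])


class TestRecoverySanity:
    """Single-process recovery at calibrated statistical tolerances.

    The precision of the solver itself is pinned elsewhere (closed-form
    binary MLE, sklearn cross-check); here we check that fitting pairs
    simulated directly from a truth kernel recovers it to within a few
    standard errors (sex/CI coefficients of rare cells have SE ~ 0.1 at
    this size).
    """

    def test_direct_pair_recovery(self, realistic, truth_table):
        rng = np.random.default_rng(17)
        n = 20_000
        sex = rng.integers(0, 2, n)
        ages = np.clip(65 + np.floor(rng.beta(1.2, 2.0, n) * 36).astype(int), 65, 100)
        origin = (rng.random(n)[:, None] > np.cumsum([0.4, 0.3, 0.2, 0.1])).sum(1)
        rows = truth_table.cog[sex, ages - 65, origin]
        dest = (rng.random(n)[:, None] > np.cumsum(rows, axis=1)).sum(1)
        pairs = pd.DataFrame(
            {
                "respondent_id": "x",
                "origin": origin,
                "dest": dest,
                "age": ages,
                "sex": sex,
                "ci": -1,
                "weight": 1.0,
            }
        )
        fit = fit_transition_model(pairs, COGNITIVE)
        for o, oc in fit.origins.items():
            err = np.abs(oc.coef - realistic.cognitive.origins[o].coef)
            assert err.max() < 0.5, f"{o}: {err.max():.3f}"
        # implied probabilities are tighter than the coefficients; the bound
        # is ~1.5 SE for the worst cell (severe origin, age 90, ~2k pairs)
        fitted = build_rate_table(fit, realistic.functional)
        for a in (5, 15, 25):
            assert np.abs(fitted.cog[:, a] - truth_table.cog[:, a]).max() < 0.08
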