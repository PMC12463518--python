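import itertools

import numpy as np
import pandas as pd
import pytest

from edflow.doe import Factor, full_factorial
from edflow.effects import (
    SingularDesignError,
    anova,
    effect_summaries,
    fit_ols,
    format_equation,
    format_p,
    standard_terms,
    term_name,
)

ADULT_FACTORS = {"TriageBed": (1, 2, 3), "ZoneNurse": (7, 9, 11), "ZoneBed": (20, 26, 32)}
PEDS_FACTORS = {"TriageBed": (1, 2, 3), "ZoneNurse": (5, 7, 9), "ZoneBed": (8, 10, 12)}

#: printed staffing equations: intercept + term coefficients, by response
ADULT_ATD = {
    "Intercept": 10.71,
    ("ZoneNurse",): -0.375,
    ("ZoneBed",): 0.490,
    ("TriageBed",): 43.77,
    ("ZoneNurse", "ZoneBed"): 0.1563,
    ("ZoneNurse", "TriageBed"): -1.937,
    ("ZoneBed", "TriageBed"): -0.9792,
}
ADULT_LOS = {
    "Intercept": -35.0,
    ("ZoneNurse",): 15.04,
    ("ZoneBed",): 4.68,
    ("TriageBed",): 52.6,
    ("ZoneNurse", "ZoneBed"): -0.365,
    ("ZoneNurse", "TriageBed"): -2.563,
    ("ZoneBed", "TriageBed"): -1.062,
}
PEDS_LOS = {
    "Intercept": 192.0,
    ("TriageBed",): 4.2,
    ("ZoneNurse",): -9.8,
    ("ZoneBed",): 0.2,
    ("TriageBed", "ZoneNurse"): -0.89,
    ("TriageBed", "ZoneBed"): -0.26,
    ("ZoneNurse", "ZoneBed"): -0.09,
    ("TriageBed", "ZoneNurse", "ZoneBed"): 0.060,
}
PEDS_ATD = {
    "Intercept": 86.5,
    ("TriageBed",): 1.8,
    ("ZoneNurse",): -6.17,
    ("ZoneBed",): -2.56,
    ("TriageBed", "ZoneNurse"): -0.42,
    ("TriageBed", "ZoneBed"): -0.09,
    ("ZoneNurse", "ZoneBed"): 0.303,
    ("TriageBed", "ZoneNurse", "ZoneBed"): 0.026,
}


def design_frame(factor_levels):
    names = list(factor_levels)
    rows = [dict(zip(names, combo)) for combo in itertools.product(*factor_levels.values())]
    return pd.DataFrame(rows)


def evaluate(frame, equation):
    y = np.full(len(frame), float(equation["Intercept"]))
    for term, coef in equation.items():
        if term == "Intercept":
            continue
        col = np.ones(len(frame))
        for f in term:
            col = col * frame[f].to_numpy(float)
        y += coef * col
    return y


@pytest.mark.parametrize(
    "levels,equation,response",
    [
        (ADULT_FACTORS, ADULT_ATD, "AtD"),
        (ADULT_FACTORS, ADULT_LOS, "LOS"),
        (PEDS_FACTORS, PEDS_LOS, "LOS"),
        (PEDS_FACTORS, PEDS_ATD, "AtD"),
    ],
    ids=["adult-AtD", "adult-LOS", "peds-LOS", "peds-AtD"],
)
def test_noiseless_recovery_of_reported_equations(levels, equation, response):
    frame = design_frame(levels)
    frame[response] = evaluate(frame, equation)
    terms = [t for t in equation if t != "Intercept"]
    fit = fit_ols(frame, terms, response)
    assert fit.intercept == pytest.approx(equation["Intercept"], abs=1e-8)
    for term in terms:
        assert fit.coef[term_name(term)] == pytest.approx(equation[term], abs=1e-8)
    assert fit.r2 == pytest.approx(100.0, abs=1e-8)


def test_ols_matches_normal_equations_oracle():
    frame = design_frame(ADULT_FACTORS)
    rng = np.random.default_rng(0)
    frame["y"] = evaluate(frame, ADULT_LOS) + rng.normal(0, 5, len(frame))
    terms = standard_terms(["TriageBed", "ZoneNurse", "ZoneBed"])
    fit = fit_ols(frame, terms, "y")

    # brute-force (X'X)^-1 X'y
    X = np.column_stack(
        [np.ones(len(frame))]
        + [np.prod([frame[f].to_numpy(float) for f in t], axis=0) for t in terms]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ frame["y"].to_numpy())
    got = [fit.intercept] + [fit.coef[term_name(t)] for t in terms]
    np.testing.assert_allclose(got, beta, atol=1e-8)


def test_constant_response_zero_slopes():
    frame = design_frame(ADULT_FACTORS)
    frame["y"] = 7.5
    fit = fit_ols(frame, standard_terms(list(ADULT_FACTORS)), "y")
    assert fit.intercept == pytest.approx(7.5, abs=1e-9)
    for term in fit.terms:
        assert fit.coef[term_name(term)] == pytest.approx(0.0, abs=1e-9)


def test_monte_carlo_coefficient_recovery():
    """Average estimate over 100 noisy refits within 4 pooled standard
    errors of the generating coefficients."""
    frame = design_frame(ADULT_FACTORS)
    truth = ADULT_LOS
    terms = [t for t in truth if t != "Intercept"]
    signal = evaluate(frame, truth)
    rng = np.random.default_rng(42)
    n_sims, reps, sigma = 100, 10, 10.0

    sums = {term_name(t): 0.0 for t in terms}
    se_ref = None
    for _ in range(n_sims):
        data = frame.loc[frame.index.repeat(reps)].reset_index(drop=True)
        data["y"] = np.repeat(signal, reps) + rng.normal(0, sigma, len(data))
        fit = fit_ols(data, terms, "y")
        for t in terms:
            sums[term_name(t)] += fit.coef[term_name(t)]
        se_ref = fit.se
    for t in terms:
        name = term_name(t)
        avg = sums[name] / n_sims
        assert abs(avg - truth[t]) < 4 * se_ref[name] / np.sqrt(n_sims), name


def test_rank_deficiency_reported_with_aliased_terms():
    # a two-level factor aliases its square with the A + intercept span
    frame = design_frame({"A": (1, 2), "B": (1, 2, 3)})
    with pytest.raises(SingularDesignError, match="aliased"):
        fit_ols(frame.assign(y=1.0), [("A",), ("A", "A")], "y")


def test_point_means_same_coefficients():
    frame = design_frame(ADULT_FACTORS)
    rng = np.random.default_rng(1)
    data = frame.loc[frame.index.repeat(4)].reset_index(drop=True)
    data["y"] = evaluate(data, ADULT_LOS) + rng.normal(0, 3, len(data))
    terms = [t for t in ADULT_LOS if t != "Intercept"]
    f_rep = fit_ols(data, terms, "y")
    f_avg = fit_ols(data, terms, "y", point_means=True)
    for t in terms:
        assert f_rep.coef[term_name(t)] == pytest.approx(f_avg.coef[term_name(t)], abs=1e-8)


def test_r2_invariant_to_response_rescaling():
    frame = design_frame(ADULT_FACTORS)
    rng = np.random.default_rng(2)
    frame["y"] = evaluate(frame, ADULT_LOS) + rng.normal(0, 20, len(frame))
    frame["y2"] = 3.5 * frame["y"] - 100.0
    terms = standard_terms(list(ADULT_FACTORS))
    assert fit_ols(frame, terms, "y").r2 == pytest.approx(
        fit_ols(frame, terms, "y2").r2, abs=1e-9
    )


def test_coded_main_effect_sign_matches_level_means():
    frame = design_frame(ADULT_FACTORS)
    rng = np.random.default_rng(7)
    data = frame.loc[frame.index.repeat(5)].reset_index(drop=True)
    data["y"] = 100 - 8.0 * data["ZoneNurse"] + 1.5 * data["ZoneBed"] + rng.normal(0, 4, len(data))
    fit = fit_ols(data, standard_terms(list(ADULT_FACTORS)), "y", coded=True)
    for factor in ADULT_FACTORS:
        means = data.groupby(factor)["y"].mean()
        slope_sign = np.sign(means.iloc[-1] - means.iloc[0])
        assert np.sign(fit.coef[factor]) == slope_sign


class TestAnova:
    def test_null_term_p_roughly_uniform(self):
        # reduced-size type-I check; the full 2000-run calibration lives
        # in the acceptance suite
        frame = design_frame(ADULT_FACTORS)
        terms = standard_terms(list(ADULT_FACTORS))
        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            data = frame.loc[frame.index.repeat(5)].reset_index(drop=True)
            data["y"] = rng.normal(0, 1, len(data))
            table = anova(fit_ols(data, terms, "y")).table
            p = float(table.loc[table["term"] == "ZoneNurse", "p"].iloc[0])
            rejections += p < 0.05
        assert 0.02 < rejections / n_sims < 0.09

    def test_power_on_planted_effect(self):
        frame = design_frame(ADULT_FACTORS)
        rng = np.random.default_rng(5)
        data = frame.loc[frame.index.repeat(10)].reset_index(drop=True)
        data["y"] = 10.0 * data["ZoneNurse"] + rng.normal(0, 1, len(data))
        table = anova(fit_ols(data, standard_terms(list(ADULT_FACTORS)), "y")).table
        p = dict(zip(table["term"], table["p"]))
        assert p["ZoneNurse"] < 1e-3
        assert p["TriageBed"] > 0.01  # null factor not spuriously tiny

    def test_noiseless_fit_degenerate_not_crash(self):
        frame = design_frame(ADULT_FACTORS)
        frame["y"] = evaluate(frame, ADULT_ATD)
        terms = [t for t in ADULT_ATD if t != "Intercept"]
        result = anova(fit_ols(frame, terms, "y"))
        assert result.degenerate
        assert np.isinf(result.table["F"]).all()

    def test_saturated_model_raises(self):
        frame = design_frame({"A": (0, 1)})
        frame["y"] = [1.0, 2.0]
        fit = fit_ols(frame, [("A",)], "y")
        with pytest.raises(ValueError, match="saturated"):
            anova(fit)

    def test_model_level_f(self):
        frame = design_frame(ADULT_FACTORS)
        rng = np.random.default_rng(9)
        data = frame.loc[frame.index.repeat(5)].reset_index(drop=True)
        data["y"] = 3.0 * data["ZoneBed"] + rng.normal(0, 1, len(data))
        result = anova(fit_ols(data, standard_terms(list(ADULT_FACTORS)), "y"))
        assert result.model_f > 100
        assert result.model_p < 1e-6


class TestEffectSummaries:
    def test_dominant_factor_ranks_first(self):
        frame = design_frame(ADULT_FACTORS)
        rng = np.random.default_rng(3)
        data = frame.loc[frame.index.repeat(8)].reset_index(drop=True)
        data["y"] = -20.0 * data["ZoneNurse"] + 0.5 * data["ZoneBed"] + rng.normal(0, 5, len(data))
        fit = fit_ols(data, standard_terms(list(ADULT_FACTORS)), "y", coded=True)
        summary = effect_summaries(data, fit)
        assert summary.pareto.iloc[0]["term"] == "ZoneNurse"
        effects = summary.pareto["standardized_effect"].to_numpy()
        assert (np.diff(effects) <= 1e-12).all()  # non-increasing

    def test_level_means_average_to_grand_mean(self):
        frame = design_frame(ADULT_FACTORS)
        rng = np.random.default_rng(8)
        frame["y"] = rng.normal(50, 5, len(frame))
        fit = fit_ols(frame, standard_terms(list(ADULT_FACTORS)), "y")
        summary = effect_summaries(frame, fit)
        for factor, means in summary.main_effects.items():
            assert means.mean() == pytest.approx(summary.grand_mean)

    def test_additive_truth_parallel_interaction_cells(self):
        frame = design_frame(ADULT_FACTORS)
        rng = np.random.default_rng(10)
        data = frame.loc[frame.index.repeat(20)].reset_index(drop=True)
        data["y"] = 2.0 * data["ZoneNurse"] - 1.0 * data["ZoneBed"] + rng.normal(0, 1, len(data))
        fit = fit_ols(data, standard_terms(list(ADULT_FACTORS)), "y")
        summary = effect_summaries(data, fit)
        cells = summary.interactions[("ZoneBed", "ZoneNurse")]
        # rows differ only by an additive offset: interaction contrast ~ 0
        contrast = cells - cells.mean(axis=0)
        spread = (contrast - contrast.mean(axis=1).to_numpy()[:, None]).abs().to_numpy().max()
        noise_bound = 5 * 1.0 / np.sqrt(20 * 3)
        assert spread < noise_bound

    def test_constant_response_all_effects_zero(self):
        frame = design_frame(ADULT_FACTORS)
        frame["y"] = 4.0
        fit = fit_ols(frame, standard_terms(list(ADULT_FACTORS)), "y")
        summary = effect_summaries(frame, fit)
        assert (summary.pareto["standardized_effect"] == 0).all()

    def test_unbalanced_warns(self):
        frame = design_frame(ADULT_FACTORS)
        frame["y"] = 1.0 * frame["ZoneNurse"]
        frame = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
        fit = fit_ols(frame, [("ZoneNurse",)], "y")
        with pytest.warns(UserWarning, match="unbalanced"):
            effect_summaries(frame, fit)


def test_format_equation_and_p():
    frame = design_frame(ADULT_FACTORS)
    frame["LOS"] = evaluate(frame, ADULT_LOS)
    terms = [t for t in ADULT_LOS if t != "Intercept"]
    fit = fit_ols(frame, terms, "LOS")
    text = format_equation(fit)
    assert text.startswith("LOS = -35")
    assert "ZoneNurse" in text
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.25) == "0.250"
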