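"""Discriminant engine: closed-form and oracle equivalence, classification
conventions, leave-one-out validation, stepwise selection, and the published
equation registry."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patellasex import (
    VARIABLES,
    classify,
    fit_lda,
    generate_cohort,
    loocv,
    pooled_spec,
    published_equations,
    stepwise_select,
)
from patellasex.discriminant import SingularCovarianceError, _wilks_lambda
from tests.conftest import POOLED_MOMENTS, affine_standardize

PRINTED_UNIVARIATE = {
    "maxh": (0.336, -13.320),
    "maxb": (0.307, -12.675),
    "maxt": (0.593, -11.420),
    "mafb": (0.471, -8.749),
    "haf": (0.368, -10.602),
    "lafb": (0.377, -9.374),
}


def _two_group_table(male, female, var="maxh"):
    df = pd.DataFrame({var: np.concatenate([male, female])})
    df["sex"] = ["M"] * len(male) + ["F"] * len(female)
    return df


# ---------------------------------------------------------------------------
# fitting


@pytest.mark.parametrize("var", list(PRINTED_UNIVARIATE))
def test_univariate_closed_form_recovers_published_equation(var):
    """Samples standardized to the published per-sex moments reproduce the
    published unstandardized coefficient (1/s_pooled) and constant."""
    rng = np.random.default_rng(1)
    male = affine_standardize(rng.standard_normal(130), *POOLED_MOMENTS[var]["M"])
    female = affine_standardize(rng.standard_normal(130), *POOLED_MOMENTS[var]["F"])
    fn = fit_lda(_two_group_table(male, female, var), (var,))
    coef_printed, const_printed = PRINTED_UNIVARIATE[var]
    assert fn.coefficients[0] == pytest.approx(coef_printed, abs=0.005)
    assert fn.constant == pytest.approx(const_printed, abs=0.06)
    # analytic identities for the univariate case
    s_m, s_f = POOLED_MOMENTS[var]["M"][1], POOLED_MOMENTS[var]["F"][1]
    s_pooled = np.sqrt((s_m**2 + s_f**2) / 2)
    assert fn.coefficients[0] == pytest.approx(1 / s_pooled)
    assert fn.sectioning_point == 0.0
    assert fn.centroid_male > 0 > fn.centroid_female
    assert fn.centroid_male == pytest.approx(-fn.centroid_female)


def test_fit_matches_dense_linear_algebra_oracle():
    """Random 3-variable fit equals an explicit S_pooled^-1 @ dmu solve
    followed by the quadratic-form rescale, computed independently."""
    rng = np.random.default_rng(5)
    Xm = rng.normal([40, 20, 30], [3, 2, 2.5], size=(10, 3))
    Xf = rng.normal([37, 18, 27], [3, 2, 2.5], size=(10, 3))
    df = pd.DataFrame(np.vstack([Xm, Xf]), columns=["maxh", "maxt", "haf"])
    df["sex"] = ["M"] * 10 + ["F"] * 10
    fn = fit_lda(df, ("maxh", "maxt", "haf"))

    # independent oracle: explicit inverse, no shared code path
    ss = np.zeros((3, 3))
    for X in (Xm, Xf):
        d = X - X.mean(0)
        ss += d.T @ d
    S = ss / (len(Xm) + len(Xf) - 2)
    w0 = np.linalg.inv(S) @ (Xm.mean(0) - Xf.mean(0))
    w = w0 / np.sqrt(w0 @ S @ w0)
    const = -w @ (Xm.mean(0) + Xf.mean(0)) / 2
    assert np.allclose(fn.coefficients, w)
    assert fn.constant == pytest.approx(const)
    assert fn.coefficients @ S @ fn.coefficients == pytest.approx(1.0)


def test_equal_means_fit_is_flagged_degenerate():
    vals = np.array([1.0, 2.0, 3.0, 4.0])
    fn = fit_lda(_two_group_table(vals, vals), ("maxh",))
    assert fn.degenerate
    s_pooled = np.std(vals, ddof=1)
    assert abs(fn.coefficients[0]) == pytest.approx(1 / s_pooled)
    assert fn.centroid_male == pytest.approx(0.0)
    assert fn.centroid_female == pytest.approx(0.0)


def test_singular_covariance_raises():
    table = _two_group_table([1, 2, 3], [4, 5, 6])
    table["maxb"] = table["maxh"] * 2  # exactly collinear
    with pytest.raises((SingularCovarianceError, np.linalg.LinAlgError)):
        fit_lda(table, ("maxh", "maxb"))


def test_missing_sex_group_raises():
    df = pd.DataFrame({"maxh": [1.0, 2.0], "sex": ["M", "M"]})
    with pytest.raises(ValueError):
        fit_lda(df, ("maxh",))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(0.1, 100.0))
def test_scale_invariance_of_classification(c):
    """Rescaling a variable's units rescales its coefficient by 1/c and
    leaves scores, centroids and classifications unchanged."""
    rng = np.random.default_rng(17)
    male = rng.normal(42, 3, 40)
    female = rng.normal(37, 3, 40)
    table = _two_group_table(male, female)
    fn = fit_lda(table, ("maxh",))
    scaled = table.copy()
    scaled["maxh"] *= c
    fn_scaled = fit_lda(scaled, ("maxh",))
    assert fn_scaled.coefficients[0] == pytest.approx(fn.coefficients[0] / c)
    assert fn_scaled.constant == pytest.approx(fn.constant)
    for x in (35.0, 39.5, 44.0):
        assert classify(fn_scaled, {"maxh": x * c}).score == pytest.approx(
            classify(fn, {"maxh": x}).score
        )


# ---------------------------------------------------------------------------
# classification


def test_classify_centroid_midpoint_scores_zero():
    rng = np.random.default_rng(3)
    table = _two_group_table(rng.normal(42, 3, 30), rng.normal(37, 3, 30))
    fn = fit_lda(table, ("maxh",))
    midpoint = (
        table.loc[table.sex == "M", "maxh"].mean()
        + table.loc[table.sex == "F", "maxh"].mean()
    ) / 2
    result = classify(fn, {"maxh": midpoint})
    assert result.score == pytest.approx(0.0, abs=1e-12)
    assert result.sex == "F" and result.on_boundary


def test_classify_published_maxh_equation_at_printed_means():
    fn = published_equations()["maxh"]
    male_mean = classify(fn, {"maxh": 42.07})
    assert male_mean.score == pytest.approx(0.336 * 42.07 - 13.320)
    assert male_mean.score == pytest.approx(0.816, abs=0.001)
    assert male_mean.sex == "M"
    female_mean = classify(fn, {"maxh": 37.25})
    assert female_mean.score == pytest.approx(-0.804, abs=0.001)
    assert female_mean.sex == "F"


def test_classify_missing_variable_names_it():
    fn = published_equations()["D1"]
    with pytest.raises(KeyError, match="maxb"):
        classify(fn, {"maxh": 42.0})


# ---------------------------------------------------------------------------
# leave-one-out validation


def test_loocv_perfectly_separated_groups():
    table = _two_group_table([10.0, 11, 12, 13], [1.0, 2, 3, 4])
    rep_o, rep_c = loocv(table, ("maxh",))
    for rep in (rep_o, rep_c):
        assert rep.male_pct == rep.female_pct == rep.average_pct == 100.0
    assert rep_o.variant == "O" and rep_c.variant == "C"


def test_loocv_matches_exhaustive_manual_refits():
    """n=6: each held-out case classified by an independently refit
    univariate discriminant (pooled-SD cut at the centroid midpoint)."""
    male = np.array([5.0, 6.0, 9.0])
    female = np.array([4.0, 3.0, 7.0])
    table = _two_group_table(male, female)
    _, rep_c = loocv(table, ("maxh",))

    correct = {"M": 0, "F": 0}
    for i in range(6):
        rest = table.drop(index=i)
        m = rest.loc[rest.sex == "M", "maxh"].to_numpy()
        f = rest.loc[rest.sex == "F", "maxh"].to_numpy()
        cut = (m.mean() + f.mean()) / 2
        x = table["maxh"].iloc[i]
        pred = "M" if x > cut else "F"  # male group always larger-mean here
        if pred == table["sex"].iloc[i]:
            correct[table["sex"].iloc[i]] += 1
    assert rep_c.male_pct == pytest.approx(100 * correct["M"] / 3)
    assert rep_c.female_pct == pytest.approx(100 * correct["F"] / 3)


def test_resubstitution_not_worse_than_loocv_on_average():
    """Resubstitution optimism: averaged over seeds the O rate is at least
    the C rate (small cohorts to keep the refits cheap)."""
    diffs = []
    for seed in range(6):
        table = generate_cohort(pooled_spec(seed=seed, n_male=40, n_female=40))
        rep_o, rep_c = loocv(table, ("maxh", "maxt"))
        diffs.append(rep_o.average_pct - rep_c.average_pct)
    assert np.mean(diffs) >= 0


# ---------------------------------------------------------------------------
# stepwise selection


def test_stepwise_selects_the_single_informative_variable():
    rng = np.random.default_rng(9)
    n = 60
    table = pd.DataFrame({v: rng.standard_normal(2 * n) for v in VARIABLES})
    table["sex"] = ["M"] * n + ["F"] * n
    table.loc[table.sex == "M", "maxt"] += 3.0  # the only signal
    trace = stepwise_select(table)
    # the informative variable leads; a noise variable may sneak past the
    # F-to-enter threshold (~5% each), but never ahead of the signal
    assert trace.steps[0].variable == "maxt"
    assert "maxt" in trace.entered
    assert trace.steps[0].f_statistic > 100


def test_stepwise_skips_conditionally_redundant_variable():
    """Second variable = first + noise adds no conditional information; the
    all-subsets Wilks'-lambda enumeration agrees it should stay out."""
    rng = np.random.default_rng(13)
    n = 50
    signal = np.concatenate([rng.normal(2, 1, n), rng.normal(0, 1, n)])
    table = pd.DataFrame({
        "maxh": signal,
        "maxb": signal + rng.normal(0, 0.1, 2 * n) * 0.999,
    })
    table["sex"] = ["M"] * n + ["F"] * n
    trace = stepwise_select(table, ("maxh", "maxb"))
    assert trace.entered == ["maxh"]

    Xm = table.loc[table.sex == "M", ["maxh", "maxb"]].to_numpy()
    Xf = table.loc[table.sex == "F", ["maxh", "maxb"]].to_numpy()
    lam1 = _wilks_lambda(Xm, Xf, [0])
    lam12 = _wilks_lambda(Xm, Xf, [0, 1])
    f_enter_second = (2 * n - 2 - 1) * (lam1 / lam12 - 1)
    assert f_enter_second < 3.84


def test_stepwise_lambda_non_increasing_and_within_candidates(pooled_table):
    trace = stepwise_select(pooled_table)
    assert set(trace.entered) <= set(VARIABLES)
    entry_lams = [s.wilks_lambda for s in trace.steps if s.action == "enter"]
    assert all(b <= a + 1e-12 for a, b in itertools.pairwise(entry_lams))


def test_stepwise_first_entry_is_maxh_by_majority_over_seeds():
    """maxh has the largest standardized sex separation, so it leads the
    entry order in most synthetic replicates."""
    firsts = [
        stepwise_select(generate_cohort(pooled_spec(seed=s))).steps[0].variable
        for s in range(20)
    ]
    assert sum(f == "maxh" for f in firsts) > 10


def test_stepwise_empty_trace_when_nothing_passes():
    rng = np.random.default_rng(21)
    table = pd.DataFrame({
        "maxh": rng.standard_normal(40),
        "maxb": rng.standard_normal(40),
    })
    table["sex"] = ["M"] * 20 + ["F"] * 20
    trace = stepwise_select(table, ("maxh", "maxb"), f_enter=1e6)
    assert trace.entered == [] and trace.steps == []


# ---------------------------------------------------------------------------
# published equation registry


def test_registry_contents():
    reg = published_equations()
    assert len(reg) == 12
    step = reg["stepwise"]
    assert set(step.variables) == {"maxh", "maxb", "maxt", "haf"}
    assert step.constant == -15.860
    d5 = reg["D5"]
    assert dict(zip(d5.variables, d5.coefficients)) == {
        "maxh": 0.294, "lafb": 0.076,
    }
    assert d5.constant == -13.568


def test_registry_functions_score_male_mean_vector_positive():
    male_means = {v: POOLED_MOMENTS[v]["M"][0] for v in VARIABLES}
    female_means = {v: POOLED_MOMENTS[v]["F"][0] for v in VARIABLES}
    for name, fn in published_equations().items():
        assert classify(fn, male_means).sex == "M", name
        assert classify(fn, female_means).sex == "F", name
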