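"""Validation statistics: exact intervals, ROC/Youden, banding, reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import indtasd as it


# --- 2x2 construction -------------------------------------------------------

def test_confusion_from_concordant_records():
    calls = {f"c{i}": True for i in range(3)}
    ct = it.confusion_from_records(calls, calls)
    assert (ct.tp, ct.fp, ct.fn, ct.tn) == (3, 0, 0, 0)


def test_confusion_reconstructs_study_margins(study_table):
    """A cohort engineered to the published margins yields the printed 2x2."""
    calls, ref = {}, {}
    cells = [("tp", True, True, 126), ("fp", True, False, 8),
             ("fn", False, True, 2), ("tn", False, False, 89)]
    i = 0
    for _, tool, truth, n in cells:
        for _ in range(n):
            calls[f"c{i}"], ref[f"c{i}"] = tool, truth
            i += 1
    ct = it.confusion_from_records(calls, ref)
    assert ct == study_table and ct.total == 225


def test_confusion_rejects_empty_and_mismatched():
    with pytest.raises(it.StatisticError):
        it.confusion_from_records({}, {})
    with pytest.raises(it.StatisticError):
        it.confusion_from_records({"a": True}, {"b": True})


# --- Clopper-Pearson --------------------------------------------------------

def test_clopper_pearson_study_sensitivity_ci():
    est = it.clopper_pearson(126, 128, 0.95)
    assert round(est.lower, 4) == 0.9447
    assert round(est.upper, 4) == 0.9981


def test_clopper_pearson_boundaries():
    assert it.clopper_pearson(0, 10).lower == 0.0
    top = it.clopper_pearson(10, 10)
    assert top.upper == 1.0
    # closed form at x=n: lower solves (lower)^n = alpha/2
    assert top.lower == pytest.approx(0.025 ** (1 / 10), abs=1e-12)


def test_clopper_pearson_matches_binomial_tail_roots():
    """Bounds solve the exact binomial tail equations (root-search oracle)."""
    from scipy import stats
    from scipy.optimize import brentq

    for x, n in [(3, 20), (7, 10), (50, 100)]:
        est = it.clopper_pearson(x, n, 0.95)
        lower = brentq(lambda p: stats.binom.sf(x - 1, n, p) - 0.025, 1e-12, 1 - 1e-12)
        upper = brentq(lambda p: stats.binom.cdf(x, n, p) - 0.025, 1e-12, 1 - 1e-12)
        assert est.lower == pytest.approx(lower, abs=1e-9)
        assert est.upper == pytest.approx(upper, abs=1e-9)


def test_clopper_pearson_matches_statsmodels():
    from statsmodels.stats.proportion import proportion_confint

    for x, n in [(126, 128), (8, 97), (0, 10), (10, 10), (45, 90)]:
        est = it.clopper_pearson(x, n, 0.95)
        lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
        assert est.lower == pytest.approx(lo, abs=1e-12)
        assert est.upper == pytest.approx(hi, abs=1e-12)


@given(st.integers(1, 60).flatmap(
    lambda n: st.tuples(st.just(n), st.integers(0, n))),
    st.sampled_from([0.90, 0.95, 0.99]))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_clopper_pearson_ordering_and_widening(nx, level):
    n, x = nx
    est = it.clopper_pearson(x, n, level)
    assert 0 <= est.lower <= est.point <= est.upper <= 1
    wider = it.clopper_pearson(x, n, min(0.999, level + 0.009))
    assert wider.lower <= est.lower + 1e-12 and wider.upper >= est.upper - 1e-12


def test_clopper_pearson_rejects_bad_input():
    with pytest.raises(it.StatisticError):
        it.clopper_pearson(5, 4)
    with pytest.raises(it.StatisticError):
        it.clopper_pearson(1, 10, level=1.0)


# --- accuracy measures ------------------------------------------------------

def test_study_table_measures(study_table):
    assert it.sensitivity(study_table).as_percent() == (98.44, 94.47, 99.81)
    assert it.specificity(study_table).as_percent() == (91.75, 84.39, 96.37)
    assert it.ppv(study_table).as_percent() == (94.03, 88.58, 97.39)
    assert it.npv(study_table).as_percent() == (97.80, 92.29, 99.73)


def test_perfect_test_measures():
    ct = it.ConfusionTable(5, 0, 0, 5)
    for measure in (it.sensitivity, it.specificity, it.ppv, it.npv):
        est = measure(ct)
        assert est.point == 1.0 and est.upper == 1.0


def test_zero_denominator_names_measure():
    ct = it.ConfusionTable(0, 0, 0, 5)
    with pytest.raises(it.StatisticError, match="sensitivity"):
        it.sensitivity(ct)
    with pytest.raises(it.StatisticError, match="ppv"):
        it.ppv(ct)


def test_relabeling_swaps_sensitivity_and_specificity(study_table):
    ct = study_table
    swapped = it.ConfusionTable(tp=ct.tn, fp=ct.fn, fn=ct.fp, tn=ct.tp)
    assert it.sensitivity(swapped).point == it.specificity(ct).point
    assert it.specificity(swapped).point == it.sensitivity(ct).point


# --- ROC / Youden -----------------------------------------------------------

def _brute_force_auc(scores, labels):
    """Pairwise concordance probability with ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_perfect_separation():
    r = it.roc_curve([10, 11, 12, 1, 2, 3], [True] * 3 + [False] * 3)
    assert r.auc == 1.0
    assert r.youden_j == 1.0


def test_roc_full_tie():
    r = it.roc_curve([2, 2], [True, False])
    assert r.auc == 0.5


def test_roc_single_class_is_error():
    with pytest.raises(it.StatisticError):
        it.roc_curve([1, 2, 3], [True, True, True])


def test_roc_auc_equals_brute_force_concordance():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(6, 13))
        labels = np.zeros(n, bool)
        labels[: int(rng.integers(1, n))] = True
        rng.shuffle(labels)
        scores = rng.integers(0, 8, n).astype(float)  # many ties
        if labels.all() or not labels.any():
            continue
        r = it.roc_curve(scores, labels)
        assert abs(r.auc - _brute_force_auc(scores, labels)) < 1e-12


def test_roc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(3)
    scores = rng.normal(size=60) + np.repeat([1.0, 0.0], 30)
    labels = np.repeat([True, False], 30)
    r = it.roc_curve(scores, labels)
    assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_roc_relabel_symmetry():
    rng = np.random.default_rng(5)
    scores = rng.integers(0, 20, 40).astype(float)
    labels = rng.random(40) < 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    a = it.roc_curve(scores, labels).auc
    b = it.roc_curve(-scores, ~labels).auc
    assert a == pytest.approx(b, abs=1e-12)


def test_youden_tie_breaks_to_smallest_cutoff():
    # cutoffs 2 and 3 both attain J = 0.5; the smaller must be chosen
    scores = [1, 2, 2, 3]
    labels = [False, False, True, True]
    r = it.roc_curve(scores, labels)
    assert r.youden_j == pytest.approx(0.5) and r.youden_cutoff == 2


def test_roc_monotone_points():
    rng = np.random.default_rng(8)
    scores = rng.integers(0, 15, 50).astype(float)
    labels = rng.random(50) < 0.4
    r = it.roc_curve(scores, labels)
    tprs = [p.tpr for p in r.points]
    fprs = [p.fpr for p in r.points]
    assert all(a >= b for a, b in zip(tprs, tprs[1:]))
    assert all(a >= b for a, b in zip(fprs, fprs[1:]))


# --- CARS banding and cross-tabulation --------------------------------------

@pytest.mark.parametrize("score,band", [
    (29.5, "non_autistic"), (30.0, "mild_moderate"), (36.5, "mild_moderate"),
    (37.0, "severe"), (15.0, "non_autistic"), (60.0, "severe"),
])
def test_cars_banding(score, band):
    assert it.cars_band(score) == band


def test_cars_band_out_of_range_warns_but_bands(caplog):
    with caplog.at_level("WARNING", logger="indtasd"):
        assert it.cars_band(10.0) == "non_autistic"
    assert "outside plausible range" in caplog.text


def _study_crosstab_inputs():
    """Tool calls and CARS scores engineered to the published band table."""
    calls, cars = {}, {}
    rows = [(25.0, 11, 95), (33.0, 37, 2), (40.0, 80, 0)]
    i = 0
    for score, n_pos, n_neg in rows:
        for _ in range(n_pos):
            calls[f"c{i}"], cars[f"c{i}"] = True, score
            i += 1
        for _ in range(n_neg):
            calls[f"c{i}"], cars[f"c{i}"] = False, score
            i += 1
    return calls, cars


def test_cross_tab_reproduces_study_percentages():
    calls, cars = _study_crosstab_inputs()
    tab = it.cross_tab_severity(calls, cars).set_index("cars_band")
    assert tab.loc["non_autistic", "pct_positive"] == 10.4
    assert tab.loc["mild_moderate", "pct_positive"] == 94.9
    assert tab.loc["severe", "pct_positive"] == 100.0
    assert (tab["tool_positive"] + tab["tool_negative"] == tab["n"]).all()
    assert tab["n"].sum() == 225


def test_cross_tab_excludes_missing_cars():
    calls = {"a": True, "b": False, "c": True}
    cars = {"a": 40.0, "b": 25.0, "c": float("nan")}
    tab = it.cross_tab_severity(calls, cars)
    assert tab["n"].sum() == 2
    assert tab.attrs["n_excluded"] == 1


def test_cross_tab_empty_band_has_nan_percentages():
    tab = it.cross_tab_severity({"a": True}, {"a": 40.0}).set_index("cars_band")
    assert np.isnan(tab.loc["non_autistic", "pct_positive"])
    assert tab.loc["severe", "pct_positive"] == 100.0


# --- reliability ------------------------------------------------------------

def test_kappa_identical_raters_is_one():
    labels = ["pos", "neg"] * 25
    assert it.cohens_kappa(labels, labels).value == pytest.approx(1.0)


def test_kappa_worked_2x2():
    # agreement table a=45, b=5, c=5, d=45: p_o = 0.9, p_e = 0.5, kappa = 0.8
    a = [1] * 50 + [0] * 50
    b = [1] * 45 + [0] * 5 + [1] * 5 + [0] * 45
    res = it.cohens_kappa(a, b)
    assert res.value == pytest.approx(0.8, abs=1e-12)
    assert res.detail["p_observed"] == pytest.approx(0.9)
    assert res.detail["p_expected"] == pytest.approx(0.5)


def test_kappa_independent_raters_near_zero():
    rng = np.random.default_rng(12)
    a = rng.integers(0, 2, 20000)
    b = rng.integers(0, 2, 20000)
    assert abs(it.cohens_kappa(a, b).value) < 3 / np.sqrt(20000)


def test_kappa_matches_sklearn():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(4)
    a = rng.integers(0, 3, 200)
    b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 3, 200))
    assert it.cohens_kappa(a, b).value == pytest.approx(
        cohen_kappa_score(a, b), abs=1e-12)


def test_kappa_label_permutation_invariant():
    rng = np.random.default_rng(9)
    a = rng.integers(0, 2, 300)
    b = np.where(rng.random(300) < 0.8, a, 1 - a)
    base = it.cohens_kappa(a, b).value
    assert it.cohens_kappa(1 - a, 1 - b).value == pytest.approx(base, abs=1e-12)


def test_kappa_constant_raters_is_error():
    with pytest.raises(it.StatisticError):
        it.cohens_kappa([1, 1, 1], [1, 1, 1])


def test_alpha_duplicated_items_is_one():
    rng = np.random.default_rng(2)
    col = rng.normal(size=30)
    m = np.column_stack([col, col, col])
    assert it.cronbach_alpha(m).value == pytest.approx(1.0, abs=1e-12)


def test_alpha_worked_matrix_matches_variance_formula():
    m = np.array([[1, 1, 1], [2, 1, 0], [3, 2, 2], [4, 3, 2]], float)
    # independent computation straight from the variance decomposition
    k = 3
    item_vars = sum(np.var(m[:, j], ddof=1) for j in range(k))
    total_var = np.var(m.sum(axis=1), ddof=1)
    expected = k / (k - 1) * (1 - item_vars / total_var)
    assert it.cronbach_alpha(m).value == pytest.approx(expected, abs=1e-12)


def test_alpha_independent_items_near_zero():
    rng = np.random.default_rng(21)
    m = rng.normal(size=(5000, 2))
    assert abs(it.cronbach_alpha(m).value) < 0.1


def test_alpha_matches_pingouin():
    import pandas as pd
    from pingouin import cronbach_alpha as pg_alpha

    rng = np.random.default_rng(14)
    latent = rng.normal(size=60)
    m = np.column_stack([latent + rng.normal(size=60) for _ in range(5)])
    expected, _ = pg_alpha(data=pd.DataFrame(m))
    assert it.cronbach_alpha(m).value == pytest.approx(expected, abs=1e-9)


def test_alpha_if_deleted_detail():
    rng = np.random.default_rng(6)
    latent = rng.normal(size=50)
    m = np.column_stack([latent + 0.3 * rng.normal(size=50) for _ in range(4)])
    res = it.cronbach_alpha(m)
    assert set(res.detail["alpha_if_deleted"]) == {0, 1, 2, 3}
    assert all(v < 1 for v in res.detail["alpha_if_deleted"].values())


def test_alpha_zero_total_variance_is_error():
    with pytest.raises(it.StatisticError):
        it.cronbach_alpha(np.array([[1.0, 2.0], [2.0, 1.0]]))


def test_pearson_exact_lines():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert it.pearson_r(x, 2 * x + 1).value == pytest.approx(1.0)
    assert it.pearson_r(x, -x).value == pytest.approx(-1.0)


def test_pearson_worked_set_matches_covariance_oracle():
    x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    y = np.array([2.0, 2.5, 1.0, 6.0, 4.5])
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    expected = cov / (x.std(ddof=0) * y.std(ddof=0))
    assert it.pearson_r(x, y).value == pytest.approx(expected, abs=1e-12)


def test_pearson_affine_invariance():
    rng = np.random.default_rng(17)
    x, y = rng.normal(size=40), rng.normal(size=40)
    base = it.pearson_r(x, y).value
    assert it.pearson_r(3 * x - 7, 0.5 * y + 2).value == pytest.approx(base, abs=1e-12)


def test_pearson_zero_variance_is_error():
    with pytest.raises(it.StatisticError):
        it.pearson_r([1, 1, 1], [1, 2, 3])
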