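import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturokit import (
    anova_oneway,
    classification_metrics,
    evaluate_risk_vs_history,
    falls_history_to_class,
    per_phone_average,
    prevalence_summary,
    remove_outliers,
    simulate_assessment_table,
    two_sample_ztest,
)
from posturokit.evaluation import ConfusionMatrix
from posturokit.io_formats import ValidationError
from posturokit.synthetic import expected_accuracy


# -- outlier rule ----------------------------------------------------------

def test_outlier_removed_single_pass(rng):
    vals = np.concatenate([rng.normal(0, 1, 50), [100.0]])
    df = pd.DataFrame({"rms_acc_res": vals})
    out, report = remove_outliers(df)
    mu, sigma = vals.mean(), vals.std(ddof=1)
    assert 100.0 > mu + 2 * sigma  # the outlier is outside the fence
    assert out["rms_acc_res"].isna().sum() == 1
    assert np.isnan(out.loc[50, "rms_acc_res"])
    # no in-range value removed
    kept = out["rms_acc_res"].dropna()
    assert np.all(np.abs(kept - mu) <= 2 * sigma)
    assert report.mu["rms_acc_res"] == pytest.approx(mu)


def test_outlier_constant_column_untouched():
    df = pd.DataFrame({"rms_acc_res": np.full(20, 3.3)})
    out, report = remove_outliers(df)
    assert out["rms_acc_res"].notna().all()
    assert report.n_removed == 0


def test_outlier_missing_stays_missing(rng):
    vals = rng.normal(0, 1, 30)
    vals[5] = np.nan
    df = pd.DataFrame({"rms_acc_res": vals})
    out, report = remove_outliers(df)
    assert np.isnan(out.loc[5, "rms_acc_res"])
    # mu/sigma computed excluding the missing entry
    assert report.mu["rms_acc_res"] == pytest.approx(np.nanmean(vals))


def test_outlier_rule_is_exact_on_adversarial_fixture():
    """Values straddling the fence: only strict exceedances are removed."""
    base = np.array([-1.0, 1.0] * 10)  # mean 0, sd ~1.026
    mu, sigma = base.mean(), base.std(ddof=1)
    fixture = np.concatenate([base, [2 * sigma * 0.999, -2 * sigma * 0.999]])
    mu2, sig2 = fixture.mean(), fixture.std(ddof=1)
    df = pd.DataFrame({"rms_acc_res": fixture})
    out, _ = remove_outliers(df)
    expect_removed = np.abs(fixture - mu2) > 2 * sig2
    assert (out["rms_acc_res"].isna().to_numpy() == expect_removed).all()


# -- per-phone averaging ---------------------------------------------------

def test_per_phone_mean():
    df = pd.DataFrame({"phone_id": ["a"] * 3, "gender": "male", "age": 70,
                       "falls_12m": 1, "rms_acc_res": [0.1, 0.2, 0.3]})
    out = per_phone_average(df)
    assert len(out) == 1
    assert out["rms_acc_res"].iloc[0] == pytest.approx(0.2)


def test_per_phone_conflicting_gender_excluded():
    df = pd.DataFrame({"phone_id": ["a", "a", "b"],
                       "gender": ["male", "female", "male"],
                       "age": [70, 70, 60], "rms_acc_res": [0.1, 0.2, 0.3]})
    out = per_phone_average(df)
    assert list(out["phone_id"]) == ["b"]


def test_per_phone_594_to_147():
    df = simulate_assessment_table(seed=31)
    assert len(df) == 594
    out = per_phone_average(df)
    assert len(out) == 147


# -- prevalence ------------------------------------------------------------

def test_prevalence_arithmetic():
    df = pd.DataFrame({"polypharmacy": [True] * 168 + [False] * (594 - 168),
                       "stroke": [False] * 594})
    prev = prevalence_summary(df, items=("polypharmacy", "stroke"))
    assert prev.loc["polypharmacy", "count"] == 168
    assert prev.loc["polypharmacy", "percent"] == 28.3
    assert prev.loc["stroke", "percent"] == 0.0


def test_prevalence_empty_rejected():
    with pytest.raises(ValidationError):
        prevalence_summary(pd.DataFrame({"polypharmacy": []}))


# -- ANOVA -----------------------------------------------------------------

def test_anova_identical_groups():
    vals = np.concatenate([np.arange(10.0), np.arange(10.0)])
    groups = np.repeat(["a", "b"], 10)
    res = anova_oneway(vals, groups)
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_anova_matches_hand_computation():
    """9-value, 3-group fixture with F computed from SSB/SSW by hand."""
    data = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
    vals = np.array(sum(data.values(), []))
    groups = np.repeat(list(data), 3)
    grand = vals.mean()
    ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in data.values())
    ssw = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in data.values())
    f_hand = (ssb / 2) / (ssw / 6)
    res = anova_oneway(vals, groups)
    assert res.F == pytest.approx(f_hand, rel=1e-9)
    assert res.group_means["c"] == pytest.approx(7.0)


def test_anova_power_under_large_shift():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])
        groups = np.repeat(["a", "b"], 100)
        if anova_oneway(vals, groups).p < 0.05:
            hits += 1
    assert hits >= 99


def test_anova_degenerate_grouping_rejected():
    with pytest.raises(ValidationError):
        anova_oneway(np.arange(5.0), np.array(["a"] * 5))


# -- z-test ----------------------------------------------------------------

def test_ztest_identical_samples(rng):
    x = rng.normal(0, 1, 100)
    res = two_sample_ztest(x, x)
    assert res.z == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)
    assert not res.significant


def test_ztest_hand_fixture():
    """Means 1 vs 0, sample variances exactly 1, n=100 -> z = 1/sqrt(0.02)."""
    n = 100
    d = np.sqrt((n - 1) / n)  # two-point sample with ddof=1 variance 1
    a = np.concatenate([np.full(n // 2, 1 + d), np.full(n // 2, 1 - d)])
    b = np.concatenate([np.full(n // 2, d), np.full(n // 2, -d)])
    res = two_sample_ztest(a, b)
    assert res.z == pytest.approx(1.0 / np.sqrt(0.02), rel=1e-12)
    assert res.significant


def test_ztest_power():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        res = two_sample_ztest(rng.normal(0, 1, 200), rng.normal(1, 1, 200))
        hits += res.significant
    assert hits >= 99


def test_ztest_small_sample_flagged():
    with pytest.warns(UserWarning):
        res = two_sample_ztest(np.arange(10.0), np.arange(10.0) + 1)
    assert res.approximate


def test_ztest_matches_statsmodels(rng):
    from statsmodels.stats.weightstats import CompareMeans, DescrStatsW

    a, b = rng.normal(0, 1, 120), rng.normal(0.4, 1.3, 90)
    res = two_sample_ztest(a, b)
    z_ref, p_ref = CompareMeans(DescrStatsW(a), DescrStatsW(b)).ztest_ind(
        usevar="unequal")
    assert res.z == pytest.approx(z_ref, rel=1e-10)
    assert res.p == pytest.approx(p_ref, rel=1e-10)


# -- falls history classes -------------------------------------------------

@pytest.mark.parametrize("falls,k,expected", [
    (0, 3, "low"), (1, 3, "medium"), (2, 3, "high"), (7, 3, "high"),
    (0, 2, "non-faller"), (1, 2, "faller"), (5, 2, "faller"),
])
def test_falls_history_classes(falls, k, expected):
    assert falls_history_to_class(falls, k) == expected


def test_falls_history_negative_rejected():
    with pytest.raises(ValidationError):
        falls_history_to_class(-1, 3)


# -- classification metrics ------------------------------------------------

def test_metrics_identity_matrix():
    cm = ConfusionMatrix(np.diag([10, 20, 30]), ("low", "medium", "high"))
    m = classification_metrics(cm)
    assert m.accuracy == 100.0
    assert all(v == 100.0 for v in m.sensitivity.values())
    assert all(v == 100.0 for v in m.predictivity.values())


def test_metrics_hand_2x2():
    cm = ConfusionMatrix(np.array([[80, 20], [30, 70]]),
                         ("non-faller", "faller"))
    m = classification_metrics(cm)
    assert m.accuracy == pytest.approx(75.0)
    assert m.sensitivity["non-faller"] == pytest.approx(80.0)
    assert m.sensitivity["faller"] == pytest.approx(70.0)
    assert m.predictivity["non-faller"] == pytest.approx(72.7, abs=0.05)
    assert m.predictivity["faller"] == pytest.approx(77.8, abs=0.05)


def _expansion_oracle(counts):
    """Expand counts to individual records and recount per class."""
    true, pred = [], []
    k = counts.shape[0]
    for i in range(k):
        for j in range(k):
            true += [i] * counts[i, j]
            pred += [j] * counts[i, j]
    true, pred = np.array(true), np.array(pred)
    acc = 100.0 * (true == pred).mean()
    sens = [100.0 * (pred[true == c] == c).mean() if (true == c).any()
            else np.nan for c in range(k)]
    prec = [100.0 * (true[pred == c] == c).mean() if (pred == c).any()
            else np.nan for c in range(k)]
    return acc, sens, prec


def test_metrics_match_expansion_oracle(rng):
    labels = ("low", "medium", "high")
    for _ in range(50):
        counts = rng.integers(0, 40, size=(3, 3))
        if counts.sum() == 0:
            continue
        m = classification_metrics(ConfusionMatrix(counts, labels))
        acc, sens, prec = _expansion_oracle(counts)
        assert m.accuracy == pytest.approx(acc, abs=1e-12)
        for c, lab in enumerate(labels):
            np.testing.assert_allclose(m.sensitivity[lab], sens[c], atol=1e-12)
            np.testing.assert_allclose(m.predictivity[lab], prec[c], atol=1e-12)


def test_metrics_undefined_not_zero():
    counts = np.array([[5, 0], [3, 0]])  # 'faller' never predicted
    m = classification_metrics(ConfusionMatrix(counts, ("non-faller", "faller")))
    assert np.isnan(m.predictivity["faller"])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_accuracy_is_weighted_mean_of_sensitivities(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 30, size=(3, 3))
    m = classification_metrics(ConfusionMatrix(counts, ("a", "b", "c")))
    weights = counts.sum(axis=1) / counts.sum()
    weighted = sum(w * m.sensitivity[lab]
                   for w, lab in zip(weights, ("a", "b", "c")))
    assert m.accuracy == pytest.approx(weighted, rel=1e-12)


def test_metrics_permutation_equivariance(rng):
    counts = rng.integers(1, 30, size=(3, 3))
    labels = ("low", "medium", "high")
    m = classification_metrics(ConfusionMatrix(counts, labels))
    perm = [2, 0, 1]
    m2 = classification_metrics(ConfusionMatrix(
        counts[np.ix_(perm, perm)], tuple(labels[i] for i in perm)))
    assert m2.accuracy == pytest.approx(m.accuracy)
    for lab in labels:
        assert m2.sensitivity[lab] == pytest.approx(m.sensitivity[lab])


# -- risk vs history -------------------------------------------------------

def test_perfect_agreement_is_100():
    df = pd.DataFrame({
        "falls_12m": [0, 1, 2, 0, 2],
        "fre_category": ["low", "medium", "high", "low", "high"]})
    cm, m = evaluate_risk_vs_history(df, k=3, risk="fre")
    assert m.accuracy == 100.0


def test_generator_preset_accuracy_near_expected():
    df = simulate_assessment_table(seed=1)
    _, m3 = evaluate_risk_vs_history(df, k=3, risk="balance")
    assert m3.accuracy == pytest.approx(expected_accuracy(3), abs=10.0)
    _, m2 = evaluate_risk_vs_history(df, k=2, risk="balance")
    assert m2.accuracy == pytest.approx(expected_accuracy(2), abs=10.0)


def test_two_class_accuracy_at_least_three_class():
    for seed in (1, 2, 3):
        df = simulate_assessment_table(seed=seed)
        _, m3 = evaluate_risk_vs_history(df, k=3, risk="balance")
        _, m2 = evaluate_risk_vs_history(df, k=2, risk="balance")
        assert m2.accuracy >= m3.accuracy - 1e-9


def test_risk_vs_history_no_pairs_rejected():
    df = pd.DataFrame({"falls_12m": [np.nan], "fre_category": [None]})
    with pytest.raises(ValidationError):
        evaluate_risk_vs_history(df, k=3)
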