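import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutdna import (
    chi2_detection_by_timepoint,
    classify_cycle2,
    clopper_pearson,
    contingency_metrics,
    km_curve,
    kruskal_dunn,
    ks_af_comparison,
    logrank_test,
    median_time_to_event,
)
from mutdna.outcome import bonferroni


# -- exact binomial intervals --------------------------------------------


@pytest.mark.parametrize("n", range(1, 51))
def test_clopper_pearson_closed_forms_at_extremes(n):
    alpha = 0.05
    lo, hi = clopper_pearson(0, n)
    assert lo == 0.0
    assert hi == pytest.approx(1 - (alpha / 2) ** (1 / n), abs=1e-12)
    lo, hi = clopper_pearson(n, n)
    assert hi == 1.0
    assert lo == pytest.approx((alpha / 2) ** (1 / n), abs=1e-12)


def test_clopper_pearson_beta_quantile_oracle():
    # independent beta-quantile computation for 5 of 6
    lo, hi = clopper_pearson(5, 6)
    assert lo == pytest.approx(stats.beta.ppf(0.025, 5, 2), abs=1e-12)
    assert hi == pytest.approx(stats.beta.ppf(0.975, 6, 1), abs=1e-12)
    assert (round(lo, 3), round(hi, 3)) == (0.359, 0.996)


def test_clopper_pearson_contains_point_estimate():
    for k, n in [(1, 10), (3, 7), (9, 12), (25, 50)]:
        lo, hi = clopper_pearson(k, n)
        assert lo <= k / n <= hi


@pytest.mark.parametrize("k,n", [(-1, 5), (6, 5), (0, 0)])
def test_clopper_pearson_invalid_inputs(k, n):
    with pytest.raises(ValueError):
        clopper_pearson(k, n)


# -- contingency metrics -------------------------------------------------


def test_perfect_classifier():
    m = contingency_metrics(3, 0, 0, 3)
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        assert getattr(m, name).percent() == 100.0


def test_degenerate_denominators_are_flagged_not_zero():
    m = contingency_metrics(0, 0, 0, 4)
    assert not m.sensitivity.defined and np.isnan(m.sensitivity.value)
    assert not m.ppv.defined
    assert m.specificity.defined and m.specificity.value == 1.0


def test_metrics_round_trip_to_counts():
    m = contingency_metrics(5, 2, 1, 6)
    assert (m.sensitivity.k, m.sensitivity.n) == (5, 6)
    assert (m.specificity.k, m.specificity.n) == (6, 8)
    assert (m.ppv.k, m.ppv.n) == (5, 7)
    assert (m.npv.k, m.npv.n) == (6, 7)
    # counts reconstruct from the proportions' numerators/denominators
    assert m.sensitivity.k == m.tp and m.sensitivity.n - m.sensitivity.k == m.fn
    assert m.specificity.k == m.tn and m.specificity.n - m.specificity.k == m.fp


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        contingency_metrics(-1, 0, 0, 0)


# -- survival ------------------------------------------------------------


def surv(rows):
    return pd.DataFrame(rows, columns=["time", "event", "group"])


def test_km_all_censored_stays_at_one():
    km = km_curve(surv([(5, 0, "a"), (8, 0, "a"), (11, 0, "a")]))
    assert (km["survival"] == 1.0).all()


def test_km_two_events_by_hand():
    km = km_curve(surv([(2, 1, "a"), (4, 1, "a")])).set_index("time")
    assert km.loc[0.0, "survival"] == 1.0
    assert km.loc[2.0, "survival"] == pytest.approx(0.5)
    assert km.loc[4.0, "survival"] == pytest.approx(0.0)


def test_km_with_censoring_matches_product_limit_oracle():
    # times 1(event), 2(censored), 3(event):
    # S(1) = 2/3; censoring removes one at-risk; S(3) = 2/3 * (1 - 1/1) = 0
    km = km_curve(surv([(1, 1, "a"), (2, 0, "a"), (3, 1, "a")])).set_index("time")
    assert km.loc[1.0, "survival"] == pytest.approx(2 / 3)
    assert km.loc[3.0, "survival"] == pytest.approx(0.0)


def test_km_is_nonincreasing_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = int(rng.integers(3, 30))
        df = surv(
            list(zip(rng.integers(1, 50, n), rng.integers(0, 2, n), ["a"] * n))
        )
        km = km_curve(df)
        assert (np.diff(km["survival"]) <= 1e-12).all()


def _logrank_oracle(df):
    """Hand-rolled two-group log-rank: sum over event times of
    (observed - hypergeometric expectation) with hypergeometric variance."""
    groups = sorted(df["group"].unique())
    o_minus_e, var = 0.0, 0.0
    for t in sorted(df.loc[df["event"] == 1, "time"].unique()):
        at_risk = df[df["time"] >= t]
        n = len(at_risk)
        n1 = (at_risk["group"] == groups[0]).sum()
        d = ((df["time"] == t) & (df["event"] == 1)).sum()
        d1 = ((df["time"] == t) & (df["event"] == 1)
              & (df["group"] == groups[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, stats.chi2.sf(chi2, 1)


def test_logrank_identical_groups_is_null():
    rows = [(3, 1, "a"), (5, 0, "a"), (9, 1, "a")]
    df = surv(rows + [(t, e, "b") for t, e, _ in rows])
    stat, p = logrank_test(df)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_per_event_time_oracle():
    df = surv([
        (2, 1, "a"), (5, 1, "a"), (7, 0, "a"), (11, 1, "a"), (14, 0, "a"), (20, 1, "a"),
        (4, 1, "b"), (6, 0, "b"), (9, 1, "b"), (13, 1, "b"), (18, 1, "b"), (25, 0, "b"),
    ])
    stat, p = logrank_test(df)
    o_stat, o_p = _logrank_oracle(df)
    assert stat == pytest.approx(o_stat, rel=1e-9)
    assert p == pytest.approx(o_p, rel=1e-9)


def test_logrank_invariant_to_group_swap():
    df = surv([(2, 1, "a"), (9, 0, "a"), (4, 1, "b"), (12, 1, "b")])
    swapped = df.assign(group=df["group"].map({"a": "b", "b": "a"}))
    assert logrank_test(df) == pytest.approx(logrank_test(swapped))


def test_logrank_requires_two_groups():
    with pytest.raises(ValueError, match="2 groups"):
        logrank_test(surv([(2, 1, "a")]))


# -- group comparisons ---------------------------------------------------


def test_ks_identical_samples():
    x = np.array([0.01, 0.02, 0.05])
    stat, p = ks_af_comparison(x, x)
    assert stat == pytest.approx(0.0)


def test_bonferroni_is_capped_multiplication():
    np.testing.assert_allclose(bonferroni([0.01], m=5), [0.05])
    np.testing.assert_allclose(bonferroni([0.4, 0.01], m=5), [1.0, 0.05])


def test_chi2_matches_expected_count_formula():
    # (9 detected / 8 not) vs (1 / 15)
    table = np.array([[9, 8], [1, 15]])
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    oracle = float(((table - expected) ** 2 / expected).sum())
    chi2, _, _, _ = stats.chi2_contingency(table, correction=False)
    assert chi2 == pytest.approx(oracle, rel=1e-12)


def test_chi2_by_timepoint_on_cohort(cohort, called_cohort):
    tab = chi2_detection_by_timepoint(called_cohort, cohort.sample_sheet)
    assert list(tab["timepoint"]) == [1, 2, 3, 4, 5, 6]
    assert (tab["p_bonferroni"] >= tab["p_raw"] - 1e-15).all()
    # pre-treatment both groups shed; the contrast emerges on treatment,
    # once responders have cleared their mutDNA
    assert (tab.set_index("timepoint")["p_bonferroni"].loc[[2, 3]] < 0.05).all()


def test_kruskal_dunn_separated_groups():
    rng = np.random.default_rng(1)
    res = kruskal_dunn({
        "PLS": rng.normal(0.0, 0.01, 40).clip(0),
        "UCP": rng.normal(0.050, 0.01, 40),
        "USN": rng.normal(0.051, 0.01, 40),
    })
    assert res["p"] < 1e-6
    pairs = {(d["a"], d["b"]): d for d in res["pairwise"]}
    assert pairs[("PLS", "UCP")]["p_bonferroni"] < 0.001
    assert pairs[("PLS", "USN")]["p_bonferroni"] < 0.001
    # near-identical urine compartments are not separated
    assert pairs[("UCP", "USN")]["p_bonferroni"] > 0.05


def test_kruskal_dunn_degenerate_flagged():
    res = kruskal_dunn({"a": np.ones(5), "b": np.ones(5)})
    assert res["degenerate"] and np.isnan(res["statistic"])
    with pytest.raises(ValueError):
        kruskal_dunn({"a": np.ones(5), "b": np.array([])})


@pytest.mark.parametrize(
    "times,expected",
    [([10], (10, 10.0, 10.0)), ([1, 2, 3, 4], (3, 1.0, 4.0)),
     ([5, 1, 9], (5, 1.0, 9.0))],
)
def test_median_time_rounds_half_up(times, expected):
    assert median_time_to_event(times) == expected


def test_median_time_empty_rejected():
    with pytest.raises(ValueError):
        median_time_to_event([])


# -- cycle-2 classification ----------------------------------------------


def test_classify_cycle2_strata_on_cohort(cohort, called_cohort):
    cls = classify_cycle2(called_cohort, cohort.sample_sheet, timepoint=2)
    counts = cls["group"].value_counts().to_dict()
    # patients with no panel SNV anywhere form the unevaluable stratum
    absent_patients = [
        p for p, d in cohort.truth["patients"].items()
        if d["trajectory"] == "mutdna-absent"
    ]
    assert counts["unevaluable"] == len(absent_patients)
    assert set(cls.loc[cls["group"] == "unevaluable", "patient"]) == set(
        absent_patients
    )
    assert len(cls) == 17
    ev = cls[cls["group"] != "unevaluable"]
    assert (ev["time"] > 0).all()
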