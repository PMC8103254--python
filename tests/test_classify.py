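import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from meganorm import (StepwiseConfig, binomial_exceedance_p,
                      coincidence_and_correlation, discriminant_scores,
                      jackknife_classify, resubstitution_classify,
                      score_group_test, second_step_rerun, stepwise_lda)
from meganorm.classify import ClassifierError, round_half_away


# ---------------------------------------------------------------------------
# exact binomial tail


def _exact_tail(correct, n, strict=True):
    lo = correct + 1 if strict else correct
    num = sum(math.comb(n, k) for k in range(lo, n + 1))
    return Fraction(num, 2 ** n)


def test_binomial_printed_table_values():
    # confusion rows from published accuracy tables, strict convention
    assert f"{binomial_exceedance_p(42, 54):.6f}" == "0.000007"
    assert f"{binomial_exceedance_p(23, 32):.4f}" == "0.0035"
    assert f"{binomial_exceedance_p(37, 48):.6f}" == "0.000031"


def test_binomial_small_cases():
    assert binomial_exceedance_p(3, 4) == pytest.approx(1 / 16)
    assert binomial_exceedance_p(10, 10) == 0.0  # empty strict tail
    assert binomial_exceedance_p(10, 10, "at_least") == pytest.approx(2 ** -10)
    assert binomial_exceedance_p(0, 10, "at_least") == pytest.approx(1.0)


def test_binomial_matches_exhaustive_enumeration():
    for n in range(1, 21):
        for c in range(n + 1):
            for conv, strict in (("strict", True), ("at_least", False)):
                exact = float(_exact_tail(c, n, strict))
                assert binomial_exceedance_p(c, n, conv) == \
                    pytest.approx(exact, rel=1e-12, abs=1e-300)


def test_binomial_matches_normal_approximation_in_moderate_range():
    # continuity-corrected normal tail agrees within a factor of 3 wherever
    # the tail probability is not extreme
    for n in (20, 50, 100):
        for c in range(n // 2, n + 1):
            exact = binomial_exceedance_p(c, n)
            if exact < 1e-4 or exact == 0.0:
                continue
            z = (c + 0.5 - n / 2) / math.sqrt(n / 4)
            approx = float(stats.norm.sf(z))
            assert 1 / 3 < approx / exact < 3


def test_binomial_input_validation():
    with pytest.raises(ClassifierError):
        binomial_exceedance_p(5, 4)
    with pytest.raises(ClassifierError):
        binomial_exceedance_p(2, 10, "sideways")


def test_round_half_away():
    assert round_half_away(77.75) == 77.8
    assert round_half_away(77.849) == 77.8
    assert round_half_away(-2.25) == -2.3


# ---------------------------------------------------------------------------
# stepwise selection

def _two_group_data(n=60, p=8, d=2.0, seed=0, signal_col=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, p))
    y = np.array(["neg"] * n + ["pos"] * n)
    X[n:, signal_col] += d
    return X, y


def test_stepwise_enters_signal_region_first():
    X, y = _two_group_data(seed=1)
    model = stepwise_lda(X, y, region_ids=[f"r{i}" for i in range(8)])
    assert model.selected_regions[0] == "r3"
    assert model.signs["r3"] == "++"  # elevated in positive group, first entry


def test_wilks_lambda_non_increasing():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(80, 10))
    X[40:, 2] += 1.2
    X[40:, 7] -= 0.9
    y = np.array(["a"] * 40 + ["b"] * 40)
    model = stepwise_lda(X, y)
    lams = model.wilks_lambda
    assert len(lams) == len(model.selected_regions)
    assert all(a >= b for a, b in zip(lams, lams[1:]))


def test_exact_duplicate_blocked_by_tolerance():
    X, y = _two_group_data(seed=2, p=4, signal_col=0)
    Xd = np.column_stack([X, X[:, 0]])  # exact copy of the signal column
    model = stepwise_lda(Xd, y, region_ids=["s", "a", "b", "c", "s_copy"])
    assert "s" in model.selected_regions
    assert "s_copy" not in model.selected_regions


def test_pure_noise_small_pool_selects_nothing():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 3))
    y = np.array(["a", "b"] * 20)
    model = stepwise_lda(X, y)
    assert model.is_empty


def test_empty_model_deterministic_fallback():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(20, 2))
    y = np.array(["first", "second"] * 10)
    model = stepwise_lda(X, y)
    assert model.is_empty
    assigned = model.classify(X, ["a", "b"])
    assert set(assigned) == {"first"}  # tie broken toward first group label


def test_needs_two_groups_and_min_sizes():
    X = np.zeros((4, 2))
    with pytest.raises(ClassifierError):
        stepwise_lda(X, ["a", "a", "a", "a"])
    with pytest.raises(ClassifierError):
        stepwise_lda(X, ["a", "b", "b", "b"])


# ---------------------------------------------------------------------------
# jackknife

def test_jackknife_matches_independent_loo_lda():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    for seed in range(5):
        X, y = _two_group_data(n=30, p=6, d=1.0, seed=seed)
        model = stepwise_lda(X, y)
        regions = model.selected_regions or ["var0", "var1"]
        rep = jackknife_classify(X, y, regions)
        idx = [int(r[3:]) for r in regions]
        correct = np.zeros(2, dtype=int)
        for i in range(len(y)):
            mask = np.ones(len(y), bool)
            mask[i] = False
            lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            lda.fit(X[mask][:, idx], y[mask])
            pred = lda.predict(X[i:i + 1, idx])[0]
            if pred == y[i]:
                correct[int(y[i] == "pos")] += 1
        assert rep.confusion[0, 0] == correct[0]
        assert rep.confusion[1, 1] == correct[1]


def test_perfect_separation_classifies_perfectly():
    X, y = _two_group_data(n=25, d=8.0, seed=3)
    model = stepwise_lda(X, y)
    rep = jackknife_classify(X, y, model.selected_regions)
    assert rep.pct_correct == {"neg": 100.0, "pos": 100.0}
    assert rep.confusion.tolist() == [[25, 0], [0, 25]]


def test_jackknife_not_better_than_resubstitution_on_average():
    diffs = []
    for seed in range(12):
        X, y = _two_group_data(n=20, p=6, d=0.8, seed=100 + seed)
        model = stepwise_lda(X, y)
        if model.is_empty:
            continue
        jack = jackknife_classify(X, y, model.selected_regions)
        resub = resubstitution_classify(X, y, model,
                                        [f"var{i}" for i in range(6)])
        diffs.append(resub.overall_accuracy - jack.overall_accuracy)
    assert np.mean(diffs) >= 0


def test_confusion_row_percentage_and_p():
    X, y = _two_group_data(n=30, d=1.5, seed=4)
    rep = jackknife_classify(X, y, ["var3"])
    assert rep.confusion.sum() == 60
    for g in ("neg", "pos"):
        row = rep.confusion[int(g == "pos")]
        assert row.sum() == 30
        expect_pct = round_half_away(100.0 * row[int(g == "pos")] / 30)
        assert rep.pct_correct[g] == expect_pct


# ---------------------------------------------------------------------------
# second-step rerun

def test_second_step_regions_disjoint_and_pick_up_the_copy():
    rng = np.random.default_rng(11)
    n = 80
    signal = np.concatenate([np.zeros(n), np.ones(n) * 2.0])
    X = rng.normal(size=(2 * n, 5))
    X[:, 0] += signal
    X[:, 4] = X[:, 0] + rng.normal(0, 0.4, size=2 * n)  # correlated duplicate
    y = np.array(["a"] * n + ["b"] * n)
    ids = ["sig", "n1", "n2", "n3", "copy"]
    first = stepwise_lda(X, y, region_ids=ids)
    assert first.selected_regions[0] == "sig"
    second, rep = second_step_rerun(X, y, None, first, ids)
    assert set(second.selected_regions).isdisjoint(first.selected_regions)
    assert "copy" in second.selected_regions
    assert rep.overall_accuracy > 0.7


def test_second_step_requires_nonempty_first_model():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(30, 3))
    y = np.array(["a", "b"] * 15)
    empty = stepwise_lda(X, y)
    assert empty.is_empty
    with pytest.raises(ClassifierError):
        second_step_rerun(X, y, None, empty, ["a", "b", "c"])


# ---------------------------------------------------------------------------
# score tests, coincidence, correlation

def test_score_test_identical_groups_gives_zero_t():
    scores = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    labels = ["a"] * 3 + ["b"] * 3
    t, df, p, lf, lp = score_group_test(scores, labels)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(0.5)


def test_score_test_welch_hand_case():
    scores = np.array([0.0, 0.0, 1.0, 1.0, 10.0, 10.0, 11.0, 11.0])
    labels = ["pos"] * 4 + ["neg"] * 4
    t, df, p, lf, lp = score_group_test(scores, labels, positive_label="pos")
    # Welch statistic: diff -10, se sqrt(1/6); df by Welch-Satterthwaite
    assert t == pytest.approx(-10.0 * math.sqrt(6), rel=1e-12)
    assert df == pytest.approx(6.0, rel=1e-12)
    assert p > 0.999  # one-sided toward positive-higher


def test_levene_nominal_rejection_rate():
    rng = np.random.default_rng(21)
    rejected = 0
    n_sim = 300
    for _ in range(n_sim):
        a = rng.normal(size=25)
        b = rng.normal(size=25)
        *_, lf, lp = score_group_test(np.concatenate([a, b]),
                                      ["x"] * 25 + ["y"] * 25)
        rejected += lp < 0.05
    assert 0.02 < rejected / n_sim < 0.09


def test_coincidence_and_correlation_edges():
    status = np.ones((10, 3), dtype=bool)
    rng = np.random.default_rng(31)
    scores = rng.normal(size=(10, 3))
    coin, corr = coincidence_and_correlation(status, scores, ["a", "b", "c"])
    assert np.allclose(coin, 1.0)
    assert np.allclose(np.diag(corr), 1.0)


def test_independent_symptoms_coincide_at_quarter_rate():
    rng = np.random.default_rng(32)
    status = rng.random((4000, 2)) < 0.5
    scores = rng.normal(size=(4000, 2))
    coin, _ = coincidence_and_correlation(status, scores, ["a", "b"])
    assert coin[0, 1] == pytest.approx(0.25, abs=0.03)


def test_discriminant_scores_standardised_and_oriented():
    X, y = _two_group_data(n=40, d=1.5, seed=6)
    model = stepwise_lda(X, y)
    s = discriminant_scores(X, y, model, [f"var{i}" for i in range(8)])
    y = np.asarray(y)
    assert s[y == "pos"].mean() > s[y == "neg"].mean()
    # pooled within-group variance is one
    v = (s[y == "pos"].var(ddof=1) + s[y == "neg"].var(ddof=1)) / 2
    assert v == pytest.approx(1.0, rel=0.05)
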