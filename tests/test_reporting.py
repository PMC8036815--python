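"""Metrics, survival machinery vs hand oracles, summaries, importance."""

import math

import numpy as np
import pandas as pd
import pytest

from immunocontext.reporting import (
    classification_metrics,
    cohort_summary,
    cox_hr_binary,
    feature_importance,
    km_curve,
    logrank_test,
    roc_auc,
    tnm_stratify,
)


# --- AUROC -----------------------------------------------------------------

def _auc_oracle(scores, labels, pos="bad"):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == pos
    pairs = wins = 0.0
    for a in s[y]:
        for b in s[~y]:
            pairs += 1
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / pairs


def test_auc_pair_enumeration_example():
    scores = [0.8, 0.4, 0.4, 0.2]
    labels = ["bad", "bad", "good", "good"]
    assert roc_auc(scores, labels) == pytest.approx((3 + 0.5) / 4)


def test_auc_perfect_ordering():
    assert roc_auc([3, 2, 1, 0], ["bad", "bad", "good", "good"]) == 1.0


def test_auc_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(4, 30))
        labels = np.array(["good"] * n)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = "bad"
        if len(set(labels)) < 2:
            continue
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # ties likely
        assert roc_auc(scores, labels) == pytest.approx(_auc_oracle(scores, labels))


def test_auc_random_scores_near_half():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=2000)
    labels = np.where(rng.random(2000) < 0.5, "bad", "good")
    assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], ["bad", "bad"])


# --- confusion-matrix metrics ----------------------------------------------

def test_metrics_all_correct():
    m = classification_metrics(["a", "b"], ["a", "b"], positive_class="a")
    assert all(v == 100.0 for v in m.values())


def test_metrics_hand_arithmetic():
    # TP=2, FN=0, TN=5, FP=2 with positive class "pos"
    pred = ["pos"] * 2 + ["pos"] * 2 + ["neg"] * 5
    true = ["pos"] * 2 + ["neg"] * 2 + ["neg"] * 5
    m = classification_metrics(pred, true, positive_class="pos")
    assert m["sensitivity"] == pytest.approx(100.0)
    assert m["specificity"] == pytest.approx(100 * 5 / 7, abs=0.05)
    assert m["accuracy"] == pytest.approx(100 * 7 / 9, abs=0.05)


def test_metrics_degenerate_f1_zero_safe():
    m = classification_metrics(["n", "n"], ["p", "p"], positive_class="p")
    assert m["f1"] == 0.0


# --- Kaplan–Meier ----------------------------------------------------------

def _km_oracle(times, events):
    """Textbook product-limit estimator."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    out = []
    s = 1.0
    for ti in np.unique(t[e]):
        at_risk = (t >= ti).sum()
        d = ((t == ti) & e).sum()
        s *= 1 - d / at_risk
        out.append((ti, s))
    return out


def test_km_no_events_flat():
    curve = km_curve([5.0, 10.0], [False, False])
    assert (curve["survival"] == 1.0).all()


def test_km_hand_product_limit():
    curve = km_curve([1.0, 2.0], [True, True])
    lookup = dict(zip(curve["time"], curve["survival"]))
    assert lookup[1.0] == pytest.approx(0.5)
    assert lookup[2.0] == pytest.approx(0.0)


def test_km_matches_textbook_oracle_random():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = int(rng.integers(3, 40))
        t = np.round(rng.exponential(10, n), 1) + 0.1
        e = rng.random(n) < 0.7
        if not e.any():
            continue
        curve = km_curve(t, e)
        lookup = dict(zip(curve["time"], curve["survival"]))
        for ti, si in _km_oracle(t, e):
            assert lookup[ti] == pytest.approx(si, abs=1e-9)


# --- log-rank ---------------------------------------------------------------

def _logrank_oracle(ta, ea, tb, eb):
    """Risk-table computation with hypergeometric variance."""
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb]).astype(bool)
    g = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    obs = exp = var = 0.0
    for ti in np.unique(t[e]):
        at = t >= ti
        n = at.sum()
        n1 = (at & (g == 1)).sum()
        d = ((t == ti) & e).sum()
        d1 = ((t == ti) & e & (g == 1)).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var


def test_logrank_identical_groups():
    t = np.array([2.0, 4.0, 6.0])
    e = np.array([True, True, False])
    chi2, p = logrank_test(t, e, t, e)
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_oracle():
    ta = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
    ea = np.array([1, 1, 0, 1, 0], dtype=bool)
    tb = np.array([2.0, 2.5, 4.0, 6.0, 8.0])
    eb = np.array([1, 1, 1, 0, 1], dtype=bool)
    chi2, _ = logrank_test(ta, ea, tb, eb)
    assert chi2 == pytest.approx(_logrank_oracle(ta, ea, tb, eb), rel=1e-6)


def test_logrank_power_under_rate_ratio_three():
    hits = 0
    n_rep = 100
    for s in range(n_rep):
        rng = np.random.default_rng(s)
        ta = rng.exponential(30.0, 200)
        tb = rng.exponential(10.0, 200)
        _, p = logrank_test(ta, np.ones(200, bool), tb, np.ones(200, bool))
        hits += p < 0.001
    assert hits >= 95


def test_logrank_invariant_to_subject_order():
    rng = np.random.default_rng(4)
    ta, tb = rng.exponential(10, 30), rng.exponential(14, 25)
    ea, eb = rng.random(30) < 0.8, rng.random(25) < 0.8
    perm = rng.permutation(30)
    c1, _ = logrank_test(ta, ea, tb, eb)
    c2, _ = logrank_test(ta[perm], ea[perm], tb, eb)
    assert c1 == pytest.approx(c2)


# --- Cox --------------------------------------------------------------------

def _cox_beta_grid_oracle(t, e, g):
    """Grid maximiser of the Breslow partial likelihood, one binary covariate."""
    t, e, g = np.asarray(t, float), np.asarray(e, bool), np.asarray(g, float)

    def pll(beta):
        ll = 0.0
        for ti in np.unique(t[e]):
            died = (t == ti) & e
            at = t >= ti
            ll += beta * g[died].sum() - died.sum() * math.log(
                np.exp(beta * g[at]).sum()
            )
        return ll

    grid = np.linspace(-4, 4, 8001)
    return grid[int(np.argmax([pll(b) for b in grid]))]


def test_cox_beta_matches_partial_likelihood_grid():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    e = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1], dtype=bool)
    g = np.array([1, 1, 1, 0, 1, 0, 0, 0, 1, 0])
    res = cox_hr_binary(t, e, g)
    assert res.beta == pytest.approx(_cox_beta_grid_oracle(t, e, g), abs=1e-3)
    assert res.ci_low < res.hr < res.ci_high


def test_cox_null_covers_one():
    covered = 0
    for s in range(100):
        rng = np.random.default_rng(s)
        t = rng.exponential(20, 1000)
        g = rng.integers(0, 2, 1000)
        res = cox_hr_binary(t, np.ones(1000, bool), g)
        covered += res.ci_low <= 1.0 <= res.ci_high
    assert covered >= 90


def test_cox_recovers_rate_ratio_three():
    rng = np.random.default_rng(11)
    g = np.repeat([0, 1], 500)
    t = np.where(g == 1, rng.exponential(10, 1000), rng.exponential(30, 1000))
    res = cox_hr_binary(t, np.ones(1000, bool), g)
    assert res.hr == pytest.approx(3.0, rel=0.2)


def test_cox_errors_and_separation():
    with pytest.raises(ValueError):
        cox_hr_binary([1.0, 2.0], [False, False], [0, 1])
    # complete separation: all events in group 1, none in group 0
    t = np.array([1.0, 2.0, 3.0, 50.0, 60.0, 70.0])
    e = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
    g = np.array([1, 1, 1, 0, 0, 0])
    res = cox_hr_binary(t, e, g)
    assert res.separated and res.hr == math.inf


def test_cox_and_logrank_agree_in_direction():
    for s in range(10):
        rng = np.random.default_rng(200 + s)
        g = rng.integers(0, 2, 120)
        t = np.where(g == 1, rng.exponential(8, 120), rng.exponential(20, 120))
        e = np.ones(120, bool)
        res = cox_hr_binary(t, e, g)
        assert res.hr > 1.0  # group 1 has worse survival


# --- TNM baseline and cohort summary ----------------------------------------

@pytest.mark.parametrize(
    "stage,risk", [("II", "low"), ("IIIA", "low"), ("IIIB", "low"), ("IV", "high")]
)
def test_tnm_stratification(stage, risk):
    assert tnm_stratify(stage) == risk


def test_tnm_unknown_stage():
    with pytest.raises(ValueError):
        tnm_stratify("I")


def test_cohort_summary_percentages():
    """55%/45% sex split for 43 males of 78; stage 17/29/5/27 → 22/37/6/35%."""
    rows = []
    stages = ["II"] * 17 + ["IIIA"] * 29 + ["IIIB"] * 5 + ["IV"] * 27
    sexes = ["male"] * 43 + ["female"] * 35
    for i in range(78):
        rows.append(dict(
            age=66.0, sex=sexes[i], stage=stages[i],
            T="T3", N="N0", M="M0", survival_months=19.0,
        ))
    summary = cohort_summary(pd.DataFrame(rows))
    assert summary["sex"]["male"]["percent"] == 55
    assert summary["sex"]["female"]["percent"] == 45
    assert [summary["stage"][s]["percent"] for s in ("II", "IIIA", "IIIB", "IV")] == [22, 37, 6, 35]
    assert summary["median_survival"] == 19.0


def test_cohort_summary_empty_errors():
    with pytest.raises(ValueError):
        cohort_summary(pd.DataFrame())


# --- feature importance ------------------------------------------------------

class _FakeSubmodel:
    def __init__(self, family, clf, names):
        from sklearn.pipeline import Pipeline
        self.family = family
        self.model = Pipeline([("clf", clf)])
        self.model.steps[-1] = ("clf", clf)
        self.feature_names = names


class _FakeTree:
    feature_importances_ = np.array([0.5, 0.3, 0.1, 0.05, 0.05])


class _FakeLinear:
    coef_ = np.array([[0.5, -0.3, 0.1, 0.05, -0.05]])
    kernel = "linear"


class _FakeRbf:
    kernel = "rbf"


NAMES = ("f1", "f2", "f3", "f4", "f5")


def test_importance_mean_rule():
    """{0.5,0.3,0.1,0.05,0.05}: threshold 2×mean = 0.4 retains one feature."""
    rep = feature_importance(_FakeSubmodel("decision_tree", _FakeTree(), NAMES))
    assert rep.threshold == pytest.approx(0.4)
    assert rep.retained == ("f1",)
    assert rep.rule == "2x_mean"


def test_importance_median_rule():
    """Same magnitudes with 2×median = 0.2 retain two features."""
    rep = feature_importance(_FakeSubmodel("svm", _FakeLinear(), NAMES))
    assert rep.threshold == pytest.approx(0.2)
    assert rep.retained == ("f1", "f2")
    assert rep.rule == "2x_median"
    # signs preserved for linear models
    signs = dict(zip(rep.ranked["feature"], rep.ranked["sign"]))
    assert signs["f2"] == -1.0


def test_importance_logistic_uses_mean_rule_with_signs():
    rep = feature_importance(_FakeSubmodel("logistic_model", _FakeLinear(), NAMES))
    assert rep.rule == "2x_mean"
    assert rep.retained == ("f1",)


def test_importance_rbf_svm_unsupported():
    with pytest.raises(ValueError, match="linear"):
        feature_importance(_FakeSubmodel("svm", _FakeRbf(), NAMES))
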