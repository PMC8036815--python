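"""Evaluation: classification metrics, survival curves and tests,
the TNM baseline, cohort summaries, and post-hoc feature importance.

Survival machinery (Kaplan–Meier, log-rank, univariate Cox with Breslow
tie handling and Wald intervals) is delegated to lifelines behind this
module's interface; the test suite cross-checks it against hand-rolled
product-limit / risk-table / partial-likelihood oracles.

Metric orientation: in the published comparison the "sensitivity" row
tracks good-prognosis patients (how many survivors the model clears) and
"specificity" tracks bad-prognosis patients (how many eventual MIBC
deaths it flags).  ``classification_metrics`` therefore defaults its
positive class to good prognosis / low risk, and the orientation is an
explicit argument.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.metrics import roc_auc_score


def roc_auc(scores, labels, positive_label="bad") -> float:
    """AUROC: P(score_pos > score_neg) + ½·P(ties) over pos–neg pairs."""
    y = np.asarray(labels) == positive_label
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def classification_metrics(
    predictions, labels, positive_class
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F1, all in percent.

    ``predictions`` and ``labels`` are label arrays over the same two
    values; ``positive_class`` fixes which class sensitivity tracks.
    F1 uses the zero-safe convention (0 when precision + recall = 0).
    """
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if len(pred) == 0 or len(pred) != len(lab):
        raise ValueError("predictions and labels must be equal-length and non-empty")
    p = pred == positive_class
    t = lab == positive_class
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "accuracy": 100.0 * (tp + tn) / len(lab),
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "f1": 100.0 * f1,
    }


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    ``events`` is True for an observed event, False for right-censoring
    (censored subjects leave the risk set only).  Returns a step function
    as a DataFrame with ``time`` and ``survival`` columns, starting at
    (0, 1).
    """
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (χ² statistic, p value)."""
    if len(np.asarray(times_a)) == 0 or len(np.asarray(times_b)) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(
        np.asarray(times_a, dtype=float),
        np.asarray(times_b, dtype=float),
        event_observed_A=np.asarray(events_a, dtype=bool),
        event_observed_B=np.asarray(events_b, dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    beta: float
    separated: bool = False


def cox_hr_binary(times, events, group) -> CoxResult:
    """Univariate Cox hazard ratio for a binary group indicator.

    Breslow tie handling; Wald 95% CI on the log scale.  Complete
    separation (a group with no events while the other has all of them
    drives β̂ → ∞) is flagged with an infinite-HR sentinel rather than
    raised.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group, dtype=int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("group must be binary 0/1")
    if e.sum() == 0:
        raise ValueError("no events observed")
    df = pd.DataFrame({"t": t, "e": e.astype(int), "g": g})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="t", event_col="e")
    except ConvergenceError:
        sign = 1.0 if e[g == 1].mean() >= e[g == 0].mean() else -1.0
        return CoxResult(
            hr=math.inf if sign > 0 else 0.0,
            ci_low=0.0, ci_high=math.inf, beta=sign * math.inf, separated=True,
        )
    beta = float(cph.params_["g"])
    se = float(cph.standard_errors_["g"])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 50:
        return CoxResult(
            hr=math.inf if beta > 0 else 0.0,
            ci_low=0.0, ci_high=math.inf, beta=beta, separated=True,
        )
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        beta=beta,
    )


def tnm_stratify(stage: str) -> str:
    """TNM risk baseline: stage IV is high risk, stages II/III low risk."""
    if stage in ("II", "IIIA", "IIIB"):
        return "low"
    if stage == "IV":
        return "high"
    raise ValueError(f"unknown stage {stage!r}")


def _pct(count: int, total: int) -> int:
    return int(math.floor(100.0 * count / total + 0.5))


def cohort_summary(clinical: pd.DataFrame) -> dict:
    """Cohort characteristics table: counts with round-half-up percentages,
    median (range) survival and mean ± SD age."""
    if len(clinical) == 0:
        raise ValueError("empty cohort")
    n = len(clinical)
    out: dict = {"n": n}
    if "survival_months" in clinical:
        t = clinical["survival_months"].to_numpy(dtype=float)
        out["median_survival"] = float(np.median(t))
        out["survival_range"] = (float(t.min()), float(t.max()))
    out["age_mean"] = float(clinical["age"].mean())
    out["age_sd"] = float(clinical["age"].std(ddof=0))
    for col, cats in (
        ("sex", ("male", "female")),
        ("stage", ("II", "IIIA", "IIIB", "IV")),
        ("T", ("T2", "T3", "T4")),
        ("N", ("N0", "N1", "N2")),
        ("M", ("M0", "M1")),
    ):
        counts = {c: int((clinical[col] == c).sum()) for c in cats}
        out[col] = {c: {"count": k, "percent": _pct(k, n)} for c, k in counts.items()}
    return out


@dataclass
class ImportanceReport:
    family: str
    ranked: pd.DataFrame       # feature, importance, sign — descending
    retained: tuple[str, ...]
    threshold: float
    rule: str                  # "2x_mean" | "2x_median"


def feature_importance(submodel) -> ImportanceReport:
    """Post-hoc importance with the family-specific retention threshold.

    DT and RF expose impurity-decrease importances (mean Gini decrease
    over trees for the forest); the logistic model and linear SVM use
    |coefficient| with the sign retained.  Retention keeps features above
    2× the mean importance (DT, logistic, RF) or 2× the median (linear
    SVM, whose |weight| distribution is long-tailed).  Nonlinear-kernel
    SVMs have no per-feature weights and are unsupported.
    """
    clf = submodel.model.named_steps["clf"]
    family = submodel.family
    names = np.asarray(submodel.feature_names)
    if family in ("decision_tree", "random_forest"):
        imp = np.asarray(clf.feature_importances_, dtype=float)
        sign = np.zeros_like(imp)
        rule = "2x_mean"
    elif family == "logistic_model":
        coef = np.asarray(clf.coef_[0], dtype=float)
        imp, sign = np.abs(coef), np.sign(coef)
        rule = "2x_mean"
    elif family == "svm":
        if clf.kernel != "linear":
            raise ValueError("feature importance requires a linear kernel")
        coef = np.asarray(clf.coef_[0], dtype=float)
        imp, sign = np.abs(coef), np.sign(coef)
        rule = "2x_median"
    else:
        raise ValueError(f"unsupported family {family!r}")

    threshold = 2.0 * (np.median(imp) if rule == "2x_median" else imp.mean())
    order = np.argsort(-imp, kind="stable")
    ranked = pd.DataFrame(
        {"feature": names[order], "importance": imp[order], "sign": sign[order]}
    )
    retained = tuple(names[order][imp[order] > threshold])
    return ImportanceReport(
        family=family, ranked=ranked, retained=retained,
        threshold=float(threshold), rule=rule,
    )


def risk_group_report(
    vote_scores,
    high_risk,
    labels,
    times,
    mibc_event,
) -> dict:
    """Full evaluation block for one risk model on one patient set.

    ``labels`` are bad/good prognosis; ``high_risk`` the model's risk
    calls; ``vote_scores`` the ordinal score used for the ROC;
    ``times``/``mibc_event`` the underlying survival data for KM,
    log-rank and Cox.
    """
    labels = np.asarray(labels)
    high = np.asarray(high_risk, dtype=bool)
    times = np.asarray(times, dtype=float)
    events = np.asarray(mibc_event, dtype=bool)

    metrics = classification_metrics(
        np.where(high, "bad", "good"), labels, positive_class="good"
    )
    # ROC orientation: higher score should track bad prognosis
    auroc = roc_auc(np.asarray(vote_scores, dtype=float), labels, positive_label="bad")
    out = {"auroc": 100.0 * auroc, **metrics}
    out["n_high"] = int(high.sum())
    out["n_low"] = int((~high).sum())
    if 0 < high.sum() < len(high):
        chi2, p = logrank_test(times[~high], events[~high], times[high], events[high])
        cox = cox_hr_binary(times, events, high.astype(int))
        out.update(
            logrank_chi2=chi2, logrank_p=p,
            hazard_ratio=cox.hr, hr_ci=(cox.ci_low, cox.ci_high),
            hr_separated=cox.separated,
        )
        out["km_low"] = km_curve(times[~high], events[~high])
        out["km_high"] = km_curve(times[high], events[high])
    return out
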