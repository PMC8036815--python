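"""Model selection, nested cross-validation, and the voting ensemble.

Five classifier families with distinct inductive biases compete: decision
tree (DT), random forest (RF), support-vector machine (SVM), a regularised
logistic model (the classification reading of "linear regression", giving
probability scores and signed coefficients), and k-nearest neighbours
(KNN).  Hyperparameters are tuned by random search — 200 configurations
sampled from per-family distributions, each scored by mean AUROC over
stratified 5-fold cross-validation.  Algorithm selection wraps that in an
outer stratified 2-fold loop (nested cross-validation): per outer fold each
family is re-tuned on the outer-training part and scored on the held-out
part; the family with the highest mean outer AUROC wins, ties going to the
lower variance.

The final risk model is an ensemble of four (family, feature-set)
submodels — linear SVM on image features, DT on image+clinical, logistic
on image+spatial, RF on all features.  Each submodel's operating threshold
maximises Youden's J on its own training ROC; a patient is called
high-risk when two or more submodels vote bad prognosis, and the 0–4 vote
count is the ensemble's ordinal score.

Feature normalisation (per-feature z-score) applies to SVM, logistic and
KNN only, fitted inside the CV pipeline so statistics never leak from
validation folds.  A row-access audit can be attached to verify that
held-out patients are untouched during tuning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import feature_subset

FAMILIES = ("decision_tree", "random_forest", "svm", "logistic_model", "knn")

#: Families whose pipelines include a z-score normalisation step.
NORMALIZED_FAMILIES = frozenset({"svm", "logistic_model", "knn"})

N_CONFIGS = 200
INNER_FOLDS = 5
OUTER_FOLDS = 2
VOTE_THRESHOLD = 2

#: The four (family, feature-set) submodels of the published ensemble.
ENSEMBLE_COMPOSITION: tuple[tuple[str, str], ...] = (
    ("svm", "image"),                       # linear kernel enforced below
    ("decision_tree", "image_clinical"),
    ("logistic_model", "image_spatial"),
    ("random_forest", "image_spatial_clinical"),
)


class RowAccessLog:
    """Audit trail of which patients each training stage touched."""

    def __init__(self) -> None:
        self.records: list[tuple[str, frozenset]] = []

    def record(self, stage: str, ids: Sequence) -> None:
        self.records.append((stage, frozenset(ids)))

    @property
    def all_ids(self) -> frozenset:
        out: frozenset = frozenset()
        for _, ids in self.records:
            out |= ids
        return out


def sample_config(family: str, rng: np.random.Generator, *, linear_only: bool = False) -> dict:
    """Draw one hyperparameter configuration from the family's distributions."""
    if family == "decision_tree":
        return {
            "max_depth": int(rng.integers(1, 21)),
            "min_samples_leaf": int(rng.integers(1, 21)),
            "criterion": str(rng.choice(["gini", "entropy"])),
        }
    if family == "random_forest":
        return {
            "n_estimators": int(rng.integers(50, 301)),
            "max_depth": int(rng.integers(1, 21)),
            "max_features": float(rng.uniform(0.1, 1.0)),
        }
    if family == "svm":
        kernel = "linear" if linear_only else str(rng.choice(["linear", "rbf"]))
        cfg = {"kernel": kernel, "C": float(10 ** rng.uniform(-3, 3))}
        if kernel == "rbf":
            cfg["gamma"] = float(10 ** rng.uniform(-4, 1))
        return cfg
    if family == "logistic_model":
        return {
            "penalty": str(rng.choice(["l1", "l2"])),
            "C": float(10 ** rng.uniform(-3, 3)),
        }
    if family == "knn":
        return {
            "n_neighbors": int(rng.integers(1, 26)),
            "weights": str(rng.choice(["uniform", "distance"])),
        }
    raise ValueError(f"unknown family {family!r}")


def make_estimator(family: str, config: Mapping, seed: int, n_rows: int) -> Pipeline:
    """Build the (optionally normalising) pipeline for one configuration."""
    cfg = dict(config)
    if family == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed, **cfg)
    elif family == "random_forest":
        est = RandomForestClassifier(random_state=seed, **cfg)
    elif family == "svm":
        est = SVC(random_state=seed, **cfg)
    elif family == "logistic_model":
        cfg["l1_ratio"] = 1.0 if cfg.pop("penalty", "l2") == "l1" else 0.0
        est = LogisticRegression(solver="liblinear", max_iter=2000, random_state=seed, **cfg)
    elif family == "knn":
        cfg["n_neighbors"] = min(cfg["n_neighbors"], max(1, n_rows - 1))
        est = KNeighborsClassifier(**cfg)
    else:
        raise ValueError(f"unknown family {family!r}")
    steps = []
    if family in NORMALIZED_FAMILIES:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", est))
    return Pipeline(steps)


def decision_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    """Continuous score for the bad-prognosis class (larger = worse)."""
    clf = model.named_steps["clf"]
    if hasattr(clf, "predict_proba"):
        proba = model.predict_proba(X)
        return proba[:, list(model.classes_).index(1)]
    return model.decision_function(X)


@dataclass
class SearchResult:
    family: str
    config: dict
    mean_auc: float
    fold_aucs: np.ndarray
    n_evaluated: int


def _check_labels(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")


def random_search(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    n_configs: int = N_CONFIGS,
    folds: int = INNER_FOLDS,
    seed: int = 0,
    *,
    linear_only: bool = False,
    audit: RowAccessLog | None = None,
    ids: Sequence | None = None,
    sampler=None,
) -> SearchResult:
    """Tune one family by random search over stratified k-fold CV.

    Returns the configuration with the highest mean validation AUROC;
    ties break to the lower across-fold variance, then to the
    first-sampled configuration.  ``sampler`` overrides the default
    hyperparameter distributions (signature ``sampler(family, rng)``),
    e.g. to collapse them to a point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_labels(y)
    if audit is not None:
        audit.record(f"random_search[{family}]", ids if ids is not None else range(len(y)))
    rng = np.random.default_rng(seed)
    fit_seed = int(rng.integers(2**31))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
    splits = list(skf.split(X, y))

    best: tuple[float, float, int] | None = None  # (-mean, var, order)
    best_result: SearchResult | None = None
    draw = sampler or (lambda fam, r: sample_config(fam, r, linear_only=linear_only))
    for order in range(n_configs):
        config = draw(family, rng)
        aucs = np.empty(len(splits))
        for f, (tr, va) in enumerate(splits):
            model = make_estimator(family, config, fit_seed, len(tr))
            model.fit(X[tr], y[tr])
            aucs[f] = roc_auc_score(y[va], decision_scores(model, X[va]))
        key = (-aucs.mean(), aucs.var(), order)
        if best is None or key < best:
            best = key
            best_result = SearchResult(family, config, float(aucs.mean()), aucs, n_configs)
    assert best_result is not None
    return best_result


@dataclass
class NestedSelection:
    best_family: str
    family_scores: dict[str, dict]     # mean, spread, per-fold outer AUROCs
    outer_folds: int


def nested_select(
    X: np.ndarray,
    y: np.ndarray,
    families: Sequence[str] = FAMILIES,
    outer_folds: int = OUTER_FOLDS,
    inner_folds: int = INNER_FOLDS,
    n_configs: int = N_CONFIGS,
    seed: int = 0,
    *,
    audit: RowAccessLog | None = None,
    ids: Sequence | None = None,
) -> NestedSelection:
    """Nested-CV algorithm selection across classifier families.

    Each outer fold re-tunes every family on its training part (inner
    random search) and scores the tuned model on its evaluation part.
    The winner maximises mean outer AUROC; ties go to the family with the
    least across-fold variance.  Scores are reported mean ± half-range
    across the outer folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_labels(y)
    if audit is not None:
        audit.record("nested_select", ids if ids is not None else range(len(y)))
    master = np.random.SeedSequence(seed)
    outer_seed, *fam_seeds = [int(s.generate_state(1)[0] % 2**31) for s in master.spawn(1 + len(families) * outer_folds)]
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=outer_seed)

    scores: dict[str, list[float]] = {f: [] for f in families}
    si = iter(fam_seeds)
    for tr, ev in skf.split(X, y):
        for fam in families:
            s = next(si)
            res = random_search(fam, X[tr], y[tr], n_configs, inner_folds, seed=s)
            model = make_estimator(fam, res.config, s, len(tr))
            model.fit(X[tr], y[tr])
            scores[fam].append(roc_auc_score(y[ev], decision_scores(model, X[ev])))

    summary = {
        f: {
            "mean": float(np.mean(v)),
            "spread": float((max(v) - min(v)) / 2),
            "var": float(np.var(v)),
            "folds": [float(x) for x in v],
        }
        for f, v in scores.items()
    }
    best = min(families, key=lambda f: (-summary[f]["mean"], summary[f]["var"]))
    return NestedSelection(best_family=best, family_scores=summary, outer_folds=outer_folds)


@dataclass
class FittedSubmodel:
    family: str
    feature_set: str
    feature_names: tuple[str, ...]
    model: Pipeline
    threshold: float
    config: dict
    train_auc: float

    def scores(self, features: pd.DataFrame) -> np.ndarray:
        X = features.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        return decision_scores(self.model, X)

    def votes(self, features: pd.DataFrame) -> np.ndarray:
        """True where the submodel votes bad prognosis."""
        return self.scores(features) >= self.threshold


def youden_threshold(y: np.ndarray, scores: np.ndarray) -> float:
    """Operating point maximising sensitivity + specificity − 1."""
    fpr, tpr, thresholds = roc_curve(y, scores)
    j = tpr - fpr
    return float(thresholds[int(np.argmax(j))])


def fit_submodel(
    family: str,
    feature_set: str,
    features: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_configs: int = N_CONFIGS,
    *,
    linear_only: bool = False,
    audit: RowAccessLog | None = None,
) -> FittedSubmodel:
    """Tune on the whole training set, refit, and pick the Youden threshold."""
    sub = feature_subset(features, feature_set)
    X = sub.to_numpy(dtype=float)
    y = np.asarray(y, dtype=int)
    res = random_search(
        family, X, y, n_configs, seed=seed, linear_only=linear_only,
        audit=audit, ids=features.index,
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    model = make_estimator(family, res.config, int(rng.integers(2**31)), len(y))
    model.fit(X, y)
    if audit is not None:
        audit.record(f"fit[{family}:{feature_set}]", features.index)
    scores = decision_scores(model, X)
    return FittedSubmodel(
        family=family,
        feature_set=feature_set,
        feature_names=tuple(sub.columns),
        model=model,
        threshold=youden_threshold(y, scores),
        config=res.config,
        train_auc=float(roc_auc_score(y, scores)),
    )


@dataclass
class EnsembleModel:
    """Majority-style voting ensemble over four fitted submodels."""

    submodels: tuple[FittedSubmodel, ...]
    vote_threshold: int = VOTE_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.submodels) != 4:
            raise ValueError("the ensemble carries exactly four submodels")
        if not 1 <= self.vote_threshold <= 4:
            raise ValueError("vote_threshold must be in 1..4")

    def vote_counts(self, features: pd.DataFrame) -> np.ndarray:
        """Number of bad-prognosis votes per patient (the ROC score)."""
        votes = np.column_stack([m.votes(features) for m in self.submodels])
        return votes.sum(axis=1)

    def predict_high_risk(self, features: pd.DataFrame) -> np.ndarray:
        return self.vote_counts(features) >= self.vote_threshold


def ensemble_predict(ensemble: EnsembleModel, features: pd.DataFrame) -> pd.DataFrame:
    """Risk class and vote count per patient."""
    missing = set()
    for m in ensemble.submodels:
        missing |= set(m.feature_names) - set(features.columns)
    if missing:
        raise KeyError(f"feature matrix lacks required columns: {sorted(missing)[:5]}")
    counts = ensemble.vote_counts(features)
    return pd.DataFrame(
        {
            "vote_count": counts,
            "risk": np.where(counts >= ensemble.vote_threshold, "high", "low"),
        },
        index=features.index,
    )


def fit_ensemble(
    features: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_configs: int = N_CONFIGS,
    *,
    audit: RowAccessLog | None = None,
) -> EnsembleModel:
    """Fit the published four-submodel composition on training data."""
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(4)]
    subs = []
    for (family, fset), s in zip(ENSEMBLE_COMPOSITION, seeds):
        subs.append(
            fit_submodel(
                family, fset, features, y, seed=s, n_configs=n_configs,
                linear_only=(family == "svm"), audit=audit,
            )
        )
    return EnsembleModel(submodels=tuple(subs))
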