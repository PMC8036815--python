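"""End-to-end study driver on a synthetic cohort.

Chains the full analysis: cohort generation → feature assembly (201
features) → 5-year label binarization with censoring exclusion →
stratified train/test split → four-submodel ensemble fitting on the
training set only → evaluation of the ensemble and the TNM baseline on
the held-out test set (classification metrics plus KM/log-rank/Cox risk
stratification).

By default patients excluded by the label rule are dropped *before*
splitting (leakage-safe); splitting before exclusion is available to
mirror bookkeeping that quotes cohort-level patient counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureSchema, DEFAULT_SCHEMA, assemble_features
from .labels import LABEL_EXCLUDED, LabelReport, binarize_survival, stratified_split
from .learning import EnsembleModel, N_CONFIGS, RowAccessLog, fit_ensemble
from .reporting import risk_group_report, tnm_stratify
from .synthetic import CohortConfig, clinical_table, generate_cohort


@dataclass
class StudyResult:
    features: pd.DataFrame
    clinical: pd.DataFrame
    label_report: LabelReport
    train_ids: np.ndarray
    test_ids: np.ndarray
    ensemble: EnsembleModel
    ensemble_report: dict
    tnm_report: dict
    audit: RowAccessLog


_STAGE_ORDINAL = {"II": 0, "IIIA": 1, "IIIB": 2, "IV": 3}


def tnm_baseline_report(clinical: pd.DataFrame, labels: pd.Series) -> dict:
    """Evaluate the TNM low/high stratification as a classifier.

    The ROC score is the ordinal stage (II < IIIA < IIIB < IV); risk
    calls follow the stage II/III = low, IV = high rule.
    """
    high = clinical["stage"].map(tnm_stratify).to_numpy() == "high"
    scores = clinical["stage"].map(_STAGE_ORDINAL).to_numpy(dtype=float)
    return risk_group_report(
        scores,
        high,
        labels.to_numpy(),
        clinical["survival_months"].to_numpy(dtype=float),
        (clinical["event_cause"] == "mibc_death").to_numpy(),
    )


def run_study(
    config: CohortConfig,
    *,
    test_fraction: float = 0.25,
    n_configs: int = N_CONFIGS,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    split_before_exclusion: bool = False,
    split_seed: int | None = None,
) -> StudyResult:
    """Run the whole pipeline once; all randomness flows from config.seed."""
    cohort = generate_cohort(config)
    features = assemble_features(cohort, schema)
    clinical = clinical_table(cohort).set_index("patient_id")
    clinical = clinical.loc[features.index]

    report = binarize_survival(clinical)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    if split_seed is None:
        split_seed = int(seeds[1].generate_state(1)[0] % 2**31)
    fit_seed = int(seeds[2].generate_state(1)[0] % 2**31)

    if split_before_exclusion:
        tr, te = stratified_split(report.labels, test_fraction, split_seed)
        keep = report.labels != LABEL_EXCLUDED
        train_ids = report.labels.index[tr][keep.iloc[tr]].to_numpy()
        test_ids = report.labels.index[te][keep.iloc[te]].to_numpy()
    else:
        labelled = report.labels[report.labels != LABEL_EXCLUDED]
        tr, te = stratified_split(labelled, test_fraction, split_seed)
        train_ids = labelled.index[tr].to_numpy()
        test_ids = labelled.index[te].to_numpy()

    audit = RowAccessLog()
    y_train = (report.labels.loc[train_ids] == "bad").astype(int).to_numpy()
    ensemble = fit_ensemble(
        features.loc[train_ids], y_train, seed=fit_seed, n_configs=n_configs,
        audit=audit,
    )

    test_feats = features.loc[test_ids]
    test_clin = clinical.loc[test_ids]
    test_labels = report.labels.loc[test_ids]
    counts = ensemble.vote_counts(test_feats)
    ens_report = risk_group_report(
        counts,
        counts >= ensemble.vote_threshold,
        test_labels.to_numpy(),
        test_clin["survival_months"].to_numpy(dtype=float),
        (test_clin["event_cause"] == "mibc_death").to_numpy(),
    )
    tnm_report = tnm_baseline_report(test_clin, test_labels)
    return StudyResult(
        features=features,
        clinical=clinical,
        label_report=report,
        train_ids=train_ids,
        test_ids=test_ids,
        ensemble=ensemble,
        ensemble_report=ens_report,
        tnm_report=tnm_report,
        audit=audit,
    )
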