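"""Binarized 5-year prognosis labels and stratified sampling.

Survival is reduced to a binary classification target at a fixed cut-off
(default 60 months): patients who died of MIBC at or before the cut-off
have a *bad* prognosis; patients observed beyond the cut-off — alive,
censored later, or dying later of any cause — have a *good* prognosis;
patients censored before the cut-off (other-cause death, or alive with
follow-up ending early) are *excluded*, since their 5-year status is
unknowable.  Because time-to-censoring is independent of the disease
process, the exclusion introduces no outcome bias.

Stratified sampling draws round-half-up(fraction × class size) per class,
then reconciles the total to round-half-up(fraction × n) by a
largest-remainder adjustment — e.g. a 20% sample of 75 + 25 patients
contains exactly 15 + 5, and a 25% test split of 78 gives 20 test / 58
train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CUTOFF_MONTHS = 60.0

LABEL_BAD = "bad"
LABEL_GOOD = "good"
LABEL_EXCLUDED = "excluded"


@dataclass
class LabelReport:
    labels: pd.Series
    n_bad: int
    n_good: int
    n_excluded: int
    excluded_fraction: float
    reasons: pd.Series


def binarize_survival(records: pd.DataFrame, cutoff: float = CUTOFF_MONTHS) -> LabelReport:
    """Assign bad / good / excluded prognosis labels.

    ``records`` needs ``survival_months`` (> 0) and ``event_cause`` in
    {mibc_death, other_death, alive_censored} columns; the index
    identifies patients.
    """
    t = records["survival_months"].to_numpy(dtype=float)
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        bad_idx = records.index[(t <= 0) | ~np.isfinite(t)].tolist()
        raise ValueError(f"non-positive survival time for {bad_idx}")
    cause = records["event_cause"].astype(str).to_numpy()
    unknown = set(cause) - {"mibc_death", "other_death", "alive_censored"}
    if unknown:
        raise ValueError(f"unknown event causes {sorted(unknown)}")

    labels = np.full(len(records), LABEL_GOOD, dtype=object)
    reasons = np.full(len(records), "", dtype=object)
    bad = (cause == "mibc_death") & (t <= cutoff)
    excl = (cause != "mibc_death") & (t <= cutoff)
    labels[bad] = LABEL_BAD
    labels[excl] = LABEL_EXCLUDED
    reasons[excl] = np.where(
        cause[excl] == "other_death",
        "other-cause death before cut-off",
        "censored alive before cut-off",
    )
    lab = pd.Series(labels, index=records.index, name="label")
    return LabelReport(
        labels=lab,
        n_bad=int(bad.sum()),
        n_good=int((labels == LABEL_GOOD).sum()),
        n_excluded=int(excl.sum()),
        excluded_fraction=float(excl.sum() / len(records)),
        reasons=pd.Series(reasons, index=records.index, name="reason"),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_sample(labels: pd.Series, fraction: float, seed: int) -> np.ndarray:
    """Sample positions proportionally per class, uniformly within class.

    Per-class quotas are round-half-up(fraction · class size); if their
    sum differs from round-half-up(fraction · n), the largest-remainder
    rule adds/removes one member at a time from the classes whose quota
    was rounded furthest from fraction · size.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    labels = pd.Series(labels).reset_index(drop=True)
    classes = labels.unique()
    if any((labels == c).sum() == 0 for c in classes) or len(labels) == 0:
        raise ValueError("every class must be non-empty")

    total_target = _round_half_up(fraction * len(labels))
    exact = {c: fraction * (labels == c).sum() for c in classes}
    quota = {c: _round_half_up(exact[c]) for c in classes}
    # largest-remainder reconciliation towards the overall target
    while sum(quota.values()) < total_target:
        c = max(classes, key=lambda c: (exact[c] - quota[c], str(c)))
        quota[c] += 1
    while sum(quota.values()) > total_target:
        c = min(
            (c for c in classes if quota[c] > 0),
            key=lambda c: (exact[c] - quota[c], str(c)),
        )
        quota[c] -= 1

    rng = np.random.default_rng(seed)
    picked: list[np.ndarray] = []
    for c in classes:
        members = np.flatnonzero(labels.to_numpy() == c)
        picked.append(rng.choice(members, size=min(quota[c], len(members)), replace=False))
    return np.sort(np.concatenate(picked))


def stratified_split(
    labels: pd.Series, test_fraction: float = 0.25, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split; returns (train, test) positions."""
    test = stratified_sample(labels, test_fraction, seed)
    n = len(labels)
    train = np.setdiff1d(np.arange(n), test)
    return train, test
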