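"""Overall-survival labeling, exclusion rules, and stratified splits.

Patients are dichotomized into short (OS <= 9 months) and long (OS >= 13
months) survivors; the band in between is excluded to avoid indeterminate
cases near the cut-offs, and day-scale outliers (< 15 days, > 1400 days) are
excluded beforehand.  The retained cohort is split into an experimentation set
(80%) and a hold-out test set (20%), with the experimentation set further
partitioned into stratified cross-validation folds; within each fold
iteration the data divide into training (80%), validation (10%) and testing
(10%) partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalRule",
    "LabeledCohort",
    "SplitPlan",
    "CohortSplit",
    "label_survival",
    "split_cohort",
    "fold_partitions",
]

LABELS = ("short", "long", "excluded_low", "excluded_high", "excluded_middle")


@dataclass(frozen=True)
class SurvivalRule:
    """Cut-offs for survival-group labeling.

    Month cut-offs are inclusive as printed (<= 9 months short, >= 13 months
    long); day-scale outlier exclusions are strict (< 15 days, > 1400 days)
    and take precedence.  ``days_per_month`` defaults to the calendar average
    365.25 / 12 = 30.4375.
    """

    short_max_months: float = 9.0
    long_min_months: float = 13.0
    min_days: float = 15.0
    max_days: float = 1400.0
    days_per_month: float = 365.25 / 12.0

    def __post_init__(self) -> None:
        if self.short_max_months >= self.long_min_months:
            raise ValueError("short cut-off must be below long cut-off")
        if self.min_days >= self.max_days:
            raise ValueError("min_days must be below max_days")

    @property
    def short_max_days(self) -> float:
        return self.short_max_months * self.days_per_month

    @property
    def long_min_days(self) -> float:
        return self.long_min_months * self.days_per_month


@dataclass
class LabeledCohort:
    """Per-patient survival labels plus rows rejected for invalid OS."""

    table: pd.DataFrame          # patient_id, os_days, label
    rejected: pd.DataFrame       # patient_id, os_days, reason
    rule: SurvivalRule

    def subset(self, labels: tuple[str, ...] = ("short", "long")) -> pd.DataFrame:
        return self.table[self.table["label"].isin(labels)].reset_index(drop=True)

    def counts(self) -> dict[str, int]:
        c = self.table["label"].value_counts().to_dict()
        return {lab: int(c.get(lab, 0)) for lab in LABELS}


def label_survival(clinical: pd.DataFrame, rule: SurvivalRule | None = None) -> LabeledCohort:
    """Label every patient short / long / excluded_{low,high,middle}.

    Rows with missing or negative ``os_days`` are rejected with a report entry
    rather than labeled.  Outlier-day rules apply before the month bands.
    """
    rule = rule or SurvivalRule()
    df = clinical[["patient_id", "os_days"]].copy()

    bad = df["os_days"].isna() | (df["os_days"] < 0)
    rejected = df[bad].copy()
    rejected["reason"] = np.where(rejected["os_days"].isna(), "missing_os", "negative_os")
    df = df[~bad].copy()

    days = df["os_days"].to_numpy(dtype=float)
    label = np.full(days.shape, "excluded_middle", dtype=object)
    label[days <= rule.short_max_days] = "short"
    label[days >= rule.long_min_days] = "long"
    # outlier exclusion takes precedence over the month bands
    label[days < rule.min_days] = "excluded_low"
    label[days > rule.max_days] = "excluded_high"
    df["label"] = label
    return LabeledCohort(table=df.reset_index(drop=True),
                         rejected=rejected.reset_index(drop=True), rule=rule)


@dataclass(frozen=True)
class SplitPlan:
    """Hold-out fraction, fold count, and the seed driving both."""

    test_fraction: float = 0.2
    cv_folds: int = 10
    seed: int = 0
    stratify_by_label: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in [0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class CohortSplit:
    """Experimentation/hold-out partition plus fold assignments.

    ``folds`` maps each experimentation patient to a fold id in [0, cv_folds).
    Within fold iteration *i*, fold *i* is the test partition, fold *i+1*
    (cyclically) the validation partition, and the rest the training
    partition — an 80/10/10 division for 10 folds.
    """

    train: pd.DataFrame          # patient_id, os_days, label
    holdout: pd.DataFrame
    folds: pd.Series             # index patient_id -> fold id
    plan: SplitPlan

    def to_manifest(self) -> dict:
        return {
            "test_fraction": self.plan.test_fraction,
            "cv_folds": self.plan.cv_folds,
            "seed": self.plan.seed,
            "experimentation": sorted(self.train["patient_id"]),
            "holdout": sorted(self.holdout["patient_id"]),
            "folds": {pid: int(f) for pid, f in self.folds.items()},
        }

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_manifest(), indent=2))


def split_cohort(cohort: LabeledCohort, plan: SplitPlan | None = None) -> CohortSplit:
    """Class-stratified hold-out split and fold assignment, seeded.

    Hold-out counts per class are ``round(test_fraction * n_class)``, so a
    balanced cohort yields a balanced hold-out (±1).  Each class's remaining
    patients are dealt round-robin into folds; a class smaller than the fold
    count is an error.
    """
    plan = plan or SplitPlan()
    rng = np.random.default_rng(plan.seed)
    usable = cohort.subset(("short", "long"))
    classes = sorted(usable["label"].unique()) if plan.stratify_by_label else ["all"]
    if plan.stratify_by_label and len(classes) < 2:
        raise ValueError("cohort must contain both classes after exclusions")

    holdout_ids: list[str] = []
    fold_of: dict[str, int] = {}
    for cls in classes:
        rows = usable if cls == "all" else usable[usable["label"] == cls]
        ids = rows["patient_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        n_test = int(round(plan.test_fraction * len(ids)))
        holdout_ids.extend(ids[:n_test])
        rest = ids[n_test:]
        if len(rest) < plan.cv_folds:
            raise ValueError(
                f"class {cls!r} has {len(rest)} members after the hold-out split; "
                f"fewer than cv_folds={plan.cv_folds}"
            )
        for i, pid in enumerate(rest):
            fold_of[pid] = i % plan.cv_folds

    holdout = usable[usable["patient_id"].isin(holdout_ids)].reset_index(drop=True)
    train = usable[~usable["patient_id"].isin(holdout_ids)].reset_index(drop=True)
    folds = pd.Series({pid: fold_of[pid] for pid in train["patient_id"]}, name="fold")
    folds.index.name = "patient_id"
    return CohortSplit(train=train, holdout=holdout, folds=folds, plan=plan)


def fold_partitions(folds: pd.Series, i: int, n_folds: int) -> dict[str, list[str]]:
    """Train/val/test patient ids for fold iteration ``i``."""
    test = folds.index[folds == i % n_folds]
    val = folds.index[folds == (i + 1) % n_folds]
    train = folds.index[~folds.isin([i % n_folds, (i + 1) % n_folds])]
    return {"train": list(train), "val": list(val), "test": list(test)}
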