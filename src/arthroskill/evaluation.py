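"""Leave-one-subject-out validation, performance measures and group statistics.

The expert is the positive class throughout: precision is the fraction
of expert calls that are true experts, recall the fraction of experts
identified.  Measures are percentages:

    accuracy  = 100 (TP + TN) / total
    precision = 100 TP / (TP + FP)          (0 when no expert calls)
    recall    = 100 TP / (TP + FN)          (0 when no experts)
    F1        = 2 * precision * recall / (precision + recall)   (0 when both 0)

Group comparisons route on normality: Shapiro-Wilk per group at
alpha = 0.05, then Welch's t test if both groups look normal, otherwise
the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .classifiers import (
    EXPERT_LABEL,
    NOVICE_LABEL,
    ClassifierSpec,
    FeatureVector,
    fit,
    predict,
)

__all__ = [
    "FeatureSet",
    "ClassificationReport",
    "GroupComparison",
    "StatTest",
    "measures",
    "confusion_from_measures",
    "loso",
    "compare_groups",
    "round_half_up",
]


class FeatureSet(str, enum.Enum):
    INSTRUMENT = "instrument"
    ARTHROSCOPE = "arthroscope"
    BOTH = "both"


class StatTest(str, enum.Enum):
    T_TEST = "t_test"
    MANN_WHITNEY_U = "mann_whitney_u"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding: half-up at ``ndigits`` decimals (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and derived measures for one evaluation cell."""

    task_id: int
    feature_set: FeatureSet
    classifier: str
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float

    @property
    def n_subjects(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float, float]:
        return tuple(
            round_half_up(v, ndigits)
            for v in (self.accuracy, self.precision, self.recall, self.f1)
        )


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    novice_mean: float
    novice_sd: float
    expert_mean: float
    expert_sd: float
    novice_normal: bool
    expert_normal: bool
    test: StatTest
    p_value: float
    significant: bool
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# measures and their inverse
# ---------------------------------------------------------------------------

def measures(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) as percentages from confusion counts."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (tp + tn) / total
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return accuracy, precision, recall, f1


def confusion_from_measures(
    precision: float,
    recall: float,
    n_expert: int,
    n_total: int,
    accuracy: Optional[float] = None,
    tol: float = 1e-6,
) -> tuple[int, int, int, int]:
    """Reconstruct (tp, fp, fn, tn) from percentage measures and cohort sizes.

    With ``precision = 0`` (so tp = 0) the false-positive count is not
    determined by precision/recall alone; pass ``accuracy`` to
    disambiguate, otherwise this raises.  Non-integral implied counts
    raise ``ValueError`` (measures inconsistent with the cohort size).
    """
    tp_f = recall * n_expert / 100.0
    tp = int(round(tp_f))
    if abs(tp_f - tp) > tol * max(1.0, abs(tp_f)) and abs(tp_f - tp) > tol:
        raise ValueError("measures inconsistent with cohort size: recall not integral")
    if precision > 0:
        fp_f = tp * (100.0 - precision) / precision
        fp = int(round(fp_f))
        if abs(fp_f - fp) > 1e-2:  # printed precisions are 2-dp rounded
            raise ValueError(
                "measures inconsistent with cohort size: predicted positives not integral"
            )
    elif tp == 0:
        if accuracy is None:
            raise ValueError(
                "precision 0 with no true positives leaves fp undetermined; "
                "supply accuracy"
            )
        tn_f = accuracy * n_total / 100.0
        tn = int(round(tn_f))
        if abs(tn_f - tn) > 1e-2:
            raise ValueError("measures inconsistent with cohort size: accuracy not integral")
        fp = n_total - n_expert - tn
    else:
        raise ValueError("precision 0 with tp > 0 is contradictory")
    fn = n_expert - tp
    tn = n_total - tp - fp - fn
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("measures imply negative confusion counts")
    return tp, fp, fn, tn


# ---------------------------------------------------------------------------
# leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------

def loso(
    dataset: Sequence[FeatureVector],
    spec: ClassifierSpec,
    task_id: int = 0,
    feature_set: FeatureSet = FeatureSet.BOTH,
    aggregate: str = "vote",
) -> ClassificationReport:
    """LOSO cross-validation over subjects.

    Every vector belonging to the held-out subject is predicted by a model
    trained on all remaining subjects' vectors (standardization statistics
    are refit inside each fold, so no information leaks from the test
    subject).  A subject with several vectors is assigned the majority
    vote (``aggregate='vote'``, ties resolving to expert, the positive
    class) or, with ``aggregate='mean'``, the prediction on their averaged
    feature vector.
    """
    if aggregate not in ("vote", "mean"):
        raise ValueError("aggregate must be 'vote' or 'mean'")
    subjects: dict[str, list[FeatureVector]] = {}
    for fv in dataset:
        subjects.setdefault(fv.subject_id, []).append(fv)
    labels = {sid: fvs[0].label for sid, fvs in subjects.items()}
    n_expert = sum(1 for v in labels.values() if v == EXPERT_LABEL)
    n_novice = len(labels) - n_expert
    if n_expert < 2 or n_novice < 2:
        raise ValueError("need at least 2 subjects per class for LOSO")

    tp = fp = fn = tn = 0
    for sid in subjects:
        train = [fv for other, fvs in subjects.items() if other != sid for fv in fvs]
        train_labels = {fv.label for fv in train}
        if len(train_labels) < 2:
            raise ValueError(f"training fold for subject {sid!r} lost a whole class")
        model = fit(spec, train)
        if aggregate == "mean":
            mean_features = np.mean([fv.features for fv in subjects[sid]], axis=0)
            predicted = predict(model, mean_features)[0]
        else:
            votes = [predict(model, fv)[0] for fv in subjects[sid]]
            n_exp_votes = sum(1 for v in votes if v == EXPERT_LABEL)
            predicted = EXPERT_LABEL if 2 * n_exp_votes >= len(votes) else NOVICE_LABEL
        actual = labels[sid]
        if actual == EXPERT_LABEL:
            if predicted == EXPERT_LABEL:
                tp += 1
            else:
                fn += 1
        else:
            if predicted == EXPERT_LABEL:
                fp += 1
            else:
                tn += 1
    accuracy, precision, recall, f1 = measures(tp, fp, fn, tn)
    return ClassificationReport(
        task_id=task_id,
        feature_set=feature_set,
        classifier=spec.kind.value,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def compare_groups(
    novice_values: Sequence[float],
    expert_values: Sequence[float],
    metric: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare a metric between groups with normality-routed testing.

    Shapiro-Wilk per group at ``alpha``; Welch's two-sided t test if both
    groups pass, otherwise the two-sided Mann-Whitney U test.  A
    constant-valued group has undefined normality and routes to
    Mann-Whitney with a warning.  Means +/- SD are reported regardless of
    the route.
    """
    nov = np.asarray(novice_values, dtype=float)
    exp = np.asarray(expert_values, dtype=float)
    if nov.size < 3 or exp.size < 3:
        raise ValueError("need at least 3 values per group")

    def normality(x: np.ndarray, name: str) -> Optional[bool]:
        if np.ptp(x) == 0:
            warnings.warn(
                f"{name} group is constant; normality undefined, "
                "routing to Mann-Whitney U",
                UserWarning,
                stacklevel=3,
            )
            return None
        return stats.shapiro(x).pvalue > alpha

    nov_normal = normality(nov, "novice")
    exp_normal = normality(exp, "expert")
    both_normal = bool(nov_normal) and bool(exp_normal)
    if both_normal:
        test = StatTest.T_TEST
        p = float(stats.ttest_ind(nov, exp, equal_var=False).pvalue)
    else:
        test = StatTest.MANN_WHITNEY_U
        p = float(stats.mannwhitneyu(nov, exp, alternative="two-sided").pvalue)
    return GroupComparison(
        metric=metric,
        novice_mean=float(nov.mean()),
        novice_sd=float(nov.std(ddof=1)),
        expert_mean=float(exp.mean()),
        expert_sd=float(exp.std(ddof=1)),
        novice_normal=bool(nov_normal),
        expert_normal=bool(exp_normal),
        test=test,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
    )
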