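"""Leave-one-trial-out SVM evaluation and the surrounding statistics.

Classification is subject-dependent: all 5-s segments of one trial are
held out per fold, an RBF-kernel support-vector machine is trained on the
remaining trials' segments, and the held-out segments are predicted.
Holding out whole trials — not random segments — is essential: segments
of one trial are strongly correlated, and mixing them across the split
would leak the test trial into training.

Features are z-scored with statistics fitted on the training fold only and
applied to the test fold, so the scaler cannot leak either.  The classifier
is pinned to the classical LIBSVM defaults (RBF kernel, C = 1, kernel
width gamma = 1/n_features) for reproducibility.

Accuracy per subject is the mean over folds; the F1 score is reported for
the "high" class.  Configurations are compared with a two-sided paired
t-test across subjects (the same subjects underlie both conditions), with
the null hypothesis that performance is similar.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import DegenerateSignalError, InvalidInputError

__all__ = [
    "ClassifierConfig",
    "FoldResult",
    "EvaluationReport",
    "f1_score",
    "leave_one_trial_out",
    "paired_ttest",
]

POSITIVE = "high"
NEGATIVE = "low"


@dataclass(frozen=True)
class ClassifierConfig:
    """RBF-SVM settings pinned to the classical LIBSVM defaults."""

    kernel: str = "rbf"
    cost: float = 1.0
    gamma: str | float = "auto"  # 1 / n_features
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise InvalidInputError("only the rbf kernel is supported")

    def make(self) -> SVC:
        return SVC(
            kernel=self.kernel, C=self.cost, gamma=self.gamma,
            random_state=self.seed,
        )


@dataclass(frozen=True)
class FoldResult:
    trial: int
    n_test: int
    n_correct: int
    model_hash: str


@dataclass
class EvaluationReport:
    """Per-fold bookkeeping plus aggregate accuracy, confusion and F1."""

    per_fold: list[FoldResult]
    confusion: dict[str, int]  # keys "tp", "fp", "fn", "tn"; positive = "high"
    config: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(f.n_test for f in self.per_fold)

    @property
    def accuracy(self) -> float:
        """Per-subject accuracy in percent (correct over all predictions)."""
        return 100.0 * sum(f.n_correct for f in self.per_fold) / self.n_total

    @property
    def f1(self) -> float:
        return f1_score(self.confusion)

    def confusion_matrix(self) -> np.ndarray:
        """2x2 counts, rows = predicted (high, low), columns = true (high, low)."""
        c = self.confusion
        return np.array([[c["tp"], c["fp"]], [c["fn"], c["tn"]]])


def f1_score(confusion: dict[str, int]) -> float:
    """F1 of the positive ("high") class from 2x2 counts.

    F1 = 2 TP / (2 TP + FP + FN); defined as 0 when the positive class is
    never predicted and never present.
    """
    tp = confusion.get("tp", 0)
    fp = confusion.get("fp", 0)
    fn = confusion.get("fn", 0)
    if min(tp, fp, fn) < 0:
        raise InvalidInputError("confusion counts must be nonnegative")
    if tp + fp + fn + confusion.get("tn", 0) == 0:
        raise InvalidInputError("empty confusion matrix")
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if "|imf" in c]


def _model_hash(scaler: StandardScaler, clf: SVC) -> str:
    h = hashlib.sha256()
    for arr in (scaler.mean_, scaler.scale_, clf.dual_coef_, clf.support_vectors_,
                clf.intercept_):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def leave_one_trial_out(
    table: pd.DataFrame,
    dimension: str = "valence",
    config: ClassifierConfig | None = None,
    feature_columns: list[str] | None = None,
) -> EvaluationReport:
    """Evaluate one subject's feature table with leave-one-trial-out folds.

    Parameters
    ----------
    table
        Feature table from :func:`emdeeg.features.feature_table` (feature
        columns plus ``trial`` and ``<dimension>_label``).
    dimension
        ``valence`` or ``arousal``.
    feature_columns
        Restrict training to these columns (e.g. one feature or one IMF
        level); default uses every feature column.

    Raises
    ------
    InvalidInputError
        Fewer than two trials, or the subject's labels contain only one
        class (chance evaluation would be meaningless).
    """
    if config is None:
        config = ClassifierConfig()
    label_col = f"{dimension}_label"
    if label_col not in table.columns or "trial" not in table.columns:
        raise InvalidInputError(f"table needs columns 'trial' and {label_col!r}")
    cols = feature_columns if feature_columns is not None else _feature_columns(table)
    if not cols:
        raise InvalidInputError("no feature columns found")
    trials = np.unique(table["trial"].to_numpy())
    if trials.size < 2:
        raise InvalidInputError("leave-one-trial-out needs >= 2 trials")
    y_all = (table[label_col] == POSITIVE).to_numpy()
    if y_all.all() or not y_all.any():
        raise InvalidInputError(
            f"subject has a single {dimension} class; evaluation skipped"
        )

    X_all = table[cols].to_numpy(dtype=float)
    trial_of = table["trial"].to_numpy()
    folds: list[FoldResult] = []
    conf = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for t in trials:
        test = trial_of == t
        train = ~test
        y_train = y_all[train]
        if y_train.all() or not y_train.any():
            # training fold degenerate: predict its only class
            pred = np.full(int(test.sum()), bool(y_train[0]))
            model_hash = "single-class-fold"
        else:
            scaler = StandardScaler().fit(X_all[train])
            clf = config.make().fit(scaler.transform(X_all[train]), y_train)
            pred = clf.predict(scaler.transform(X_all[test])).astype(bool)
            model_hash = _model_hash(scaler, clf)
        truth = y_all[test]
        conf["tp"] += int(np.sum(pred & truth))
        conf["fp"] += int(np.sum(pred & ~truth))
        conf["fn"] += int(np.sum(~pred & truth))
        conf["tn"] += int(np.sum(~pred & ~truth))
        folds.append(
            FoldResult(
                trial=int(t),
                n_test=int(test.sum()),
                n_correct=int(np.sum(pred == truth)),
                model_hash=model_hash,
            )
        )
    return EvaluationReport(
        per_fold=folds,
        confusion=conf,
        config={
            "dimension": dimension,
            "n_features": len(cols),
            "kernel": config.kernel,
            "cost": config.cost,
            "gamma": config.gamma,
        },
    )


def paired_ttest(accuracies_a, accuracies_b, alpha: float = 0.05):
    """Two-sided paired t-test on per-subject accuracies.

    Returns ``(t, p, verdict)`` where the verdict is ``"similar"`` when
    p > alpha (the null of similar performance is retained) and
    ``"different"`` otherwise.  Identical vectors give p = 1.
    """
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise InvalidInputError("need equal-length paired vectors of >= 3 subjects")
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0, "similar"
    if np.std(diff, ddof=1) == 0:
        raise DegenerateSignalError(
            "constant nonzero paired differences: t statistic undefined"
        )
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), "similar" if p > alpha else "different"
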