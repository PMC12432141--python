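"""Statistical evaluation of the screening method on a labeled dataset.

Three ingredients, mirroring how such screens are usually reported:

* a two-tailed t-test (Welch by default) on the IREs of artifact-free vs
  artifact-laden images — the basic premise that laden images score higher;
* a balanced-bootstrap ROC analysis: many subsets with equal numbers of
  images per class, a one-feature logistic regression of label on IRE per
  subset, and the mean AUC over subsets;
* confusion-matrix metrics (sensitivity / specificity / accuracy, in
  percent) of the thresholded classification, with artifact-laden as the
  positive class.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .errors import ValidationError
from .scoring import classify, dataset_threshold

#: Number of bootstrap subsets used by default for the mean AUC.
DEFAULT_N_SUBSETS = 10_000


def _check_group(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.size < 2:
        raise ValidationError(f"{name} group needs >= 2 values, got {arr.size}")
    if arr.std() == 0:
        raise ValidationError(f"{name} group has zero variance")
    return arr


def ttest_ire(clean_ires, artifact_ires, equal_var: bool = False) -> float:
    """Two-sided p-value comparing mean IRE of the two groups.

    Welch's unequal-variance variant by default, since group sizes and
    spreads differ strongly in practice; ``equal_var=True`` gives Student's.
    """
    clean = _check_group("clean", clean_ires)
    artifact = _check_group("artifact", artifact_ires)
    return float(stats.ttest_ind(clean, artifact, equal_var=equal_var).pvalue)


def bootstrap_auc(clean_ires, artifact_ires, n_subsets: int = DEFAULT_N_SUBSETS,
                  seed: int = 0, return_details: bool = False):
    """Mean ROC AUC over balanced bootstrap subsets.

    Each subset draws m = min(group sizes) images per class with
    replacement, fits an unregularized single-feature logistic regression of
    class on IRE, and computes the AUC of its scores on the subset. Because
    the logistic score is monotone in its one feature, each subset's AUC
    equals the Mann-Whitney rank AUC whenever the fitted slope is positive.

    With ``return_details`` also returns per-subset (auc, slope) pairs.
    """
    clean = np.asarray(clean_ires, dtype=np.float64)
    artifact = np.asarray(artifact_ires, dtype=np.float64)
    if clean.size == 0 or artifact.size == 0:
        raise ValidationError("both groups must be non-empty")
    if n_subsets < 1:
        raise ValidationError(f"n_subsets must be >= 1, got {n_subsets}")
    m = min(clean.size, artifact.size)
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.zeros(m), np.ones(m)])  # artifact = positive class
    aucs = np.empty(n_subsets)
    slopes = np.empty(n_subsets)
    # unregularized fit (a penalty would bias the single-feature scores)
    lr = LogisticRegression(C=np.inf, solver="lbfgs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in range(n_subsets):
            xs = np.concatenate([rng.choice(clean, m, replace=True),
                                 rng.choice(artifact, m, replace=True)])
            X = xs[:, None]
            if xs.min() == xs.max():
                # Degenerate subset: constant feature, uninformative scores.
                aucs[i], slopes[i] = 0.5, 0.0
                continue
            lr.fit(X, y)
            scores = lr.decision_function(X)
            aucs[i] = roc_auc_score(y, scores)
            slopes[i] = lr.coef_[0, 0]
    mean_auc = float(aucs.mean())
    if return_details:
        return mean_auc, aucs, slopes
    return mean_auc


def confusion_metrics(predicted, truth) -> tuple[float, float, float]:
    """Sensitivity, specificity, accuracy in percent (artifact = positive).

    When the truth contains no positives (or no negatives) the corresponding
    rate is undefined and reported as NaN, never as 0.
    """
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValidationError("predicted and truth label sequences differ in length")
    for name, labels in (("predicted", pred), ("truth", true)):
        bad = set(np.unique(labels)) - {"clean", "artifact"}
        if bad:
            raise ValidationError(f"unknown {name} labels: {sorted(bad)}")
    pos = true == "artifact"
    neg = ~pos
    tp = int(np.sum(pos & (pred == "artifact")))
    tn = int(np.sum(neg & (pred == "clean")))
    sensitivity = 100.0 * tp / pos.sum() if pos.any() else math.nan
    specificity = 100.0 * tn / neg.sum() if neg.any() else math.nan
    accuracy = 100.0 * (tp + tn) / true.size
    return sensitivity, specificity, accuracy


@dataclass
class EvalReport:
    p_value: float
    mean_auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_clean: int
    n_artifact: int
    threshold_used: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_dataset(truth_labels, ires, threshold: float | None = None,
                     n_subsets: int = DEFAULT_N_SUBSETS, seed: int = 0,
                     equal_var: bool = False) -> EvalReport:
    """Full evaluation of a scored, ground-truth-labeled dataset.

    Classifies every image against the (given or dataset-adaptive)
    threshold, then computes confusion metrics, the two-tailed t-test on
    group IREs, and the balanced-bootstrap mean AUC.
    """
    truth = np.asarray(truth_labels)
    arr = np.asarray(ires, dtype=np.float64)
    if truth.shape != arr.shape:
        raise ValidationError("labels and IREs differ in length")
    bad = [i for i, lab in enumerate(truth) if lab not in ("clean", "artifact")]
    if bad:
        raise ValidationError(f"images without a usable truth label at indices {bad}")
    if threshold is None:
        threshold = dataset_threshold(arr).threshold
    pred = classify(arr, threshold)
    sens, spec, acc = confusion_metrics(pred, truth)
    clean = arr[truth == "clean"]
    artifact = arr[truth == "artifact"]
    p = ttest_ire(clean, artifact, equal_var=equal_var)
    auc = bootstrap_auc(clean, artifact, n_subsets=n_subsets, seed=seed)
    return EvalReport(p_value=p, mean_auc=auc, sensitivity=sens, specificity=spec,
                      accuracy=acc, n_clean=int(clean.size), n_artifact=int(artifact.size),
                      threshold_used=float(threshold))
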