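"""Leave-one-out classification of subjects from regional delta-SUV features.

Each subject is represented by its 8-region delta-SUV mean vector and
labelled CON (negative class) or LS (positive class).  Because cohorts are
small, evaluation is leave-one-out: for every subject, a classifier is
trained on all other subjects — with hyperparameters tuned by an inner
stratified cross-validation on those subjects only — and the held-out
subject's hard prediction and continuous decision score are recorded.
Confusion rates come from the hard predictions; the ROC curve and AUC are
computed on the pooled held-out scores, the only n scores that exist.

Model kinds: ridge-penalized logistic regression, linear-kernel SVM, and
Gentle AdaBoost over regression stumps (implemented here).  Features are
standardized inside each training fold to avoid leakage.  A decision score
of exactly zero predicts the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

NEGATIVE_CLASS = "CON"
POSITIVE_CLASS = "LS"
MODEL_KINDS = ("logistic", "svm", "gentleboost")


@dataclass
class FeatureMatrix:
    """Subjects x regions feature table with group labels."""

    X: pd.DataFrame            # index = subject, columns = region codes
    y: pd.Series               # subject -> group label

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature rows and labels are misaligned")

    @classmethod
    def from_subject_means(cls, means: pd.DataFrame, labels: dict[str, str]) -> "FeatureMatrix":
        """Pivot a (subject, region, delta_suv) table into a feature matrix."""
        X = means.pivot(index="subject", columns="region", values="delta_suv")
        X = X.reindex(sorted(X.columns), axis=1)
        y = pd.Series({s: labels[s] for s in X.index}, name="group").loc[X.index]
        return cls(X=X, y=y)


@dataclass
class LoocvResult:
    per_subject: pd.DataFrame  # subject, true, predicted, score
    confusion: dict[str, float]  # TN/FP/FN/TP rates in percent
    roc: dict                   # fpr, tpr, auc
    model_kind: str
    seed: int
    fold_models: list | None = None


class GentleBoostClassifier(BaseEstimator, ClassifierMixin):
    """Gentle AdaBoost over weighted-least-squares regression stumps.

    Each round fits the stump (feature, threshold, left value, right value)
    minimizing the weighted squared error to the +/-1 labels — the stump
    outputs are the weighted class means on each side — adds it to the
    additive score F, and reweights ``w_i <- w_i * exp(-y_i f_t(x_i))``.
    The training exponential loss ``mean(exp(-y F))`` is nonincreasing in
    rounds because the fitted stump output is a shrunken version of the
    loss-minimizing step on every leaf.
    """

    def __init__(self, n_rounds: int = 100):
        self.n_rounds = n_rounds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size > 2:
            raise ValueError("binary classification only")
        # map first class -> -1, last -> +1 (classes_ sorted); a lone class
        # maps to +1, giving the degenerate all-positive constant model
        ysgn = np.where(y == self.classes_[-1], 1.0, -1.0)
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        F = np.zeros(n)
        self.rounds_ = []
        self.loss_path_ = []
        for _ in range(self.n_rounds):
            feat, thr, left, right = self._best_stump(X, ysgn, w)
            f = np.where(X[:, feat] < thr, left, right)
            F += f
            self.rounds_.append((int(feat), float(thr), float(left), float(right)))
            w = w * np.exp(-ysgn * f)
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                break
            w = w / total
            self.loss_path_.append(float(np.mean(np.exp(-ysgn * F))))
        return self

    @staticmethod
    def _best_stump(X, y, w):
        best = (0, -np.inf, float(np.average(y, weights=w)), float(np.average(y, weights=w)))
        # baseline: constant stump (all samples on the right side)
        best_err = float(np.sum(w * (y - best[2]) ** 2))
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            xs, ys, ws = X[order, j], y[order], w[order]
            cw = np.cumsum(ws)
            cwy = np.cumsum(ws * ys)
            tw, twy = cw[-1], cwy[-1]
            sw2 = np.sum(ws * ys * ys)
            # candidate splits between distinct consecutive values
            distinct = np.nonzero(np.diff(xs) > 0)[0]
            for i in distinct:
                wl, wyl = cw[i], cwy[i]
                wr, wyr = tw - wl, twy - wyl
                if wl <= 0 or wr <= 0:  # weight underflow on one side
                    continue
                left = wyl / wl
                right = wyr / wr
                # weighted SSE = sum(w y^2) - wl*left^2 - wr*right^2
                err = sw2 - wl * left * left - wr * right * right
                if err < best_err - 1e-15:
                    best_err = err
                    thr = 0.5 * (xs[i] + xs[i + 1])
                    best = (j, float(thr), float(left), float(right))
        return best

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        F = np.zeros(X.shape[0])
        for feat, thr, left, right in self.rounds_:
            F += np.where(X[:, feat] < thr, left, right)
        return F

    def predict(self, X):
        score = self.decision_function(X)
        pos = self.classes_[-1] if self.classes_.size > 1 else self.classes_[0]
        neg = self.classes_[0]
        return np.where(score >= 0, pos, neg)


def _candidates(model_kind: str) -> list:
    if model_kind == "logistic":
        return [LogisticRegression(solver="lbfgs", max_iter=5000, C=c)
                for c in (0.01, 0.1, 1.0, 10.0)]
    if model_kind == "svm":
        return [SVC(kernel="linear", C=c) for c in (0.01, 0.1, 1.0, 10.0)]
    if model_kind == "gentleboost":
        return [GentleBoostClassifier(n_rounds=r) for r in (25, 50, 100)]
    raise ValueError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")


def _fit_tuned(X_train: np.ndarray, y_train: np.ndarray, model_kind: str, seed: int):
    """Fit with hyperparameters tuned by inner stratified CV on the
    training rows only; features standardized on the training fold.

    Returns (scaler, fitted model).  The candidate with the best inner-CV
    accuracy wins; ties favor the first (most regularized) candidate.
    """
    scaler = StandardScaler().fit(X_train)
    Xs = scaler.transform(X_train)
    candidates = _candidates(model_kind)
    min_class = int(min(np.sum(y_train == c) for c in np.unique(y_train)))
    if min_class < 2:
        # inner CV infeasible: fall back to the default hyperparameter
        default = {"logistic": 2, "svm": 2, "gentleboost": 2}[model_kind]
        return scaler, clone(candidates[default]).fit(Xs, y_train)
    n_splits = max(2, min(3, min_class))
    inner = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(inner.split(Xs, y_train))
    scores = np.zeros(len(candidates))
    for ci, cand in enumerate(candidates):
        correct = 0
        for tr, va in folds:
            m = clone(cand).fit(Xs[tr], y_train[tr])
            correct += int(np.sum(m.predict(Xs[va]) == y_train[va]))
        scores[ci] = correct
    best = clone(candidates[int(np.argmax(scores))]).fit(Xs, y_train)
    return scaler, best


def loocv(
    features: FeatureMatrix,
    model_kind: str = "logistic",
    seed: int = 0,
    keep_models: bool = False,
    train_labels: pd.Series | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validated classification.

    For each subject i the model is trained (and tuned by inner stratified
    CV) on all other subjects only, then scores subject i.  Returns one
    prediction and decision score per subject plus confusion rates and the
    pooled-score ROC.  ``train_labels`` substitutes the labels seen during
    training (used by the scrambled-label control); evaluation is always
    against the true labels in ``features.y``.
    """
    X = features.X.to_numpy(dtype=float)
    y = features.y.to_numpy()
    y_train_all = y if train_labels is None else train_labels.loc[features.X.index].to_numpy()
    subjects = list(features.X.index)
    classes, counts = np.unique(y_train_all, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 subjects each")
    rows = []
    models = [] if keep_models else None
    for i in range(len(subjects)):
        train = np.ones(len(subjects), dtype=bool)
        train[i] = False
        scaler, model = _fit_tuned(X[train], y_train_all[train], model_kind, seed)
        score = float(model.decision_function(scaler.transform(X[i: i + 1]))[0])
        pred = POSITIVE_CLASS if score >= 0 else NEGATIVE_CLASS
        rows.append((subjects[i], y[i], pred, score))
        if keep_models:
            models.append((scaler, model))
    per_subject = pd.DataFrame(rows, columns=["subject", "true", "predicted", "score"])
    confusion, roc = confusion_and_roc(
        per_subject["score"].to_numpy(),
        per_subject["true"].to_numpy(),
        per_subject["predicted"].to_numpy(),
    )
    return LoocvResult(per_subject, confusion, roc, model_kind, seed, models)


def confusion_and_roc(scores, y_true, y_pred) -> tuple[dict[str, float], dict]:
    """Confusion rates (percent) from hard predictions and ROC/AUC from the
    continuous scores, treating CON as negative and LS as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    n_neg = int(np.sum(y_true == NEGATIVE_CLASS))
    n_pos = int(np.sum(y_true == POSITIVE_CLASS))
    if n_neg == 0 or n_pos == 0:
        raise ValueError("both classes must be present")
    tn = int(np.sum((y_true == NEGATIVE_CLASS) & (y_pred == NEGATIVE_CLASS)))
    fp = n_neg - tn
    tp = int(np.sum((y_true == POSITIVE_CLASS) & (y_pred == POSITIVE_CLASS)))
    fn = n_pos - tp
    confusion = {
        "TNR": 100.0 * tn / n_neg,
        "FPR": 100.0 * fp / n_neg,
        "TPR": 100.0 * tp / n_pos,
        "FNR": 100.0 * fn / n_pos,
    }
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=POSITIVE_CLASS)
    auc = float(np.trapezoid(tpr, fpr))
    roc = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": auc}
    return confusion, roc


def scrambled_control(
    features: FeatureMatrix, model_kind: str = "logistic", seed: int = 0
) -> LoocvResult:
    """LOOCV with training labels permuted uniformly at random (seeded).

    The permutation preserves class counts.  Models are trained on the
    scrambled labels but evaluated against the true ones, so the control
    behaves like a random classifier (AUC near 0.5) when the models work
    and the labels carry no information about the features.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(features.y))
    y_scrambled = pd.Series(
        features.y.to_numpy()[perm], index=features.y.index, name="group"
    )
    return loocv(features, model_kind=model_kind, seed=seed, train_labels=y_scrambled)
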