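"""One-vs-all classification and Monte Carlo evaluation.

Four classifier families are compared for the four-way lesion diagnosis
(blue nevus, Clark nevus, malignant melanoma, Spitz nevus): k-nearest
neighbors (k in {3, 5, 10, 15}), multinomial-free logistic regression,
a Gini decision tree, and an RBF-kernel support vector machine whose
(C, gamma) pair is chosen by exponential grid search. The multiclass
problem is decomposed one-vs-all with winner-takes-all combination: one
binary scorer per class, predicted class = argmax of the per-class scores
(posterior probabilities), ties broken by the fixed class order.

Misclassifying melanoma is four times as costly as any other error; the
cost enters as the positive-class weight of the melanoma-vs-rest binary
problem (and symmetrically down-weights nothing else).

Validation is stratified Monte Carlo cross-validation: repeated random
splits with 10% of samples (per-class proportions preserved) held out,
with scaling, SMOTE and feature selection refit inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .prep import LABEL_COLUMN, FeatureScaler, cfs_select, smote

CLASS_ORDER = ("BN", "CN", "MM", "SN")
MELANOMA_CLASS = "MM"
MELANOMA_COST = 4.0

SVM_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))  # 2^-5 .. 2^15
SVM_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))  # 2^-15 .. 2^3


@dataclass
class ClassifierSpec:
    """Family + hyperparameters of one classifier."""

    family: str  # knn | logit | tree | svm
    knn_k: int = 5
    svm_C: float = 1.0
    svm_gamma: float | str = "scale"
    melanoma_cost: float = MELANOMA_COST

    def make_binary(self, positive_class: str, seed: int, probability: bool = True):
        pos_weight = self.melanoma_cost if positive_class == MELANOMA_CLASS else 1.0
        weight = {1: pos_weight, 0: 1.0}
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k)
        if self.family == "logit":
            return LogisticRegression(C=1.0, max_iter=2000, class_weight=weight)
        if self.family == "tree":
            return DecisionTreeClassifier(
                criterion="gini", min_samples_leaf=2, class_weight=weight, random_state=seed
            )
        if self.family == "svm":
            svc = SVC(
                kernel="rbf",
                C=self.svm_C,
                gamma=self.svm_gamma,
                class_weight=weight,
                random_state=seed,
            )
            if not probability:
                return svc
            # Platt-style sigmoid mapping of the SVM margin to a posterior,
            # fitted by internal cross-validation on the training fold
            return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
        raise ValueError(f"unknown classifier family {self.family!r}")


@dataclass
class OneVsAllModel:
    """Per-class binary models combined winner-takes-all."""

    spec: ClassifierSpec
    classes: tuple[str, ...]
    models: dict
    feature_columns: list[str]
    uses_probability: bool = True

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for cls in self.classes:
            model = self.models[cls]
            if self.uses_probability:
                proba = model.predict_proba(X)
                pos = list(model.classes_).index(1)
                cols.append(proba[:, pos])
            else:
                cols.append(model.decision_function(X))
        return np.stack(cols, axis=1)

    def predict(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Predicted class labels and the per-class score matrix.

        Argmax over scores; exact ties go to the earliest class in the
        fixed order, which ``argmax`` yields by construction.
        """
        X = table[self.feature_columns].to_numpy(dtype=float)
        scores = self.score_matrix(X)
        idx = scores.argmax(axis=1)
        return np.asarray(self.classes)[idx], scores


def train(spec: ClassifierSpec, table: pd.DataFrame, seed: int = 0,
          probability: bool = True) -> OneVsAllModel:
    """Fit one binary model per class on a prepared feature table."""
    y = table[LABEL_COLUMN].to_numpy()
    present = [c for c in CLASS_ORDER if c in set(y)] or sorted(set(y))
    if len(present) < 2:
        raise ValueError("training data holds a single class")
    feat_cols = [c for c in table.columns if c != LABEL_COLUMN]
    X = table[feat_cols].to_numpy(dtype=float)
    models = {}
    uses_prob = probability or spec.family != "svm"
    for cls in present:
        binary = spec.make_binary(cls, seed, probability=probability)
        models[cls] = binary.fit(X, (y == cls).astype(int))
    return OneVsAllModel(spec, tuple(present), models, feat_cols, uses_probability=uses_prob)


def ova_predict(model: OneVsAllModel, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Winner-takes-all prediction; returns (labels, score matrix)."""
    return model.predict(table)


# ---------------------------------------------------------------- metrics

def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     classes: tuple[str, ...] = CLASS_ORDER) -> np.ndarray:
    """Rows = actual class, columns = predicted class."""
    index = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        out[index[t], index[p]] += 1
    return out


def metrics(confusion: np.ndarray) -> dict:
    """Overall accuracy plus one-vs-all TPR/TNR per class.

    ``TPR_c = TP / (TP + FN)`` and ``TNR_c = TN / (TN + FP)`` with class c
    as positive; classes absent from the test set get NaN.
    """
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(confusion) / total)
    tpr, tnr = [], []
    for c in range(confusion.shape[0]):
        tp = confusion[c, c]
        fn = confusion[c, :].sum() - tp
        fp = confusion[:, c].sum() - tp
        tn = total - tp - fn - fp
        tpr.append(tp / (tp + fn) if tp + fn > 0 else float("nan"))
        tnr.append(tn / (tn + fp) if tn + fp > 0 else float("nan"))
    return {"accuracy": acc, "tpr": tpr, "tnr": tnr}


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC curve (FPR, TPR points) and trapezoidal AUC for binary labels.

    Thresholds sweep the distinct score values (tied scores grouped), so
    the curve rises from (0, 0) to (1, 1).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group ties: cumulative counts at the end of each distinct-score block
    distinct = np.nonzero(np.diff(s))[0]
    block_ends = np.concatenate([distinct, [len(s) - 1]])
    tp = np.concatenate([[0], np.cumsum(y)[block_ends]])
    fp = np.concatenate([[0], (block_ends + 1) - np.cumsum(y)[block_ends]])
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return np.stack([fpr, tpr], axis=1), auc


# ---------------------------------------------------------------- validation

@dataclass
class CVPlan:
    """Stratified Monte Carlo cross-validation plan."""

    n_iterations: int = 100
    test_fraction: float = 0.10
    seed: int = 0


@dataclass
class PrepConfig:
    """Which preparation stages run inside each training fold."""

    scale: bool = True
    rebalance: bool = True
    select: bool = False
    k_max: int = 20
    smote_k: int = 5


@dataclass
class EvaluationReport:
    classes: tuple[str, ...]
    confusion: np.ndarray
    accuracy: float
    tpr: list[float]
    tnr: list[float]
    auc: list[float]
    roc_curves: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "auc": self.auc,
        }


def stratified_split(y: np.ndarray, test_fraction: float, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified train/test index split (>= 1 test sample per class)."""
    test_idx = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        n_test = max(1, round(test_fraction * len(idx)))
        if n_test >= len(idx):
            raise ValueError(f"class {cls!r} too small for a {test_fraction:.0%} test split")
        test_idx.append(rng.choice(idx, n_test, replace=False))
    test = np.concatenate(test_idx)
    mask = np.ones(len(y), dtype=bool)
    mask[test] = False
    return np.nonzero(mask)[0], np.sort(test)


def _prepare_fold(train_tbl: pd.DataFrame, test_tbl: pd.DataFrame, prep: PrepConfig,
                  seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    if prep.scale:
        scaler = FeatureScaler().fit(train_tbl)
        train_tbl = scaler.transform(train_tbl)
        test_tbl = scaler.transform(test_tbl)
    if prep.select:
        subset = cfs_select(train_tbl, prep.k_max)
        if subset.features:
            keep = subset.features + [LABEL_COLUMN]
            train_tbl = train_tbl[keep]
            test_tbl = test_tbl[keep]
    if prep.rebalance:
        train_tbl = smote(train_tbl, k_neighbors=prep.smote_k, seed=seed)
    return train_tbl, test_tbl


def validate(spec: ClassifierSpec, table: pd.DataFrame, plan: CVPlan,
             prep: PrepConfig | None = None, probability: bool = True) -> EvaluationReport:
    """Stratified Monte Carlo cross-validation of one classifier spec.

    Every iteration refits the whole preparation chain on its training
    fold, so no statistic of a test sample influences the model that
    scores it. Confusion counts and per-class scores accumulate across
    iterations; AUC is computed from the pooled scores.
    """
    if prep is None:
        prep = PrepConfig()
    rng = np.random.default_rng(plan.seed)
    y_all = table[LABEL_COLUMN].to_numpy()
    classes = tuple(c for c in CLASS_ORDER if c in set(y_all)) or tuple(sorted(set(y_all)))
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    for _ in range(plan.n_iterations):
        it_seed = int(rng.integers(2**31))
        train_idx, test_idx = stratified_split(y_all, plan.test_fraction, rng)
        train_tbl = table.iloc[train_idx].reset_index(drop=True)
        test_tbl = table.iloc[test_idx].reset_index(drop=True)
        train_tbl, test_tbl = _prepare_fold(train_tbl, test_tbl, prep, it_seed)
        model = train(spec, train_tbl, seed=it_seed, probability=probability)
        pred, scores = model.predict(test_tbl)
        truth = test_tbl[LABEL_COLUMN].to_numpy()
        confusion += confusion_matrix(truth, pred, classes)
        pooled_scores.append(scores)
        pooled_truth.append(truth)

    scores = np.concatenate(pooled_scores)
    truth = np.concatenate(pooled_truth)
    m = metrics(confusion)
    aucs, curves = [], {}
    for i, cls in enumerate(classes):
        binary = (truth == cls).astype(int)
        if 0 < binary.sum() < len(binary):
            curve, auc = roc_auc(binary, scores[:, i])
            aucs.append(auc)
            curves[cls] = curve
        else:
            aucs.append(float("nan"))
    return EvaluationReport(classes, confusion, m["accuracy"], m["tpr"], m["tnr"], aucs, curves)


@dataclass
class GridSearchResult:
    best_C: float
    best_gamma: float
    best_accuracy: float
    surface: pd.DataFrame
    model: OneVsAllModel


def grid_search_svm(
    table: pd.DataFrame,
    plan: CVPlan | None = None,
    C_grid=SVM_C_GRID,
    gamma_grid=SVM_GAMMA_GRID,
    prep: PrepConfig | None = None,
) -> GridSearchResult:
    """Exponential grid search over (C, gamma) for the RBF SVM.

    Each pair is scored by the Monte Carlo validation accuracy (the grid
    phase uses decision-function scores, so no per-pair Platt fit is
    needed); ties prefer smaller C, then smaller gamma. The returned model
    is retrained on the full table at the optimum, with probability
    calibration enabled.
    """
    if plan is None:
        plan = CVPlan(n_iterations=10)
    if prep is None:
        prep = PrepConfig()
    rows = []
    best = None
    for C in C_grid:
        for gamma in gamma_grid:
            spec = ClassifierSpec("svm", svm_C=C, svm_gamma=gamma)
            report = validate(spec, table, plan, prep, probability=False)
            rows.append({"C": C, "gamma": gamma, "accuracy": report.accuracy})
            key = (report.accuracy, -C, -gamma)
            if best is None or key > best[0]:
                best = (key, C, gamma, report.accuracy)
    _, C_star, gamma_star, acc = best
    final_spec = ClassifierSpec("svm", svm_C=C_star, svm_gamma=gamma_star)
    final_train = table
    if prep.scale:
        final_train = FeatureScaler().fit_transform(final_train)
    if prep.rebalance:
        final_train = smote(final_train, k_neighbors=prep.smote_k, seed=plan.seed)
    model = train(final_spec, final_train, seed=plan.seed, probability=True)
    return GridSearchResult(C_star, gamma_star, acc, pd.DataFrame(rows), model)
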