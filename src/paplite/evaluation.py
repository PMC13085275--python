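"""Seven-classifier evaluation harness with formula-defined metrics.

The classical classifier battery: linear / quadratic / cubic / Gaussian
SVMs (one-vs-one voting, kernel scale sqrt(p) i.e. gamma = 1/p — an
approximation to a toolbox's automated kernel scaling), Euclidean and
cosine 10-NN, and LDA.  Evaluation is repeated stratified 5-fold
cross-validation; standardisation statistics are always fit on the
training folds only.

Metrics are computed from one-vs-rest binarised confusion matrices:

    Sens = TP/(TP+FN)            Spec = TN/(TN+FP)
    Prec = TP/(TP+FP)            F1   = 2TP/(2TP+FP+FN)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    Acc  = trace(CM)/n

"Macro" values are unweighted means over classes; the multiclass MCC is
the mean of the per-class binary MCCs.  Zero denominators define the
metric as 0 and are flagged.

The across-classifier significance test is a one-way ANOVA on per-fold
accuracies (7 classifiers x 5 folds gives the df structure 6 / 28 / 34).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

CLASSIFIER_NAMES = ("LSVM", "QSVM", "CSVM", "GSVM", "MKNN", "CKNN", "LDA")


@dataclass
class ClassifierSpec:
    """One of the seven fixed classifier configurations."""

    name: str
    k_neighbors: int = 10
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")
        if self.name in ("MKNN", "CKNN") and self.k_neighbors != 10:
            raise ValueError("KNN classifiers use the fixed k = 10")


def default_classifiers() -> list[ClassifierSpec]:
    """The full battery; cosine KNN skips standardisation (scale-free)."""
    return [ClassifierSpec(name=n, standardize=(n != "CKNN"))
            for n in CLASSIFIER_NAMES]


def make_estimator(spec: ClassifierSpec, n_features: int):
    """Scikit-learn estimator for a spec; SVM gamma = 1/p (scale sqrt(p))."""
    gamma = 1.0 / n_features
    if spec.name == "LSVM":
        est = SVC(kernel="linear", C=1.0, decision_function_shape="ovr")
    elif spec.name == "QSVM":
        est = SVC(kernel="poly", degree=2, gamma=gamma, coef0=1.0, C=1.0,
                  decision_function_shape="ovr")
    elif spec.name == "CSVM":
        est = SVC(kernel="poly", degree=3, gamma=gamma, coef0=1.0, C=1.0,
                  decision_function_shape="ovr")
    elif spec.name == "GSVM":
        est = SVC(kernel="rbf", gamma=gamma, C=1.0,
                  decision_function_shape="ovr")
    elif spec.name == "MKNN":
        est = KNeighborsClassifier(n_neighbors=spec.k_neighbors,
                                   metric="euclidean")
    elif spec.name == "CKNN":
        est = KNeighborsClassifier(n_neighbors=spec.k_neighbors,
                                   metric="cosine")
    else:  # LDA; the svd solver tolerates singular within-class covariance
        est = LinearDiscriminantAnalysis(solver="svd")
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def stratified_folds(labels: np.ndarray, n_folds: int = 5,
                     n_repeats: int = 1, seed: int = 0
                     ) -> list[list[np.ndarray]]:
    """Test-fold index sets per repeat; folds preserve class proportions.

    Within a repeat the folds partition ``range(n)``; every class must
    have at least ``n_folds`` members (errors with the offending class).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        bad = classes[counts.argmin()]
        raise ValueError(
            f"class {bad} has only {counts.min()} samples; "
            f"needs at least n_folds={n_folds}"
        )
    repeats = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed + rep)
        repeats.append([test for _, test in
                        skf.split(np.zeros(len(labels)), labels)])
    return repeats


def fit_predict(spec: ClassifierSpec, train: FeatureMatrix,
                test: FeatureMatrix):
    """Fit on train, predict on test; returns (labels, per-class scores).

    Scores are decision values (SVM/LDA) or posterior estimates (KNN),
    usable for one-vs-rest ROC analysis.  Standardisation parameters are
    fit on the training matrix only.
    """
    if train.n_features != test.n_features:
        raise ValueError("train/test column mismatch")
    est = make_estimator(spec, train.n_features)
    est.fit(train.values, train.labels)
    pred = est.predict(test.values)
    # posterior estimates (KNN, LDA) rank better one-vs-rest than raw
    # discriminant values; SVMs expose only vote-margin decision values
    if hasattr(est, "predict_proba"):
        scores = est.predict_proba(test.values)
    elif hasattr(est, "decision_function"):
        scores = est.decision_function(test.values)
    else:  # pragma: no cover
        raise TypeError("estimator yields no usable scores")
    if scores.ndim == 1:  # binary decision_function -> two-column scores
        scores = np.column_stack([-scores, scores])
    return pred, scores


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
              ) -> np.ndarray:
    """K x K count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    for arr, which in ((y_true, "true"), (y_pred, "predicted")):
        if arr.min(initial=0) < 0 or arr.max(initial=0) >= n_classes:
            raise ValueError(f"{which} labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _binary_counts(cm: np.ndarray, c: int):
    tp = cm[c, c]
    fn = cm[c].sum() - tp
    fp = cm[:, c].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return float(tp), float(tn), float(fp), float(fn)


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(what)
        return 0.0
    return num / den


def metrics_from_confusion(cm: np.ndarray) -> dict:
    """Per-class one-vs-rest and macro metrics from a confusion matrix.

    Returns a dict with per-class arrays (``sensitivity``, ``specificity``,
    ``precision``, ``f1``, ``mcc``), their unweighted ``macro`` means,
    overall ``accuracy`` (trace/total) and a list of zero-denominator
    ``flags``.
    """
    cm = np.asarray(cm)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    flags: list[str] = []
    per = {m: np.zeros(k) for m in
           ("sensitivity", "specificity", "precision", "f1", "mcc")}
    for c in range(k):
        tp, tn, fp, fn = _binary_counts(cm, c)
        per["sensitivity"][c] = _safe_div(tp, tp + fn, flags, f"sens[{c}]")
        per["specificity"][c] = _safe_div(tn, tn + fp, flags, f"spec[{c}]")
        per["precision"][c] = _safe_div(tp, tp + fp, flags, f"prec[{c}]")
        per["f1"][c] = _safe_div(2 * tp, 2 * tp + fp + fn, flags, f"f1[{c}]")
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        per["mcc"][c] = _safe_div(tp * tn - fp * fn, denom, flags,
                                  f"mcc[{c}]")
    out = dict(per)
    out["macro"] = {m: float(v.mean()) for m, v in per.items()}
    out["accuracy"] = float(np.trace(cm) / cm.sum())
    out["flags"] = flags
    return out


def roc_ovr(scores: np.ndarray, y_true: np.ndarray) -> dict:
    """One-vs-rest ROC points and trapezoidal AUC per class.

    A class absent from ``y_true`` gets ``auc = nan`` and is flagged.
    """
    y_true = np.asarray(y_true)
    k = scores.shape[1]
    out = {"classes": {}, "flags": []}
    for c in range(k):
        pos = (y_true == c).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            out["classes"][c] = {"fpr": None, "tpr": None, "auc": np.nan}
            out["flags"].append(f"class {c}: single-class fold")
            continue
        fpr, tpr, _ = roc_curve(pos, scores[:, c])
        out["classes"][c] = {"fpr": fpr, "tpr": tpr,
                             "auc": float(auc(fpr, tpr))}
    return out


@dataclass
class AnovaTable:
    """One-way ANOVA decomposition: Columns (between groups), Error, Total."""

    ss_columns: float
    ss_error: float
    df_columns: int
    df_error: int
    f: float
    p: float

    @property
    def ss_total(self) -> float:
        return self.ss_columns + self.ss_error

    @property
    def df_total(self) -> int:
        return self.df_columns + self.df_error

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Source": ["Columns", "Error", "Total"],
            "SS": [self.ss_columns, self.ss_error, self.ss_total],
            "df": [self.df_columns, self.df_error, self.df_total],
            "MS": [self.ss_columns / self.df_columns,
                   self.ss_error / self.df_error if self.df_error else np.nan,
                   np.nan],
            "F": [self.f, np.nan, np.nan],
            "p": [self.p, np.nan, np.nan],
        })


def anova_across_classifiers(accuracies: dict[str, np.ndarray]) -> AnovaTable:
    """One-way ANOVA on per-fold accuracies grouped by classifier.

    Handles unequal group sizes (unbalanced one-way layout).  With 7
    classifiers and 5 observations each: df = (6, 28), total 34.
    """
    groups = [np.asarray(v, dtype=np.float64) for v in accuracies.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 classifiers")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 observations per classifier")
    all_obs = np.concatenate(groups)
    grand = all_obs.mean()
    ss_col = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_err = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_col = len(groups) - 1
    df_err = len(all_obs) - len(groups)
    if ss_err == 0:
        f = 0.0 if ss_col == 0 else np.inf
        p = 1.0 if ss_col == 0 else 0.0
    else:
        f = (ss_col / df_col) / (ss_err / df_err)
        p = float(stats.f.sf(f, df_col, df_err))
    return AnovaTable(ss_columns=float(ss_col), ss_error=float(ss_err),
                      df_columns=df_col, df_error=df_err, f=float(f), p=p)


def cross_val_accuracy(x: FeatureMatrix, spec: ClassifierSpec,
                       n_folds: int = 5, seed: int = 0) -> float:
    """Mean stratified k-fold accuracy for one classifier."""
    folds = stratified_folds(x.labels, n_folds=n_folds, seed=seed)[0]
    accs = []
    all_idx = np.arange(x.n_samples)
    for test in folds:
        train = np.setdiff1d(all_idx, test)
        pred, _ = fit_predict(spec, _subset(x, train), _subset(x, test))
        accs.append(float(np.mean(pred == x.labels[test])))
    return float(np.mean(accs))


def _subset(x: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(values=x.values[idx], labels=x.labels[idx],
                         source=x.source, network=x.network,
                         feature_names=list(x.feature_names))


@dataclass
class EvaluationReport:
    """Cross-validated results for a classifier battery on one feature set."""

    metric_means: pd.DataFrame  # classifiers x metrics
    metric_variances: pd.DataFrame
    confusions: dict[str, np.ndarray]  # summed over test folds (1st repeat)
    rocs: dict[str, dict]
    fold_accuracies: dict[str, np.ndarray]  # first repeat, one per fold
    anova: AnovaTable | None = None
    selected_k: int | None = None
    extras: dict = field(default_factory=dict)

    def summary_json(self) -> dict:
        return {
            "metric_means": self.metric_means.to_dict(),
            "metric_variances": self.metric_variances.to_dict(),
            "fold_accuracies": {k: v.tolist()
                                for k, v in self.fold_accuracies.items()},
            "anova": (None if self.anova is None
                      else self.anova.to_frame().to_dict(orient="list")),
            "selected_k": self.selected_k,
        }


MACRO_METRICS = ("accuracy", "precision", "f1", "specificity", "mcc",
                 "sensitivity")


def evaluate_classifiers(x: FeatureMatrix, specs: list[ClassifierSpec]
                         | None = None, n_folds: int = 5, n_repeats: int = 5,
                         seed: int = 0, with_anova: bool = True
                         ) -> EvaluationReport:
    """Repeated stratified k-fold CV of the battery on one feature matrix.

    Per repeat, metrics are computed on the confusion matrix summed over
    that repeat's test folds; means and variances are taken across
    repeats.  Confusions/ROC/fold accuracies are reported from the first
    repeat (5 per-fold accuracies per classifier feed the across-
    classifier ANOVA).
    """
    specs = specs or default_classifiers()
    k_classes = x.n_classes
    folds_per_repeat = stratified_folds(x.labels, n_folds=n_folds,
                                        n_repeats=n_repeats, seed=seed)
    all_idx = np.arange(x.n_samples)
    means = pd.DataFrame(index=[s.name for s in specs],
                         columns=MACRO_METRICS, dtype=float)
    variances = means.copy()
    confusions: dict[str, np.ndarray] = {}
    rocs: dict[str, dict] = {}
    fold_accs: dict[str, np.ndarray] = {}
    for spec in specs:
        repeat_metrics = {m: [] for m in MACRO_METRICS}
        for rep, folds in enumerate(folds_per_repeat):
            cm_sum = np.zeros((k_classes, k_classes), dtype=np.int64)
            rep_scores, rep_true, rep_fold_acc = [], [], []
            for test in folds:
                train = np.setdiff1d(all_idx, test)
                pred, scores = fit_predict(spec, _subset(x, train),
                                           _subset(x, test))
                cm = confusion(x.labels[test], pred, k_classes)
                cm_sum += cm
                if rep == 0:
                    rep_scores.append(scores)
                    rep_true.append(x.labels[test])
                    rep_fold_acc.append(float(np.trace(cm) / cm.sum()))
            m = metrics_from_confusion(cm_sum)
            repeat_metrics["accuracy"].append(m["accuracy"])
            for name in MACRO_METRICS[1:]:
                repeat_metrics[name].append(m["macro"][name])
            if rep == 0:
                confusions[spec.name] = cm_sum
                rocs[spec.name] = roc_ovr(np.concatenate(rep_scores),
                                          np.concatenate(rep_true))
                fold_accs[spec.name] = np.asarray(rep_fold_acc)
        for name in MACRO_METRICS:
            vals = np.asarray(repeat_metrics[name])
            means.loc[spec.name, name] = vals.mean()
            variances.loc[spec.name, name] = vals.var(ddof=0)
    anova = anova_across_classifiers(fold_accs) if (
        with_anova and len(specs) >= 2) else None
    return EvaluationReport(metric_means=means, metric_variances=variances,
                            confusions=confusions, rocs=rocs,
                            fold_accuracies=fold_accs, anova=anova)
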