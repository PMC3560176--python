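"""Variable importance and cross-validated activity-vs-attention modeling.

Random-forest classification ranks every activity and attention measure by
out-of-bag permutation importance (mean decrease in accuracy) and by mean
decrease in Gini impurity.  A repeated stratified 75/25 split harness then
compares six model families (linear discriminant, general linear model,
multinomial logistic, neural network, RBF support-vector machine, random
forest) on three feature sets — the 12 No-4's attention measures, the 12
CPT measures, or the 12 movement measures, each plus age and sex — scoring
accuracy, kappa, ROC-AUC, sensitivity and specificity with the clinical
group as the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import reference_tables as ref
from .stats import roc_auc

MODEL_FAMILIES = ("linear_discriminant", "general_linear",
                  "multinomial_logistic", "neural_network",
                  "support_vector", "random_forest")

FEATURE_SETS = {
    "no4s_attention": list(ref.NO4S_KEYS),
    "cptii_attention": list(ref.CPTII_KEYS),
    "activity": list(ref.ACTIVITY_KEYS),
}

CV_METRICS = ("accuracy", "kappa", "roc_auc", "sensitivity", "specificity")


# ---------------------------------------------------------------------------
# random-forest importance

@dataclass
class ImportanceResult:
    table: pd.DataFrame      # variable, mean_decrease_accuracy,
    # mean_decrease_gini, rank_accuracy, rank_gini (rank 1 = most important)
    n_trees: int
    m_try: int

    def ranked(self, criterion: str = "accuracy") -> pd.DataFrame:
        return self.table.sort_values(f"rank_{criterion}")


def _bootstrap_indices(tree_random_state: int, n: int) -> np.ndarray:
    # sklearn draws each tree's bootstrap with RandomState(tree.random_state)
    return np.random.RandomState(tree_random_state).randint(0, n, n)


def rf_importance(features: pd.DataFrame, labels: np.ndarray,
                  n_trees: int = 10_000, m_try: int = 4,
                  seed: int | None = None) -> ImportanceResult:
    """Out-of-bag permutation importance and Gini-decrease importance.

    Permutation importance follows the classic recipe: for each tree, its
    out-of-bag accuracy is compared with the accuracy after permuting one
    predictor among the out-of-bag rows, and the drops are averaged over
    trees.  Constant features legitimately receive (near-)zero importance.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    if p < m_try:
        raise ValueError("m_try exceeds the number of features")
    forest = RandomForestClassifier(n_estimators=n_trees, max_features=m_try,
                                    bootstrap=True, random_state=seed,
                                    n_jobs=1)
    forest.fit(X, y)
    # individual trees predict encoded class indices, not the raw labels
    y_enc = np.searchsorted(forest.classes_, y).astype(float)

    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    weights = 0.0
    for tree in forest.estimators_:
        boot = _bootstrap_indices(tree.random_state, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size == 0:
            continue
        Xo, yo = X[oob], y_enc[oob]
        # one prediction call: [unpermuted | feature 0 permuted | ...]
        blocks = [Xo]
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            blocks.append(Xp)
        pred = tree.predict(np.vstack(blocks)).reshape(p + 1, oob.size)
        base = (pred[0] == yo).mean()
        drops += ((base - (pred[1:] == yo).mean(axis=1))) * oob.size
        weights += oob.size
    mda = drops / weights if weights else np.zeros(p)
    gini = forest.feature_importances_

    table = pd.DataFrame({
        "variable": list(features.columns),
        "mean_decrease_accuracy": mda,
        "mean_decrease_gini": gini,
    })
    table["rank_accuracy"] = (-table["mean_decrease_accuracy"]).rank(
        method="first").astype(int)
    table["rank_gini"] = (-table["mean_decrease_gini"]).rank(
        method="first").astype(int)
    return ImportanceResult(table, n_trees, m_try)


def importance_agreement(result_a: ImportanceResult | np.ndarray,
                         result_b: ImportanceResult | np.ndarray,
                         criterion: str = "accuracy") -> float:
    """Pearson correlation between two importance vectors."""
    def _vec(r):
        if isinstance(r, ImportanceResult):
            return r.table[f"mean_decrease_{criterion}"].to_numpy(dtype=float)
        return np.asarray(r, dtype=float)
    a, b = _vec(result_a), _vec(result_b)
    if a.size != b.size:
        raise ValueError("importance vectors differ in length")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# agreement with clinical diagnosis

def cohen_kappa(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Chance-corrected agreement; NaN when chance agreement is 1."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.size != actual.size:
        raise ValueError("length mismatch")
    cats = np.unique(np.concatenate([predicted, actual]))
    p_pred = np.array([(predicted == c).mean() for c in cats])
    p_act = np.array([(actual == c).mean() for c in cats])
    pe = float(p_pred @ p_act)
    if pe >= 1.0:
        return float("nan")
    return float(cohen_kappa_score(predicted, actual))


# ---------------------------------------------------------------------------
# repeated-split predictive modeling

@dataclass
class CvComparisonResult:
    feature_set: str
    model_family: str
    n_splits: int
    split_fraction: float
    per_split: pd.DataFrame       # one row per split, CV_METRICS columns
    means: dict[str, float]


#: trees per forest inside the repeated-split harness; the importance
#: analysis uses its own much larger forest
CV_RF_TREES = 150


def _make_model(family: str, seed: int, rf_trees: int = CV_RF_TREES):
    if family == "linear_discriminant":
        return LinearDiscriminantAnalysis()
    if family == "general_linear":
        return LinearRegression()
    if family == "multinomial_logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000))
    if family == "neural_network":
        # one hidden layer of 5 units, weight decay 0.1
        return make_pipeline(StandardScaler(),
                             MLPClassifier(hidden_layer_sizes=(5,), alpha=0.1,
                                           solver="lbfgs", max_iter=500,
                                           random_state=seed))
    if family == "support_vector":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0))
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=rf_trees, max_features=4,
                                      random_state=seed, n_jobs=1)
    raise ValueError(f"unknown model family: {family}")


def _scores_and_pred(model, family: str, X: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    if family == "general_linear":
        score = model.predict(X)
        return score, (score >= 0.5).astype(int)
    if hasattr(model, "predict_proba"):
        score = model.predict_proba(X)[:, 1]
        return score, (score >= 0.5).astype(int)
    score = model.decision_function(X)
    return score, (score >= 0.0).astype(int)


def design_matrix(cohort: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    """Age + sex + the 12 measures of the chosen set."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set: {feature_set}")
    X = cohort[FEATURE_SETS[feature_set]].copy()
    X.insert(0, "age", cohort["age"].to_numpy(dtype=float))
    X.insert(1, "sex_code", (cohort["sex"] == "male").to_numpy(dtype=float))
    return X


def cv_compare(cohort: pd.DataFrame, feature_set: str, model_family: str,
               n_splits: int = 200, split_fraction: float = 0.75,
               seed: int = 0) -> CvComparisonResult:
    """Repeated stratified 75/25 evaluation of one family on one feature set.

    The clinical group is the positive class throughout; sensitivity is the
    case recall and specificity the control recall at the 0.5 posterior
    (or midpoint score) threshold.  `(seed, n_splits)` fully determines the
    split sequence, which is shared across families and feature sets.
    """
    y = (cohort["group"].to_numpy() == "ADHD").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both groups")
    X = design_matrix(cohort, feature_set).to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")

    splitter = StratifiedShuffleSplit(n_splits=n_splits,
                                      train_size=split_fraction,
                                      random_state=seed % (2 ** 31))
    rows = []
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        model = _make_model(model_family, seed=(seed + 7919 * k) % (2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X[tr], y[tr])
        score, pred = _scores_and_pred(model, model_family, X[te])
        yt = y[te]
        pos, neg = yt == 1, yt == 0
        rows.append({
            "split": k,
            "accuracy": float((pred == yt).mean()),
            "kappa": cohen_kappa(pred, yt),
            "roc_auc": roc_auc(score, yt).auc,
            "sensitivity": float((pred[pos] == 1).mean()),
            "specificity": float((pred[neg] == 0).mean()),
        })
    per_split = pd.DataFrame(rows)
    means = {m: float(np.nanmean(per_split[m])) for m in CV_METRICS}
    return CvComparisonResult(feature_set, model_family, n_splits,
                              split_fraction, per_split, means)


def cv_grid(cohort: pd.DataFrame, n_splits: int = 200,
            n_splits_rf: int | None = None, seed: int = 0,
            families: tuple[str, ...] = MODEL_FAMILIES,
            feature_sets: tuple[str, ...] = tuple(FEATURE_SETS)
            ) -> dict[tuple[str, str], CvComparisonResult]:
    """The full criteria x family x feature-set comparison grid."""
    out = {}
    for fam in families:
        reps = n_splits_rf if (fam == "random_forest" and n_splits_rf) else n_splits
        for fs in feature_sets:
            out[(fs, fam)] = cv_compare(cohort, fs, fam, n_splits=reps,
                                        seed=seed)
    return out


@dataclass
class PairedComparison:
    p: float
    statistic: float
    method: str               # "paired_t" or "wilcoxon"
    mean_difference: float


def paired_feature_set_test(metrics_activity: np.ndarray,
                            metrics_attention: np.ndarray
                            ) -> PairedComparison:
    """Two-sided paired comparison of split-level metric values.

    Uses the paired t-test; falls back to the Wilcoxon signed-rank test
    when the split differences are clearly non-normal (Shapiro p < 0.01).
    Both sequences must come from the same split series.
    """
    a = np.asarray(metrics_activity, dtype=float)
    b = np.asarray(metrics_attention, dtype=float)
    if a.size != b.size:
        raise ValueError("metric sequences must share the split series")
    diff = a - b
    if np.allclose(diff, 0.0):
        return PairedComparison(1.0, 0.0, "paired_t", 0.0)
    method = "paired_t"
    if 8 <= diff.size <= 5000 and np.ptp(diff) > 0:
        if sps.shapiro(diff).pvalue < 0.01:
            method = "wilcoxon"
    if method == "wilcoxon":
        res = sps.wilcoxon(a, b)
        return PairedComparison(float(res.pvalue), float(res.statistic),
                                method, float(diff.mean()))
    res = sps.ttest_rel(a, b)
    return PairedComparison(float(res.pvalue), float(res.statistic),
                            method, float(diff.mean()))
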