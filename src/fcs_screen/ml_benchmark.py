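"""Classification benchmark: feature engineering, repeated train/test
evaluation of boosted trees / kernel machine / ReLU network, 0-100 feature
importance and decision-cut extraction from early trees.

Feature vectors aggregate each analyte's history into highest, lowest,
average, fluctuation (sample standard deviation) and count, plus binary
ICD-10 prefix flags. Missing aggregates stay NaN for tree models (handled
natively) and are median-imputed — with missingness indicator columns — and
z-scored for the kernel machine and the network, so tree cuts remain in
canonical laboratory units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from fcs_screen.records_io import CriteriaConfig, PatientHistory, matches_any_prefix

METHODS = ("gradient_boost", "adaboost", "svm", "relu_net")

DIRECTION_TOWARD = "+"
DIRECTION_AWAY = "-"

_AGGREGATES = ("highest", "lowest", "average", "fluctuation", "count")


@dataclass(frozen=True)
class EvalMetrics:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class EvalSummary:
    method: str
    n_experiments: int
    mean_auc: float
    std_auc: float
    mean_accuracy: float
    std_accuracy: float
    mean_sensitivity: float
    std_sensitivity: float
    mean_specificity: float
    std_specificity: float


@dataclass(frozen=True)
class FeatureImportance:
    feature: str
    importance: float  # 0-100, top feature = 100


@dataclass(frozen=True)
class CutRule:
    feature: str
    cut: float  # canonical units
    direction: str  # "+" toward FCS, "-" away


@dataclass(frozen=True)
class TrainTestSplit:
    train_pos: tuple
    train_neg: tuple
    test_pos: tuple
    test_neg: tuple

    @property
    def train(self) -> tuple:
        return self.train_pos + self.train_neg

    @property
    def test(self) -> tuple:
        return self.test_pos + self.test_neg


# ---------------------------------------------------------------------------
# feature engineering


def default_icd_prefixes(cfg: CriteriaConfig) -> tuple[str, ...]:
    prefixes = list(cfg.all_secondary_prefixes())
    prefixes += list(cfg.pancreatitis_codes)
    prefixes += list(cfg.abdominal_pain_codes)
    prefixes += list(cfg.fchl_codes)
    return tuple(dict.fromkeys(prefixes))


def build_feature_vector(
    history: PatientHistory,
    cfg: CriteriaConfig,
    analytes: Optional[Sequence[str]] = None,
    icd_prefixes: Optional[Sequence[str]] = None,
) -> dict[str, float]:
    """Aggregate one patient's record into a flat feature mapping.

    Missing analytes yield NaN aggregates (count 0); fluctuation is NaN
    when fewer than two measurements exist.
    """
    if analytes is None:
        analytes = sorted({l.analyte for l in history.labs})
    if icd_prefixes is None:
        icd_prefixes = default_icd_prefixes(cfg)
    by_analyte: dict[str, list[float]] = {a: [] for a in analytes}
    for lab in history.labs:
        if lab.analyte in by_analyte:
            by_analyte[lab.analyte].append(lab.value)
    out: dict[str, float] = {}
    for analyte in analytes:
        values = by_analyte[analyte]
        n = len(values)
        if n == 0:
            hi = lo = avg = fluct = math.nan
        else:
            hi, lo = max(values), min(values)
            avg = sum(values) / n
            if n >= 2:
                fluct = math.sqrt(sum((v - avg) ** 2 for v in values) / (n - 1))
            else:
                fluct = math.nan
        out[f"{analyte}_highest"] = hi
        out[f"{analyte}_lowest"] = lo
        out[f"{analyte}_average"] = avg
        out[f"{analyte}_fluctuation"] = fluct
        out[f"{analyte}_count"] = float(n)
    codes = [d.icd10 for d in history.diagnoses]
    for prefix in icd_prefixes:
        out[f"ICD_{prefix}"] = float(any(c.startswith(prefix) for c in codes))
    return out


def build_feature_matrix(
    histories: Mapping[str, PatientHistory],
    cfg: CriteriaConfig,
    patient_ids: Optional[Sequence[str]] = None,
    analytes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Feature matrix (rows = patients) with a shared analyte panel."""
    if patient_ids is None:
        patient_ids = list(histories)
    if analytes is None:
        analytes = sorted(
            {l.analyte for pid in patient_ids for l in histories[pid].labs}
        )
    prefixes = default_icd_prefixes(cfg)
    rows = [
        build_feature_vector(histories[pid], cfg, analytes, prefixes)
        for pid in patient_ids
    ]
    return pd.DataFrame(rows, index=list(patient_ids))


# ---------------------------------------------------------------------------
# splitting and metrics


def make_training_sets(
    positives: Sequence,
    negatives: Sequence,
    split_fraction: float = 0.5,
    seed: int = 0,
) -> TrainTestSplit:
    """Stratified random train/test split, deterministic per seed."""
    positives, negatives = list(positives), list(negatives)
    if set(positives) & set(negatives):
        raise ValueError("positives and negatives must be disjoint")
    if len(positives) < 2 or len(negatives) < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    rng = np.random.default_rng(seed)

    def _split(items: list) -> tuple[tuple, tuple]:
        order = rng.permutation(len(items))
        n_train = int(round(len(items) * split_fraction))
        n_train = min(max(n_train, 1), len(items) - 1)
        train = tuple(items[i] for i in order[:n_train])
        test = tuple(items[i] for i in order[n_train:])
        return train, test

    train_pos, test_pos = _split(positives)
    train_neg, test_neg = _split(negatives)
    return TrainTestSplit(train_pos, train_neg, test_pos, test_neg)


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (ties count 1/2): probability a positive outranks a
    negative."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks implement the 1/2 tie rule
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_scores(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> EvalMetrics:
    """AUC plus threshold-based accuracy/sensitivity/specificity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    auc = auc_score(scores, labels)
    preds = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(preds & pos))
    tn = int(np.sum(~preds & ~pos))
    sensitivity = tp / int(pos.sum())
    specificity = tn / int((~pos).sum())
    accuracy = (tp + tn) / len(labels)
    return EvalMetrics(auc, accuracy, sensitivity, specificity)


# ---------------------------------------------------------------------------
# models


def _impute_scale(X_train: np.ndarray, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median imputation (train statistics) + missingness indicators +
    z-scoring, for estimators that cannot consume NaN."""
    medians = np.nanmedian(X_train, axis=0)
    medians = np.where(np.isnan(medians), 0.0, medians)

    def _transform(X: np.ndarray) -> np.ndarray:
        missing = np.isnan(X)
        filled = np.where(missing, medians, X)
        return np.hstack([filled, missing.astype(float)])

    A, B = _transform(X_train), _transform(X_test)
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    sd[sd == 0] = 1.0
    return (A - mu) / sd, (B - mu) / sd


def _impute_only(X_train: np.ndarray, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median fill in canonical units (keeps tree cuts interpretable)."""
    medians = np.nanmedian(X_train, axis=0)
    medians = np.where(np.isnan(medians), 0.0, medians)
    return (
        np.where(np.isnan(X_train), medians, X_train),
        np.where(np.isnan(X_test), medians, X_test),
    )


def fit_and_score(
    method: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, object]:
    """Fit one model; return probability-like test scores and the model."""
    if method == "gradient_boost":
        # stochastic gradient boosting with early stopping: row subsampling
        # tempers the variance of small positive classes, and stopping at
        # validation plateau avoids late trees that only fit noise (which
        # would dilute occurrence-based importance)
        model = GradientBoostingClassifier(
            n_estimators=200, max_depth=3, learning_rate=0.1, subsample=0.8,
            n_iter_no_change=10, validation_fraction=0.2, random_state=seed,
        )
        A, B = _impute_only(X_train, X_test)
        model.fit(A, y_train)
        return model.predict_proba(B)[:, 1], model
    if method == "adaboost":
        model = AdaBoostClassifier(n_estimators=100, random_state=seed)
        A, B = _impute_only(X_train, X_test)
        model.fit(A, y_train)
        return model.predict_proba(B)[:, 1], model
    if method == "svm":
        A, B = _impute_scale(X_train, X_test)
        best_model, best_train_auc = None, -1.0
        for kernel in ("linear", "poly", "rbf"):
            with warnings.catch_warnings():
                # SVC(probability=True) is deprecated in favour of explicit
                # calibration; Platt scaling is exactly what we want here.
                warnings.simplefilter("ignore", FutureWarning)
                candidate = SVC(kernel=kernel, probability=True, random_state=seed)
                candidate.fit(A, y_train)
            train_auc = auc_score(candidate.decision_function(A), y_train)
            if train_auc > best_train_auc:
                best_model, best_train_auc = candidate, train_auc
        return best_model.predict_proba(B)[:, 1], best_model
    if method == "relu_net":
        A, B = _impute_scale(X_train, X_test)
        model = MLPClassifier(
            hidden_layer_sizes=(32, 16),
            activation="relu",
            solver="adam",
            max_iter=300,
            random_state=seed,
        )
        model.fit(A, y_train)
        return model.predict_proba(B)[:, 1], model
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_benchmark(
    features: pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    method: str,
    n_experiments: int = 30,
    split_fraction: float = 0.5,
    base_seed: int = 0,
    threshold: float = 0.5,
) -> tuple[EvalSummary, list]:
    """Repeated split/fit/score evaluation of one method.

    Experiment ``i`` uses seed ``base_seed + i``. Returns the metric summary
    (mean and population std over experiments) and the fitted models.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    labels = pd.Series(labels).reindex(features.index)
    if labels.isna().any():
        raise ValueError("labels missing for some feature rows")
    pos_ids = list(features.index[labels == 1])
    neg_ids = list(features.index[labels == 0])
    metrics: list[EvalMetrics] = []
    models = []
    X = features.to_numpy(dtype=float)
    row_of = {pid: i for i, pid in enumerate(features.index)}
    for i in range(n_experiments):
        seed = base_seed + i
        split = make_training_sets(pos_ids, neg_ids, split_fraction, seed)
        tr = [row_of[p] for p in split.train]
        te = [row_of[p] for p in split.test]
        y_tr = labels.iloc[tr].to_numpy(dtype=int)
        y_te = labels.iloc[te].to_numpy(dtype=int)
        scores, model = fit_and_score(method, X[tr], y_tr, X[te], seed)
        metrics.append(evaluate_scores(scores, y_te, threshold))
        models.append(model)

    def _mean_std(attr: str) -> tuple[float, float]:
        vals = np.array([getattr(m, attr) for m in metrics])
        return float(vals.mean()), float(vals.std())  # population std

    summary = EvalSummary(
        method,
        n_experiments,
        *_mean_std("auc"),
        *_mean_std("accuracy"),
        *_mean_std("sensitivity"),
        *_mean_std("specificity"),
    )
    return summary, models


def summary_frame(summaries: Iterable[EvalSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": s.method,
                "experiments": s.n_experiments,
                "mean_auc": round(s.mean_auc, 3),
                "std_auc": round(s.std_auc, 3),
                "mean_acc": round(s.mean_accuracy, 3),
                "std_acc": round(s.std_accuracy, 3),
                "mean_sens": round(s.mean_sensitivity, 3),
                "std_sens": round(s.std_sensitivity, 3),
                "mean_spec": round(s.mean_specificity, 3),
                "std_spec": round(s.std_specificity, 3),
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# tree introspection


def _component_trees(ensemble) -> list:
    estimators = getattr(ensemble, "estimators_", None)
    if estimators is None:
        raise ValueError("model exposes no tree ensemble (estimators_)")
    return [est for est in np.asarray(estimators).ravel()]


def _node_depths(tree) -> np.ndarray:
    depths = np.zeros(tree.node_count, dtype=int)
    stack = [(0, 0)]
    while stack:
        node, depth = stack.pop()
        depths[node] = depth
        left, right = tree.children_left[node], tree.children_right[node]
        if left != -1:
            stack.append((left, depth + 1))
            stack.append((right, depth + 1))
    return depths


def _node_affinity(tree, node: int) -> float:
    """Monotone proxy for P(positive) of a node's subtree."""
    value = tree.value[node]
    flat = np.asarray(value, dtype=float).ravel()
    if flat.size == 1:  # regression tree (gradient boosting): raw score
        return float(flat[0])
    return float(flat[-1] / flat.sum()) if flat.sum() else 0.0  # class histogram


def rank_feature_importance(
    ensembles: Iterable, feature_names: Sequence[str]
) -> list[FeatureImportance]:
    """Depth-weighted split-occurrence importance, rescaled to top = 100.

    Each split contributes ``1 / (1 + depth)`` for its feature, summed over
    all trees of all ensembles; ties are ordered by feature name.
    """
    weights: dict[str, float] = {}
    for ensemble in ensembles:
        for est in _component_trees(ensemble):
            tree = est.tree_
            depths = _node_depths(tree)
            for node in range(tree.node_count):
                if tree.children_left[node] == -1:
                    continue
                name = feature_names[tree.feature[node]]
                weights[name] = weights.get(name, 0.0) + 1.0 / (1 + depths[node])
    if not weights:
        return []
    top = max(weights.values())
    ranked = [
        FeatureImportance(name, 100.0 * w / top) for name, w in weights.items()
    ]
    ranked.sort(key=lambda fi: (-fi.importance, fi.feature))
    return ranked


def extract_decision_cuts(
    ensemble, k_first_trees: int = 5, feature_names: Optional[Sequence[str]] = None
) -> list[CutRule]:
    """Read (feature, threshold, direction) from the first boosted trees.

    Direction is ``+`` when the high side of the cut (value above the
    threshold) carries the higher predicted FCS affinity. Duplicate
    (feature, threshold) pairs keep the earliest tree's cut.
    """
    trees = _component_trees(ensemble)[:k_first_trees]
    if feature_names is None:
        n = getattr(ensemble, "n_features_in_", 0)
        feature_names = [f"x{i}" for i in range(n)]
    cuts: list[CutRule] = []
    seen: set[tuple[str, float]] = set()
    for est in trees:
        tree = est.tree_
        for node in range(tree.node_count):
            left, right = tree.children_left[node], tree.children_right[node]
            if left == -1:
                continue
            name = feature_names[tree.feature[node]]
            threshold = float(tree.threshold[node])
            key = (name, round(threshold, 8))
            if key in seen:
                continue
            seen.add(key)
            direction = (
                DIRECTION_TOWARD
                if _node_affinity(tree, right) > _node_affinity(tree, left)
                else DIRECTION_AWAY
            )
            cuts.append(CutRule(name, threshold, direction))
    return cuts


def importance_frame(ranked: Iterable[FeatureImportance]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"condition": fi.feature, "importance": round(fi.importance, 1)} for fi in ranked]
    )


def cuts_frame(cuts: Iterable[CutRule]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"feature": c.feature, "cut": round(c.cut, 4), "impact": c.direction} for c in cuts]
    )
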