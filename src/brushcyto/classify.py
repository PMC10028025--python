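"""Feature selection, class-balanced multi-expert training, and evaluation.

Selection offers three schemes: Wilcoxon rank-sum and two-sided t-test
ranking (top-k among features passing alpha = 0.05) and a greedy
minimum-redundancy maximum-relevance (mRMR) search with a Pearson
correlation pruning threshold of 0.7.

Class imbalance is handled by a multi-expert scheme: with minority size b
and majority size m, the first expert trains on all b minority examples
plus b sampled majority examples; the second trains on the (m - b)
remaining majority examples plus (m - b) minority examples resampled from
the b available.  Predictions average expert probabilities.

Evaluation reports a threshold-sweep ROC (trapezoidal AUC), and
sensitivity/specificity at an operating probability-of-malignancy
threshold (default 0.3) at cluster or patient level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

POSITIVE_LABEL = 1  # malignant
BASE_LEARNERS = ("lda", "qda", "bagged_c45")
SELECTION_METHODS = ("wilcoxon", "ttest", "mrmr")

#: default operating point on the probability-of-malignancy axis
DEFAULT_OPERATING_THRESHOLD = 0.3


@dataclass
class SelectionConfig:
    """Feature-selection and cross-validation settings."""

    method: str = "ttest"
    k_top: int = 5
    alpha: float = 0.05
    mrmr_corr_threshold: float = 0.7
    cv_folds: int = 3
    cv_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in SELECTION_METHODS:
            raise ValueError(f"method must be one of {SELECTION_METHODS}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.mrmr_corr_threshold <= 1.0):
            raise ValueError("mrmr_corr_threshold must lie in (0, 1]")
        if self.k_top < 1 or self.cv_folds < 2 or self.cv_iterations < 1:
            raise ValueError("k_top >= 1, cv_folds >= 2, cv_iterations >= 1")


def _as_matrix(X) -> Tuple[np.ndarray, List[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _as_binary(y) -> np.ndarray:
    """Map labels to {0 benign, 1 malignant}; accepts strings or ints."""
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        out = np.array([1 if str(v).lower().startswith("mal") else 0
                        for v in y])
    else:
        out = y.astype(int)
    if set(np.unique(out)) - {0, 1}:
        raise ValueError("labels must be binary")
    return out


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def rank_univariate(X, y, method: str = "ttest") -> pd.DataFrame:
    """Rank features by a two-sample test between the classes.

    Returns a table (feature, p_value, effect_size) in ascending p order;
    ties break on larger effect size, then name.  Effect size is the
    rank-biserial deviation |U/(n0*n1) - 1/2| for ``wilcoxon`` and the
    absolute standardized mean difference for ``ttest``.  Constant features
    get p = 1 (flagged), never an exception.
    """
    if method not in ("wilcoxon", "ttest"):
        raise ValueError("method must be 'wilcoxon' or 'ttest'")
    mat, names = _as_matrix(X)
    yb = _as_binary(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("both classes must be present")
    x0 = mat[yb == 0]
    x1 = mat[yb == 1]
    pvals = np.ones(mat.shape[1])
    effects = np.zeros(mat.shape[1])
    constant = []
    for j in range(mat.shape[1]):
        a, b = x1[:, j], x0[:, j]
        if np.ptp(mat[:, j]) < 1e-300:
            constant.append(names[j])
            continue
        if method == "wilcoxon":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            pvals[j] = res.pvalue
            effects[j] = abs(res.statistic / (len(a) * len(b)) - 0.5)
        else:
            res = stats.ttest_ind(a, b)
            pvals[j] = res.pvalue if np.isfinite(res.pvalue) else 1.0
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
            effects[j] = (abs(a.mean() - b.mean()) / pooled
                          if pooled > 0 else 0.0)
    if constant:
        warnings.warn(f"constant features ranked last (p=1): "
                      f"{constant[:5]}", stacklevel=2)
    table = pd.DataFrame(
        {"feature": names, "p_value": pvals, "effect_size": effects}
    )
    table = table.sort_values(
        by=["p_value", "effect_size", "feature"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def _relevance(mat: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Absolute point-biserial (Pearson) correlation with the class label."""
    yc = yb - yb.mean()
    rel = np.zeros(mat.shape[1])
    ys = np.sqrt((yc**2).sum())
    for j in range(mat.shape[1]):
        xc = mat[:, j] - mat[:, j].mean()
        xs = np.sqrt((xc**2).sum())
        if xs > 0 and ys > 0:
            rel[j] = abs(float(xc @ yc) / (xs * ys))
    return rel


def mrmr_objective(mat: np.ndarray, yb: np.ndarray,
                   subset: Sequence[int]) -> float:
    """Set score: mean relevance minus mean pairwise |Pearson r|."""
    subset = list(subset)
    rel = _relevance(mat[:, subset], yb).mean()
    if len(subset) < 2:
        return float(rel)
    corr = np.corrcoef(mat[:, subset], rowvar=False)
    iu = np.triu_indices(len(subset), k=1)
    red = np.abs(corr[iu]).mean()
    return float(rel - red)


def select_mrmr(X, y, cfg: Optional[SelectionConfig] = None) -> List[str]:
    """Greedy forward mRMR selection of ``k_top`` features.

    The first pick maximizes relevance (absolute point-biserial
    correlation with the label); each later pick maximizes the set
    objective :func:`mrmr_objective` (mean relevance minus mean pairwise
    absolute Pearson redundancy) of the augmented selection.  Candidates
    correlated above ``mrmr_corr_threshold`` (absolute Pearson) with any
    selected feature are pruned.  Returns fewer than ``k_top`` names
    (with a warning) when the pruning exhausts the candidates.
    """
    cfg = cfg or SelectionConfig(method="mrmr")
    mat, names = _as_matrix(X)
    yb = _as_binary(y)
    if cfg.k_top > mat.shape[1]:
        raise ValueError("k_top exceeds the number of features")
    rel = _relevance(mat, yb)
    selected: List[int] = []
    candidates = list(range(mat.shape[1]))
    while candidates and len(selected) < cfg.k_top:
        if not selected:
            best = max(candidates, key=lambda j: (rel[j], names[j]))
        else:
            best = max(
                candidates,
                key=lambda j: (mrmr_objective(mat, yb, selected + [j]),
                               names[j]),
            )
        selected.append(best)
        candidates.remove(best)
        candidates = [
            j for j in candidates
            if abs(_pearson(mat[:, j], mat[:, best]))
            <= cfg.mrmr_corr_threshold
        ]
    if len(selected) < cfg.k_top:
        warnings.warn(
            f"mRMR pruning left only {len(selected)} features "
            f"(k_top={cfg.k_top})", stacklevel=2,
        )
    return [names[j] for j in selected]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    d = np.sqrt((ac**2).sum() * (bc**2).sum())
    return float(ac @ bc / d) if d > 0 else 0.0


def _select_in_fold(X_tr: pd.DataFrame, y_tr: np.ndarray,
                    cfg: SelectionConfig) -> List[str]:
    """One fold's feature choice under the configured scheme."""
    if cfg.method == "mrmr":
        return select_mrmr(X_tr, y_tr, cfg)
    table = rank_univariate(X_tr, y_tr, cfg.method)
    significant = table[table["p_value"] <= cfg.alpha]
    pool = significant if len(significant) >= cfg.k_top else table
    return pool["feature"].head(cfg.k_top).tolist()


def select_stable(
    X, y, cfg: Optional[SelectionConfig] = None,
) -> Tuple[List[str], pd.Series]:
    """Features most frequently selected across repeated CV folds.

    Runs the configured per-fold selection on every training fold of
    ``cv_iterations`` re-randomized ``cv_folds``-fold splits and returns
    the ``k_top`` most frequent features plus the full frequency table
    (fraction of folds, descending).  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or SelectionConfig()
    mat, names = _as_matrix(X)
    frame = pd.DataFrame(mat, columns=names)
    yb = _as_binary(y)
    rng = np.random.default_rng(cfg.seed)
    counts: Dict[str, int] = {n: 0 for n in names}
    n_folds_total = 0
    for _ in range(cfg.cv_iterations):
        folds = _stratified_folds(yb, cfg.cv_folds, rng)
        for test_idx in folds:
            tr = np.setdiff1d(np.arange(len(yb)), test_idx)
            chosen = _select_in_fold(frame.iloc[tr], yb[tr], cfg)
            for name in chosen:
                counts[name] += 1
            n_folds_total += 1
    freq = (pd.Series(counts, dtype=float) / n_folds_total).sort_values(
        ascending=False, kind="mergesort"
    )
    return list(freq.index[: cfg.k_top]), freq


# ---------------------------------------------------------------------------
# multi-expert training
# ---------------------------------------------------------------------------

def base_learner(name: str, seed: int = 0):
    """Instantiate a base classifier by name."""
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=1e-6)
    if name == "bagged_c45":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(criterion="entropy",
                                             random_state=seed),
            n_estimators=100,
            random_state=seed,
        )
    raise ValueError(f"base learner must be one of {BASE_LEARNERS}")


@dataclass
class MultiExpertModel:
    """Parallel classifiers trained on class-balanced resamples."""

    experts: List = field(default_factory=list)
    expert_indices: List[np.ndarray] = field(default_factory=list)
    b: int = 0
    m: int = 0
    feature_names: Optional[List[str]] = None
    base_name: str = "lda"

    def predict_proba_malignant(self, X) -> np.ndarray:
        """Mean of expert probabilities for the malignant class."""
        mat, names = _as_matrix(X)
        if self.feature_names is not None and isinstance(X, pd.DataFrame):
            mat = X[self.feature_names].to_numpy(dtype=float)
        probs = np.zeros(mat.shape[0])
        for est in self.experts:
            idx = list(est.classes_).index(POSITIVE_LABEL)
            probs += est.predict_proba(mat)[:, idx]
        return probs / len(self.experts)


def fit_multi_expert(
    X, y, base: str = "lda", seed: int = 0,
    feature_names: Optional[List[str]] = None,
) -> MultiExpertModel:
    """Train the class-balancing multi-expert ensemble.

    With balanced classes (b = m) a single expert sees all the data.
    Otherwise expert 1 trains on all b minority plus b majority examples
    sampled without replacement, and expert 2 on the (m - b) remaining
    majority examples plus (m - b) minority examples drawn from the b
    available (with replacement when m - b > b).
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
    mat, _ = _as_matrix(X)
    yb = _as_binary(y)
    classes, counts = np.unique(yb, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present for training")
    rng = np.random.default_rng(seed)
    b, m = int(counts.min()), int(counts.max())
    model = MultiExpertModel(b=b, m=m, feature_names=feature_names,
                             base_name=base)
    if b == m:
        est = clone(base_learner(base, seed))
        est.fit(mat, yb)
        model.experts.append(est)
        model.expert_indices.append(np.arange(len(yb)))
        return model

    minority_class = classes[np.argmin(counts)]
    min_idx = np.flatnonzero(yb == minority_class)
    maj_idx = np.flatnonzero(yb != minority_class)

    # expert 1: all minority + b majority (without replacement)
    maj_sample = rng.choice(maj_idx, size=b, replace=False)
    idx1 = np.concatenate([min_idx, maj_sample])
    # expert 2: the (m - b) left-over majority + (m - b) resampled minority
    complement = np.setdiff1d(maj_idx, maj_sample)
    k = m - b
    min_sample = rng.choice(min_idx, size=k, replace=k > b)
    idx2 = np.concatenate([min_sample, complement])

    for idx in (idx1, idx2):
        est = clone(base_learner(base, seed))
        est.fit(mat[idx], yb[idx])
        model.experts.append(est)
        model.expert_indices.append(idx)
    return model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """ROC, AUC and operating-point metrics for one prediction set."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    operating_threshold: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    level: str = "cluster"
    summary: Dict[str, float] = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        tn, fp, fn, tp = self.confusion.ravel()
        return tp / (tp + fn) if tp + fn else float("nan")

    @property
    def specificity(self) -> float:
        tn, fp, fn, tp = self.confusion.ravel()
        return tn / (tn + fp) if tn + fp else float("nan")


def confusion_at(probabilities: np.ndarray, yb: np.ndarray,
                 threshold: float) -> np.ndarray:
    """2x2 counts [[TN, FP], [FN, TP]]; probability >= threshold = positive."""
    pred = probabilities >= threshold
    tp = int(np.sum(pred & (yb == 1)))
    tn = int(np.sum(~pred & (yb == 0)))
    fp = int(np.sum(pred & (yb == 0)))
    fn = int(np.sum(~pred & (yb == 1)))
    return np.array([[tn, fp], [fn, tp]])


def evaluate(
    probabilities,
    labels,
    threshold: float = DEFAULT_OPERATING_THRESHOLD,
    level: str = "cluster",
) -> EvaluationReport:
    """Threshold-sweep ROC with trapezoidal AUC plus operating-point
    confusion.  The sweep grid is the sorted unique probabilities plus
    endpoints; ``probability >= t`` counts as a positive call.  Raises for
    single-class label vectors (AUC undefined)."""
    probs = np.asarray(probabilities, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    yb = _as_binary(labels)
    if len(np.unique(yb)) < 2:
        raise ValueError("AUC undefined: only one class present")
    grid = np.concatenate([[0.0], np.unique(probs), [np.nextafter(1.0, 2)]])
    sens = np.empty(grid.size)
    spec = np.empty(grid.size)
    n_pos = int((yb == 1).sum())
    n_neg = int((yb == 0).sum())
    for i, t in enumerate(grid):
        pred = probs >= t
        sens[i] = np.sum(pred & (yb == 1)) / n_pos
        spec[i] = np.sum(~pred & (yb == 0)) / n_neg
    fpr = 1.0 - spec
    # sort by (fpr, tpr) so vertical ROC segments contribute zero width
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return EvaluationReport(
        thresholds=grid,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        operating_threshold=threshold,
        confusion=confusion_at(probs, yb, threshold),
        level=level,
    )


def predict_patients(
    model: MultiExpertModel,
    X,
    patient_ids: Sequence[str],
    rule: str = "mean",
) -> pd.Series:
    """Patient-level probability of malignancy from cluster probabilities.

    ``rule`` is mean (default), median or max over the patient's clusters.
    """
    probs = model.predict_proba_malignant(X)
    return aggregate_patient_probabilities(probs, patient_ids, rule)


def aggregate_patient_probabilities(
    probabilities, patient_ids: Sequence[str], rule: str = "mean"
) -> pd.Series:
    if rule not in ("mean", "median", "max"):
        raise ValueError("rule must be mean, median or max")
    s = pd.Series(np.asarray(probabilities, dtype=float),
                  index=list(patient_ids))
    if s.empty:
        raise ValueError("no clusters given")
    grouped = s.groupby(level=0)
    return getattr(grouped, rule)()


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _stratified_folds(
    yb: np.ndarray, n_folds: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """Random stratified fold assignment; returns test index arrays."""
    folds: List[List[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(yb):
        idx = np.flatnonzero(yb == cls)
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _patient_folds(
    yb: np.ndarray,
    groups: Sequence[str],
    n_folds: int,
    rng: np.random.Generator,
    max_retries: int = 20,
) -> List[np.ndarray]:
    """Patient-level stratified folds mapped back to cluster indices.

    Every cluster of a patient lands in the same fold; folds are resplit
    (bounded retries) until each one contains both classes.
    """
    groups = np.asarray(groups)
    patients, first_idx = np.unique(groups, return_index=True)
    pat_y = yb[first_idx]
    for _ in range(max_retries):
        pat_folds = _stratified_folds(pat_y, n_folds, rng)
        cluster_folds = [
            np.flatnonzero(np.isin(groups, patients[f])) for f in pat_folds
        ]
        ok = all(
            len(np.unique(yb[np.setdiff1d(np.arange(len(yb)), f)])) == 2
            and len(f) > 0
            for f in cluster_folds
        )
        if ok:
            return cluster_folds
    raise RuntimeError("could not build folds containing both classes")


def cross_validate(
    X,
    y,
    groups: Sequence[str],
    cfg: Optional[SelectionConfig] = None,
    base: str = "lda",
    operating_threshold: float = DEFAULT_OPERATING_THRESHOLD,
) -> EvaluationReport:
    """Repeated patient-stratified k-fold cross-validation.

    Per iteration: a fresh patient-level stratified split; feature
    selection refit inside each training fold; a multi-expert model per
    fold; AUC / sensitivity / specificity computed on the pooled
    held-out predictions of the iteration.  The returned report carries the
    last iteration's ROC and the mean +/- sd summary over iterations.
    """
    cfg = cfg or SelectionConfig()
    mat, names = _as_matrix(X)
    frame = pd.DataFrame(mat, columns=names)
    yb = _as_binary(y)
    rng = np.random.default_rng(cfg.seed)
    aucs, senss, specs = [], [], []
    report = None
    for it in range(cfg.cv_iterations):
        folds = _patient_folds(yb, groups, cfg.cv_folds, rng)
        probs = np.full(len(yb), np.nan)
        for test_idx in folds:
            tr = np.setdiff1d(np.arange(len(yb)), test_idx)
            chosen = _select_in_fold(frame.iloc[tr], yb[tr], cfg)
            model = fit_multi_expert(
                frame.iloc[tr][chosen], yb[tr], base=base,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            probs[test_idx] = model.predict_proba_malignant(
                frame.iloc[test_idx][chosen]
            )
        report = evaluate(probs, yb, threshold=operating_threshold)
        aucs.append(report.auc)
        senss.append(report.sensitivity)
        specs.append(report.specificity)
    report.summary = {
        "auc_mean": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs)),
        "sensitivity_mean": float(np.mean(senss)),
        "sensitivity_sd": float(np.std(senss)),
        "specificity_mean": float(np.mean(specs)),
        "specificity_sd": float(np.std(specs)),
        "n_iterations": cfg.cv_iterations,
    }
    return report


# ---------------------------------------------------------------------------
# diagnostic cross-tabulation arithmetic
# ---------------------------------------------------------------------------

def diagnostic_table_metrics(table: pd.DataFrame) -> Dict[str, float]:
    """Sensitivity/specificity arithmetic on a diagnostic cross-tabulation.

    ``table`` has one row per (cytology, machine) cell with columns
    ``cytology`` in {benign, atypical, malignant}, ``machine`` in
    {negative, positive}, and follow-up counts ``n_benign``/``n_malignant``.

    Returns machine sensitivity and specificity against follow-up, plus
    cytology-alone sensitivity computed two ways: excluding atypicals, and
    including atypicals treated as negative (non-malignant) calls.
    """
    t = table.copy()
    for col in ("cytology", "machine", "n_benign", "n_malignant"):
        if col not in t.columns:
            raise ValueError(f"missing column {col!r}")
    mal = t["n_malignant"]
    ben = t["n_benign"]
    machine_pos = t["machine"] == "positive"
    tp = int(mal[machine_pos].sum())
    fn = int(mal[~machine_pos].sum())
    tn = int(ben[~machine_pos].sum())
    fp = int(ben[machine_pos].sum())
    cyto_pos = t["cytology"] == "malignant"
    atypical = t["cytology"] == "atypical"
    cyto_tp = int(mal[cyto_pos].sum())
    return {
        "machine_sensitivity": tp / (tp + fn),
        "machine_specificity": tn / (tn + fp),
        "cytology_sensitivity_excl_atypical":
            cyto_tp / int(mal[~atypical].sum()),
        "cytology_sensitivity_incl_atypical": cyto_tp / int(mal.sum()),
    }
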