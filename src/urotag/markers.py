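"""Random-forest marker selection, POD index and ROC/AUC.

The marker workflow restricts attention to the most abundant species
(top 30 by overall mean relative abundance), ranks them by random-forest
Gini importance, and traces a cross-validation error curve over nested
top-k feature sets under repeated stratified 10-fold CV.  The optimal
marker set is chosen by the min-error-plus-SD rule: the cut-off value is
the minimum mean CV error plus the SD at that point, and the optimal set
is the smallest k whose error beats the cut-off.

The probability-of-disease (POD) index of a sample is the fraction of
ensemble trees voting for the stone-side class; for training samples the
vote is taken among trees for which the sample is out-of-bag, which avoids
resubstitution optimism.  Discrimination is summarised by the ROC curve
and the rank (Mann-Whitney) AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = [
    "rank_features",
    "cv_error_curve",
    "select_optimal_set",
    "pod_index",
    "roc_auc",
    "MarkerModel",
    "fit_marker_model",
    "POSITIVE_CLASS",
]

POSITIVE_CLASS = "stone"


def _check_two_classes(y: np.ndarray) -> list:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need exactly two classes with >= 2 samples each")
    return list(classes)


def top_abundant_features(profiles: pd.DataFrame, top_n: int = 30) -> list[str]:
    """The ``top_n`` taxa by overall mean relative abundance."""
    return profiles.mean(axis=1).sort_values(ascending=False).head(top_n).index.tolist()


def rank_features(
    profiles: pd.DataFrame,
    labels,
    n_trees: int = 500,
    seed: int | None = None,
    top_n: int = 30,
) -> list[str]:
    """Species ranked by decreasing random-forest Gini importance.

    The forest is trained on the ``top_n`` most abundant species only; ties
    break alphabetically so the ranking is deterministic for a fixed seed.
    """
    features = top_abundant_features(profiles, top_n)
    x = profiles.loc[features].T.to_numpy(dtype=float)
    y = np.asarray(labels)
    _check_two_classes(y)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed).fit(x, y)
    order = sorted(
        range(len(features)), key=lambda i: (-rf.feature_importances_[i], features[i])
    )
    return [features[i] for i in order]


def cv_error_curve(
    profiles: pd.DataFrame,
    labels,
    ranking: list[str],
    folds: int = 10,
    repeats: int = 10,
    seed: int | None = None,
    n_trees: int = 100,
) -> pd.DataFrame:
    """Mean and SD of CV misclassification error for nested top-k feature sets.

    For each k the forest is retrained on the k top-ranked species under
    repeated stratified ``folds``-fold CV; the error of one repeat pools
    its folds, and mean/SD are taken across the ``repeats``.
    """
    if not ranking:
        raise ValueError("ranking must be nonempty")
    y = np.asarray(labels)
    _check_two_classes(y)
    if np.unique(y, return_counts=True)[1].min() < folds:
        raise ValueError("each class needs at least `folds` samples for stratified CV")
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    splits = list(splitter.split(np.zeros(len(y)), y))
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, len(ranking) + 1):
        x = profiles.loc[ranking[:k]].T.to_numpy(dtype=float)
        errors = np.zeros(repeats)
        for r in range(repeats):
            wrong = total = 0
            for train, test in splits[r * folds : (r + 1) * folds]:
                rf = RandomForestClassifier(
                    n_estimators=n_trees,
                    random_state=int(rng.integers(2**31)),
                )
                rf.fit(x[train], y[train])
                wrong += int((rf.predict(x[test]) != y[test]).sum())
                total += len(test)
            errors[r] = wrong / total
        rows.append({"k": k, "mean_error": errors.mean(), "sd": errors.std(ddof=1)})
    return pd.DataFrame(rows)


def select_optimal_set(
    curve: pd.DataFrame, ranking: list[str]
) -> tuple[int, list[str]]:
    """Min-error-plus-SD smallest-set rule.

    The cut-off value is (minimum mean error) + (SD at the minimising k);
    the optimal k is the smallest k with error below the cut-off (the
    minimising k itself always qualifies, covering the SD = 0 case).
    """
    if len(curve) == 0:
        raise ValueError("curve must be nonempty")
    curve = curve.sort_values("k").reset_index(drop=True)
    i_min = int(curve["mean_error"].idxmin())
    min_err = float(curve.loc[i_min, "mean_error"])
    cutoff = min_err + float(curve.loc[i_min, "sd"])
    eligible = (curve["mean_error"] < cutoff) | (curve["mean_error"] == min_err)
    k_star = int(curve.loc[eligible, "k"].min())
    return k_star, ranking[:k_star]


@dataclass
class MarkerModel:
    """A fitted marker panel with its selection diagnostics."""

    ranking: list[str]
    cv_curve: pd.DataFrame
    k_star: int
    optimal_set: list[str]
    forest: RandomForestClassifier
    pod: pd.Series  # per training sample, out-of-bag vote fraction for "stone"
    pod_fallback_samples: list[str] = field(default_factory=list)
    auc: float = float("nan")
    roc: pd.DataFrame | None = None

    def pod_for(self, profiles: pd.DataFrame) -> pd.Series:
        """POD for new samples: fraction of all trees voting the positive class."""
        x = profiles.loc[self.optimal_set].T.to_numpy(dtype=float)
        return pd.Series(_vote_fraction(self.forest, x), index=profiles.columns)


def _vote_fraction(forest: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    # Sub-estimators predict encoded class indices; map back through classes_.
    votes = np.zeros(len(x))
    for est in forest.estimators_:
        votes += forest.classes_.take(est.predict(x).astype(int)) == POSITIVE_CLASS
    return votes / len(forest.estimators_)


def pod_index(
    forest: RandomForestClassifier, x: np.ndarray, oob: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample POD: fraction of trees voting the stone-side class.

    With ``oob=True`` the training-cohort convention applies: each sample is
    scored by the trees for which it was out-of-bag (fully grown trees cast
    effectively hard votes).  Samples that no tree left out fall back to the
    full-ensemble vote and are flagged in the returned boolean mask.
    """
    pos = list(forest.classes_).index(POSITIVE_CLASS)
    if not oob:
        return _vote_fraction(forest, x), np.zeros(len(x), dtype=bool)
    dec = forest.oob_decision_function_
    fallback = ~np.isfinite(dec).all(axis=1)
    pod = np.empty(len(x))
    pod[~fallback] = dec[~fallback, pos]
    if fallback.any():
        pod[fallback] = _vote_fraction(forest, x[fallback])
    return pod, fallback


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC step curve and the rank (Mann-Whitney) AUC with tie correction.

    AUC = P(score_positive > score_negative) + 0.5 P(tie), computed from
    mid-ranks; equal scores for all samples therefore give 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == POSITIVE_CLASS
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = roc_curve(pos.astype(int), s)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return roc, float(auc)


def fit_marker_model(
    profiles: pd.DataFrame,
    labels,
    n_trees: int = 500,
    folds: int = 10,
    repeats: int = 10,
    top_n: int = 30,
    cv_n_trees: int = 100,
    seed: int | None = None,
) -> MarkerModel:
    """Full marker workflow: rank, CV curve, optimal set, OOB POD, ROC/AUC."""
    y = np.asarray(labels)
    ranking = rank_features(profiles, y, n_trees=n_trees, seed=seed, top_n=top_n)
    curve = cv_error_curve(
        profiles, y, ranking, folds=folds, repeats=repeats, seed=seed,
        n_trees=cv_n_trees,
    )
    k_star, optimal = select_optimal_set(curve, ranking)
    x_opt = profiles.loc[optimal].T.to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed
    ).fit(x_opt, y)
    pod, fallback = pod_index(forest, x_opt, oob=True)
    pod = pd.Series(pod, index=profiles.columns, name="pod")
    roc, auc = roc_auc(pod.to_numpy(), y)
    return MarkerModel(
        ranking=ranking,
        cv_curve=curve,
        k_star=k_star,
        optimal_set=optimal,
        forest=forest,
        pod=pod,
        pod_fallback_samples=list(pod.index[fallback]),
        auc=auc,
        roc=roc,
    )
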