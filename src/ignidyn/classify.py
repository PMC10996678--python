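"""Disease-stage classification from ignition and burden features.

Binary problems (e.g. HC vs AD, HC vs MCI) are solved with a k-nearest-
neighbour classifier on features selected by minimum-Redundancy-Maximum-
Relevance (mRMR), evaluated under nested cross-validation: leave-one-out in
the outer loop, repeated stratified 75/25 splits in the inner loop to tune k.
Feature selection and tuning see training data only — the held-out subject
never influences which features are chosen or which k wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .errors import ParameterError

__all__ = [
    "ClassificationReport",
    "mrmr_select",
    "knn_predict",
    "nested_cv",
    "feature_attribution",
    "build_feature_table",
]


@dataclass
class ClassificationReport:
    """Nested-CV performance of one binary staging problem (percent scale)."""

    problem: str
    accuracy_test: float
    auc_test: float
    accuracy_train: float
    auc_train: float
    best_k: int
    n_features: int
    selected_features: list[str]
    attribution: pd.Series = field(default_factory=pd.Series)
    attribution_method: str = "permutation-importance"
    fold_features: list[list[str]] = field(default_factory=list)
    fold_ks: list[int] = field(default_factory=list)
    test_scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [self.problem],
                "accuracy_test_pct": [self.accuracy_test],
                "auc_test_pct": [self.auc_test],
                "accuracy_train_pct": [self.accuracy_train],
                "auc_train_pct": [self.auc_train],
                "best_k": [self.best_k],
                "n_features": [self.n_features],
            }
        )


def build_feature_table(
    profiles: dict[str, "object"],
    burdens: dict[str, pd.DataFrame],
    cortical_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Subjects × features table: ignition, metastability, Aβ and tau per region.

    Feature names are ``<measure>:<region_id>``; with four measures over the
    cortical regions this mirrors the study's per-parcel feature layout.
    """
    rows = {}
    for sid, prof in profiles.items():
        bt = burdens[sid].set_index("region_id")
        ids = cortical_ids if cortical_ids is not None else list(prof.region_ids)
        idx = [prof.region_ids.index(r) for r in ids]
        feats = {}
        for r, i in zip(ids, idx):
            feats[f"ignition:{r}"] = prof.ignition[i]
            feats[f"metastability:{r}"] = prof.node_metastability[i]
            feats[f"abeta:{r}"] = bt.loc[r, "abeta_suvr"]
            feats[f"tau:{r}"] = bt.loc[r, "tau_suvr"]
        rows[sid] = feats
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table


def _binned(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Equal-frequency discretisation for mutual-information estimates."""
    ranks = pd.Series(x).rank(method="first").to_numpy()
    return np.ceil(ranks * n_bins / len(ranks)).astype(int)


def mrmr_select(
    X: pd.DataFrame, y: np.ndarray, m: int = 10, n_bins: int = 4
) -> list[str]:
    """Greedy mRMR feature selection (mutual-information difference scheme).

    Features are discretised into ``n_bins`` equal-frequency bins; relevance
    is I(feature; label) and redundancy the mean mutual information with the
    already-selected set.  Constant features are excluded with a warning.
    The result is deterministic given column order (ties keep earlier columns).
    """
    if m > X.shape[1]:
        raise ParameterError(f"cannot select {m} of {X.shape[1]} features")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ParameterError("need at least two classes")
    cols = list(X.columns)
    const = [c for c in cols if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"excluding {len(const)} constant feature(s): {const[:3]}")
        cols = [c for c in cols if c not in const]
    if m > len(cols):
        raise ParameterError("too few non-constant features")
    binned = {c: _binned(X[c].to_numpy(), n_bins) for c in cols}
    relevance = {c: mutual_info_score(binned[c], y) for c in cols}
    selected: list[str] = []
    remaining = list(cols)
    red_sum = dict.fromkeys(cols, 0.0)
    while len(selected) < m:
        if selected:
            last = selected[-1]
            for c in remaining:
                red_sum[c] += mutual_info_score(binned[c], binned[last])
            best = max(
                remaining,
                key=lambda c: (relevance[c] - red_sum[c] / len(selected), -remaining.index(c)),
            )
        else:
            best = max(remaining, key=lambda c: (relevance[c], -remaining.index(c)))
        selected.append(best)
        remaining.remove(best)
    return selected


def knn_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    k: int,
) -> np.ndarray:
    """k-nearest-neighbour class-1 vote fractions.

    Features are standardised by training-fold statistics, neighbours found
    by Euclidean distance.  Scores are the fraction of the k neighbours in
    the larger class label; a downstream 0.5 threshold with ties broken
    toward the smaller label turns them into predictions.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if k > X_train.shape[0]:
        raise ParameterError(f"k={k} exceeds {X_train.shape[0]} training points")
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Xt = (X_train - mu) / sd
    Xs = (X_test - mu) / sd
    classes = np.unique(y_train)
    pos = classes.max()
    d2 = ((Xs[:, None, :] - Xt[None, :, :]) ** 2).sum(axis=2)
    # stable argsort so equidistant neighbours resolve by training order
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return (np.asarray(y_train)[nn] == pos).mean(axis=1)


def _labels_from_scores(scores: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """0.5-threshold predictions; exact ties go to the smaller class label."""
    return np.where(scores > 0.5, classes.max(), classes.min())


def nested_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    n_features: int = 10,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    n_inner_splits: int = 20,
    inner_test_size: float = 0.25,
    seed: int = 0,
    problem: str = "",
) -> ClassificationReport:
    """Leave-one-out nested cross-validation of the mRMR + kNN pipeline.

    Per outer fold, mRMR selection and k tuning use the training subjects
    only; the inner loop scores each candidate k on ``n_inner_splits``
    stratified 75/25 train/validation splits and keeps the k with the best
    mean validation accuracy (ties → smaller k).  Test accuracy and AUC are
    computed from the pooled outer-fold scores; train metrics average the
    per-fold refit models evaluated on their own training folds.  All
    percentages are on the 0–100 scale.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ParameterError("nested_cv handles binary problems")
    if counts.min() < 2:
        raise ParameterError("each class needs at least 2 subjects for stratification")
    n = len(y)
    rng = np.random.default_rng(seed)
    test_scores = np.empty(n)
    best_ks, fold_feats = [], []
    train_accs, train_aucs = [], []
    for i in range(n):
        tr = np.setdiff1d(np.arange(n), [i])
        X_tr, y_tr = X.iloc[tr], y[tr]
        feats = mrmr_select(X_tr, y_tr, n_features)
        Xf = X_tr[feats].to_numpy()
        inner_seed = int(rng.integers(0, 2**31 - 1))
        sss = StratifiedShuffleSplit(
            n_splits=n_inner_splits, test_size=inner_test_size, random_state=inner_seed
        )
        k_acc = {k: [] for k in k_range}
        for itr, ival in sss.split(Xf, y_tr):
            for k in k_range:
                if k > len(itr):
                    k_acc[k].append(0.0)
                    continue
                s = knn_predict(Xf[itr], y_tr[itr], Xf[ival], k)
                pred = _labels_from_scores(s, classes)
                k_acc[k].append(float(np.mean(pred == y_tr[ival])))
        best_k = min(k_range, key=lambda k: (-np.mean(k_acc[k]), k))
        best_ks.append(best_k)
        fold_feats.append(feats)
        test_scores[i] = knn_predict(Xf, y_tr, X.iloc[[i]][feats].to_numpy(), best_k)[0]
        s_tr = knn_predict(Xf, y_tr, Xf, best_k)
        train_accs.append(float(np.mean(_labels_from_scores(s_tr, classes) == y_tr)))
        train_aucs.append(float(roc_auc_score(y_tr == classes.max(), s_tr)))
    preds = _labels_from_scores(test_scores, classes)
    acc_test = float(np.mean(preds == y))
    auc_test = float(roc_auc_score(y == classes.max(), test_scores))
    # consensus features/k for the reportable final model: refit on all data
    best_k_overall = int(np.median(best_ks))
    if best_k_overall not in k_range:
        best_k_overall = min(k_range, key=lambda k: abs(k - best_k_overall))
    final_feats = mrmr_select(X, y, n_features)
    report = ClassificationReport(
        problem=problem,
        accuracy_test=100 * acc_test,
        auc_test=100 * auc_test,
        accuracy_train=100 * float(np.mean(train_accs)),
        auc_train=100 * float(np.mean(train_aucs)),
        best_k=best_k_overall,
        n_features=n_features,
        selected_features=final_feats,
        fold_features=fold_feats,
        fold_ks=best_ks,
        test_scores=test_scores,
    )
    report.attribution = feature_attribution(
        X[final_feats], y, best_k_overall, seed=int(rng.integers(0, 2**31 - 1))
    )
    return report


def feature_attribution(
    X: pd.DataFrame, y: np.ndarray, k: int, n_repeats: int = 30, seed: int = 0
) -> pd.Series:
    """Permutation-importance attribution for the selected-feature kNN model.

    Each feature column is shuffled ``n_repeats`` times; the importance is
    the mean drop in in-sample accuracy, a model-agnostic Shapley-style
    ranking of how much each selected feature carries.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    base_scores = knn_predict(Xv, y, Xv, k)
    base_acc = np.mean(_labels_from_scores(base_scores, classes) == y)
    drops = {}
    for j, col in enumerate(X.columns):
        accs = []
        for _ in range(n_repeats):
            Xp = Xv.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            s = knn_predict(Xv, y, Xp, k)
            accs.append(np.mean(_labels_from_scores(s, classes) == y))
        drops[col] = float(base_acc - np.mean(accs))
    return pd.Series(drops).sort_values(ascending=False)
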