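"""Linear classifiers and Consensus Feature Elimination (CFE).

Classical recursive feature elimination ranks features by the weight a single
classifier assigns them, which is unstable on small cohorts. CFE stabilizes
the ranking with an ensemble: at every elimination step, 100 alternative
stratified 5-fold splits yield 500 train/test fits; each feature is ranked by
its average squared weight over the 500 weight vectors,

    w_bar_f = sum_j w_{j,f}^2 / 500,

the lowest-ranked feature is removed, and the held-out AUCs of the 500 fits
are averaged into the step's accuracy. The feature set at the step with
maximal mean AUC is the selected marker set. Because that set is not always
unique across reruns, the whole procedure is repeated (100 times by default)
and the most frequently occurring set is kept as the final marker set.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .activity import ActivityMatrix

__all__ = [
    "LinearClassifier",
    "CFEResult",
    "train_lda",
    "train_linear_svm",
    "auc",
    "ConsensusFeatureEliminator",
    "ConsensusMarkerSelector",
    "consensus_feature_elimination",
    "select_final_markers",
]


@dataclass
class LinearClassifier:
    """A separating hyperplane D(x) = w . x + b; D > 0 predicts class +1."""

    weights: np.ndarray
    bias: float
    kind: str

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) >= 0, 1, -1)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (samples x features)")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match the number of samples")
    classes = set(np.unique(y))
    if not classes <= {-1, 1} or len(classes) != 2:
        raise ValueError("y must contain both classes, coded -1/+1")
    return X, y


def _ledoit_wolf_cov(resid: np.ndarray) -> np.ndarray:
    """Shrunk covariance (1-s)*S + s*mu*I of centered residuals.

    Closed-form Ledoit-Wolf intensity on already-centered rows; matches
    sklearn.covariance.ledoit_wolf(..., assume_centered=True).
    """
    n, p = resid.shape
    S = resid.T @ resid / n
    mu = np.trace(S) / p
    delta = np.sum(S**2) / p - 2.0 * mu * np.trace(S) / p + mu**2
    X2 = resid**2
    beta = (np.sum(X2.T @ X2) / n - np.sum(S**2)) / (p * n)
    beta = min(beta, delta)
    shrink = 0.0 if delta == 0 else beta / delta
    out = (1.0 - shrink) * S
    out.flat[:: p + 1] += shrink * mu + 1e-10  # tiny ridge guards delta == 0
    return out


def train_lda(X: np.ndarray, y: np.ndarray) -> LinearClassifier:
    """Fisher linear discriminant with Ledoit-Wolf shrinkage.

    The weight vector is w = S^-1 (mu_+ - mu_-) where S is the pooled
    within-class covariance shrunk toward a scaled identity with the
    Ledoit-Wolf automatic intensity (handles collinear activity features);
    the bias places the boundary midway between the projected class means.
    """
    X, y = _check_xy(X, y)
    pos, neg = X[y == 1], X[y == -1]
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    resid = np.vstack([pos - mu_p, neg - mu_n])
    cov = _ledoit_wolf_cov(resid)
    w = np.linalg.solve(cov, mu_p - mu_n)
    b = -float(w @ (mu_p + mu_n)) / 2.0
    return LinearClassifier(weights=w, bias=b, kind="lda")


def train_linear_svm(X: np.ndarray, y: np.ndarray, c: float = 1.0) -> LinearClassifier:
    """Soft-margin linear support vector machine (regularization ``c``)."""
    X, y = _check_xy(X, y)
    clf = SVC(kernel="linear", C=c)
    clf.fit(X, y)
    return LinearClassifier(weights=clf.coef_[0].copy(),
                            bias=float(clf.intercept_[0]), kind="svm")


_TRAINERS = {"lda": train_lda, "svm": train_linear_svm}


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals the probability that a random case scores above a random control;
    tied scores contribute 1/2. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks implement the tie = 1/2 rule
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CFEResult:
    """Full elimination trajectory of one CFE run."""

    auc_trajectory: list[float]
    auc_sd: list[float]
    n_features_per_step: list[int]
    removed_order: list
    selected_features: list
    selected_step: int
    weight_ranks: list[dict] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.selected_features:
            raise ValueError("selected feature set may not be empty")
        if any(not (0.0 <= a <= 1.0) for a in self.auc_trajectory):
            raise ValueError("mean AUC outside [0, 1]")

    @property
    def max_mean_auc(self) -> float:
        return self.auc_trajectory[self.selected_step]

    def to_frame(self) -> pd.DataFrame:
        removed = list(self.removed_order) + [None]
        return pd.DataFrame({
            "step": range(len(self.auc_trajectory)),
            "n_features": self.n_features_per_step,
            "mean_auc": self.auc_trajectory,
            "sd_auc": self.auc_sd,
            "removed_feature": removed[: len(self.auc_trajectory)],
        })


class ConsensusFeatureEliminator(BaseEstimator):
    """Ensemble recursive feature elimination with consensus weight ranking.

    Parameters
    ----------
    classifier : {"lda", "svm"}
        Linear classifier whose squared weights rank the features.
    n_splits : int, default 100
        Alternative stratified k-fold splits per elimination step
        (n_splits * n_folds classifiers are fitted per step).
    n_folds : int, default 5
    svm_c : float, default 1.0
    random_state : int or None
        Seeds the split generation; a fixed value makes the run
        bit-reproducible. The splits are drawn once and reused at every
        elimination step so that steps differ only in the feature set.

    Attributes
    ----------
    result_ : CFEResult
    selected_features_ : list of retained feature names/indices
    support_ : boolean mask over input features
    auc_trajectory_ : mean held-out AUC per elimination step
    """

    def __init__(self, classifier: str = "lda", n_splits: int = 100,
                 n_folds: int = 5, svm_c: float = 1.0,
                 random_state: int | None = None):
        self.classifier = classifier
        self.n_splits = n_splits
        self.n_folds = n_folds
        self.svm_c = svm_c
        self.random_state = random_state

    def fit(self, X, y) -> "ConsensusFeatureEliminator":
        names = None
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy()
        X, y = _check_xy(X, y)
        n, p = X.shape
        if names is None:
            names = list(range(p))
        for cls in (-1, 1):
            if int(np.sum(y == cls)) < self.n_folds:
                raise ValueError(
                    f"class {cls:+d} has fewer samples than n_folds={self.n_folds}"
                )
        if self.classifier not in _TRAINERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        trainer = _TRAINERS[self.classifier]
        kwargs = {"c": self.svm_c} if self.classifier == "svm" else {}

        rng = np.random.default_rng(self.random_state)
        folds: list[tuple[np.ndarray, np.ndarray]] = []
        for _ in range(self.n_splits):
            skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                                  random_state=int(rng.integers(2**31)))
            folds.extend(skf.split(X, y))

        active = list(range(p))
        traj, sds, n_feats, removed, ranks = [], [], [], [], []
        while True:
            cols = np.array(active)
            aucs = np.empty(len(folds))
            sq = np.zeros(len(active))
            for j, (tr, te) in enumerate(folds):
                clf = trainer(X[np.ix_(tr, cols)], y[tr], **kwargs)
                if not np.all(np.isfinite(clf.weights)):
                    raise ValueError(
                        f"non-finite classifier weights at step {len(traj)}"
                    )
                sq += clf.weights**2
                aucs[j] = auc(clf.decision(X[np.ix_(te, cols)]), y[te])
            sq /= len(folds)
            traj.append(float(aucs.mean()))
            sds.append(float(aucs.std(ddof=1)))
            n_feats.append(len(active))
            ranks.append({names[f]: float(v) for f, v in zip(active, sq)})
            if len(active) == 1:
                break
            drop = int(np.argmin(sq))  # first minimum on ties
            removed.append(names[active[drop]])
            del active[drop]

        best = 0
        for i in range(1, len(traj)):
            # maximize mean AUC; on exact ties prefer the smaller feature set
            if traj[i] > traj[best] or (traj[i] == traj[best]
                                        and n_feats[i] < n_feats[best]):
                best = i
        selected = sorted(ranks[best].keys(), key=lambda f: names.index(f)) \
            if best < len(traj) else []
        self.feature_names_in_ = names
        self.n_features_in_ = p
        self.result_ = CFEResult(
            auc_trajectory=traj, auc_sd=sds, n_features_per_step=n_feats,
            removed_order=removed, selected_features=selected,
            selected_step=best, weight_ranks=ranks,
            seed=self.random_state,
        )
        self.selected_features_ = selected
        self.auc_trajectory_ = traj
        self.support_ = np.array([nm in set(selected) for nm in names])
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_features_]
        return np.asarray(X)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def most_frequent_set(counts: Counter) -> frozenset:
    """Most frequent marker set; ties go to the smaller set, then lexicographic."""
    if not counts:
        raise ValueError("no candidate sets")
    top = max(counts.values())
    return min((s for s, c in counts.items() if c == top),
               key=lambda s: (len(s), tuple(sorted(map(str, s)))))


class ConsensusMarkerSelector(BaseEstimator):
    """Repeat CFE and keep the most frequently selected marker set.

    The maximum mean AUC of a single CFE run is stable but the arg-max
    feature set is not; repeating the elimination ``n_repeats`` times under
    different split randomizations and voting over exact sets removes that
    ambiguity. Ties go to the smaller set, then lexicographic order.

    Attributes
    ----------
    selected_features_ : the winning marker set (sorted)
    set_counts_ : Counter over frozensets of selected features
    feature_frequencies_ : per-feature selection frequency (diagnostic)
    max_mean_auc_ : mean over repeats of each run's maximal mean AUC
    """

    def __init__(self, classifier: str = "lda", n_repeats: int = 100,
                 n_splits: int = 100, n_folds: int = 5, svm_c: float = 1.0,
                 random_state: int | None = None):
        self.classifier = classifier
        self.n_repeats = n_repeats
        self.n_splits = n_splits
        self.n_folds = n_folds
        self.svm_c = svm_c
        self.random_state = random_state

    def fit(self, X, y) -> "ConsensusMarkerSelector":
        seeds = [
            int(child.generate_state(1)[0] % 2**31)
            for child in np.random.SeedSequence(self.random_state).spawn(self.n_repeats)
        ]
        counts: Counter = Counter()
        feat_counts: Counter = Counter()
        max_aucs = []
        results = []
        for s in seeds:
            elim = ConsensusFeatureEliminator(
                classifier=self.classifier, n_splits=self.n_splits,
                n_folds=self.n_folds, svm_c=self.svm_c, random_state=s,
            ).fit(X, y)
            res = elim.result_
            counts[frozenset(res.selected_features)] += 1
            feat_counts.update(res.selected_features)
            max_aucs.append(res.max_mean_auc)
            results.append(res)
        winner = most_frequent_set(counts)
        self.set_counts_ = counts
        self.feature_frequencies_ = pd.Series(
            {f: feat_counts[f] / self.n_repeats for f in feat_counts}
        ).sort_values(ascending=False)
        self.selected_features_ = sorted(winner, key=str)
        self.max_mean_auc_ = float(np.mean(max_aucs))
        self.results_ = results
        return self


def _as_xy(X, y):
    if isinstance(X, ActivityMatrix):
        frame = pd.DataFrame(X.sample_major(), columns=X.feature_ids)
        return frame, (X.labels if y is None else y)
    return X, y


def consensus_feature_elimination(
    X, y=None, classifier_kind: str = "lda", n_splits: int = 100,
    n_folds: int = 5, seed: int | None = None,
) -> CFEResult:
    """One CFE run over an ActivityMatrix or a samples x features array."""
    X, y = _as_xy(X, y)
    elim = ConsensusFeatureEliminator(classifier=classifier_kind,
                                      n_splits=n_splits, n_folds=n_folds,
                                      random_state=seed).fit(X, y)
    return elim.result_


def select_final_markers(
    X, y=None, classifier_kind: str = "lda", n_repeats: int = 100,
    n_splits: int = 100, n_folds: int = 5, seed: int | None = None,
) -> tuple[list, pd.Series, "ConsensusMarkerSelector"]:
    """Repeated CFE; returns (final marker set, per-feature frequencies, selector)."""
    X, y = _as_xy(X, y)
    sel = ConsensusMarkerSelector(classifier=classifier_kind, n_repeats=n_repeats,
                                  n_splits=n_splits, n_folds=n_folds,
                                  random_state=seed).fit(X, y)
    return sel.selected_features_, sel.feature_frequencies_, sel
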