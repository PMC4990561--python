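"""EEG-feature classification harness and group comparison.

Ten classifier configurations (the roster of a standard data-mining
workbench) are evaluated by stratified 10-fold cross-validation on
per-epoch EEG band-power features, separately for the non-self-regulated
group (G1), the self-regulated group (G2), and everyone pooled (All).
The resulting 10 x 3 accuracy matrix feeds the four rank tests of
:mod:`affectsync.stats`, asking whether the participant groups are
statistically equivalent.

Backends are scikit-learn estimators; the harness, the configurations,
the folds and the seeding are this module's contract.  Two roster
entries have no scikit-learn twin: the RIPPER rule learner is stood in
for by a pruned entropy decision tree, and the RBF network is rebuilt
as k-means RBF features (2 centers) feeding a logistic output layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .core import Epoch
from .stats import ALGORITHMS, RankTestResult, all_tests
from .valence import ALPHA_BAND, FRONTAL_PAIRS, band_power

GROUPS = ("G1", "G2", "All")
ALPHA_LEVEL = 0.05


@dataclass
class FeatureTable:
    """Per-epoch feature rows with pleasant/unpleasant/neutral labels
    and a participant-group tag."""

    X: pd.DataFrame
    y: pd.Series
    group: str = "All"

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.y.isna().any():
            raise ValueError("missing labels")


class _RBFNetwork(BaseEstimator, TransformerMixin):
    """Gaussian RBF feature layer with k-means centers (workbench-style
    RBF network front end)."""

    def __init__(self, n_clusters: int = 2, min_std: float = 0.01,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.min_std = min_std
        self.random_state = random_state

    def fit(self, X, y=None):
        km = KMeans(n_clusters=self.n_clusters, n_init=5,
                    random_state=self.random_state)
        km.fit(X)
        self.centers_ = km.cluster_centers_
        d = np.linalg.norm(X[:, None, :] - self.centers_[None], axis=2)
        lab = km.labels_
        stds = np.array([d[lab == j, j].std() if np.any(lab == j) else 0.0
                         for j in range(self.n_clusters)])
        self.stds_ = np.maximum(stds, self.min_std)
        return self

    def transform(self, X):
        d = np.linalg.norm(X[:, None, :] - self.centers_[None], axis=2)
        return np.exp(-0.5 * (d / self.stds_) ** 2)


def make_classifier(name: str, n_features: int, n_classes: int,
                    seed: int = 0):
    """Instantiate one of the ten roster configurations.

    Hyperparameters follow the published configuration list where the
    backend exposes them (SVM: C=1, linear polynomial kernel; RF: 100
    unpruned trees; C4.5-style tree: >= 15 instances per leaf; MLP:
    (features+classes)/2 hidden units, 1000 epochs, learning rate 0.4,
    momentum 0.3; KNN: 1000 neighbours, capped at the training size at
    fit time by scikit-learn semantics -- see cv_accuracy).
    """
    if name == "SVM":
        return SVC(C=1.0, kernel="poly", degree=1, gamma="scale",
                   coef0=1.0, random_state=seed)
    if name == "L":
        # multinomial logistic with a (near-vanishing) ridge of 1e-8
        return LogisticRegression(C=1e8, max_iter=1000)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, max_depth=None,
                                      random_state=seed)
    if name == "RIPPER":
        # rule-learner stand-in: repeatedly pruned decision tree
        return DecisionTreeClassifier(criterion="entropy",
                                      min_samples_leaf=3, ccp_alpha=0.01,
                                      random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=1000, algorithm="brute")
    if name == "NB":
        return GaussianNB()
    if name == "LR":
        return LogisticRegression(max_iter=500)
    if name == "C4.5":
        return DecisionTreeClassifier(criterion="entropy",
                                      min_samples_leaf=15, random_state=seed)
    if name == "RBF":
        return Pipeline([
            ("scale", StandardScaler()),
            ("rbf", _RBFNetwork(n_clusters=2, min_std=0.01,
                                random_state=seed)),
            ("out", LogisticRegression(max_iter=1000)),
        ])
    if name == "MLP":
        hidden = max(2, (n_features + n_classes) // 2)
        return MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=1000,
                             solver="sgd", learning_rate_init=0.4,
                             momentum=0.3, random_state=seed)
    raise ValueError(
        f"unknown algorithm {name!r}; supported: {', '.join(ALGORITHMS)}")


def cv_accuracy(features: FeatureTable, algorithm: str, folds: int = 10,
                seed: int = 0) -> float:
    """Stratified k-fold cross-validated accuracy, as a percent.

    Deterministic for a given (data, algorithm, seed).  If a class has
    fewer members than folds, the fold count degrades gracefully with a
    warning.
    """
    X = features.X.to_numpy(dtype=float)
    y = features.y.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    n_folds = folds
    if counts.min() < folds:
        n_folds = max(2, int(counts.min()))
        warnings.warn(
            f"smallest class has {counts.min()} rows < {folds} folds; "
            f"using {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        clf = make_classifier(algorithm, X.shape[1], len(classes), seed=seed)
        if algorithm == "KNN":
            clf.set_params(n_neighbors=min(1000, len(tr)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            clf.fit(X[tr], y[tr])
            correct += int((clf.predict(X[te]) == y[te]).sum())
    return 100.0 * correct / len(y)


def extract_features(epochs: list[Epoch],
                     band: tuple[float, float] = ALPHA_BAND,
                     include_asymmetry: bool = True,
                     group: str = "All") -> FeatureTable:
    """Per-channel band powers (and optional pair log-asymmetries) for
    every non-rejected epoch, labelled by stimulus category."""
    rows, labels = [], []
    for ep in epochs:
        if ep.rejected:
            continue
        bp = band_power(ep, band=band)
        row = {f"pow_{ch}": p for ch, p in bp.power.items()}
        if include_asymmetry:
            for left, right in FRONTAL_PAIRS:
                if bp.power[left] > 0 and bp.power[right] > 0:
                    row[f"asym_{left}_{right}"] = (np.log(bp.power[left])
                                                   - np.log(bp.power[right]))
                else:
                    row[f"asym_{left}_{right}"] = 0.0
        rows.append(row)
        labels.append(ep.stimulus.category)
    if not rows:
        raise ValueError("no usable epochs")
    return FeatureTable(X=pd.DataFrame(rows), y=pd.Series(labels),
                        group=group)


@dataclass
class GroupComparison:
    matrix: pd.DataFrame
    tests: dict[str, RankTestResult]
    verdict: str
    alpha: float = ALPHA_LEVEL
    warnings: list[str] = field(default_factory=list)


def compare_groups(features_by_group: dict[str, FeatureTable],
                   algorithms: tuple[str, ...] = ALGORITHMS,
                   folds: int = 10, seed: int = 0,
                   alpha: float = ALPHA_LEVEL,
                   transpose: bool = False) -> GroupComparison:
    """Full pipeline: per-group per-algorithm CV accuracy, the
    groups-as-treatments rank tests, and the alpha-level verdict.

    ``features_by_group`` maps group names (e.g. G1, G2) to feature
    tables; an "All" column is added by pooling unless already present.
    """
    groups = dict(features_by_group)
    if "All" not in groups and len(groups) > 1:
        groups["All"] = FeatureTable(
            X=pd.concat([g.X for g in groups.values()], ignore_index=True),
            y=pd.concat([g.y for g in groups.values()], ignore_index=True),
            group="All")
    for name, ft in groups.items():
        if ft.y.nunique() < 2:
            raise ValueError(f"group {name} has fewer than 2 classes")

    acc = {gname: {alg: cv_accuracy(ft, alg, folds=folds, seed=seed)
                   for alg in algorithms}
           for gname, ft in groups.items()}
    matrix = pd.DataFrame(acc, index=list(algorithms))
    tests = all_tests(matrix, transpose=transpose)
    min_p = min(t.p_value for t in tests.values())
    verdict = (f"reject equivalence at alpha = {alpha:g}" if min_p < alpha
               else f"fail to reject equivalence at alpha = {alpha:g}")
    return GroupComparison(matrix=matrix, tests=tests, verdict=verdict,
                           alpha=alpha)
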