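"""Random-forest phosphosite classifier with in-pipeline feature selection.

:class:`PhosphoClassifier` is a scikit-learn estimator wrapping an
optional Wilcoxon rank-sum top-k selection step and a voting classifier
(random forest by default; naive Bayes, decision tree, RBF-SVM and a
shallow neural network are available behind the same interface).  The
positive-class score of a site is the fraction of trees voting positive
and a site is called ``+1`` when the score reaches the decision cutoff.

Feature selection is refit inside every training fold during
cross-validation (the selector lives inside the estimator), so test
labels can never leak into the selected feature set.

Higher-level helpers operate on a :class:`Dataset` (sequences + site
table + optional profiles): end-to-end training, prediction over all
candidate S/T sites, the window-size sweep and the negative:positive
ratio sweep.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import fragments as frag_mod
from .encoders import DEFAULT_K_VALUES, encode_fragments, make_encoder
from .fragments import PeptideFragment, balance_negatives, extract_fragments
from .metrics import EvalResult, evaluate, roc_auc
from .profiles import PSSMProfile, StructProfile, require_profiles
from .selection import WilcoxonSelector

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("rf", "nb", "dt", "svm", "ann")

#: Default hyperparameter grid for the random forest: number of trees x
#: per-split feature count (sqrt(p) or p/4).
DEFAULT_GRID = {
    "n_estimators": [100, 300, 500, 1000],
    "max_features": ["sqrt", 0.25],
}


def _base_classifier(kind: str, n_estimators: int, max_features, random_state):
    kind = kind.lower()
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=random_state,
            n_jobs=1,
        )
    if kind == "dt":
        return DecisionTreeClassifier(random_state=random_state)
    if kind == "nb":
        return GaussianNB()
    if kind == "svm":
        return SVC(kernel="rbf", probability=True, random_state=random_state)
    if kind == "ann":
        return MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=500, random_state=random_state
        )
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


class PhosphoClassifier(ClassifierMixin, BaseEstimator):
    """Wilcoxon top-k selection + voting classifier for +1/-1 site labels.

    Parameters
    ----------
    classifier : {"rf", "nb", "dt", "svm", "ann"}
        Base learner; random forest by default.
    n_estimators : int
        Number of trees (random forest only).
    max_features : "sqrt", float or int
        Per-split feature count (random forest only).
    select_k : int or None
        When set, keep the top-k features by Wilcoxon rank-sum p-value,
        refit on every call to :meth:`fit`.
    cutoff : float
        Decision cutoff on the positive-class score in [0, 1].
    random_state : int or None
        Seed for the base learner.
    """

    def __init__(
        self,
        classifier: str = "rf",
        n_estimators: int = 500,
        max_features="sqrt",
        select_k: int | None = None,
        cutoff: float = 0.5,
        random_state: int | None = None,
    ):
        self.classifier = classifier
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.select_k = select_k
        self.cutoff = cutoff
        self.random_state = random_state

    def fit(self, X, y):
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError(f"cutoff must lie in [0,1], got {self.cutoff}")
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        names = list(X.columns) if hasattr(X, "columns") else None
        arr = np.asarray(X, dtype=float)
        self.n_features_in_ = arr.shape[1]
        self.input_feature_names_ = (
            np.asarray([str(c) for c in names], dtype=object)
            if names is not None
            else np.asarray([f"f{i}" for i in range(arr.shape[1])], dtype=object)
        )
        if self.select_k is not None:
            self.selector_ = WilcoxonSelector(k=self.select_k)
            self.selector_.fit(X if names is not None else arr, y)
            arr_sel = self.selector_.transform(arr)
            self.selected_features_ = list(self.selector_.get_feature_names_out())
        else:
            self.selector_ = None
            arr_sel = arr
            self.selected_features_ = list(self.input_feature_names_)
        self.estimator_ = _base_classifier(
            self.classifier, self.n_estimators, self.max_features, self.random_state
        )
        self.estimator_.fit(arr_sel, y)
        self.classes_ = self.estimator_.classes_
        return self

    def _transform(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {arr.shape[1]} features, expected {self.n_features_in_}"
            )
        return self.selector_.transform(arr) if self.selector_ is not None else arr

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator_.predict_proba(self._transform(X))

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class score (vote fraction for the forest) in [0, 1]."""
        proba = self.predict_proba(X)
        pos_col = int(np.where(self.classes_ == 1)[0][0])
        return proba[:, pos_col]

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        return np.where(scores >= self.cutoff, 1, -1)


def train(matrix, labels, params: dict | None = None, seed: int | None = 0) -> PhosphoClassifier:
    """Fit a :class:`PhosphoClassifier` with the given parameter overrides."""
    clf = PhosphoClassifier(random_state=seed, **(params or {}))
    return clf.fit(matrix, labels)


# ---------------------------------------------------------------------------
# cross-validation and grid search


@dataclass
class CVReport:
    """Stratified k-fold cross-validation summary."""

    fold_results: list[EvalResult]
    fold_indices: list[np.ndarray]
    pooled_labels: np.ndarray
    pooled_scores: np.ndarray
    roc_points: list[tuple[float, float]]
    auc: float
    auc_mean: float
    params: dict = field(default_factory=dict)

    @property
    def pooled_eval(self) -> EvalResult:
        cutoff = self.params.get("cutoff", 0.5)
        calls = np.where(self.pooled_scores >= cutoff, 1, -1)
        return evaluate(self.pooled_labels, calls, self.pooled_scores)


def cross_validate(
    matrix,
    labels,
    n_folds: int = 5,
    params: dict | None = None,
    seed: int = 0,
    select_k: int | None = None,
) -> CVReport:
    """Stratified k-fold CV; selection (when requested) refit per fold."""
    y = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than {n_folds} folds"
        )
    arr = np.asarray(matrix, dtype=float)
    params = dict(params or {})
    cutoff = params.get("cutoff", 0.5)
    base = PhosphoClassifier(select_k=select_k, random_state=seed, **params)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_results, fold_indices = [], []
    pooled_scores = np.empty(len(y))
    fold_aucs = []
    X_df = matrix if hasattr(matrix, "columns") else arr
    for train_idx, test_idx in skf.split(arr, y):
        clf = clone(base)
        Xtr = X_df.iloc[train_idx] if hasattr(X_df, "iloc") else arr[train_idx]
        clf.fit(Xtr, y[train_idx])
        scores = clf.decision_scores(arr[test_idx])
        pooled_scores[test_idx] = scores
        calls = np.where(scores >= cutoff, 1, -1)
        res = evaluate(y[test_idx], calls, scores)
        fold_results.append(res)
        fold_aucs.append(res.AUC)
        fold_indices.append(test_idx)
    points, auc = roc_auc(y, pooled_scores)
    return CVReport(
        fold_results=fold_results,
        fold_indices=fold_indices,
        pooled_labels=y,
        pooled_scores=pooled_scores,
        roc_points=points,
        auc=auc,
        auc_mean=float(np.mean(fold_aucs)),
        params={**params, "select_k": select_k, "cutoff": cutoff, "seed": seed},
    )


def _mtry_count(max_features, n_features: int) -> float:
    if max_features == "sqrt":
        return float(np.sqrt(n_features))
    if isinstance(max_features, float):
        return max_features * n_features
    return float(max_features)


def grid_search(
    matrix,
    labels,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
    n_folds: int = 5,
    select_k: int | None = None,
) -> tuple[dict, CVReport]:
    """Exhaustive grid search scored by mean CV AUC.

    Ties are broken toward fewer trees, then the smaller per-split
    feature count, so the result is independent of grid enumeration
    order.
    """
    grid = dict(grid or DEFAULT_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    n_features = np.asarray(matrix).shape[1]
    keys = sorted(grid)
    candidates = [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]
    results = []
    for params in candidates:
        report = cross_validate(
            matrix, labels, n_folds=n_folds, params=params, seed=seed, select_k=select_k
        )
        results.append((params, report))
    results.sort(
        key=lambda pr: (
            -pr[1].auc_mean,
            pr[0].get("n_estimators", 0),
            _mtry_count(pr[0].get("max_features", "sqrt"), n_features),
        )
    )
    best_params, best_report = results[0]
    return best_params, best_report


# ---------------------------------------------------------------------------
# end-to-end pipeline on datasets


@dataclass
class Dataset:
    """Sequences + labeled sites + optional per-protein profiles."""

    sequences: dict[str, str]
    sites: pd.DataFrame
    pssm: dict[str, PSSMProfile] = field(default_factory=dict)
    struct: dict[str, StructProfile] = field(default_factory=dict)


PROFILE_ENCODERS = {"ssf", "pssm", "pka", "combined"}


def encode_with_tags(
    fragments: Sequence[PeptideFragment],
    tags: Sequence[str],
    pssm: Mapping[str, PSSMProfile] | None = None,
    struct: Mapping[str, StructProfile] | None = None,
    k_values: tuple[int, ...] = DEFAULT_K_VALUES,
) -> pd.DataFrame:
    """Concatenate the feature matrices of several encoder tags."""
    needs_pssm = {"pssm", "pka", "combined"} & {t.lower() for t in tags}
    if needs_pssm:
        require_profiles(fragments, pssm or {}, "PSSM")
    if "ssf" in {t.lower() for t in tags}:
        require_profiles(fragments, struct or {}, "structural")
    parts = [
        encode_fragments(
            fragments,
            make_encoder(tag, pssm_profiles=pssm, struct_profiles=struct, k_values=k_values),
        )
        for tag in tags
    ]
    return pd.concat(parts, axis=1)


@dataclass
class TrainedModel:
    """A fitted classifier together with its encoding configuration."""

    classifier: PhosphoClassifier
    encoder_tags: tuple[str, ...]
    half_width: int
    k_values: tuple[int, ...]
    cutoff: float
    seed: int

    @property
    def selected_features(self) -> list[str]:
        return self.classifier.selected_features_

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.classifier, directory / "classifier.joblib")
        pd.DataFrame({"feature": self.selected_features}).to_csv(
            directory / "features.tsv", sep="\t", index=False
        )
        config = {
            "encoder_tags": list(self.encoder_tags),
            "half_width": self.half_width,
            "k_values": list(self.k_values),
            "cutoff": self.cutoff,
            "seed": self.seed,
            "classifier_params": self.classifier.get_params(),
        }
        with open(directory / "config.json", "w") as fh:
            json.dump(config, fh, indent=2, default=str)
            fh.write("\n")

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        classifier = joblib.load(directory / "classifier.joblib")
        with open(directory / "config.json") as fh:
            config = json.load(fh)
        return cls(
            classifier=classifier,
            encoder_tags=tuple(config["encoder_tags"]),
            half_width=int(config["half_width"]),
            k_values=tuple(int(k) for k in config["k_values"]),
            cutoff=float(config["cutoff"]),
            seed=int(config["seed"]),
        )


def train_on_dataset(
    dataset: Dataset,
    encoder_tags: Sequence[str] = ("combined",),
    half_width: int = 10,
    k_values: tuple[int, ...] = DEFAULT_K_VALUES,
    select_k: int | None = None,
    params: dict | None = None,
    cutoff: float = 0.5,
    seed: int = 0,
) -> TrainedModel:
    """Extract fragments, encode, select and fit in one step."""
    frags = extract_fragments(dataset.sequences, dataset.sites, half_width)
    X = encode_with_tags(frags, encoder_tags, dataset.pssm, dataset.struct, k_values)
    y = np.asarray([f.label for f in frags])
    clf = PhosphoClassifier(
        select_k=select_k, cutoff=cutoff, random_state=seed, **(params or {})
    )
    clf.fit(X, y)
    return TrainedModel(
        classifier=clf,
        encoder_tags=tuple(encoder_tags),
        half_width=half_width,
        k_values=k_values,
        cutoff=cutoff,
        seed=seed,
    )


def predict_sites(
    model: TrainedModel,
    sequences: Mapping[str, str],
    pssm: Mapping[str, PSSMProfile] | None = None,
    struct: Mapping[str, StructProfile] | None = None,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score candidate S/T sites; every S/T is scanned when no site table given."""
    if sites is None:
        rows = []
        for pid, seq in sequences.items():
            for pos in frag_mod.scan_st_sites(seq):
                rows.append((pid, pos, 0))
        sites = pd.DataFrame(rows, columns=["protein_id", "position", "label"])
    frags = [
        frag_mod.extract_window(
            sequences[r.protein_id], int(r.position), model.half_width,
            protein_id=r.protein_id, label=None,
        )
        for r in sites.itertuples(index=False)
    ]
    X = encode_with_tags(frags, model.encoder_tags, pssm, struct, model.k_values)
    scores = model.classifier.decision_scores(np.asarray(X, dtype=float))
    calls = np.where(scores >= model.cutoff, 1, -1)
    return pd.DataFrame(
        {
            "protein_id": [f.protein_id for f in frags],
            "position": [f.center_pos for f in frags],
            "residue": [f.residue for f in frags],
            "score": scores,
            "call": calls,
        }
    )


def window_sweep(
    dataset: Dataset,
    sizes: Sequence[int] = tuple(range(7, 26, 2)),
    encoder_tags: Sequence[str] = ("combined",),
    params: dict | None = None,
    seed: int = 0,
    select_k: int | None = None,
    n_folds: int = 5,
) -> pd.DataFrame:
    """Mean CV AUC as a function of window size (fragments re-extracted per size)."""
    rows = []
    for size in sorted(sizes):
        if size % 2 == 0 or size < 3:
            raise ValueError(f"window size must be odd and >= 3, got {size}")
        hw = (size - 1) // 2
        frags = extract_fragments(dataset.sequences, dataset.sites, hw)
        X = encode_with_tags(frags, encoder_tags, dataset.pssm, dataset.struct)
        y = np.asarray([f.label for f in frags])
        report = cross_validate(X, y, n_folds=n_folds, params=params, seed=seed, select_k=select_k)
        rows.append((size, report.auc_mean))
    return pd.DataFrame(rows, columns=["window", "cv_auc"])


def ratio_sweep(
    dataset: Dataset,
    ratios: Sequence[float] = (1.0, 2.0, 5.0),
    encoder_tags: Sequence[str] = ("combined",),
    half_width: int = 10,
    params: dict | None = None,
    seed: int = 0,
    select_k: int | None = None,
    n_folds: int = 5,
) -> pd.DataFrame:
    """CV performance as the negative:positive training ratio varies."""
    frags = extract_fragments(dataset.sequences, dataset.sites, half_width)
    positives = [f for f in frags if f.label == 1]
    negatives = [f for f in frags if f.label == -1]
    rows = []
    for ratio in ratios:
        subset = balance_negatives(positives, negatives, ratio=ratio, seed=seed)
        X = encode_with_tags(subset, encoder_tags, dataset.pssm, dataset.struct)
        y = np.asarray([f.label for f in subset])
        report = cross_validate(X, y, n_folds=n_folds, params=params, seed=seed, select_k=select_k)
        pooled = report.pooled_eval
        rows.append((ratio, pooled.Sn, pooled.Sp, pooled.Ac, pooled.MCC, report.auc))
    return pd.DataFrame(rows, columns=["ratio", "Sn", "Sp", "Ac", "MCC", "AUC"])
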