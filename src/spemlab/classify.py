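"""Nested cross-validated psychosis/control classification.

The protocol mirrors common clinical machine-learning practice on
case-control feature tables:

* preprocessing per training partition only: z-scaling, median
  imputation of missing measures (on the scaled values), class balancing
  (random undersampling of the majority or SMOTE oversampling of the
  minority — the choice is itself a hyperparameter), and PCA;
* hyperparameter search over five classifier families (linear/rbf SVM
  across a small C grid, random forest, Gaussian naive Bayes, logistic
  regression, AdaBoost) scored by balanced accuracy in a 10-fold inner
  cycle;
* a 3-fold stratified outer cycle estimating generalization of the
  per-fold winners;
* the deployable model = the configuration winning a final inner search
  on the full sample, refit on all rows and frozen for external cohorts.

Statistical inference uses label-permutation tests; external validation
applies the frozen model (never refit) after dropping rows with any
missing measure.

Balancing utilities (random undersampling and SMOTE) are implemented
here directly on top of scikit-learn's nearest-neighbour machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .metrics import ClassificationMetrics, ConfusionCounts, classification_metrics, mean_fold_metrics
from .simulate import FEATURES

__all__ = [
    "PursuitClassifier",
    "CVResult",
    "FoldResult",
    "ValidationReport",
    "PermutationResult",
    "random_undersample",
    "smote_oversample",
    "nested_cv_train",
    "permutation_test",
    "external_validate",
    "run_variants",
]


# ---------------------------------------------------------------------------
# Class balancing (training partitions only)
# ---------------------------------------------------------------------------

def random_undersample(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly subsample every class down to the minority count."""
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    order = np.sort(np.concatenate(keep))
    return X[order], y[order]


def smote_oversample(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: synthesize minority samples by interpolating nearest neighbours."""
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    X_out, y_out = [X], [y]
    for cls, count in zip(classes, counts):
        deficit = n_max - count
        if deficit == 0:
            continue
        Xc = X[y == cls]
        k = min(k_neighbors, len(Xc) - 1)
        if k < 1:  # cannot interpolate a singleton class; replicate instead
            synth = np.repeat(Xc, deficit, axis=0)
        else:
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, neigh = nn.kneighbors(Xc)
            base = rng.integers(0, len(Xc), size=deficit)
            pick = rng.integers(1, k + 1, size=deficit)  # skip self at column 0
            partner = neigh[base, pick]
            gamma = rng.random((deficit, 1))
            synth = Xc[base] + gamma * (Xc[partner] - Xc[base])
        X_out.append(synth)
        y_out.append(np.full(deficit, cls, dtype=y.dtype))
    return np.vstack(X_out), np.concatenate(y_out)


_BALANCERS = {"undersample": random_undersample, "smote": smote_oversample}


# ---------------------------------------------------------------------------
# Hyperparameter grid
# ---------------------------------------------------------------------------

def _make_classifier(cfg: dict, seed: int):
    name = cfg["classifier"]
    if name == "svm":
        return SVC(kernel=cfg["kernel"], C=cfg["C"], random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "gaussian_nb":
        return GaussianNB()
    if name == "logistic":
        return LogisticRegression(random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def _enumerate_grid(
    classifiers, svm_kernels, svm_C, balancers, n_components
) -> list[dict]:
    """Fixed enumeration order; ties on inner score go to the earlier entry."""
    clf_specs: list[dict] = []
    for name in classifiers:
        if name == "svm":
            for kernel in svm_kernels:
                for C in svm_C:
                    clf_specs.append({"classifier": "svm", "kernel": kernel, "C": C})
        else:
            clf_specs.append({"classifier": name})
    grid = []
    for spec in clf_specs:
        for balancer in balancers:
            for n_comp in n_components:
                grid.append({**spec, "balancer": balancer, "n_components": n_comp})
    return grid


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    counts: ConfusionCounts
    metrics: ClassificationMetrics
    config: dict
    test_index: np.ndarray
    # concatenated fitted-stage parameters (scaler moments, imputation
    # medians, PCA loadings, probe predictions); lets tests assert that
    # outer-test rows never influence the fold's fitted model
    fingerprint: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


@dataclass
class CVResult:
    folds: list[FoldResult]
    mean: ClassificationMetrics
    permutation_p: float | None = None

    @property
    def mean_bac(self) -> float:
        return self.mean.balanced_accuracy


@dataclass
class ValidationReport:
    n_input: int
    n_dropped: int
    predictions: pd.Series
    metrics: ClassificationMetrics | None = None
    counts: ConfusionCounts | None = None
    group_table: pd.DataFrame | None = None


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    permuted: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class PursuitClassifier(BaseEstimator, ClassifierMixin):
    """Nested-CV classifier over pursuit feature profiles.

    scikit-learn compatible: ``fit`` runs the full nested search and
    freezes the winning pipeline; ``predict`` applies the frozen
    preprocessing and classifier.  The outer-fold generalization record
    is stored in ``cv_result_``.

    Parameters mirror the protocol defaults; shrink ``classifiers`` or
    the grids for quick experiments.

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray of the two labels
    best_config_ : winning hyperparameter configuration
    cv_result_ : :class:`CVResult` with per-outer-fold confusion counts
    scaler_, impute_medians_, pca_, classifier_ : frozen pipeline stages
    """

    def __init__(
        self,
        classifiers: tuple[str, ...] = (
            "svm",
            "random_forest",
            "gaussian_nb",
            "logistic",
            "adaboost",
        ),
        svm_kernels: tuple[str, ...] = ("linear", "rbf"),
        svm_C: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
        balancers: tuple[str, ...] = ("undersample", "smote"),
        n_components: tuple[int, ...] = (1, 2, 3, 4),
        inner_folds: int = 10,
        outer_folds: int = 3,
        positive_label=None,
        random_state: int | None = None,
    ):
        self.classifiers = classifiers
        self.svm_kernels = svm_kernels
        self.svm_C = svm_C
        self.balancers = balancers
        self.n_components = n_components
        self.inner_folds = inner_folds
        self.outer_folds = outer_folds
        self.positive_label = positive_label
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _validate(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("training labels must be binary")
        for cls in classes:
            if (y == cls).sum() < 2:
                raise ValueError("each class needs at least 2 subjects")
        if np.isnan(X).all(axis=0).any():
            raise ValueError("a feature column is entirely missing")
        if self.inner_folds < 2 or self.outer_folds < 2:
            raise ValueError("fold counts must be >= 2")
        return X, y, classes

    def _positive(self, classes: np.ndarray):
        if self.positive_label is not None:
            if self.positive_label not in classes:
                raise ValueError("positive_label not among training labels")
            return self.positive_label
        if "psychosis" in classes:
            return "psychosis"
        return classes[-1]

    def _fit_stages(self, X, y, cfg, seed):
        """Fit scale -> impute -> balance -> reduce -> classify on one split."""
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        medians = np.nanmedian(Xs, axis=0)
        Xs = np.where(np.isnan(Xs), medians, Xs)
        rng = np.random.default_rng(seed)
        Xb, yb = _BALANCERS[cfg["balancer"]](Xs, y, rng)
        n_comp = min(cfg["n_components"], X.shape[1], len(Xb) - 1)
        pca = PCA(n_components=n_comp, random_state=seed).fit(Xb)
        clf = _make_classifier(cfg, seed).fit(pca.transform(Xb), yb)
        return scaler, medians, pca, clf

    @staticmethod
    def _transform(X, scaler, medians, pca):
        Xs = scaler.transform(X)
        Xs = np.where(np.isnan(Xs), medians, Xs)
        return pca.transform(Xs)

    def _inner_select(self, X, y, grid, seed) -> dict:
        """10-fold inner CV scoring every configuration; returns the winner."""
        inner = StratifiedKFold(
            n_splits=self.inner_folds, shuffle=True, random_state=seed
        )
        scores = np.zeros(len(grid))
        counts = np.zeros(len(grid))
        for f, (tr, te) in enumerate(inner.split(X, y)):
            Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]
            scaler = StandardScaler().fit(Xtr)
            Xs = scaler.transform(Xtr)
            medians = np.nanmedian(Xs, axis=0)
            Xs = np.where(np.isnan(Xs), medians, Xs)
            Xe = scaler.transform(Xte)
            Xe = np.where(np.isnan(Xe), medians, Xe)
            for balancer in self.balancers:
                rng = np.random.default_rng(seed + 1000 + f)
                Xb, yb = _BALANCERS[balancer](Xs, ytr, rng)
                for n_comp in self.n_components:
                    nc = min(n_comp, Xb.shape[1], len(Xb) - 1)
                    pca = PCA(n_components=nc, random_state=seed).fit(Xb)
                    Zb, Ze = pca.transform(Xb), pca.transform(Xe)
                    for g, cfg in enumerate(grid):
                        if cfg["balancer"] != balancer or cfg["n_components"] != n_comp:
                            continue
                        clf = _make_classifier(cfg, seed).fit(Zb, yb)
                        scores[g] += balanced_accuracy_score(yte, clf.predict(Ze))
                        counts[g] += 1
        mean_scores = scores / np.maximum(counts, 1)
        return grid[int(np.argmax(mean_scores))]  # argmax keeps first on ties

    def _counts(self, y_true, y_pred, positive) -> ConfusionCounts:
        pos = y_true == positive
        pred_pos = y_pred == positive
        return ConfusionCounts(
            tp=int((pos & pred_pos).sum()),
            fn=int((pos & ~pred_pos).sum()),
            tn=int((~pos & ~pred_pos).sum()),
            fp=int((~pos & pred_pos).sum()),
        )

    # -- API ---------------------------------------------------------------

    def fit(self, X, y) -> "PursuitClassifier":
        X, y, classes = self._validate(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        positive = self._positive(classes)
        self.positive_label_ = positive
        seed = 0 if self.random_state is None else int(self.random_state)
        grid = _enumerate_grid(
            self.classifiers, self.svm_kernels, self.svm_C, self.balancers, self.n_components
        )

        outer = StratifiedKFold(n_splits=self.outer_folds, shuffle=True, random_state=seed)
        folds: list[FoldResult] = []
        for f, (tr, te) in enumerate(outer.split(X, y)):
            winner = self._inner_select(X[tr], y[tr], grid, seed + 10 * f + 1)
            scaler, medians, pca, clf = self._fit_stages(X[tr], y[tr], winner, seed + 10 * f + 2)
            y_pred = clf.predict(self._transform(X[te], scaler, medians, pca))
            counts = self._counts(y[te], y_pred, positive)
            probe = X[tr][: min(20, len(tr))]
            probe_pred = clf.predict(self._transform(probe, scaler, medians, pca))
            fingerprint = np.concatenate(
                [
                    scaler.mean_,
                    scaler.scale_,
                    medians,
                    pca.components_.ravel(),
                    (probe_pred == positive).astype(float),
                ]
            )
            folds.append(
                FoldResult(
                    counts, classification_metrics(counts), winner, te.copy(), fingerprint
                )
            )
        self.cv_result_ = CVResult(folds, mean_fold_metrics([f.metrics for f in folds]))

        # deployable model: winner of a final inner search on the full table
        self.best_config_ = self._inner_select(X, y, grid, seed + 997)
        self.scaler_, self.impute_medians_, self.pca_, self.classifier_ = self._fit_stages(
            X, y, self.best_config_, seed + 998
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        Z = self._transform(X, self.scaler_, self.impute_medians_, self.pca_)
        return self.classifier_.predict(Z)

    def score(self, X, y) -> float:
        return float(balanced_accuracy_score(np.asarray(y), self.predict(X)))


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def _split_table(table: pd.DataFrame, features: tuple[str, ...] = FEATURES):
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    if "group" not in table.columns:
        raise ValueError("feature table needs a 'group' column")
    return table[list(features)], table["group"].to_numpy()


def nested_cv_train(
    table: pd.DataFrame, seed: int = 0, features: tuple[str, ...] = FEATURES, **params
) -> tuple[PursuitClassifier, CVResult]:
    """Train on a feature table (columns: features + ``group``)."""
    X, y = _split_table(table, features)
    model = PursuitClassifier(random_state=seed, **params).fit(X, y)
    return model, model.cv_result_


def _outer_bac_for_config(model: PursuitClassifier, X, y, cfg, seed, positive) -> float:
    """Outer-CV balanced accuracy of one fixed configuration (no inner search)."""
    outer = StratifiedKFold(n_splits=model.outer_folds, shuffle=True, random_state=seed)
    bacs = []
    for f, (tr, te) in enumerate(outer.split(X, y)):
        stages = model._fit_stages(X[tr], y[tr], cfg, seed + 10 * f + 2)
        y_pred = stages[3].predict(model._transform(X[te], *stages[:3]))
        bacs.append(balanced_accuracy_score(y[te], y_pred))
    return float(np.mean(bacs))


def permutation_test(
    table: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "full",
    features: tuple[str, ...] = FEATURES,
    model: PursuitClassifier | None = None,
    **params,
) -> PermutationResult:
    """Label-permutation inference for the nested-CV balanced accuracy.

    ``mode='full'`` re-runs the entire nested search per permutation
    (faithful, slow); ``mode='fast'`` freezes the observed winning
    hyperparameters and re-evaluates only the outer cycle per permutation
    — an approximation that skips per-permutation hyperparameter
    optimization.  p = (1 + #{permuted BAC >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("full", "fast"):
        raise ValueError("mode must be 'full' or 'fast'")
    X_df, y = _split_table(table, features)
    X = X_df.to_numpy(dtype=float)
    if model is None:
        model = PursuitClassifier(random_state=seed, **params).fit(X, y)
    observed = model.cv_result_.mean_bac / 100.0
    positive = model.positive_label_

    rng = np.random.default_rng(seed + 31337)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        pseed = int(rng.integers(0, 2**31 - 1))
        if mode == "full":
            m = PursuitClassifier(random_state=pseed, **params).fit(X, y_perm)
            permuted[i] = m.cv_result_.mean_bac / 100.0
        else:
            permuted[i] = _outer_bac_for_config(
                model, X, y_perm, model.best_config_, pseed, positive
            )
    p = (1.0 + float(np.sum(permuted >= observed))) / (n_perm + 1.0)
    model.cv_result_.permutation_p = p
    return PermutationResult(p_value=p, observed=observed, permuted=permuted)


def external_validate(
    model: PursuitClassifier,
    table: pd.DataFrame,
    features: tuple[str, ...] = FEATURES,
    group_col: str | None = None,
) -> ValidationReport:
    """Apply a frozen model to an external cohort.

    Rows with at least one missing measure are dropped (and counted);
    the rest pass through the frozen preprocessing and classifier.  When
    the table's ``group`` column contains both training labels, balanced
    accuracy / sensitivity / specificity are computed; per-group
    predicted-label tables use ``group_col`` (e.g. a subgroup column).
    """
    check_is_fitted(model, "classifier_")
    X = table[list(features)]
    complete = ~X.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    kept = table.loc[complete]
    if len(kept) == 0:
        raise ValueError("all rows dropped: every subject has a missing measure")
    y_pred = model.predict(kept[list(features)])
    predictions = pd.Series(y_pred, index=kept.index, name="predicted")

    metrics = counts = None
    if "group" in kept.columns:
        y_true = kept["group"].to_numpy()
        present = set(np.unique(y_true))
        if set(model.classes_) <= present:
            pos = model.positive_label_
            neg = [c for c in model.classes_ if c != pos][0]
            use = np.isin(y_true, list(model.classes_))
            counts = model._counts(y_true[use], y_pred[use], pos)
            metrics = classification_metrics(counts)

    group_table = None
    if group_col is not None and group_col in kept.columns:
        from .metrics import group_classification_report

        pos = model.positive_label_
        neg = [c for c in model.classes_ if c != pos][0]
        group_table = group_classification_report(
            kept[group_col], predictions, positive=pos, negative=neg
        )

    return ValidationReport(
        n_input=len(table),
        n_dropped=n_dropped,
        predictions=predictions,
        metrics=metrics,
        counts=counts,
        group_table=group_table,
    )


def run_variants(
    table: pd.DataFrame,
    seed: int = 0,
    variants: tuple[str, ...] = ("pairwise", "gains_only", "half_sample"),
    pooled_table: pd.DataFrame | None = None,
    subgroup_pairs: tuple[tuple[str, str], ...] = (("SZ", "SAD"), ("SZ", "BP"), ("SAD", "BP")),
    **params,
) -> dict[str, CVResult]:
    """Protocol variants, each reusing the nested-CV trainer unchanged.

    * ``pairwise`` — within-psychosis subgroup pairs (requires a
      ``subgroup`` column); absent subgroups are skipped with a warning.
    * ``gains_only`` — only the two velocity-gain measures as predictors.
    * ``half_sample`` — a random stratified 50 % subsample.
    * ``pooled`` — training on ``table`` concatenated with ``pooled_table``.
    """
    out: dict[str, CVResult] = {}
    if "pairwise" in variants:
        if "subgroup" not in table.columns:
            warnings.warn("no 'subgroup' column; skipping pairwise variant")
        else:
            for a, b in subgroup_pairs:
                sub = table[table["subgroup"].isin([a, b])]
                if sub["subgroup"].nunique() < 2:
                    warnings.warn(f"subgroup pair {a}/{b} not present; skipped")
                    continue
                pair = sub.copy()
                pair["group"] = pair["subgroup"]
                _, cv = nested_cv_train(pair, seed=seed, **params)
                out[f"pairwise_{a}_vs_{b}"] = cv
    if "gains_only" in variants:
        _, cv = nested_cv_train(
            table, seed=seed, features=("gain_pred", "gain_early"), **params
        )
        out["gains_only"] = cv
    if "half_sample" in variants:
        rng = np.random.default_rng(seed)
        parts = []
        for _, sub in table.groupby("group", sort=False):
            take = rng.choice(sub.index, size=len(sub) // 2, replace=False)
            parts.append(table.loc[np.sort(take)])
        half = pd.concat(parts)
        _, cv = nested_cv_train(half, seed=seed, **params)
        out["half_sample"] = cv
    if "pooled" in variants:
        if pooled_table is None:
            warnings.warn("no pooled_table supplied; skipping pooled variant")
        else:
            both = pd.concat([table, pooled_table], ignore_index=True)
            _, cv = nested_cv_train(both, seed=seed, **params)
            out["pooled"] = cv
    return out
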