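"""Feature selection and classification, sklearn-estimator style.

Three composable estimators implement the per-region modeling chain:

``PearsonPrefilter``
    drops zero-variance columns, then greedily removes the later member
    of every feature pair with |Pearson r| > 0.95 (canonical column
    order), mirroring the usual radiomics redundancy prefilter.

``LassoSelector``
    L1-penalized logistic path on z-scored features; the penalty is
    chosen by 10-fold cross-validated deviance (CV-minimum rule).

``SubregionClassifier``
    CART decision tree with cost-complexity pruning, or RBF-kernel SVM
    with a (C, gamma) grid, tuned by an inner stratified 10-fold CV and
    refit on the full training data.  ``predict_scores`` returns the
    continuous malignancy score used for ROC analysis (leaf class-1
    probability for the tree, signed decision value for the SVM).

All three follow the sklearn estimator contract (``get_params`` /
``set_params``, fitted attributes with trailing underscores) and compose
with sklearn model-selection utilities.  Fold assignment and tuning are
deterministic for a fixed ``random_state``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PearsonPrefilter",
    "LassoSelector",
    "SubregionClassifier",
    "RegionModel",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=np.float64))


class PearsonPrefilter(TransformerMixin, BaseEstimator):
    """Remove near-duplicate features by absolute Pearson correlation.

    Zero-variance columns are dropped first (their correlation is
    undefined).  Then a greedy scan in canonical (input) column order
    removes, for every pair with ``|r| > threshold``, the feature that
    appears later — a deterministic rule that is invariant to row order.

    Attributes
    ----------
    support_ : bool array of shape (n_features,)
    kept_ : list of retained column names
    removed_ : list of (dropped, kept_partner | None) pairs
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X, y=None):
        df = _as_frame(X)
        if df.shape[0] < 2:
            raise ValueError("need at least 2 rows to estimate correlations")
        cols = list(df.columns)
        values = df.to_numpy(dtype=np.float64)
        keep = np.ones(len(cols), dtype=bool)
        removed: list[tuple] = []

        sd = values.std(axis=0)
        for j in np.flatnonzero(sd == 0):
            keep[j] = False
            removed.append((cols[j], None))  # constant column

        live = np.flatnonzero(keep)
        if live.size == 0:
            raise ValueError("all features are constant")
        corr = np.corrcoef(values[:, live], rowvar=False)
        corr = np.atleast_2d(corr)
        dropped = np.zeros(live.size, dtype=bool)
        for a in range(live.size):
            if dropped[a]:
                continue
            too_high = np.abs(corr[a, a + 1:]) > self.threshold
            for b in np.flatnonzero(too_high) + a + 1:
                if not dropped[b]:
                    dropped[b] = True
                    removed.append((cols[live[b]], cols[live[a]]))
        keep[live[dropped]] = False

        if not keep.any():
            raise ValueError("prefilter removed every feature")
        self.support_ = keep
        self.kept_ = [c for c, k in zip(cols, keep) if k]
        self.removed_ = removed
        self.feature_names_in_ = np.array(cols, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        df = _as_frame(X)
        return df.loc[:, self.kept_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_.copy()


class LassoSelector(TransformerMixin, BaseEstimator):
    """LASSO (L1 logistic) feature selection with CV-chosen penalty.

    Features are z-scored internally; the regularization path is scored
    by 10-fold cross-validated binomial deviance and the CV-minimum
    penalty retained.  Selected features are those with nonzero
    coefficients at that penalty.  An all-zero solution is legal and
    flagged via ``empty_selection_``.
    """

    def __init__(self, folds: int = 10, random_state: int = 0, n_cs: int = 25):
        self.folds = folds
        self.random_state = random_state
        self.n_cs = n_cs

    def fit(self, X, y):
        df = _as_frame(X)
        y = np.asarray(y)
        if np.unique(y).size != 2:
            raise ValueError("LASSO selection needs exactly two classes")
        cv = StratifiedKFold(self.folds, shuffle=True, random_state=self.random_state)
        model = Pipeline([
            ("scale", StandardScaler()),
            ("lasso", LogisticRegressionCV(
                Cs=np.logspace(-3, 2, self.n_cs),
                cv=cv,
                penalty="l1",
                solver="liblinear",
                scoring="neg_log_loss",
                max_iter=500,
                refit=True,
                random_state=self.random_state,
            )),
        ])
        model.fit(df.to_numpy(dtype=np.float64), y)
        lasso = model.named_steps["lasso"]
        coef = lasso.coef_.ravel()
        self.coef_ = pd.Series(coef, index=df.columns)
        self.C_ = float(lasso.C_[0])
        self.selected_ = [c for c, w in zip(df.columns, coef) if w != 0.0]
        self.empty_selection_ = len(self.selected_) == 0
        self.feature_names_in_ = np.array(list(df.columns), dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_")
        return _as_frame(X).loc[:, self.selected_]


class SubregionClassifier(ClassifierMixin, BaseEstimator):
    """DT or SVM classifier with inner-CV hyperparameter tuning.

    Parameters
    ----------
    kind : {"dt", "svm"}
        CART tree (Gini, cost-complexity pruning chosen by inner CV) or
        RBF-kernel SVM (C in {0.1, 1, 10, 100}, gamma in
        {1/p, 0.01, 0.1, 1}).
    folds : inner/outer stratified CV fold count (10 by default).
    random_state : drives fold assignment and tree randomness.

    Attributes
    ----------
    model_ : fitted sklearn Pipeline (scaler + tuned classifier),
        refit on all training rows.
    best_params_ : chosen hyperparameters.
    cv_scores_ : pooled out-of-fold decision scores on the training rows
        (the cross-validated training ROC input).
    cv_auc_ : mean inner-CV ROC-AUC of the winning hyperparameters.
    """

    def __init__(self, kind: str = "svm", folds: int = 10, random_state: int = 0):
        self.kind = kind
        self.folds = folds
        self.random_state = random_state

    def _base(self, n_features: int):
        if self.kind == "dt":
            est = DecisionTreeClassifier(criterion="gini", random_state=self.random_state)
            grid = {"clf__ccp_alpha": [0.0]}  # placeholder; filled in fit
        elif self.kind == "svm":
            est = SVC(kernel="rbf")
            grid = {
                "clf__C": [0.1, 1.0, 10.0, 100.0],
                "clf__gamma": [1.0 / n_features, 0.01, 0.1, 1.0],
            }
        else:
            raise ValueError("kind must be 'dt' or 'svm'")
        return Pipeline([("scale", StandardScaler()), ("clf", est)]), grid

    def fit(self, X, y):
        df = _as_frame(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("need exactly two classes")
        if counts.min() < self.folds:
            raise ValueError(
                f"smallest class ({counts.min()}) cannot stratify {self.folds} folds"
            )
        Xv = df.to_numpy(dtype=np.float64)
        pipe, grid = self._base(Xv.shape[1])
        if self.kind == "dt":
            # candidate pruning strengths from the unpruned tree's path
            probe = clone(pipe)
            probe.fit(Xv, y)
            tree = probe.named_steps["clf"]
            path = tree.cost_complexity_pruning_path(probe.named_steps["scale"].transform(Xv), y)
            alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
            if alphas.size > 20:
                alphas = alphas[np.linspace(0, alphas.size - 1, 20).astype(int)]
            grid = {"clf__ccp_alpha": list(alphas)}
        cv = StratifiedKFold(self.folds, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(pipe, grid, cv=cv, scoring="roc_auc", refit=True)
        search.fit(Xv, y)
        self.model_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.cv_auc_ = float(search.best_score_)
        self.classes_ = classes
        self.feature_names_in_ = np.array(list(df.columns), dtype=object)
        # pooled out-of-fold scores with the winning hyperparameters
        method = "predict_proba" if self.kind == "dt" else "decision_function"
        oof = cross_val_predict(clone(self.model_), Xv, y, cv=cv, method=method)
        self.cv_scores_ = oof[:, 1] if oof.ndim == 2 else oof
        return self

    def predict_scores(self, X) -> np.ndarray:
        """Continuous malignancy score; higher = more malignant."""
        check_is_fitted(self, "model_")
        df = _as_frame(X)
        missing = [c for c in self.feature_names_in_ if c not in df.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing[:5]}")
        Xv = df.loc[:, list(self.feature_names_in_)].to_numpy(dtype=np.float64)
        if self.kind == "dt":
            return self.model_.predict_proba(Xv)[:, 1]
        return self.model_.decision_function(Xv)

    def predict(self, X):
        check_is_fitted(self, "model_")
        df = _as_frame(X)
        Xv = df.loc[:, list(self.feature_names_in_)].to_numpy(dtype=np.float64)
        return self.model_.predict(Xv)


class RegionModel:
    """Full per-region chain: prefilter -> LASSO -> classifier.

    Fits on labeled training rows only; validation rows are scored without
    their labels ever entering the chain.  An empty LASSO selection is
    tolerated: the model then emits a constant score (chance-level ROC)
    and sets ``empty_selection``.
    """

    def __init__(self, kind: str = "svm", folds: int = 10, random_state: int = 0,
                 prefilter_threshold: float = 0.95):
        self.prefilter = PearsonPrefilter(threshold=prefilter_threshold)
        self.selector = LassoSelector(folds=folds, random_state=random_state)
        self.classifier = SubregionClassifier(kind=kind, folds=folds,
                                              random_state=random_state)
        self.empty_selection = False

    def fit(self, X: pd.DataFrame, y) -> "RegionModel":
        Xp = self.prefilter.fit(X, y).transform(X)
        Xs = self.selector.fit(Xp, y).transform(Xp)
        self.empty_selection = self.selector.empty_selection_
        if not self.empty_selection:
            self.classifier.fit(Xs, y)
            self.cv_scores_ = self.classifier.cv_scores_
        else:
            self.cv_scores_ = np.zeros(len(X))
        return self

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        if self.empty_selection:
            return np.zeros(len(X))
        Xs = self.selector.transform(self.prefilter.transform(X))
        return self.classifier.predict_scores(Xs)

    @property
    def selected_features(self) -> list[str]:
        return list(self.selector.selected_)
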