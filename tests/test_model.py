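"""Prefilter, LASSO selection, DT/SVM classifiers."""

import numpy as np
import pandas as pd
import pytest
from sklearn.utils.estimator_checks import check_get_params_invariance

from habitat_tex.model import (
    LassoSelector,
    PearsonPrefilter,
    RegionModel,
    SubregionClassifier,
)


def _noise_frame(rng, n=200, p=6, prefix="f"):
    return pd.DataFrame(rng.standard_normal((n, p)),
                        columns=[f"{prefix}{i}" for i in range(p)])


class TestPearsonPrefilter:
    def test_duplicate_column_removed(self, rng):
        df = _noise_frame(rng)
        df["f0_copy"] = df["f0"]
        pf = PearsonPrefilter().fit(df)
        assert "f0" in pf.kept_
        assert "f0_copy" not in pf.kept_

    def test_negated_column_removed(self, rng):
        df = _noise_frame(rng)
        df["neg"] = -df["f2"]
        pf = PearsonPrefilter().fit(df)
        assert "f2" in pf.kept_ and "neg" not in pf.kept_

    def test_independent_noise_retained(self, rng):
        df = _noise_frame(rng, n=200, p=2)
        pf = PearsonPrefilter().fit(df)
        assert abs(np.corrcoef(df.f0, df.f1)[0, 1]) < 0.95  # oracle
        assert pf.kept_ == ["f0", "f1"]

    def test_constant_column_dropped(self, rng):
        df = _noise_frame(rng)
        df["const"] = 3.0
        pf = PearsonPrefilter().fit(df)
        assert "const" not in pf.kept_
        assert ("const", None) in pf.removed_

    def test_row_permutation_invariant(self, rng):
        df = _noise_frame(rng, n=60, p=10)
        df["dup"] = df["f3"] + 1e-9 * rng.standard_normal(60)
        a = PearsonPrefilter().fit(df).kept_
        b = PearsonPrefilter().fit(df.sample(frac=1, random_state=5)).kept_
        assert a == b

    def test_transform_selects_columns(self, rng):
        df = _noise_frame(rng)
        df["dup"] = df["f1"]
        pf = PearsonPrefilter().fit(df)
        assert list(pf.transform(df).columns) == pf.kept_


class TestLassoSelector:
    def test_planted_signal_selected(self, rng):
        X = _noise_frame(rng, n=200, p=20)
        y = rng.integers(0, 2, 200)
        X["signal"] = y + 0.05 * rng.standard_normal(200)
        sel = LassoSelector(random_state=0).fit(X, y)
        assert "signal" in sel.selected_

    def test_sparse_under_null(self, rng):
        X = _noise_frame(rng, n=120, p=30)
        y = np.array([0, 1] * 60)
        sel = LassoSelector(random_state=3).fit(X, y)
        assert len(sel.selected_) <= 3

    def test_unselected_coefficients_zero(self, rng):
        X = _noise_frame(rng, n=150, p=10)
        y = rng.integers(0, 2, 150)
        X["s"] = y * 2.0 + 0.1 * rng.standard_normal(150)
        sel = LassoSelector(random_state=0).fit(X, y)
        for col in X.columns:
            if col not in sel.selected_:
                assert sel.coef_[col] == 0.0

    def test_degenerate_labels_rejected(self, rng):
        X = _noise_frame(rng, n=30)
        with pytest.raises(ValueError, match="two classes"):
            LassoSelector().fit(X, np.zeros(30))

    def test_deterministic(self, rng):
        X = _noise_frame(rng, n=100, p=15)
        y = rng.integers(0, 2, 100)
        a = LassoSelector(random_state=9).fit(X, y)
        b = LassoSelector(random_state=9).fit(X, y)
        assert a.selected_ == b.selected_ and a.C_ == b.C_


def _separable(rng, n=60):
    y = np.array([0, 1] * (n // 2))
    X = pd.DataFrame({
        "a": y * 4.0 + 0.1 * rng.standard_normal(n),
        "b": -y * 3.0 + 0.1 * rng.standard_normal(n),
    })
    return X, y


class TestSubregionClassifier:
    @pytest.mark.parametrize("kind", ["dt", "svm"])
    def test_separable_toy_perfect_cv(self, kind, rng):
        X, y = _separable(rng)
        clf = SubregionClassifier(kind=kind, folds=10, random_state=0).fit(X, y)
        assert clf.cv_auc_ == pytest.approx(1.0)
        assert (clf.predict(X) == y).all()

    @pytest.mark.parametrize("kind", ["dt", "svm"])
    def test_shuffled_labels_near_chance(self, kind):
        r = np.random.default_rng(42)
        X = _noise_frame(r, n=200, p=5)
        y = r.permutation([0, 1] * 100)
        clf = SubregionClassifier(kind=kind, folds=10, random_state=0).fit(X, y)
        from habitat_tex.evalstats import delong_components
        auc, _, _ = delong_components(clf.cv_scores_, y)
        assert 0.35 <= auc <= 0.65

    def test_fixed_seed_reproducible(self, rng):
        X, y = _separable(rng, n=40)
        a = SubregionClassifier("svm", folds=5, random_state=7).fit(X, y)
        b = SubregionClassifier("svm", folds=5, random_state=7).fit(X, y)
        assert a.best_params_ == b.best_params_
        assert np.array_equal(a.cv_scores_, b.cv_scores_)

    def test_dt_scores_are_leaf_probabilities(self, rng):
        X, y = _separable(rng, n=40)
        clf = SubregionClassifier("dt", folds=5, random_state=0).fit(X, y)
        s = clf.predict_scores(X)
        assert set(np.round(s, 6)) <= {0.0, 1.0}  # pure leaves on separable data

    def test_scores_pure_function(self, rng):
        X, y = _separable(rng, n=40)
        clf = SubregionClassifier("svm", folds=5, random_state=0).fit(X, y)
        assert np.array_equal(clf.predict_scores(X), clf.predict_scores(X))

    def test_missing_column_raises(self, rng):
        X, y = _separable(rng, n=40)
        clf = SubregionClassifier("svm", folds=5, random_state=0).fit(X, y)
        with pytest.raises(KeyError, match="missing"):
            clf.predict_scores(X.drop(columns=["b"]))

    def test_unstratifiable_fold_rejected(self, rng):
        X = _noise_frame(rng, n=12)
        y = np.array([0] * 9 + [1] * 3)
        with pytest.raises(ValueError, match="stratify"):
            SubregionClassifier("svm", folds=10).fit(X, y)

    def test_sklearn_param_contract(self):
        clf = SubregionClassifier(kind="dt", folds=3, random_state=1)
        check_get_params_invariance("SubregionClassifier", clf)
        assert clf.get_params()["kind"] == "dt"
        clf.set_params(kind="svm")
        assert clf.kind == "svm"


class TestRegionModel:
    def test_end_to_end_chain(self, rng):
        n = 80
        y = np.array([0, 1] * (n // 2))
        X = _noise_frame(rng, n=n, p=10)
        X["sig"] = y * 3.0 + 0.3 * rng.standard_normal(n)
        X["sig_dup"] = X["sig"]  # must fall to the prefilter
        rm = RegionModel(kind="svm", folds=5, random_state=0).fit(X, y)
        assert "sig_dup" not in rm.prefilter.kept_
        assert "sig" in rm.selected_features
        s = rm.predict_scores(X)
        from habitat_tex.evalstats import delong_components
        auc, _, _ = delong_components(s, y)
        assert auc > 0.95

    def test_empty_selection_emits_constant_scores(self, rng):
        rm = RegionModel(kind="svm", folds=5, random_state=0)
        rm.empty_selection = True
        scores = rm.predict_scores(_noise_frame(rng, n=10))
        assert (scores == scores[0]).all()

    def test_validation_labels_never_consulted(self, rng):
        # scoring a table works without any label column present
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = _noise_frame(rng, n=n, p=5)
        X["sig"] = y * 2.0 + 0.2 * rng.standard_normal(n)
        rm = RegionModel(kind="dt", folds=5, random_state=0).fit(X, y)
        Xv = _noise_frame(np.random.default_rng(5), n=20, p=5)
        Xv["sig"] = np.random.default_rng(6).standard_normal(20)
        assert rm.predict_scores(Xv).shape == (20,)
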