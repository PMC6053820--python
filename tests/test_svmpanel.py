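import numpy as np
import pandas as pd
import pytest

import ratiopanel as rp
from ratiopanel.exceptions import MissingFeatureError, ParameterError
from ratiopanel.svmpanel import _standardize


def make_data(n=40, informative=1, noise=1, effect=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
    cols = {}
    for i in range(informative):
        cols[f"inf{i}"] = rng.normal(0, 1, n) + effect * y
    for i in range(noise):
        cols[f"noise{i}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)]), y


class TestSvmRfeRank:
    def test_informative_beats_noise(self):
        feats, y = make_data(n=40, informative=1, noise=1, effect=3.0, seed=1)
        assert rp.svm_rfe_rank(feats, y)[0] == "inf0"

    def test_single_feature_is_rank_one(self):
        feats, y = make_data(n=20, informative=1, noise=0)
        assert rp.svm_rfe_rank(feats, y) == ["inf0"]

    def test_duplicate_features_tie_break_deterministic(self):
        feats, y = make_data(n=30, informative=1, noise=0, seed=2)
        feats = feats.copy()
        feats["a_copy"] = feats["inf0"]
        feats["b_copy"] = feats["inf0"]
        ranked = rp.svm_rfe_rank(feats, y)
        # identical columns: lexicographically larger ids eliminated first
        assert ranked == ["a_copy", "b_copy", "inf0"]

    def test_performs_n_minus_one_eliminations(self):
        feats, y = make_data(n=30, informative=2, noise=4, seed=3)
        ranked = rp.svm_rfe_rank(feats, y)
        assert sorted(ranked) == sorted(feats.columns)
        assert len(ranked) == feats.shape[1]

    def test_constant_feature_ranked_last_with_warning(self):
        feats, y = make_data(n=30, informative=1, noise=1, seed=4)
        feats["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            ranked = rp.svm_rfe_rank(feats, y)
        assert ranked[-1] == "flat"

    def test_matches_sklearn_rfe(self):
        """Cross-check against sklearn's reference RFE (same SVM, step 1)."""
        from sklearn.feature_selection import RFE
        from sklearn.svm import SVC

        feats, y = make_data(n=50, informative=3, noise=5, effect=1.5, seed=5)
        Z, _, _ = _standardize(feats.to_numpy())
        ref = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=1, step=1)
        ref.fit(Z, y)
        # standardization is per-column, so re-standardizing survivors is a
        # no-op and the two loops see identical inputs at every step
        ours = rp.svm_rfe_rank(feats, y)
        sklearn_order = [feats.columns[j] for j in np.argsort(ref.ranking_)]
        assert ours == sklearn_order


class TestCrossValidation:
    def test_stratification_arithmetic(self):
        feats, y = make_data(n=100, informative=1, noise=2, seed=6)
        from sklearn.model_selection import StratifiedKFold

        folds = list(StratifiedKFold(10, shuffle=True, random_state=0).split(feats, y))
        for _, test in folds:
            assert len(test) == 10
            assert y[test].sum() == 5

    def test_same_seed_identical_decisions(self):
        feats, y = make_data(n=40, informative=1, noise=3, seed=7)
        d1 = rp.cross_validate_panel(feats, y, k=5, seed=3)
        d2 = rp.cross_validate_panel(feats, y, k=5, seed=3)
        pd.testing.assert_series_equal(d1, d2)

    def test_every_sample_predicted_once(self):
        feats, y = make_data(n=34, informative=1, noise=1, seed=8)
        dec = rp.cross_validate_panel(feats, y, k=5, seed=0)
        assert list(dec.index) == list(feats.index)
        assert np.isfinite(dec).all()

    def test_no_leakage_fold_refit_audit(self):
        """Out-of-fold decisions must be reproducible from a classifier fit
        on the complement of each fold only."""
        from sklearn.model_selection import StratifiedKFold
        from sklearn.svm import SVC

        feats, y = make_data(n=30, informative=1, noise=2, seed=9)
        dec = rp.cross_validate_panel(feats, y, k=3, seed=5)
        X = feats.to_numpy()
        for train, test in StratifiedKFold(3, shuffle=True, random_state=5).split(X, y):
            Z, mean, scale = _standardize(X[train])
            clf = SVC(kernel="linear", C=1.0).fit(Z, y[train])
            expect = clf.decision_function((X[test] - mean) / np.where(scale == 0, 1, scale))
            np.testing.assert_allclose(dec.to_numpy()[test], expect)

    def test_separable_data_high_cv_auc(self):
        feats, y = make_data(n=60, informative=3, noise=2, effect=4.0, seed=10)
        dec = rp.cross_validate_panel(feats, y, k=10, seed=0)
        assert rp.auc(dec.to_numpy(), y) >= 0.99

    def test_k_below_two_rejected(self):
        feats, y = make_data(n=20)
        with pytest.raises(ParameterError):
            rp.cross_validate_panel(feats, y, k=1)

    def test_pure_noise_cv_auc_centers_on_half(self):
        """With only noise features the pooled CV AUC distribution is
        centred on 0.5 (no optimism, no structure)."""
        aucs = []
        for rep in range(40):
            feats, y = make_data(n=30, informative=0, noise=8, seed=100 + rep)
            dec = rp.cross_validate_panel(feats, y, k=5, seed=rep)
            aucs.append(rp.auc(dec.to_numpy(), y))
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 0.02


class TestBuildApplyPanel:
    def test_fixed_size_prefix_rule(self):
        feats, y = make_data(n=40, informative=3, noise=4, effect=2.0, seed=11)
        ranked = rp.svm_rfe_rank(feats, y)
        panel = rp.build_panel(ranked, feats, y, size=5, seed=0, k=5)
        assert panel.pair_ids == ranked[:5]

    def test_auto_size_near_best_prefix(self):
        feats, y = make_data(n=50, informative=3, noise=7, effect=2.0, seed=12)
        ranked = rp.svm_rfe_rank(feats, y)
        panel = rp.build_panel(ranked, feats, y, size="auto", seed=0, k=5)
        best = max(
            rp.auc(
                rp.cross_validate_panel(feats[ranked[:s]], y, k=5, seed=0).to_numpy(),
                y,
            )
            for s in range(1, len(ranked) + 1)
        )
        got = rp.auc(panel.cv_decision.to_numpy(), y)
        assert got >= best - 0.02

    def test_size_one_cv_auc_close_to_pair_roc_auc(self):
        feats, y = make_data(n=60, informative=1, noise=0, effect=2.0, seed=13)
        panel = rp.build_panel(["inf0"], feats, y, size=1, seed=0, k=10)
        univariate = rp.auc(feats["inf0"], y)
        cv = rp.auc(panel.cv_decision.to_numpy(), y)
        assert abs(cv - univariate) < 0.05

    def test_oversized_panel_rejected(self):
        feats, y = make_data(n=20, informative=1, noise=1)
        with pytest.raises(ParameterError):
            rp.build_panel(list(feats.columns), feats, y, size=10)

    def test_apply_identity_on_training(self):
        feats, y = make_data(n=30, informative=2, noise=2, seed=14)
        ranked = rp.svm_rfe_rank(feats, y)
        panel = rp.build_panel(ranked, feats, y, size=2, seed=0, k=5)
        d1 = rp.apply_panel(panel, feats)
        d2 = rp.apply_panel(panel, feats)
        pd.testing.assert_series_equal(d1, d2)

    def test_missing_feature_error(self):
        feats, y = make_data(n=30, informative=2, noise=1, seed=15)
        panel = rp.build_panel(["inf0", "inf1"], feats, y, size=2, seed=0, k=5)
        with pytest.raises(MissingFeatureError):
            rp.apply_panel(panel, feats.drop(columns=["inf1"]))

    def test_yaml_round_trip(self, tmp_path):
        feats, y = make_data(n=30, informative=2, noise=1, seed=16)
        panel = rp.build_panel(["inf0", "inf1"], feats, y, size=2, seed=0, k=5)
        path = tmp_path / "panel.yaml"
        rp.save_panel(panel, path)
        back = rp.load_panel(path)
        pd.testing.assert_series_equal(
            rp.apply_panel(back, feats), rp.apply_panel(panel, feats),
            check_names=False,
        )
        assert back.threshold == panel.threshold

    def test_validation_auc_tracks_training_cv(self):
        """Independent cohorts simulated from the same effects score close
        to the training CV AUC (averaged over replicates)."""
        gaps = []
        for rep in range(10):
            feats, y = make_data(n=60, informative=3, noise=3, effect=1.5,
                                 seed=200 + rep)
            vfeats, vy = make_data(n=60, informative=3, noise=3, effect=1.5,
                                   seed=700 + rep)
            ranked = rp.svm_rfe_rank(feats, y)
            panel = rp.build_panel(ranked, feats, y, size=3, seed=0, k=5)
            cv_auc = rp.auc(panel.cv_decision.to_numpy(), y)
            val_auc = rp.auc(rp.apply_panel(panel, vfeats).to_numpy(), vy)
            gaps.append(val_auc - cv_auc)
        assert abs(np.mean(gaps)) < 0.05
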