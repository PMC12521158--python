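import numpy as np
import pandas as pd
import pytest

from netsweep import (
    forward_lr_logistic,
    label_responders,
    partial_correlation,
    roc_analysis,
)
from netsweep.clinical import SeparationError, _fit_logistic


def clinical_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "hamd17_pre",
                                       "hamd17_post"])


class TestLabelResponders:
    @pytest.mark.parametrize("pre,post,expected", [
        (20, 10, True),    # exactly 50% counts as response
        (20, 11, False),   # 45%
        (18, 18, False),   # no change
        (18, 20, False),   # worsening, negative rate
    ])
    def test_boundary_and_direction(self, pre, post, expected):
        out = label_responders(clinical_frame([("s1", pre, post)]))
        assert bool(out["responder"].item()) is expected
        assert out["reduction_rate"].item() == pytest.approx(
            (pre - post) / pre)

    def test_nonpositive_pre_score_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            label_responders(clinical_frame([("s1", 0, 0)]))


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        pc = partial_correlation(x, y)
        from scipy import stats
        r, p = stats.pearsonr(x, y)
        assert pc.r_partial == pytest.approx(r, abs=1e-12)
        assert pc.p == pytest.approx(p, abs=1e-10)
        assert pc.df == 28

    def test_outcome_explained_by_covariate_gives_zero(self, rng):
        z = rng.normal(size=25)
        x = rng.normal(size=25)
        y = 2.0 * z - 1.0  # exact linear function of the covariate
        pc = partial_correlation(x, y, z[:, None])
        assert pc.r_partial == pytest.approx(0.0, abs=1e-8)

    def test_matches_closed_form_three_variable_identity(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 6.0, 5.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 7.0, 8.0])
        z = np.array([0.5, 1.5, 1.0, 3.0, 2.0, 4.0])
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expected = (r_xy - r_xz * r_yz) / np.sqrt(
            (1 - r_xz**2) * (1 - r_yz**2))
        pc = partial_correlation(x, y, z[:, None])
        assert pc.r_partial == pytest.approx(expected, abs=1e-10)
        assert pc.df == 3

    def test_rank_deficient_covariates_rejected(self, rng):
        z = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(rng.normal(size=20), rng.normal(size=20),
                                np.column_stack([z, 2 * z]))


class TestLogisticFit:
    def test_gradient_vanishes_at_convergence(self, rng):
        x = rng.normal(size=(60, 2))
        eta = 0.8 * x[:, 0] - 0.5 * x[:, 1]
        y = (rng.random(60) < 1 / (1 + np.exp(-eta))).astype(float)
        design = np.column_stack([np.ones(60), x])
        beta, _, _ = _fit_logistic(design, y)
        from scipy.special import expit
        grad = design.T @ (y - expit(design @ beta))
        assert np.abs(grad).max() < 1e-6

    def test_matches_statsmodels_mle(self, rng):
        import statsmodels.api as sm
        x = rng.normal(size=(80, 2))
        eta = 1.0 * x[:, 0]
        y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(float)
        design = np.column_stack([np.ones(80), x])
        beta, _, ll = _fit_logistic(design, y)
        ref = sm.Logit(y, design).fit(disp=0)
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)
        assert ll == pytest.approx(ref.llf, abs=1e-6)

    def test_perfect_separation_raises_naming_feature(self):
        x = np.linspace(-2, 2, 20)
        y = (x > 0).astype(float)
        design = np.column_stack([np.ones(20), x])
        with pytest.raises(SeparationError, match="separation"):
            _fit_logistic(design, y, feature_names=["sep_feat"])


class TestForwardLrLogistic:
    def test_balanced_fixture_has_no_association(self):
        features = pd.DataFrame({"f": [1.0, 0.0, 1.0, 0.0]})
        labels = np.array([1, 1, 0, 0])
        model = forward_lr_logistic(features, labels)
        assert model.selected_predictors == []
        assert model.selection_trace == []

    def test_planted_predictor_enters_first(self, rng):
        n = 69
        labels = np.zeros(n, dtype=bool)
        labels[:37] = True
        x = rng.normal(size=(n, 5))
        x[labels, 0] += 2.0
        features = pd.DataFrame(x, columns=[f"f{i}" for i in range(5)])
        model = forward_lr_logistic(features, labels)
        assert model.selection_trace[0]["variable"] == "f0"
        assert "f0" in model.selected_predictors
        or_, lo, hi = model.odds_ratios["f0"]
        assert lo < or_ < hi
        assert or_ > 1.0

    def test_feature_column_order_does_not_change_selection(self, rng):
        n = 60
        labels = np.zeros(n, dtype=bool)
        labels[:30] = True
        x = rng.normal(size=(n, 4))
        x[labels, 2] += 1.5
        features = pd.DataFrame(x, columns=list("abcd"))
        m1 = forward_lr_logistic(features, labels)
        m2 = forward_lr_logistic(features[list("dcba")], labels)
        assert set(m1.selected_predictors) == set(m2.selected_predictors)
        for k in m1.selected_predictors:
            assert m1.coefficients[k] == pytest.approx(
                m2.coefficients[k], rel=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="per class"):
            forward_lr_logistic(pd.DataFrame({"f": [1.0, 2.0, 3.0]}),
                                np.array([1, 1, 1]))


class TestRocAnalysis:
    def test_perfect_separation(self):
        roc = roc_analysis(np.array([0.9, 0.8, 0.2, 0.1]),
                           np.array([1, 1, 0, 0]))
        assert roc.auc == pytest.approx(1.0)
        assert roc.operating_point == (1.0, 1.0)

    def test_constant_scores_fall_back_to_chance(self):
        roc = roc_analysis(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0]))
        assert roc.auc == pytest.approx(0.5)

    def test_concordant_pair_counting_example(self):
        roc = roc_analysis(np.array([0.1, 0.4, 0.35, 0.8]),
                           np.array([0, 0, 1, 1]))
        assert roc.auc == pytest.approx(0.75)

    def test_flipping_labels_mirrors_auc(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        a1 = roc_analysis(scores, labels).auc
        a2 = roc_analysis(scores, ~labels).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(
            roc_auc_score(labels.astype(int), scores), abs=1e-10)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_analysis(np.array([0.1, 0.9]), np.array([1, 1]))
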