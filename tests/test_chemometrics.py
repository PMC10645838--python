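"""Pareto scaling, PCA, OPLS-DA validation statistics, S-plot selection and
the Rf -> DP calibration."""
import numpy as np
import pandas as pd
import pytest

from fructans.chemometrics import (
    OplsDa,
    pareto_scale,
    pca,
    rf_to_dp,
    select_discriminant_bands,
    stratified_folds,
)
from fructans.io import band_matrix
from fructans.simulate import HptlcSimParams, simulate_hptlc


@pytest.fixture(scope="module")
def separable():
    """Two-cluster band table with the default planted age effects."""
    table = simulate_hptlc(HptlcSimParams(seed=11))
    x, labels = band_matrix(table)
    return pareto_scale(x), labels


class TestParetoScaling:
    def test_definition_on_random_matrix(self, rng):
        x = pd.DataFrame(rng.normal(10, 3, size=(20, 5)))
        scaled = pareto_scale(x)
        # scaled column variance equals the original column's sd
        assert np.allclose(scaled.var(axis=0, ddof=1), x.std(axis=0, ddof=1))
        assert np.allclose(scaled.mean(axis=0), 0.0)

    def test_known_sd_divisor(self):
        col = np.array([1.0, 5.0, 9.0, 13.0])  # sd 16/sqrt(... ) -> check directly
        x = pd.DataFrame({"a": col, "b": [1.0, 2.0, 3.0, 4.0]})
        scaled = pareto_scale(x)
        sd = col.std(ddof=1)
        assert np.allclose(scaled["a"], (col - col.mean()) / np.sqrt(sd))

    def test_constant_column_dropped_with_warning(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled = pareto_scale(x)
        assert list(scaled.columns) == ["a"]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pareto_scale(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))


class TestPca:
    def test_rank_one_matrix_loads_on_single_component(self, rng):
        u = rng.normal(size=12)
        v = rng.normal(size=6)
        x = pd.DataFrame(np.outer(u, v))
        res = pca(x, 1)
        assert res.r2x[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 8)))
        res = pca(x, 3)
        xc = x - x.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(xc.T)))[::-1]
        assert np.allclose(res.r2x, eig[:3] / eig.sum())
        assert np.all(np.diff(res.r2x_cum) >= 0)

    def test_duplicated_samples_coincide(self, rng):
        base = rng.normal(size=(6, 4))
        x = pd.DataFrame(np.vstack([base, base[0]]))
        res = pca(x, 2)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[-1])

    def test_components_beyond_rank_rejected(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=5)
        with pytest.raises(ValueError, match="rank"):
            pca(pd.DataFrame(np.outer(u, v)), 3)

    def test_dominant_direction_concentrates_in_pc1(self, rng):
        # planted one strong direction; Pareto scaling must keep it dominant
        strong = rng.normal(size=20)
        x = pd.DataFrame(
            np.outer(strong, np.ones(6)) * 50 + rng.normal(size=(20, 6))
        )
        scaled = pareto_scale(x)
        res = pca(scaled, 2)
        xc = np.asarray(scaled - scaled.mean(axis=0))
        eig = np.sort(np.linalg.eigvalsh(np.cov(xc.T)))[::-1]
        assert res.r2x[0] >= eig[0] / eig.sum() - 1e-9


class TestFolds:
    def test_stratified_and_deterministic(self):
        y = np.array([1.0] * 6 + [-1.0] * 6)
        f1 = stratified_folds(y, 7, seed=3)
        f2 = stratified_folds(y, 7, seed=3)
        assert np.array_equal(f1, f2)
        assert set(f1) == set(range(7))
        # every training split keeps both classes
        for k in range(7):
            train = y[f1 != k]
            assert (train == 1).any() and (train == -1).any()


class TestOplsDa:
    def test_separable_classes_validate(self, separable):
        scaled, labels = separable
        res = OplsDa(scaled, labels, positive_class="old").fit(seed=11)
        assert res.q2 > 0.9
        assert res.q2 <= res.r2y + 1e-9

    def test_label_swap_flips_scores_only(self, separable):
        scaled, labels = separable
        a = OplsDa(scaled, labels, positive_class="old").fit(seed=5)
        b = OplsDa(scaled, labels, positive_class="young").fit(seed=5)
        assert a.q2 == pytest.approx(b.q2)
        assert np.allclose(a.fitted["t"], -b.fitted["t"])

    def test_noise_labels_average_nonpositive_q2(self, rng):
        q2s = []
        for i in range(10):
            x = pd.DataFrame(rng.normal(size=(12, 10)))
            labels = ["a"] * 6 + ["b"] * 6
            q2s.append(OplsDa(x, labels).fit(seed=i).q2)
        assert np.mean(q2s) <= 0

    def test_predictive_score_beats_plain_pls_on_training_correlation(
        self, separable
    ):
        from sklearn.cross_decomposition import PLSRegression

        scaled, labels = separable
        res = OplsDa(scaled, labels, positive_class="old").fit(seed=0)
        y = res.model.y
        pls = PLSRegression(n_components=1, scale=False).fit(scaled, y)
        t_pls = pls.x_scores_[:, 0]
        r_opls = abs(np.corrcoef(res.fitted["t"], y)[0, 1])
        r_pls = abs(np.corrcoef(t_pls, y)[0, 1])
        assert r_opls >= r_pls - 1e-9

    def test_single_class_rejected(self, separable):
        scaled, _ = separable
        with pytest.raises(ValueError, match="two classes"):
            OplsDa(scaled, ["same"] * len(scaled))


class TestValidationStatistics:
    def test_permutation_p_reproducible_and_small_for_signal(self, separable):
        scaled, labels = separable
        res = OplsDa(scaled, labels, positive_class="old").fit(seed=11)
        p1 = res.permutation_test(n_perm=100, seed=4)
        res2 = OplsDa(scaled, labels, positive_class="old").fit(seed=11)
        p2 = res2.permutation_test(n_perm=100, seed=4)
        assert p1 == p2
        assert p1 <= 0.02  # floor is 1/101 for 100 permutations

    def test_identical_class_profiles_give_large_p(self, rng):
        base = rng.normal(size=(1, 8))
        x = pd.DataFrame(
            np.repeat(base, 12, axis=0) + rng.normal(0, 1, size=(12, 8))
        )
        labels = ["a"] * 6 + ["b"] * 6
        res = OplsDa(x, labels).fit(seed=2)
        assert res.permutation_test(n_perm=50, seed=2) >= 0.2

    def test_cv_anova_orders_with_signal(self, separable, rng):
        scaled, labels = separable
        strong = OplsDa(scaled, labels, positive_class="old").fit(seed=1)
        p_strong = strong.cv_anova()
        weak = OplsDa(
            pd.DataFrame(rng.normal(size=(12, len(scaled.columns)))),
            list(labels),
        ).fit(seed=1)
        p_weak = weak.cv_anova()
        assert p_strong < 0.05 < p_weak

    def test_invalid_n_perm_rejected(self, separable):
        scaled, labels = separable
        res = OplsDa(scaled, labels).fit(seed=0)
        with pytest.raises(ValueError):
            res.permutation_test(n_perm=0)


class TestSplotSelection:
    def test_planted_bands_selected_exactly(self, separable):
        scaled, labels = separable
        res = OplsDa(scaled, labels, positive_class="old").fit(seed=11)
        sel = select_discriminant_bands(res, corr_thresh=0.8)
        old_bands = set(sel.index[sel["direction"] == "positive"])
        planted = {c for c in scaled.columns if float(c[3:]) <= 0.163}
        assert old_bands == planted
        young_bands = set(sel.index[sel["direction"] == "negative"])
        assert young_bands == {"rf_0.57", "rf_0.51", "rf_0.4"}

    def test_zero_thresholds_select_everything(self, separable):
        scaled, labels = separable
        res = OplsDa(scaled, labels).fit(seed=0)
        sel = select_discriminant_bands(res, cov_thresh=0.0, corr_thresh=0.0)
        assert len(sel) == len(scaled.columns)

    def test_unreachable_thresholds_select_nothing(self, separable):
        scaled, labels = separable
        res = OplsDa(scaled, labels).fit(seed=0)
        assert select_discriminant_bands(res, corr_thresh=1.1).empty


class TestRfCalibration:
    @pytest.mark.parametrize("rf,dp", [(0.57, 1), (0.51, 2), (0.40, 3), (0.09, 11)])
    def test_anchor_points_exact(self, rf, dp):
        assert rf_to_dp(rf) == dp

    def test_monotone_decreasing(self):
        grid = np.linspace(0.09, 0.95, 200)
        dps = [rf_to_dp(rf) for rf in grid]
        assert all(a >= b for a, b in zip(dps, dps[1:]))

    def test_application_point_below_last_anchor(self):
        from fructans.chemometrics import APPLICATION_POINT, describe_rf

        assert rf_to_dp(0.05) is None
        assert describe_rf(0.05) == APPLICATION_POINT

    @pytest.mark.parametrize("rf", [0.0, 1.0, -0.2, 1.7])
    def test_out_of_range_rf_rejected(self, rf):
        with pytest.raises(ValueError):
            rf_to_dp(rf)
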