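"""OPLS-DA fitting, VIP, p-values and marker screening."""

import numpy as np
import pandas as pd
import pytest

from npannotate import synthetic
from npannotate.chemometrics import (
    feature_pvalues,
    opls_da_fit,
    screen_markers,
    splot_coordinates,
    vip_scores,
)


def _cohort(seed=1, **kw):
    return synthetic.simulate_cohort(synthetic.CohortConfig(seed=seed, **kw))


class TestOplsFit:
    def test_separating_feature_carries_largest_weight(self):
        rng = np.random.default_rng(0)
        n = 10
        X = pd.DataFrame(rng.lognormal(10, 0.3, size=(2 * n, 5)),
                         columns=[f"f{i}" for i in range(5)])
        labels = np.array(["treated"] * n + ["blank"] * n)
        X.loc[labels == "treated", "f2"] *= 8.0
        model = opls_da_fit(X, labels)
        weights = pd.Series(np.abs(model.w), index=np.array(model.feature_names)[model.kept])
        assert weights.idxmax() == "f2"

    def test_orthogonal_scores_uncorrelated_with_y(self):
        X, labels, _ = _cohort(n_features=50)
        model = opls_da_fit(X, labels)
        yc = model.y - model.y.mean()
        for j in range(model.t_orth.shape[1]):
            assert abs(np.corrcoef(model.t_orth[:, j], yc)[0, 1]) < 1e-8

    def test_predictive_weight_unit_norm(self):
        X, labels, _ = _cohort(n_features=50)
        model = opls_da_fit(X, labels)
        assert np.linalg.norm(model.w) == pytest.approx(1.0)

    def test_orthogonal_variation_does_not_degrade_r2y(self):
        rng = np.random.default_rng(3)
        n, k = 10, 30
        base = rng.normal(0, 0.1, size=(2 * n, k))
        y_dir = np.concatenate([np.full(n, 0.5), np.full(n, -0.5)])
        signal = np.zeros((2 * n, k))
        signal[:, 0] = y_dir * 2
        clean = pd.DataFrame(10 ** (5 + base + signal))
        labels = np.array(["treated"] * n + ["blank"] * n)
        # inject y-orthogonal structured variation
        t_orth = rng.normal(size=2 * n)
        t_orth -= t_orth @ y_dir / (y_dir @ y_dir) * y_dir
        noisy = pd.DataFrame(10 ** (5 + base + signal + np.outer(t_orth, rng.uniform(0.2, 0.5, k))))
        m_clean = opls_da_fit(clean, labels)
        m_noisy = opls_da_fit(noisy, labels, n_orthogonal=1)
        assert m_noisy.r2y == pytest.approx(m_clean.r2y, abs=0.05)

    def test_permuted_labels_collapse_r2y_when_samples_exceed_features(self):
        rng = np.random.default_rng(4)
        n = 40
        X = pd.DataFrame(rng.lognormal(10, 0.3, size=(2 * n, 5)))
        labels = np.array(["treated"] * n + ["blank"] * n)
        X.iloc[:n, 0] *= 6.0
        informative = opls_da_fit(X, labels).r2y
        permuted = opls_da_fit(X, rng.permutation(labels)).r2y
        assert permuted < 0.2 < informative

    def test_deterministic(self):
        X, labels, _ = _cohort(n_features=40)
        m1, m2 = opls_da_fit(X, labels), opls_da_fit(X, labels)
        assert np.array_equal(m1.w, m2.w) and np.array_equal(m1.t, m2.t)

    def test_small_group_rejected(self):
        X = pd.DataFrame(np.ones((3, 4)) + np.arange(12).reshape(3, 4))
        with pytest.raises(ValueError):
            opls_da_fit(X, np.array(["treated", "treated", "blank"]))

    def test_constant_feature_dropped(self):
        X, labels, _ = _cohort(n_features=20)
        X["const"] = 100.0
        model = opls_da_fit(X, labels)
        assert model.kept.sum() == 20
        assert vip_scores(model)["const"] == 0.0


class TestVip:
    def test_mean_square_is_one(self):
        X, labels, _ = _cohort(n_features=80)
        vip = vip_scores(opls_da_fit(X, labels))
        assert (vip ** 2).mean() == pytest.approx(1.0)

    def test_single_informative_feature_dominates(self):
        # large n keeps null correlations with y near zero, so the closed
        # form VIP ~ sqrt(K) for the lone informative feature applies
        rng = np.random.default_rng(7)
        n, k = 200, 50
        X = pd.DataFrame(rng.lognormal(10, 0.05, size=(2 * n, k)),
                         columns=[f"f{i}" for i in range(k)])
        labels = np.array(["treated"] * n + ["blank"] * n)
        X.loc[labels == "treated", "f0"] *= 20.0
        vip = vip_scores(opls_da_fit(X, labels))
        assert vip["f0"] > 0.8 * np.sqrt(k)
        assert vip.drop("f0").max() < 2.0

    def test_equal_weights_give_unit_vip(self):
        rng = np.random.default_rng(8)
        n, k = 20, 4
        shift = np.concatenate([np.ones(n), -np.ones(n)])
        X = pd.DataFrame(10 ** (5 + 0.2 * np.tile(shift[:, None], (1, k))
                                + rng.normal(0, 1e-6, size=(2 * n, k))))
        labels = np.array(["treated"] * n + ["blank"] * n)
        vip = vip_scores(opls_da_fit(X, labels))
        assert vip.to_numpy() == pytest.approx(np.ones(k), abs=1e-3)


class TestPvalues:
    def test_identical_group_means_large_p(self):
        X, labels, _ = _cohort(seed=3, n_markers=0, n_features=100)
        p = feature_pvalues(X, labels)
        assert p.median() > 0.2

    def test_planted_shift_small_p(self):
        rng = np.random.default_rng(9)
        n = 10
        X = pd.DataFrame(rng.lognormal(10, 0.3, size=(2 * n, 3)), columns=list("abc"))
        labels = np.array(["treated"] * n + ["blank"] * n)
        X.loc[labels == "treated", "b"] *= 8.0
        p = feature_pvalues(X, labels)
        assert p["b"] < 1e-3 < p["a"]

    def test_single_sample_group_rejected(self):
        X = pd.DataFrame(np.arange(8.0).reshape(4, 2))
        with pytest.raises(ValueError):
            feature_pvalues(X, np.array(["treated", "blank", "blank", "blank"]))

    def test_zero_variance_feature_p_one(self):
        X, labels, _ = _cohort(n_features=10)
        X["flat"] = 5.0
        p = feature_pvalues(X, labels)
        assert p["flat"] == 1.0


class TestScreen:
    def test_recovers_planted_markers(self):
        X, labels, manifest = _cohort(seed=2)
        results = screen_markers(X, labels)
        markers = set(manifest[manifest.is_marker].feature_id)
        passed = {r.feature_id for r in results if r.passes}
        assert len(markers & passed) >= 9

    def test_null_false_positive_rate_near_nominal_level(self):
        """Nulls pass the conjunction at about the t-test's 5% level: the
        VIP >= 1.5 gate is looser than p < 0.05 under these conditions."""
        X, labels, manifest = _cohort(seed=2)
        results = screen_markers(X, labels)
        nulls = set(manifest[~manifest.is_marker].feature_id)
        fp = sum(1 for r in results if r.passes and r.feature_id in nulls)
        assert fp / len(nulls) < 0.08

    def test_global_null_pass_rate_five_percent(self):
        rates = []
        for seed in range(3):
            X, labels, _ = _cohort(seed=seed, n_markers=0)
            results = screen_markers(X, labels)
            rates.append(np.mean([r.passes for r in results]))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_trivial_thresholds_pass_everything(self):
        X, labels, _ = _cohort(n_features=30)
        results = screen_markers(X, labels, vip_min=0.0, p_max=1.1)
        assert all(r.passes for r in results)

    def test_sorted_by_vip_descending(self):
        X, labels, _ = _cohort(n_features=30)
        vips = [r.vip for r in screen_markers(X, labels)]
        assert vips == sorted(vips, reverse=True)

    def test_direction_reflects_group_shift(self):
        X, labels, manifest = _cohort(seed=5)
        results = {r.feature_id: r for r in screen_markers(X, labels)}
        for fid in manifest[manifest.is_marker].feature_id:
            assert results[fid].direction == "up"


class TestSplot:
    def test_pcorr_bounded(self):
        X, labels, _ = _cohort(n_features=60)
        sp = splot_coordinates(opls_da_fit(X, labels))
        assert (sp.pcorr.abs() <= 1 + 1e-12).all()

    def test_top_marker_has_top_pcorr_and_positive_sign(self):
        rng = np.random.default_rng(11)
        n, k = 10, 40
        X = pd.DataFrame(rng.lognormal(10, 0.2, size=(2 * n, k)),
                         columns=[f"f{i}" for i in range(k)])
        labels = np.array(["treated"] * n + ["blank"] * n)
        X.loc[labels == "treated", "f5"] *= 10.0
        model = opls_da_fit(X, labels)
        sp = splot_coordinates(model)
        assert sp.pcorr.abs().idxmax() == "f5"
        # predictive score is oriented with y, so an up-regulated marker
        # correlates positively
        t_sign = np.corrcoef(model.t, model.y)[0, 1]
        assert np.sign(sp.pcorr["f5"]) == np.sign(t_sign)
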