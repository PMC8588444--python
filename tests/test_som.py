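import numpy as np
import pytest

from phasesom.som import (
    SOMModel,
    SOMSchedule,
    ThresholdModel,
    activation_map,
    band_relevance,
    bmu,
    bmus,
    classify,
    fit_threshold,
    init_som_pca,
    kl_divergence,
    quantization_errors,
    symmetrized_kl,
    train_som,
)


@pytest.fixture
def cloud(rng):
    return rng.standard_normal((40, 5)) @ np.diag([3.0, 2.0, 0.5, 0.2, 0.1])


class TestPcaInit:
    def test_line_data_stays_on_line(self, rng):
        direction = np.array([1.0, 2.0, -1.0])
        ts = rng.standard_normal(30)
        X = np.outer(ts, direction) + np.array([5.0, 0.0, 1.0])
        model = init_som_pca(X, (4, 3))
        # residual of each prototype to the line through the mean
        d = direction / np.linalg.norm(direction)
        rel = model.prototypes - X.mean(axis=0)
        residual = rel - np.outer(rel @ d, d)
        assert np.abs(residual).max() < 1e-8

    def test_deterministic(self, cloud):
        a = init_som_pca(cloud, (3, 3))
        b = init_som_pca(cloud, (3, 3))
        np.testing.assert_array_equal(a.prototypes, b.prototypes)

    def test_single_unit_at_mean(self, cloud):
        model = init_som_pca(cloud, (1, 1))
        np.testing.assert_allclose(model.prototypes[0], cloud.mean(axis=0), atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            init_som_pca(np.ones((1, 3)), (2, 2))


class TestTraining:
    def test_single_point_single_unit_converges(self):
        x = np.array([[2.0, -1.0, 0.5]])
        model = SOMModel(grid=(1, 1), prototypes=np.zeros((1, 3)))
        trained = train_som(model, x, SOMSchedule(n_iter=500, seed=0))
        assert np.linalg.norm(trained.prototypes[0] - x[0]) < 1e-3
        qs = quantization_errors(trained, x)
        assert qs.qe[0] < 1e-3

    def test_two_clusters_two_units(self, rng):
        a = rng.standard_normal((100, 2)) * 0.5 + np.array([0.0, 0.0])
        b = rng.standard_normal((100, 2)) * 0.5 + np.array([10.0, 0.0])
        X = np.vstack([a, b])
        model = init_som_pca(X, (2, 1))
        trained = train_som(model, X, SOMSchedule(n_iter=20_000, seed=1, sigma_end=0.2))
        centroids = np.array([a.mean(axis=0), b.mean(axis=0)])
        # each prototype near a distinct centroid, within 0.1 cluster radius
        radius = 3 * 0.5
        d = np.linalg.norm(trained.prototypes[:, None, :] - centroids[None], axis=2)
        assignment = d.argmin(axis=1)
        assert set(assignment) == {0, 1}
        assert d.min(axis=1).max() < 0.1 * radius

    def test_training_reduces_mean_qe(self, cloud):
        model = init_som_pca(cloud, (3, 3))
        before = quantization_errors(model, cloud).qe.mean()
        trained = train_som(model, cloud)
        after = quantization_errors(trained, cloud).qe.mean()
        assert after <= before

    def test_seeded_training_bit_reproducible(self, cloud):
        model = init_som_pca(cloud, (3, 3))
        a = train_som(model, cloud, SOMSchedule(n_iter=2000, seed=42))
        b = train_som(model, cloud, SOMSchedule(n_iter=2000, seed=42))
        np.testing.assert_array_equal(a.prototypes, b.prototypes)

    def test_dimension_mismatch_rejected(self, cloud):
        model = init_som_pca(cloud, (2, 2))
        with pytest.raises(ValueError):
            train_som(model, cloud[:, :3])


class TestBmu:
    def test_sample_equal_to_prototype(self, cloud):
        model = init_som_pca(cloud, (3, 3))
        k = 5
        idx, dist = bmu(model, model.prototypes[k])
        assert idx == k and dist == 0.0

    def test_tie_breaks_to_lowest_index(self):
        protos = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])
        model = SOMModel(grid=(3, 1), prototypes=protos)
        idx, _ = bmu(model, np.array([0.0, 0.0]))
        assert idx == 0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(20):
            protos = rng.standard_normal((12, 4))
            model = SOMModel(grid=(3, 4), prototypes=protos)
            x = rng.standard_normal(4)
            idx, dist = bmu(model, x)
            brute = [np.linalg.norm(p - x) for p in protos]
            assert idx == int(np.argmin(brute))
            assert dist == pytest.approx(min(brute), abs=1e-12)

    def test_vectorized_agrees_with_scalar(self, rng, cloud):
        model = init_som_pca(cloud, (3, 3))
        idx, dist = bmus(model, cloud)
        for n in range(len(cloud)):
            i, d = bmu(model, cloud[n])
            assert idx[n] == i and dist[n] == pytest.approx(d, abs=1e-10)


class TestQuantizationErrors:
    def test_samples_equal_prototypes_give_zero(self, cloud):
        model = init_som_pca(cloud, (3, 3))
        qs = quantization_errors(model, model.prototypes)
        np.testing.assert_allclose(qs.qe, 0.0, atol=1e-9)

    def test_known_distance(self):
        model = SOMModel(grid=(1, 1), prototypes=np.array([[0.0, 0.0]]))
        qs = quantization_errors(model, np.array([[0.0, 2.0]]))
        assert qs.qe[0] == pytest.approx(2.0)
        assert qs.receptive_field_means()[0] == pytest.approx(2.0)

    def test_receptive_fields_partition_samples(self, rng, cloud):
        model = train_som(init_som_pca(cloud, (3, 3)), cloud)
        qs = quantization_errors(model, cloud)
        counts = np.bincount(qs.bmu_index, minlength=model.n_units)
        assert counts.sum() == len(cloud)  # every sample in exactly one field

    def test_empty_sample_set_rejected(self, cloud):
        model = init_som_pca(cloud, (2, 2))
        with pytest.raises(ValueError):
            quantization_errors(model, np.empty((0, 5)))


class TestActivationMap:
    def test_prototype_samples_give_zero_map(self, cloud):
        model = init_som_pca(cloud, (3, 3))
        amap = activation_map(model, model.prototypes)
        np.testing.assert_allclose(amap, 0.0, atol=1e-9)

    def test_empty_units_are_nan_not_zero(self):
        protos = np.array([[0.0], [10.0]])
        model = SOMModel(grid=(2, 1), prototypes=protos)
        amap = activation_map(model, np.array([[0.5]]))
        assert amap.shape == (2, 1)
        assert amap[0, 0] == pytest.approx(0.5)
        assert np.isnan(amap[1, 0])


class TestBandRelevance:
    def test_identical_distributions_have_zero_divergence(self):
        p = np.array([0.25, 0.5, 0.25])
        assert symmetrized_kl(p, p) == 0.0

    def test_hand_computed_two_bin_value(self):
        # D(P||Q) = .5 ln(.5/.9) + .5 ln(.5/.1) = 0.510826
        # D(Q||P) = .9 ln(.9/.5) + .1 ln(.1/.5) = 0.368064
        p = np.array([0.5, 0.5])
        q = np.array([0.9, 0.1])
        assert kl_divergence(p, q) == pytest.approx(0.5108256238, abs=1e-9)
        assert kl_divergence(q, p) == pytest.approx(0.3680642071, abs=1e-9)
        assert symmetrized_kl(p, q) == pytest.approx(0.4394449155, abs=1e-6)

    def test_symmetry(self, rng):
        a = rng.normal(1.0, 0.2, 300)
        b = rng.normal(1.6, 0.3, 200)
        assert band_relevance(a, b) == pytest.approx(band_relevance(b, a))

    def test_separated_samples_diverge_more_than_identical(self, rng):
        a = rng.normal(1.0, 0.2, 400)
        b = rng.normal(2.0, 0.2, 400)
        c = rng.normal(1.0, 0.2, 400)
        assert band_relevance(a, b) > band_relevance(a, c)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            band_relevance(np.ones(10), np.ones(10))


class TestThreshold:
    def test_symmetric_classes_cross_at_midpoint(self, rng):
        dev = rng.normal(0.0, 0.3, 200)
        qe0 = 1.0 + dev
        qe1 = 3.0 + dev  # identical deviations: equal sample variances
        qe = np.concatenate([qe0, qe1])
        labels = np.r_[np.zeros(200, int), np.ones(200, int)]
        tm = fit_threshold(qe, labels)
        assert tm.tau == pytest.approx((qe0.mean() + qe1.mean()) / 2, abs=1e-9)

    def test_posteriors_sum_to_one(self, rng):
        qe = np.concatenate([rng.normal(1, 0.2, 50), rng.normal(2, 0.4, 30)])
        labels = np.r_[np.zeros(50, int), np.ones(30, int)]
        tm = fit_threshold(qe, labels)
        xs = np.linspace(0, 3, 50)
        lc, ld = tm._log_joint(xs)
        post_dd = tm.posterior_dd(xs)
        post_cn = np.exp(lc - np.logaddexp(lc, ld))
        np.testing.assert_allclose(post_dd + post_cn, 1.0, atol=1e-12)

    def test_control_mean_classified_normal(self, rng):
        qe = np.concatenate([rng.normal(1, 0.2, 100), rng.normal(2.5, 0.3, 50)])
        labels = np.r_[np.zeros(100, int), np.ones(50, int)]
        tm = fit_threshold(qe, labels)
        label, post = classify(tm, tm.mean_cn)
        assert label == "control" and post < 0.5

    def test_zero_variance_class_rejected(self):
        qe = np.r_[np.ones(5), np.full(5, 2.0)]
        labels = np.r_[np.zeros(5, int), np.ones(5, int)]
        with pytest.raises(ValueError, match="variance"):
            fit_threshold(qe, labels)

    def test_recovers_analytic_crossing(self):
        """Fitted tau within 5% of the true-parameter posterior crossing."""
        from scipy.optimize import brentq
        from scipy.stats import norm

        m0, s0, m1, s1 = 1.0, 0.2, 2.0, 0.5
        rng = np.random.default_rng(77)
        qe = np.concatenate([rng.normal(m0, s0, 500), rng.normal(m1, s1, 500)])
        labels = np.r_[np.zeros(500, int), np.ones(500, int)]
        tm = fit_threshold(qe, labels)
        g = lambda x: norm.logpdf(x, m0, s0) - norm.logpdf(x, m1, s1)
        true_tau = brentq(g, m0, m1)
        assert abs(tm.tau - true_tau) / true_tau < 0.05


class TestSerialization:
    def test_save_load_round_trip(self, cloud, tmp_path):
        from phasesom.som import load_model, save_model

        model = train_som(init_som_pca(cloud, (3, 3)), cloud,
                          SOMSchedule(n_iter=1000, seed=2))
        save_model(model, tmp_path / "som")
        back = load_model(tmp_path / "som")
        np.testing.assert_array_equal(back.prototypes, model.prototypes)
        assert back.grid == model.grid
        assert back.trained and back.schedule.seed == 2


class TestClassify:
    def make_tm(self):
        return ThresholdModel(
            mean_cn=1.0, sd_cn=0.2, mean_dd=2.0, sd_dd=0.2,
            prior_cn=0.5, prior_dd=0.5, tau=1.5,
        )

    def test_boundary_counts_as_normal(self):
        tm = self.make_tm()
        assert classify(tm, tm.tau)[0] == "control"

    def test_extreme_qe_saturates_posterior(self):
        tm = self.make_tm()
        label, post = classify(tm, 50.0)
        assert label == "case" and post == pytest.approx(1.0, abs=1e-12)

    def test_label_matches_posterior_half_rule(self, rng):
        tm = self.make_tm()
        for qe in rng.uniform(0.5, 2.5, 100):
            label, post = classify(tm, qe)
            assert (label == "case") == (post > 0.5) or post == pytest.approx(0.5)

    def test_nonfinite_qe_rejected(self):
        with pytest.raises(ValueError):
            classify(self.make_tm(), np.nan)
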