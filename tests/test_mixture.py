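import numpy as np
import pytest
from scipy.stats import multivariate_normal

import multiseg as ms
from multiseg.mixture import _estep, _poly_basis, _prior_matrix
from conftest import make_volume


def naive_responsibilities(X, prior, model):
    """Independent Bayes-rule oracle over all class/component densities."""
    cols = []
    for ci, comps in enumerate(model.components):
        for c in comps:
            pdf = multivariate_normal(mean=c.mean, cov=c.covariance).pdf(X)
            cols.append(prior[:, ci] * c.weight * np.atleast_1d(pdf))
    dens = np.stack(cols, axis=1)
    return dens / dens.sum(axis=1, keepdims=True)


class TestInit:
    def test_constant_image_single_class(self):
        stack = ms.stack_channels([make_volume(np.full((5, 5, 5), 5.0))], ["t1w"])
        model = ms.init_model(stack, [ms.ClassSpec("GM", 1)], seed=0)
        comp = model.components[0][0]
        assert comp.mean[0] == pytest.approx(5.0)
        assert comp.covariance[0, 0] > 0  # regularization floor applied

    def test_disjoint_prior_supports(self):
        data = np.zeros((6, 6, 6))
        data[3:] = 10.0
        stack = ms.stack_channels([make_volume(data)], ["t1w"])
        p0 = np.zeros((6, 6, 6)); p0[:3] = 1.0
        priors = [make_volume(p0), make_volume(1.0 - p0)]
        model = ms.init_model(
            stack, [ms.ClassSpec("A", 1), ms.ClassSpec("B", 1)],
            priors=priors, seed=0,
        )
        means = [float(c[0].mean[0]) for c in model.components]
        assert abs(means[0] - 0.0) < 0.5 and abs(means[1] - 10.0) < 0.5

    def test_deterministic_given_seed(self, two_cluster_stack):
        specs = [ms.ClassSpec("A", 1), ms.ClassSpec("B", 1)]
        a = ms.init_model(two_cluster_stack, specs, seed=9)
        b = ms.init_model(two_cluster_stack, specs, seed=9)
        assert a.to_json() == b.to_json()

    def test_too_many_components(self):
        stack = ms.stack_channels([make_volume(np.full((4, 4, 4), 1.0))], ["t1w"])
        with pytest.raises(ValueError, match="distinct"):
            ms.init_model(stack, [ms.ClassSpec("A", 3)], seed=0)

    def test_bad_priors_rejected(self, two_cluster_stack):
        half = make_volume(np.full((10, 10, 10), 0.4))
        with pytest.raises(ValueError, match="sum to 1"):
            ms.init_model(
                two_cluster_stack,
                [ms.ClassSpec("A", 1), ms.ClassSpec("B", 1)],
                priors=[half, half], seed=0,
            )


class TestEMFit:
    def test_single_gaussian_matches_sample_moments(self, rng):
        data = rng.normal(7.0, 2.0, 1000)
        stack = ms.stack_channels([make_volume(data.reshape(10, 10, 10))], ["t1w"])
        model, maps, trace = ms.segment(stack, [ms.ClassSpec("ALL", 1)], seed=0)
        comp = model.components[0][0]
        assert comp.mean[0] == pytest.approx(data.mean(), abs=1e-6)
        assert comp.covariance[0, 0] == pytest.approx(data.var(), rel=1e-4)

    def test_two_class_1d_recovery(self, two_cluster_stack):
        specs = [ms.ClassSpec("A", 1), ms.ClassSpec("B", 1)]
        model, maps, trace = ms.segment(two_cluster_stack, specs, seed=7)
        means = sorted(float(c[0].mean[0]) for c in model.components)
        assert abs(means[0] - 0.0) < 0.1
        assert abs(means[1] - 10.0) < 0.1
        np.testing.assert_allclose(model.stationary_priors, [0.5, 0.5], atol=0.02)
        assert trace.is_monotone()

    def test_max_iter_zero_returns_initial(self, two_cluster_stack):
        specs = [ms.ClassSpec("A", 1), ms.ClassSpec("B", 1)]
        model0 = ms.init_model(two_cluster_stack, specs, seed=1)
        model, trace = ms.em_fit(two_cluster_stack, model0, max_iter=0)
        assert model is model0
        assert trace.log_likelihood == [] and trace.iterations == 0

    def test_dimension_mismatch(self, two_cluster_stack):
        specs = [ms.ClassSpec("A", 1)]
        model0 = ms.init_model(two_cluster_stack, specs, seed=1)
        vols = [make_volume(np.zeros((10, 10, 10))) for _ in range(2)]
        stack2 = ms.stack_channels(vols, ["a", "b"])
        with pytest.raises(ValueError, match="channels"):
            ms.em_fit(stack2, model0)

    def test_loglikelihood_monotone(self, two_cluster_stack):
        _, _, trace = ms.segment(
            two_cluster_stack,
            [ms.ClassSpec("A", 1), ms.ClassSpec("B", 2)], seed=3,
        )
        assert trace.is_monotone(rtol=1e-8)


class TestPosterior:
    def test_single_class_is_one(self, two_cluster_stack):
        _, maps, _ = ms.segment(two_cluster_stack, [ms.ClassSpec("ALL", 1)], seed=0)
        np.testing.assert_allclose(maps.maps[0].data, 1.0, atol=1e-12)

    def test_symmetric_midpoint_is_half(self):
        comps = [
            [ms.GaussianComponent([-2.0], [[1.0]], 1.0)],
            [ms.GaussianComponent([2.0], [[1.0]], 1.0)],
        ]
        model = ms.TissueModel(
            [ms.ClassSpec("A", 1), ms.ClassSpec("B", 1)], comps, ["t1w"],
            stationary_priors=np.array([0.5, 0.5]),
        )
        stack = ms.stack_channels([make_volume(np.zeros((3, 3, 3)))], ["t1w"])
        maps = ms.posterior_maps(stack, model)
        np.testing.assert_allclose(maps.get("A").data, 0.5, atol=1e-12)
        np.testing.assert_allclose(maps.get("B").data, 0.5, atol=1e-12)

    def test_sums_to_one_in_mask(self, two_cluster_stack):
        _, maps, _ = ms.segment(
            two_cluster_stack,
            [ms.ClassSpec("A", 1), ms.ClassSpec("B", 2)], seed=2,
        )
        np.testing.assert_allclose(maps.total(), 1.0, atol=1e-6)

    def test_matches_bruteforce_bayes_oracle(self, two_cluster_stack):
        specs = [ms.ClassSpec("A", 1), ms.ClassSpec("B", 2)]
        model, _, _ = ms.segment(two_cluster_stack, specs, seed=4)
        X, idx = two_cluster_stack.samples()
        P = _prior_matrix(
            two_cluster_stack, idx, None, model.stationary_priors, 2
        )
        means, covs, weights, class_of = model._flat()
        R, _ = _estep(X, np.log(P), means, covs, weights, class_of)
        R_naive = naive_responsibilities(X, P, model)
        np.testing.assert_allclose(R, R_naive, atol=1e-10)


class TestBiasField:
    def test_imposed_polynomial_bias_recovered(self):
        spec = ms.PhantomSpec(
            shape=(40, 40, 40), seed=5, bias_order=2, bias_range=0.15,
            noise_model="rician", snr=50,
        )
        stack, _, truth = ms.generate(spec)
        priors = ms.make_priors(truth)
        res = ms.MultichannelMixture(stack, priors=priors).fit(seed=5, bias_order=2)
        idx = np.flatnonzero(stack.effective_mask().ravel())
        basis = _poly_basis(stack.shape, idx, 2)
        est = basis @ res.params.bias_coefficients
        for ci, ch in enumerate(stack.channel_names):
            true = truth.bias_log_fields[ch].data.ravel()[idx]
            r = np.corrcoef(est[:, ci], true - true.mean())[0, 1]
            assert r >= 0.98, f"{ch}: bias-field correlation {r:.3f}"

    def test_bias_with_scaling_rejected(self, two_cluster_stack):
        model = ms.MultichannelMixture(
            two_cluster_stack, [ms.ClassSpec("A", 1)], scale_channels=True
        )
        with pytest.raises(ValueError, match="scaling"):
            model.fit(bias_order=2)


class TestModelObject:
    def test_results_carry_trace_maps_summary(self, two_cluster_stack):
        res = ms.MultichannelMixture(
            two_cluster_stack, [ms.ClassSpec("A", 1), ms.ClassSpec("B", 1)]
        ).fit(seed=7)
        assert res.trace.converged
        text = res.summary()
        assert "log-likelihood" in text and "mean[t1w]" in text
        assert res.tissue_probability_maps.class_names == ["A", "B"]

    def test_json_roundtrip_preserves_separation(self, two_cluster_stack):
        res = ms.MultichannelMixture(
            two_cluster_stack, [ms.ClassSpec("A", 1), ms.ClassSpec("B", 2)]
        ).fit(seed=7)
        back = ms.TissueModel.from_json(res.params.to_json())
        r1 = ms.class_separation(res.params)
        r2 = ms.class_separation(back)
        assert r1.distance("A", "B") == pytest.approx(
            r2.distance("A", "B"), rel=1e-12
        )

    def test_segment_deterministic(self, two_cluster_stack):
        specs = [ms.ClassSpec("A", 1), ms.ClassSpec("B", 1)]
        _, maps1, _ = ms.segment(two_cluster_stack, specs, seed=11)
        _, maps2, _ = ms.segment(two_cluster_stack, specs, seed=11)
        for a, b in zip(maps1.maps, maps2.maps):
            np.testing.assert_array_equal(a.data, b.data)
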