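"""CSP, shrinkage covariance and Riemannian tangent space."""

import numpy as np
import pytest
import scipy.linalg
from sklearn.covariance import OAS

from olfeeg import (
    EEGTrial,
    EEGTrialSet,
    Label,
    Odor,
    SPDMatrix,
    estimate_covariance,
    fit_csp,
    fit_tangent,
    riemannian_mean,
    tangent_map,
    transform_csp,
)
from olfeeg.errors import DataError, DegenerateDataError, StateError
from olfeeg.spatial import CSPModel


def _trial(data, subject="s", label=Label.AD):
    return EEGTrial(data=np.asarray(data, float), subject_id=subject,
                    label=label, odor=Odor.LEMON, fs=200.0)


def _toy_two_class_set(rng, cov_a, cov_b, n_trials=20, n_samples=500):
    """Gaussian trials with prescribed class covariances."""
    la, lb = np.linalg.cholesky(cov_a), np.linalg.cholesky(cov_b)
    trials = []
    d = cov_a.shape[0]
    for i in range(n_trials):
        trials.append(_trial(la @ rng.standard_normal((d, n_samples)),
                             subject=f"a{i}", label=Label.AD))
        trials.append(_trial(lb @ rng.standard_normal((d, n_samples)),
                             subject=f"b{i}", label=Label.HEALTHY))
    return EEGTrialSet(trials, channel_names=[f"c{i}" for i in range(d)])


class TestCSP:
    def test_filters_match_generalized_eigendecomposition(self, rng):
        # oracle: direct scipy eigh on the class covariances
        cov_a = np.diag([10.0, 1.0])
        cov_b = np.diag([1.0, 10.0])
        ts = _toy_two_class_set(rng, cov_a, cov_b)
        model = fit_csp(ts, n_components=2)
        xa = np.concatenate([t.data for t in ts if t.label == Label.AD], axis=1)
        xb = np.concatenate([t.data for t in ts if t.label == Label.HEALTHY], axis=1)
        ca = xa @ xa.T / xa.shape[1]
        cb = xb @ xb.T / xb.shape[1]
        ca, cb = ca / np.trace(ca), cb / np.trace(cb)
        _, vecs = scipy.linalg.eigh(ca, ca + cb)
        # extremal oracle eigenvectors, normalized
        oracle = [vecs[:, -1] / np.linalg.norm(vecs[:, -1]),
                  vecs[:, 0] / np.linalg.norm(vecs[:, 0])]
        for w in model.filters:
            cos = max(abs(float(w @ o)) for o in oracle)
            assert cos >= 0.999

    def test_toy_filters_align_with_axes(self, rng):
        ts = _toy_two_class_set(rng, np.diag([10.0, 1.0]), np.diag([1.0, 10.0]))
        model = fit_csp(ts, n_components=2)
        # the discriminative directions are the coordinate axes (up to sign)
        for w in model.filters:
            assert max(abs(w)) / np.linalg.norm(w) >= 0.99

    def test_identical_covariances_no_discriminative_ordering(self, rng):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        ts = _toy_two_class_set(rng, cov, cov, n_trials=40, n_samples=2000)
        xa = np.concatenate([t.data for t in ts if t.label == Label.AD], axis=1)
        xb = np.concatenate([t.data for t in ts if t.label == Label.HEALTHY], axis=1)
        ca = xa @ xa.T / xa.shape[1]
        cb = xb @ xb.T / xb.shape[1]
        ca, cb = ca / np.trace(ca), cb / np.trace(cb)
        vals = scipy.linalg.eigh(ca, ca + cb, eigvals_only=True)
        np.testing.assert_allclose(vals, 0.5, atol=0.02)

    def test_default_component_count(self, strong_trialset):
        model = fit_csp(strong_trialset)
        assert model.filters.shape == (4, 4)
        assert model.fitted

    def test_single_class_rejected(self, rng):
        trials = [_trial(rng.standard_normal((3, 200)), subject=f"s{i}")
                  for i in range(4)]
        with pytest.raises(DataError):
            fit_csp(EEGTrialSet(trials, ["a", "b", "c"]))

    def test_transform_zero_trial_gives_zero(self, strong_trialset):
        model = fit_csp(strong_trialset)
        z = transform_csp(model, _trial(np.zeros((4, 100))))
        np.testing.assert_array_equal(z, 0.0)

    def test_transform_quadratic_scaling(self, strong_trialset, rng):
        model = fit_csp(strong_trialset)
        data = rng.standard_normal((4, 300))
        f1 = transform_csp(model, _trial(data))
        f2 = transform_csp(model, _trial(3.0 * data))
        np.testing.assert_allclose(f2, 9.0 * f1, rtol=1e-10)
        assert np.all(f1 >= 0)

    def test_unit_filter_sinusoid_power_half(self):
        # mean of sin^2 over whole periods is exactly 1/2
        model = CSPModel(filters=np.array([[1.0, 0.0]]), n_components=1,
                         classes=[0, 1], fitted=True)
        t = np.arange(400) / 200.0
        data = np.vstack([np.sin(2 * np.pi * 10.0 * t), np.zeros(400)])
        power = transform_csp(model, _trial(data))
        assert power[0] == pytest.approx(0.5, abs=1e-12)

    def test_unfitted_model_rejected(self):
        model = CSPModel(filters=np.eye(2), n_components=2, classes=[0, 1],
                         fitted=False)
        with pytest.raises(StateError):
            transform_csp(model, _trial(np.zeros((2, 100))))


class TestCovarianceEstimation:
    def test_oas_matches_sklearn(self, rng):
        x = rng.standard_normal((4, 300))
        ours = estimate_covariance(_trial(x)).values
        ref = OAS(assume_centered=True).fit(x.T).covariance_
        np.testing.assert_allclose(ours, ref, rtol=1e-8)

    def test_oas_converges_to_identity_for_white_noise(self, rng):
        # Monte-Carlo oracle: iid N(0,1) channels -> covariance -> I
        errs = []
        for _ in range(50):
            x = rng.standard_normal((4, 4000))
            errs.append(np.max(np.abs(estimate_covariance(_trial(x)).values - np.eye(4))))
        assert np.mean(errs) < 0.08

    def test_constant_channel_rejected(self):
        with pytest.raises(DegenerateDataError):
            estimate_covariance(_trial(np.ones((2, 50))))

    def test_isotropic_data_full_shrinkage_limit(self):
        # when S is exactly a scaled identity the shrinkage intensity clamps
        # to 1 and the estimate equals (tr S / d) I = S itself
        t = np.arange(64)
        x = np.vstack([np.cos(2 * np.pi * 8 * t / 64), np.sin(2 * np.pi * 8 * t / 64)])
        s = x @ x.T / x.shape[1]
        np.testing.assert_allclose(s, 0.5 * np.eye(2), atol=1e-12)
        c = estimate_covariance(_trial(x)).values
        np.testing.assert_allclose(c, 0.5 * np.eye(2), atol=1e-12)

    def test_result_is_spd(self, rng):
        for _ in range(5):
            x = rng.standard_normal((4, 50))
            c = estimate_covariance(_trial(x)).values
            assert np.min(np.linalg.eigvalsh(c)) > 0
            assert np.max(np.abs(c - c.T)) <= 1e-12

    def test_sample_method_needs_enough_samples(self, rng):
        with pytest.raises(DataError):
            estimate_covariance(_trial(rng.standard_normal((8, 6))), method="sample")


def _random_spd(rng, d=4, scale=1.0):
    a = rng.standard_normal((d, d))
    return SPDMatrix(a @ a.T + scale * np.eye(d))


class TestRiemannianMean:
    def test_mean_of_identical_matrices(self, rng):
        c = _random_spd(rng)
        m = riemannian_mean([c, c, c])
        np.testing.assert_allclose(m.values, c.values, atol=1e-8)

    def test_commuting_family_closed_form(self, rng):
        # oracle: for simultaneously diagonalizable matrices the Karcher mean
        # is exp(mean(log)) in the shared eigenbasis
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        diags = [np.abs(rng.standard_normal(4)) + 0.3 for _ in range(5)]
        mats = [SPDMatrix(q @ np.diag(d) @ q.T) for d in diags]
        expected = q @ np.diag(np.exp(np.mean(np.log(diags), axis=0))) @ q.T
        m = riemannian_mean(mats)
        np.testing.assert_allclose(m.values, expected, atol=1e-8)

    def test_congruence_invariance(self, rng):
        mats = [_random_spd(rng) for _ in range(4)]
        a = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        transformed = [SPDMatrix(a.T @ m.values @ a) for m in mats]
        lhs = riemannian_mean(transformed).values
        rhs = a.T @ riemannian_mean(mats).values @ a
        np.testing.assert_allclose(lhs, rhs, atol=1e-6 * np.max(np.abs(rhs)))

    def test_mean_is_spd(self, rng):
        m = riemannian_mean([_random_spd(rng) for _ in range(8)])
        assert np.min(np.linalg.eigvalsh(m.values)) > 0


class TestTangentSpace:
    def test_reference_maps_to_zero(self, rng):
        c = _random_spd(rng)
        model = fit_tangent([c])
        np.testing.assert_allclose(tangent_map(model, c), 0.0, atol=1e-10)

    def test_duplicated_list_same_reference(self, rng):
        mats = [_random_spd(rng) for _ in range(3)]
        r1 = fit_tangent(mats).reference.values
        r2 = fit_tangent(mats + mats).reference.values
        np.testing.assert_allclose(r1, r2, atol=1e-7)

    def test_vector_length_is_triangular_number(self, rng):
        model = fit_tangent([_random_spd(rng) for _ in range(4)])
        v = tangent_map(model, _random_spd(rng))
        assert v.shape == (10,)  # d(d+1)/2 with d=4

    def test_norm_equals_riemannian_distance(self, rng):
        # oracle: delta(R, C) = sqrt(sum log^2 eigvals(R^-1/2 C R^-1/2))
        model = fit_tangent([_random_spd(rng) for _ in range(5)])
        c = _random_spd(rng)
        v = tangent_map(model, c)
        r = model.reference.values
        w, vec = np.linalg.eigh(r)
        inv_sqrt = (vec * w ** -0.5) @ vec.T
        eig = np.linalg.eigvalsh(inv_sqrt @ c.values @ inv_sqrt)
        assert np.linalg.norm(v) == pytest.approx(
            np.sqrt(np.sum(np.log(eig) ** 2)), abs=1e-8)

    def test_unfitted_rejected(self, rng):
        from olfeeg.spatial import TangentSpaceModel
        model = TangentSpaceModel(reference=_random_spd(rng), fitted=False)
        with pytest.raises(StateError):
            tangent_map(model, _random_spd(rng))
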