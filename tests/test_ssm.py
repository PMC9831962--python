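"""Shape model: PCA correctness against brute-force oracles, Kaiser
retention, reconstruction completeness, and the accuracy / specificity /
generalisation metric suite."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from spineshape.alignment import align_cohort
from spineshape.geometry import CorrespondedShape
from spineshape.phantom import PhantomSpec, generate_cohort
from spineshape.ssm import (
    PointDistributionModel,
    evaluate,
    fit_ssm,
    rmse_between,
)
from tests.conftest import random_shapes


def _model_with_eigenvalues(eigenvalues):
    """Bare model carrying given eigenvalues (for retention arithmetic)."""
    model = PointDistributionModel()
    ev = np.asarray(eigenvalues, dtype=float)
    model.modes_ = np.eye(ev.size)
    model.mean_ = np.zeros(ev.size)
    model.eigenvalues_ = ev
    model.lambda_total_ = float(ev.sum())
    model.lambda_bar_ = float(ev.mean())
    model.n_total_modes_ = ev.size
    model.n_points_ = ev.size // 3 or 1
    model.n_training_ = ev.size + 1
    model.retained_ = ev.size
    return model


class TestRmse:
    def test_identical_shapes(self):
        s = random_shapes(1, 10)[0]
        assert rmse_between(s, s) == 0.0

    def test_three_four_five_offset(self):
        a = CorrespondedShape(np.zeros((1, 3)))
        b = CorrespondedShape(np.array([[3.0, 4.0, 0.0]]))
        assert rmse_between(a, b) == pytest.approx(5.0)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(0)
        a = CorrespondedShape(rng.normal(size=(10, 3)))
        b = CorrespondedShape(rng.normal(size=(10, 3)))
        acc = sum(
            float(np.linalg.norm(pa - pb)) ** 2 for pa, pb in zip(a.points, b.points)
        )
        assert rmse_between(a, b) == pytest.approx(np.sqrt(acc / 10))

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse_between(random_shapes(1, 4)[0], random_shapes(1, 5)[0])


class TestFit:
    def test_rank_one_cohort_has_single_nonzero_eigenvalue(self):
        base = random_shapes(1, 8, seed=1)[0]
        direction = np.random.default_rng(1).normal(size=(8, 3))
        shapes = [
            CorrespondedShape(base.points + w * direction) for w in (-1.0, 0.0, 1.0)
        ]
        model = fit_ssm(shapes)
        assert model.eigenvalues_[0] > 1e-8
        assert np.all(model.eigenvalues_[1:] < 1e-10 * model.eigenvalues_[0])

    def test_eigenvalues_match_covariance_oracle(self):
        # tiny cohort: explicit 12x12 covariance eigendecomposition
        shapes = random_shapes(5, 4, seed=2)
        X = np.array([s.as_vector() for s in shapes])
        C = np.cov(X, rowvar=False)  # (12, 12), t-1 divisor
        oracle = np.sort(np.linalg.eigvalsh(C))[::-1]
        model = fit_ssm(shapes)
        np.testing.assert_allclose(
            model.eigenvalues_, oracle[: model.n_total_modes_], atol=1e-10
        )

    def test_mode_orthonormality(self, phantom_cohort):
        _, shapes, _, _ = phantom_cohort
        model = fit_ssm(align_cohort(shapes))
        gram = model.modes_.T @ model.modes_
        assert np.abs(gram - np.eye(model.n_total_modes_)).max() <= 1e-8

    def test_eigenvalue_sum_equals_total_variance(self, phantom_cohort):
        _, shapes, _, _ = phantom_cohort
        model = fit_ssm(shapes)
        X = np.array([s.as_vector() for s in shapes])
        total = ((X - X.mean(axis=0)) ** 2).sum() / (len(shapes) - 1)
        assert model.lambda_total_ == pytest.approx(total, rel=1e-8)

    def test_reconstruction_completeness(self, phantom_cohort):
        _, shapes, _, _ = phantom_cohort
        model = fit_ssm(shapes)
        for s in shapes:
            w = model.project(s, model.n_total_modes_)
            assert rmse_between(s, model.reconstruct(w)) < 1e-6

    def test_too_few_shapes_rejected(self):
        with pytest.raises(ValueError):
            fit_ssm(random_shapes(2, 6))

    def test_noiseless_phantom_modes_span_generative_fields(self, noiseless_cohort):
        # the noiseless, unit-scale phantom cohort is already in a common
        # frame; the fitted modes must span the generative fields exactly
        _, shapes, _, truth = noiseless_cohort
        model = fit_ssm(shapes)
        k = truth.latent_sd.size
        angles = subspace_angles(model.modes_[:, :k], truth.surface_fields.T)
        assert angles.max() < 1e-3


class TestReconstruct:
    def test_zero_weights_give_mean(self, phantom_cohort):
        _, shapes, _, _ = phantom_cohort
        model = fit_ssm(shapes)
        recon = model.reconstruct(np.zeros(model.retained_))
        np.testing.assert_allclose(recon.as_vector(), model.mean_)

    def test_mode_displacement_map_matches_direct(self, phantom_cohort):
        _, shapes, _, _ = phantom_cohort
        model = fit_ssm(shapes)
        two_sd = 2.0 * np.sqrt(model.eigenvalues_[0])
        shape_plus = model.reconstruct(np.array([two_sd]))
        direct = np.linalg.norm(
            shape_plus.points - model.mean_shape().points, axis=1
        )
        np.testing.assert_allclose(
            model.mode_displacement_map(0, 2.0), direct, atol=1e-10
        )

    def test_too_many_weights_rejected(self, phantom_cohort):
        _, shapes, _, _ = phantom_cohort
        model = fit_ssm(shapes)
        with pytest.raises(ValueError):
            model.reconstruct(np.zeros(model.n_total_modes_ + 1))

    def test_transform_inverse_transform_round_trip(self, phantom_cohort):
        _, shapes, _, _ = phantom_cohort
        model = fit_ssm(shapes)
        W = model.transform(shapes[:3])
        assert W.shape == (3, model.retained_)
        recons = model.inverse_transform(W)
        assert len(recons) == 3


class TestCompactness:
    def test_forced_arithmetic(self):
        model = _model_with_eigenvalues([3.0, 2.0, 1.0])
        assert model.compactness(2) == pytest.approx(5.0 / 6.0)
        assert model.compactness(3) == pytest.approx(1.0)

    def test_matches_cumulative_sum_oracle(self):
        rng = np.random.default_rng(3)
        ev = np.sort(rng.uniform(0.1, 10.0, size=9))[::-1]
        model = _model_with_eigenvalues(ev)
        cum = np.cumsum(ev) / ev.sum()
        for M in range(1, 10):
            assert model.compactness(M) == pytest.approx(cum[M - 1])

    def test_out_of_range_rejected(self):
        model = _model_with_eigenvalues([1.0, 0.5])
        with pytest.raises(ValueError):
            model.compactness(0)
        with pytest.raises(ValueError):
            model.compactness(3)


class TestKaiserRetention:
    def test_printed_mean_variance_threshold(self):
        # lambda_bar = 1.0039e3 -> threshold 0.7 * lambda_bar = 702.73
        model = _model_with_eigenvalues(np.full(151, 1.0039e3))
        assert model.kaiser_threshold(0.7) == pytest.approx(702.73, abs=0.005)

    def test_small_example(self):
        model = _model_with_eigenvalues([10.0, 5.0, 0.1])
        assert model.retain_kaiser(0.7) == 2

    def test_equal_eigenvalues_retain_all(self):
        model = _model_with_eigenvalues([2.0] * 6)
        assert model.retain_kaiser(0.7) == 6

    def test_bad_factor_rejected(self):
        model = _model_with_eigenvalues([1.0, 0.5])
        with pytest.raises(ValueError):
            model.retain_kaiser(0.0)


class TestEvaluate:
    def test_full_mode_accuracy_is_exact(self):
        # p=4 keeps the full mode count (3p) below the leave-one-out capacity
        shapes = random_shapes(20, 4, seed=4)
        full = evaluate(shapes, M=12, n_specificity_samples=5, seed=0,
                        generalisation_curve=False)
        assert full.accuracy_mean < 1e-6

    def test_generalisation_curve_non_increasing(self, phantom_cohort):
        _, shapes, _, _ = phantom_cohort
        perf = evaluate(align_cohort(shapes), M=4, n_specificity_samples=30, seed=1)
        curve = perf.per_mode_generalisation
        assert np.all(np.diff(curve) <= 1e-3 * curve[0])

    def test_noiseless_generalisation_vanishes(self):
        spec = PhantomSpec(t=50, p=1300, latent_dim=2, seed=21,
                           noise_sd=0.0, size_sd=0.0, latent_sd=[6.0, 3.0])
        shapes, _, _ = generate_cohort(spec)
        perf = evaluate(shapes, M=2, n_specificity_samples=10,
                        seed=0, generalisation_curve=False)
        assert perf.generalisation_mean < 1e-6

    def test_degenerate_model_specificity(self):
        shape = random_shapes(1, 8, seed=5)[0]
        shapes = [shape.copy() for _ in range(4)]
        perf = evaluate(shapes, M=1, n_specificity_samples=10, seed=0,
                        generalisation_curve=False)
        # zero-variance sampler: every synthetic shape is the mean shape,
        # whose distance to the (identical) training shapes is zero
        assert perf.specificity_mean == pytest.approx(0.0, abs=1e-9)

    def test_excessive_modes_rejected(self):
        shapes = random_shapes(5, 10, seed=6)
        with pytest.raises(ValueError):
            evaluate(shapes, M=4)
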