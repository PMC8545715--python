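import numpy as np
import pytest

from poretomo import (
    CascadeParams,
    DyadicPartition,
    FrequencyCurve,
    MultifractalConfig,
    cascade_true_spectrum,
    chhabra_weights,
    dyadic_measures,
    estimate_Dq,
    estimate_alpha_f,
    generate_binomial_cascade,
    partition_sum,
    run_multifractal,
    spectrum_descriptors,
)
from poretomo.errors import (
    DegenerateInputError,
    DescriptorError,
    EstimationError,
    InvalidParameterError,
)


def cascade(p, depth, shuffle_seed=None):
    return generate_binomial_cascade(CascadeParams(p=p, depth=depth, shuffle_seed=shuffle_seed))


class TestDyadicMeasures:
    def test_uniform_curve_level_one(self):
        part = dyadic_measures(np.full(8, 3.0), k=1)
        np.testing.assert_allclose(part.measures, [0.5, 0.5])
        assert part.epsilon == 0.5

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_cascade_rebinning_self_consistency(self, k):
        fine = cascade(0.7, 6)
        coarse = dyadic_measures(fine, k)
        np.testing.assert_allclose(coarse.measures, cascade(0.7, k), atol=1e-14)

    def test_measures_sum_to_one(self):
        rng = np.random.default_rng(0)
        for k in (1, 3, 5):
            part = dyadic_measures(rng.random(64), k)
            assert abs(part.measures.sum() - 1.0) < 1e-12

    def test_all_zero_curve_rejected(self):
        with pytest.raises(DegenerateInputError):
            dyadic_measures(np.zeros(16), 2)

    def test_indivisible_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            dyadic_measures(np.ones(12), 3)

    def test_k_too_large_rejected(self):
        with pytest.raises(InvalidParameterError):
            dyadic_measures(np.ones(8), 4)


class TestPartitionSum:
    def test_q1_is_normalization(self):
        part = dyadic_measures(np.random.default_rng(1).random(32), 3)
        assert partition_sum(part, 1.0) == pytest.approx(1.0)

    def test_q0_counts_occupied_bins(self):
        part = dyadic_measures(np.ones(32), 4)
        assert partition_sum(part, 0.0) == 16

    def test_q0_skips_empty_bins(self):
        signal = np.zeros(8)
        signal[:4] = 1.0
        part = dyadic_measures(signal, 3)
        assert partition_sum(part, 0.0) == 4

    @pytest.mark.parametrize("q", [-2.0, 2.0])
    def test_cascade_product_structure(self, q):
        # for the binomial cascade the moment sum factorizes per level
        k = 6
        part = dyadic_measures(cascade(0.7, 10), k)
        expected = (0.7**q + 0.3**q) ** k
        assert partition_sum(part, q) == pytest.approx(expected, rel=1e-10)


class TestChhabraWeights:
    def test_q0_uniform_over_occupied(self):
        signal = np.zeros(8)
        signal[:4] = np.array([1.0, 2.0, 3.0, 4.0])
        part = dyadic_measures(signal, 3)
        w = chhabra_weights(part, 0.0)
        np.testing.assert_allclose(w[:4], 0.25)
        np.testing.assert_allclose(w[4:], 0.0)

    def test_q1_identity(self):
        part = dyadic_measures(np.random.default_rng(2).random(16), 2)
        np.testing.assert_allclose(chhabra_weights(part, 1.0), part.measures)

    def test_cascade_level_one_q2(self):
        part = dyadic_measures(cascade(0.7, 1), 1)
        np.testing.assert_allclose(
            chhabra_weights(part, 2.0), [0.49 / 0.58, 0.09 / 0.58]
        )

    def test_weights_sum_to_one(self):
        part = dyadic_measures(np.random.default_rng(3).random(64), 5)
        for q in (-5.0, -1.0, 0.0, 0.5, 3.0):
            assert chhabra_weights(part, q).sum() == pytest.approx(1.0)


class TestEstimateAlphaF:
    def test_uniform_curve_exact(self):
        for q in (-3.0, 0.0, 1.0, 4.0):
            est = estimate_alpha_f(np.full(1024, 7.0), q, range(1, 11))
            assert est.alpha.value == pytest.approx(1.0, abs=1e-12)
            assert est.alpha.r2 == 1.0
            assert est.f.value == pytest.approx(1.0)
            assert est.accepted

    def test_cascade_alpha0(self):
        est = estimate_alpha_f(cascade(0.7, 10), 0.0, range(1, 11))
        assert est.alpha.value == pytest.approx(1.1258, abs=0.02)

    def test_uniform_limit_cascade(self):
        est = estimate_alpha_f(cascade(0.5, 10), 5.0, range(1, 11))
        assert est.alpha.value == pytest.approx(1.0, abs=1e-9)
        assert est.f.value == pytest.approx(1.0, abs=1e-9)

    def test_too_few_scales_raises(self):
        with pytest.raises(EstimationError):
            estimate_alpha_f(np.ones(1024), 0.0, range(1, 3))

    def test_negative_q_with_empty_bins_rejected(self):
        # half the support empty at every usable scale: all levels dropped
        signal = np.zeros(64)
        signal[:32] = 1.0
        est = estimate_alpha_f(signal, -2.0, range(1, 7))
        assert not est.accepted
        assert np.isnan(est.alpha.value)


class TestEstimateDq:
    def test_uniform_curve_all_q(self):
        for q in (-9.0, -1.0, 0.0, 1.0, 2.0, 9.0):
            est = estimate_Dq(np.full(1024, 3.0), q, range(1, 11))
            assert est.value == pytest.approx(1.0, abs=1e-12)
            assert est.r2 == 1.0
            assert est.accepted

    def test_cascade_d2(self):
        est = estimate_Dq(cascade(0.7, 10), 2.0, range(1, 11))
        assert est.value == pytest.approx(-np.log2(0.58), abs=0.02)

    def test_d0_exactly_one_for_strictly_positive_curve(self):
        rng = np.random.default_rng(4)
        signal = rng.random(1024) + 0.1
        est = estimate_Dq(signal, 0.0, range(1, 11))
        assert est.value == pytest.approx(1.0, abs=1e-12)

    def test_d1_entropy_form_on_cascade(self):
        est = estimate_Dq(cascade(0.7, 10), 1.0, range(1, 11))
        d1_true, _, _ = cascade_true_spectrum(0.7, 1.0)
        assert est.value == pytest.approx(float(d1_true), abs=1e-10)

    def test_se_scaling_for_q_not_one(self):
        rng = np.random.default_rng(5)
        signal = rng.random(256) + 0.5
        est2 = estimate_Dq(signal, 3.0, range(1, 9))
        assert est2.se >= 0


class TestRunMultifractal:
    def test_cascade_matches_closed_form(self):
        spectrum = run_multifractal(cascade(0.7, 10))
        d_true, a_true, f_true = cascade_true_spectrum(0.7, spectrum.q)
        sel = np.abs(spectrum.q) <= 5
        assert np.max(np.abs(spectrum.d[sel] - d_true[sel])) < 0.03
        assert np.max(np.abs(spectrum.alpha[sel] - a_true[sel])) < 0.03
        assert np.max(np.abs(spectrum.f[sel] - f_true[sel])) < 0.03

    def test_uniform_1024_curve(self):
        curve = FrequencyCurve(
            counts=np.full(1024, 600_000), axis=0, slice_area_vox=1024 * 1024
        )
        spectrum = run_multifractal(curve)
        assert spectrum.accepted.all()
        assert len(spectrum.q) == 19
        np.testing.assert_allclose(spectrum.d, 1.0, atol=1e-12)
        np.testing.assert_allclose(spectrum.d_r2, 1.0)

    def test_monotone_dq_on_exact_cascade(self):
        spectrum = run_multifractal(cascade(0.7, 10))
        acc = spectrum.accepted
        assert (np.diff(spectrum.d[acc]) <= 1e-6).all()

    def test_tangent_identities_closed_form(self):
        d, a, f = cascade_true_spectrum(0.7, np.array([0.0, 1.0]))
        assert f[0] == pytest.approx(d[0], abs=1e-6)  # f(alpha_0) = D_0
        assert a[1] == pytest.approx(d[1], abs=1e-6)  # alpha_1 = D_1
        assert f[1] == pytest.approx(a[1], abs=1e-6)  # f(alpha_1) = alpha_1

    def test_tangent_identities_estimated(self):
        spectrum = run_multifractal(cascade(0.7, 10))
        i0 = int(np.flatnonzero(spectrum.q == 0)[0])
        i1 = int(np.flatnonzero(spectrum.q == 1)[0])
        assert spectrum.f[i0] == pytest.approx(spectrum.d[i0], abs=0.02)
        assert spectrum.alpha[i1] == pytest.approx(spectrum.d[i1], abs=0.02)

    def test_truncates_non_power_of_two_with_warning(self):
        signal = np.random.default_rng(6).random(1000) + 0.1
        with pytest.warns(UserWarning, match="not a power of two"):
            spectrum = run_multifractal(signal)
        assert spectrum.k_max == 9  # 2**9 = 512 <= 1000

    def test_unshuffled_alpha_min_recovers_weight(self):
        # exact dyadic arrangement: alpha at the largest accepted q
        # approaches -log2(max(p, 1-p))
        spectrum = run_multifractal(cascade(0.7, 10))
        desc = spectrum.descriptors()
        assert desc.alpha_min == pytest.approx(-np.log2(0.7), abs=0.05)

    def test_shuffling_destroys_dyadic_scaling(self):
        # permuting bins breaks coarse-scale self-similarity, so the
        # estimate must move away from the arrangement-dependent value:
        # the estimator depends on how mass is arranged across bins
        target = -np.log2(0.7)
        for seed in range(5):
            spectrum = run_multifractal(cascade(0.7, 10, shuffle_seed=seed))
            desc = spectrum.descriptors()
            assert abs(desc.alpha_min - target) > 0.05


class TestSpectrumDescriptors:
    def test_uniform_degenerate_spectrum(self):
        spectrum = run_multifractal(np.full(1024, 2.0))
        desc = spectrum_descriptors(spectrum)
        assert desc.width == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(desc.asymmetry)
        assert desc.d0 == pytest.approx(1.0)

    def test_cascade_asymmetry_is_one(self):
        spectrum = run_multifractal(cascade(0.7, 10))
        desc = spectrum.descriptors()
        assert desc.asymmetry == pytest.approx(1.0, abs=0.05)

    def test_uniform_cascade_d0_equals_d2(self):
        spectrum = run_multifractal(cascade(0.5, 10))
        desc = spectrum.descriptors()
        assert desc.d0_minus_d2 == pytest.approx(0.0, abs=1e-9)

    def test_descriptor_error_when_q0_rejected(self):
        spectrum = run_multifractal(np.full(1024, 2.0))
        broken = type(spectrum)(
            q=spectrum.q,
            alpha=spectrum.alpha, alpha_se=spectrum.alpha_se, alpha_r2=spectrum.alpha_r2,
            f=spectrum.f, f_se=spectrum.f_se, f_r2=spectrum.f_r2,
            d=spectrum.d, d_se=spectrum.d_se, d_r2=spectrum.d_r2,
            accepted=np.zeros_like(spectrum.accepted),
            k_min=spectrum.k_min, k_max=spectrum.k_max,
            r2_threshold=spectrum.r2_threshold,
        )
        with pytest.raises(DescriptorError):
            spectrum_descriptors(broken)

    def test_csv_export(self, tmp_path):
        import pandas as pd

        spectrum = run_multifractal(cascade(0.7, 8))
        path = tmp_path / "spectrum.csv"
        spectrum.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns)[:3] == ["q", "alpha", "alpha_se"]
        assert len(frame) == 19


class TestDyadicPartitionInvariants:
    def test_measures_must_normalize(self):
        with pytest.raises(InvalidParameterError):
            DyadicPartition(k=1, measures=np.array([0.6, 0.6]))

    def test_negative_measures_rejected(self):
        with pytest.raises(InvalidParameterError):
            DyadicPartition(k=1, measures=np.array([1.5, -0.5]))

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            MultifractalConfig(q_min=3, q_max=-3)
        with pytest.raises(InvalidParameterError):
            MultifractalConfig(k_min=0)
        with pytest.raises(InvalidParameterError):
            MultifractalConfig(r2_threshold=1.5)
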