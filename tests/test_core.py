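"""Lead-matrix construction, closure, and spectral phase recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclicity import (
    SinusoidSpec,
    TimeCourse,
    center_and_close,
    circular_rmse,
    gen_cyclic_aperiodic,
    gen_phase_shifted_sinusoids,
    lead_matrix,
    recover_phase_offsets,
    spectral_decomposition,
)
from cyclicity.core import DataError, LeadMatrix, UndefinedPhaseError


def two_channel_course(a, b, delta, n_periods, n_samples):
    t = 2 * np.pi * n_periods * np.arange(n_samples) / n_samples
    return TimeCourse(np.vstack([a * np.sin(t + delta), b * np.sin(t)]))


class TestCenterAndClose:
    def test_pure_ramp_vanishes(self):
        tc = TimeCourse(np.array([[0.0, 1.0, 2.0, 3.0]]))
        assert np.allclose(center_and_close(tc).values, 0.0)

    def test_idempotent_on_closed_zero_mean_channel(self):
        t = np.linspace(0, 2 * np.pi, 101)[:-1]
        tc = TimeCourse(np.vstack([np.sin(t), np.cos(t)]))
        closed = center_and_close(tc)
        again = center_and_close(closed)
        assert np.allclose(closed.values, again.values, atol=1e-12)

    def test_removes_linear_trend_from_sinusoid(self):
        # sin over exactly 2 periods + 0.5t trend; trend removal is exact
        # because the sinusoid itself starts and ends at the same value
        t = np.linspace(0, 4 * np.pi, 400, endpoint=False)
        clean = np.sin(t)
        tc = TimeCourse((clean + 0.5 * t)[None, :])
        rec = center_and_close(tc).values[0]
        # the closing ramp removes 0.5*t up to the wraparound increment
        assert np.allclose(rec, clean - clean.mean(), atol=1e-8 + 0.5 * t[1])

    def test_endpoints_equal_and_zero_mean(self):
        rng = np.random.default_rng(0)
        tc = TimeCourse(rng.standard_normal((3, 50)))
        out = center_and_close(tc)
        assert np.allclose(out.values[:, 0], out.values[:, -1], atol=1e-12)
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(DataError):
            TimeCourse(np.array([[0.0, np.nan, 1.0]]))


class TestLeadMatrix:
    @pytest.mark.parametrize("a", [1.0, 2.0])
    @pytest.mark.parametrize("b", [1.0, 3.0])
    @pytest.mark.parametrize("delta", [np.pi / 6, np.pi / 2, 2.5])
    @pytest.mark.parametrize("n_periods", [1, 3])
    def test_closed_form_sinusoid_area(self, a, b, delta, n_periods):
        # pair a*sin(t+delta), b*sin(t): signed area = n*pi*a*b*sin(delta),
        # positive when the row channel leads (peaks earlier)
        tc = two_channel_course(a, b, delta, n_periods, 10_000)
        A = lead_matrix(tc).values
        expected = n_periods * np.pi * a * b * np.sin(delta)
        assert A[0, 1] == pytest.approx(expected, rel=1e-3)

    def test_quarter_period_gap_gives_pi(self):
        A = lead_matrix(two_channel_course(1, 1, np.pi / 2, 1, 10_000)).values
        assert A[0, 1] == pytest.approx(np.pi, rel=1e-3)

    def test_identical_channels_enclose_no_area(self):
        t = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        tc = TimeCourse(np.vstack([np.sin(t), np.sin(t)]))
        assert lead_matrix(tc).values[0, 1] == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 200))
        a1 = lead_matrix(TimeCourse(x)).values
        a2 = lead_matrix(TimeCourse(x + rng.standard_normal((4, 1)) * 10)).values
        assert np.allclose(a1, a2, atol=1e-9 * np.abs(a1).max())

    @pytest.mark.parametrize("power", [2, 3])
    def test_reparameterization_invariance(self, power):
        spec = SinusoidSpec(8, n_periods=4, n_samples=4000)
        a_plain = lead_matrix(gen_phase_shifted_sinusoids(spec, 0)).values
        a_warp = lead_matrix(gen_cyclic_aperiodic(spec, lambda u: u**power, 0)).values
        assert np.abs(a_plain - a_warp).max() <= 0.01 * np.abs(a_plain).max()

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            lead_matrix(TimeCourse(np.ones((2, 2))))

    def test_single_channel_rejected(self):
        with pytest.raises(DataError):
            lead_matrix(TimeCourse(np.sin(np.linspace(0, 6, 50))[None, :]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_antisymmetry_for_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        a = lead_matrix(TimeCourse(rng.standard_normal((5, 40)))).values
        assert np.abs(a + a.T).max() == 0.0

    def test_first_iterated_integral_vanishes_after_closing(self):
        # increment of a closed path is zero per channel
        rng = np.random.default_rng(3)
        closed = center_and_close(TimeCourse(rng.standard_normal((4, 100))))
        inc = closed.values[:, -1] - closed.values[:, 0]
        assert np.allclose(inc, 0.0, atol=1e-12)


class TestSpectralDecomposition:
    def test_zero_matrix_flagged_undefined(self):
        ss = spectral_decomposition(LeadMatrix(np.zeros((4, 4))))
        assert not ss.defined
        assert np.allclose(ss.eigen_magnitudes, 0.0)
        assert np.all(np.isnan(ss.leading_phases))

    def test_hand_built_phase_matrix_rank_two(self):
        phi = np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        a = np.sin(phi[:, None] - phi[None, :])
        ss = spectral_decomposition(LeadMatrix(a))
        # rank 2: one nonzero conjugate pair
        assert ss.eigen_magnitudes[0] > 1e-8
        assert ss.eigen_magnitudes[1] < 1e-10
        assert np.allclose(ss.leading_strengths, ss.leading_strengths[0])
        rec = recover_phase_offsets(ss, ss.channel_labels[0])
        assert circular_rmse(rec, phi) < 1e-8

    def test_two_by_two_eigenvalue_is_entry(self):
        tc = two_channel_course(1, 1, np.pi / 2, 1, 2000)
        lm = lead_matrix(tc)
        ss = spectral_decomposition(lm)
        assert ss.eigen_magnitudes[0] == pytest.approx(abs(lm.values[0, 1]), rel=1e-10)

    def test_eigenvalues_purely_imaginary(self):
        rng = np.random.default_rng(7)
        lm = lead_matrix(TimeCourse(rng.standard_normal((6, 80))))
        ev = np.linalg.eigvals(lm.values)
        assert np.abs(ev.real).max() < 1e-10 * np.abs(lm.values).max()

    def test_asymmetric_input_rejected(self):
        with pytest.raises(DataError):
            LeadMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestPhaseRecovery:
    def test_noiseless_eight_channel_recovery(self):
        spec = SinusoidSpec(8, n_periods=4, n_samples=800, snr=np.inf)
        tc = gen_phase_shifted_sinusoids(spec, 0)
        ss = spectral_decomposition(lead_matrix(tc))
        rec = recover_phase_offsets(ss, "ch0")
        assert circular_rmse(rec, spec.phases) < 0.05
        assert rec[0] == 0.0  # reference channel pinned exactly

    def test_noisy_recovery_snr20(self):
        spec = SinusoidSpec(8, n_periods=4, n_samples=600, snr=20)
        tc = gen_phase_shifted_sinusoids(spec, 1)
        ss = spectral_decomposition(lead_matrix(tc))
        rec = recover_phase_offsets(ss, "ch0")
        assert circular_rmse(rec, spec.phases) < 0.15

    def test_zero_leading_eigenvalue_raises(self):
        ss = spectral_decomposition(LeadMatrix(np.zeros((3, 3))))
        with pytest.raises(UndefinedPhaseError):
            recover_phase_offsets(ss, "ch0")

    def test_unknown_reference_channel(self):
        tc = two_channel_course(1, 1, 1.0, 1, 500)
        ss = spectral_decomposition(lead_matrix(tc))
        with pytest.raises(KeyError):
            recover_phase_offsets(ss, "nope")
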