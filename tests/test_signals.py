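"""Forward-model unit and property tests: Buxton-type closed form vs the
exact configuration-state steady state, model reductions, and the
magnitude noise floor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dwssfp import (
    BallSticksParams,
    DiffusionTensor,
    SequenceParams,
    TissueParams,
    ballsticks_signal,
    buxton_signal,
    classical_ssfp_echo,
    epg_ss_signal,
    noise_floor_signal,
    q_from_gradient,
    tensor_signal,
)


class TestQValue:
    def test_table_protocol(self):
        # 52 mT/m for 13.56 ms is the 300 cm^-1 protocol
        assert round(q_from_gradient(52.0, 13.56)) == 300

    def test_zero_duration(self):
        assert q_from_gradient(52.0, 0.0) == 0.0

    def test_hand_calculation(self):
        # 42.577 MHz/T * 0.052 T/m * 0.014 s = 31013 m^-1 = 310.1 cm^-1
        assert q_from_gradient(52.0, 14.0) == pytest.approx(310.1, abs=0.5)

    def test_sequence_consistency_check(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SequenceParams(TR=30, alpha_nominal=24, delta=13.56, G=52, q=250.0)


class TestBuxtonSignal:
    def test_no_q_removes_diffusion_dependence(self, tissue, seq):
        s1 = buxton_signal(40.0, tissue, seq, 1e-4, q=0.0)
        s2 = buxton_signal(40.0, tissue, seq, 5e-4, q=0.0)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_zero_diffusivity_equals_unweighted(self, tissue, seq):
        s_d0 = buxton_signal(40.0, tissue, seq, 0.0)
        s_q0 = buxton_signal(40.0, tissue, seq, 1e-4, q=0.0)
        assert s_d0 == pytest.approx(s_q0, rel=1e-12)

    @pytest.mark.parametrize("alpha", [10.0, 24.0, 40.0, 94.0, 120.0, 179.0])
    def test_d0_matches_classical_echo(self, tissue, seq, alpha):
        # at D = 0 the closed form must be the Freeman-Hill SSFP echo
        s = buxton_signal(alpha, tissue, seq, 0.0)
        ref = classical_ssfp_echo(alpha, tissue.T1, tissue.T2, seq.TR)
        assert s == pytest.approx(ref, rel=1e-12)

    def test_epg_oracle_example(self, tissue, seq):
        # frozen derived example: alpha=90, q=300 cm^-1, D=1e-4 mm^2/s
        s = buxton_signal(90.0, tissue, seq, 1e-4)
        ref = epg_ss_signal(90.0, tissue, seq, 1e-4)
        assert ref == pytest.approx(0.0074492769, rel=1e-6)
        assert s == pytest.approx(ref, rel=0.02)

    def test_monotone_in_d_and_q(self, tissue, seq):
        D = np.linspace(0.0, 1e-3, 21)
        for alpha in (15.0, 40.0, 90.0):
            s = buxton_signal(alpha, tissue, seq, D)
            assert np.all(np.diff(s) <= 1e-15)
            qs = np.linspace(0.0, 400.0, 17)
            sq = np.array(
                [buxton_signal(alpha, tissue, seq, 2e-4, q=q) for q in qs]
            )
            assert np.all(np.diff(sq) <= 1e-15)

    def test_invalid_inputs(self, seq):
        with pytest.raises(ValueError):
            TissueParams(T1=30.0, T2=500.0)  # T2 >= T1
        with pytest.raises(ValueError):
            SequenceParams(TR=-1.0, alpha_nominal=24, delta=13.56, q=300.0)
        with pytest.raises(ValueError):
            buxton_signal(0.0, TissueParams(500, 30), seq, 1e-4)
        with pytest.raises(ValueError):
            buxton_signal(40.0, TissueParams(500, 30), seq, -1e-4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        alpha=st.floats(5.0, 175.0),
        D=st.floats(0.0, 1e-3),
    )
    def test_signal_finite_nonnegative(self, alpha, D):
        t = TissueParams(T1=500.0, T2=30.0)
        s = SequenceParams(TR=30.0, alpha_nominal=24.0, delta=13.56, q=300.0)
        val = buxton_signal(alpha, t, s, D)
        assert np.isfinite(val) and val >= 0.0


class TestEPGAgreement:
    def test_closed_form_within_two_percent(self, tissue, seq):
        # alpha in [10, 120] deg, D in [5e-5, 5e-4] mm^2/s
        for alpha in np.arange(10.0, 121.0, 10.0):
            for D in (5e-5, 1e-4, 2e-4, 5e-4):
                ref = epg_ss_signal(alpha, tissue, seq, D)
                val = buxton_signal(alpha, tissue, seq, D)
                assert val == pytest.approx(ref, rel=0.02), (alpha, D)

    def test_classic_depth_one_closure_is_coarser(self, tissue, seq):
        # the single-level (classic) closure stays within ~5% here but is
        # visibly worse than the default depth at low flip angles
        ref = epg_ss_signal(10.0, tissue, seq, 2e-4)
        d1 = buxton_signal(10.0, tissue, seq, 2e-4, depth=1)
        d3 = buxton_signal(10.0, tissue, seq, 2e-4, depth=3)
        assert abs(d3 - ref) < abs(d1 - ref)


class TestTensorSignal:
    def test_along_eigenvector_equals_scalar(self, tissue, seq):
        V = np.linalg.qr(np.random.default_rng(3).normal(size=(3, 3)))[0]
        if np.linalg.det(V) < 0:
            V[:, 2] *= -1
        T = DiffusionTensor((1.7e-4, 8e-5, 5e-5), V)
        s = tensor_signal(60.0, tissue, seq, V[:, 0], T)
        assert s == pytest.approx(buxton_signal(60.0, tissue, seq, 1.7e-4), rel=1e-12)

    def test_near_isotropic_direction_independence(self, tissue, seq):
        d = 1e-4
        T = DiffusionTensor((d * 1.0002, d, d * 0.9998))
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(5):
            g = rng.normal(size=3)
            g /= np.linalg.norm(g)
            vals.append(tensor_signal(60.0, tissue, seq, g, T))
        assert np.ptp(vals) / np.mean(vals) < 1e-3

    def test_projection_oracle(self, tissue, seq):
        # direct 3x3 quadratic-form oracle
        rng = np.random.default_rng(7)
        for _ in range(5):
            V = np.linalg.qr(rng.normal(size=(3, 3)))[0]
            if np.linalg.det(V) < 0:
                V[:, 2] *= -1
            L = np.sort(rng.uniform(2e-5, 4e-4, 3))[::-1]
            L[0] *= 1.01
            T = DiffusionTensor(tuple(L), V)
            g = rng.normal(size=3)
            g /= np.linalg.norm(g)
            Dmat = V @ np.diag(L) @ V.T
            Dg = g @ Dmat @ g
            assert tensor_signal(45.0, tissue, seq, g, T) == pytest.approx(
                buxton_signal(45.0, tissue, seq, Dg), rel=1e-10
            )

    def test_nonunit_direction_rejected(self, tissue, seq):
        T = DiffusionTensor((1.7e-4, 8e-5, 5e-5))
        with pytest.raises(ValueError, match="unit"):
            tensor_signal(60.0, tissue, seq, [1.0, 1.0, 0.0], T)


class TestBallSticksSignal:
    def test_zero_fraction_is_pure_ball(self, tissue, seq):
        p = BallSticksParams((0.0,), [[1.0, 0.0, 0.0]], d_low=1e-4, d_high=1.4e-4)
        s = ballsticks_signal(50.0, tissue, seq, [0.0, 0.0, 1.0], p, "low")
        assert s == pytest.approx(buxton_signal(50.0, tissue, seq, 1e-4), rel=1e-12)

    def test_perpendicular_stick_unattenuated(self, tissue, seq):
        p = BallSticksParams((1.0,), [[1.0, 0.0, 0.0]], d_low=1e-4, d_high=1.4e-4)
        s = ballsticks_signal(50.0, tissue, seq, [0.0, 0.0, 1.0], p, "low")
        assert s == pytest.approx(buxton_signal(50.0, tissue, seq, 0.0), rel=1e-12)

    def test_mixture_hand_computed(self, tissue, seq):
        # f = 0.5, g.v = 0.6 -> 0.5*S(d) + 0.5*S(0.36 d)
        v = np.array([1.0, 0.0, 0.0])
        g = np.array([0.6, 0.8, 0.0])
        p = BallSticksParams((0.5,), [v], d_low=1e-4, d_high=1.4e-4)
        expect = 0.5 * buxton_signal(50.0, tissue, seq, 1e-4) + 0.5 * buxton_signal(
            50.0, tissue, seq, 1e-4 * 0.36
        )
        assert ballsticks_signal(50.0, tissue, seq, g, p, "low") == pytest.approx(
            expect, rel=1e-12
        )

    def test_which_flip_selects_diffusivity(self, tissue, seq):
        p = BallSticksParams((0.0,), [[1.0, 0.0, 0.0]], d_low=1e-4, d_high=1.4e-4)
        hi = ballsticks_signal(50.0, tissue, seq, [0.0, 0.0, 1.0], p, "high")
        assert hi == pytest.approx(buxton_signal(50.0, tissue, seq, 1.4e-4), rel=1e-12)

    def test_overweight_fractions_rejected(self):
        with pytest.raises(ValueError):
            BallSticksParams((0.7, 0.5), [[1, 0, 0], [0, 1, 0]], 1e-4, 1e-4)


class TestNoiseFloor:
    def test_three_four_five(self):
        assert noise_floor_signal(4.0, 3.0) == pytest.approx(5.0)
        assert noise_floor_signal(0.0, 3.0) == pytest.approx(3.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(S=st.floats(0, 1e3), Snf=st.floats(0, 1e3))
    def test_euclidean_norm_property(self, S, Snf):
        out = noise_floor_signal(S, Snf)
        assert out == pytest.approx(np.hypot(S, Snf))
        assert out >= max(S, Snf) - 1e-12
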