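"""Forward-model correctness: lineshapes, saturation, SPGR, bSSFP, oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from qmtpipe.signal_models import (
    AcquisitionSpec,
    TwoPoolParams,
    bloch_mcconnell_batch,
    bloch_mcconnell_steady_state,
    bssfp_two_pool_signal,
    default_protocol,
    lineshape_value,
    mean_saturation_rate,
    protocol_arrays,
    spgr_signal,
)
from qmtpipe.signal_models import _bssfp_signal_arrays


def single_pool_bssfp(m0, t1, t2, alpha_rad, tr_s):
    e1, e2 = math.exp(-tr_s / t1), math.exp(-tr_s / t2)
    return (
        m0 * math.sin(alpha_rad) * (1 - e1)
        / (1 - (e1 - e2) * math.cos(alpha_rad) - e1 * e2)
    )


class TestLineshape:
    def test_gaussian_zero_offset_closed_form(self):
        val = lineshape_value("gaussian", 12e-6, 0.0)
        assert val == pytest.approx(12e-6 / math.sqrt(2 * math.pi), rel=1e-12)

    @pytest.mark.parametrize("shape", ["gaussian", "super_lorentzian"])
    def test_vanishes_far_off_resonance(self, shape):
        near = lineshape_value(shape, 12e-6, 2e3)
        far = lineshape_value(shape, 12e-6, 2e6)
        assert far < 1e-4 * near

    def test_super_lorentzian_matches_fine_grid_quadrature(self):
        # independent oracle: dense trapezoidal rule over fiber orientation
        t2b, offset = 12e-6, 1e4
        theta = np.linspace(0.0, math.pi / 2, 2_000_001)[1:]  # skip theta=0 (u=2, fine anyway)
        u = np.abs(3 * np.cos(theta) ** 2 - 1)
        integrand = (
            np.sin(theta) * math.sqrt(2 / math.pi) * (t2b / u)
            * np.exp(-2 * (2 * math.pi * offset * t2b / u) ** 2)
        )
        oracle = np.trapezoid(integrand, theta)
        val = lineshape_value("super_lorentzian", t2b, offset)
        assert val == pytest.approx(oracle, rel=1e-4)

    def test_invalid_t2b_raises(self):
        with pytest.raises(ValueError):
            lineshape_value("gaussian", -1e-6, 0.0)


class TestSaturationRate:
    def test_rectangular_rms_amplitude(self):
        seq = AcquisitionSpec(kind="bssfp", flip_angle=35.0, tr=4.81, trf=1.0)
        ctx = mean_saturation_rate(seq)
        assert ctx.omega1_rms == pytest.approx(math.radians(35.0) / 1e-3, rel=1e-12)

    def test_doubling_trf_quarters_w(self):
        s1 = AcquisitionSpec(kind="bssfp", flip_angle=30.0, tr=5.0, trf=1.0)
        s2 = AcquisitionSpec(kind="bssfp", flip_angle=30.0, tr=5.0, trf=2.0)
        w1 = mean_saturation_rate(s1).w
        w2 = mean_saturation_rate(s2).w
        assert w2 == pytest.approx(w1 / 4.0, rel=1e-12)

    def test_w_equals_independent_arithmetic(self):
        seq = AcquisitionSpec(kind="bssfp", flip_angle=40.0, tr=4.0, trf=0.5)
        ctx = mean_saturation_rate(seq, "gaussian", 12e-6)
        omega1 = math.radians(40.0) / 0.5e-3
        g0 = 12e-6 / math.sqrt(2 * math.pi)
        assert ctx.w == pytest.approx(math.pi * omega1**2 * g0, rel=1e-12)

    def test_spgr_has_no_saturation_context(self):
        seq = AcquisitionSpec(kind="spgr", flip_angle=15.0, tr=30.0)
        with pytest.raises(ValueError):
            mean_saturation_rate(seq)


class TestSpgr:
    def test_signal_maximized_at_ernst_angle(self):
        tr, t1 = 30.0, 1.0
        ernst = math.degrees(math.acos(math.exp(-tr * 1e-3 / t1)))
        res = optimize.minimize_scalar(
            lambda a: -spgr_signal(1.0, t1, AcquisitionSpec("spgr", a, tr)),
            bounds=(1.0, 89.0), method="bounded",
        )
        assert res.x == pytest.approx(ernst, abs=1e-3)

    def test_matches_spoiled_bloch_simulation(self):
        # time-stepping oracle: rotate, relax over TR, spoil transverse
        tr_s, t1, alpha = 0.030, 1.0, math.radians(15.0)
        e1 = math.exp(-tr_s / t1)
        mz = 1.0
        for _ in range(3000):
            mxy = mz * math.sin(alpha)
            mz = 1.0 + (mz * math.cos(alpha) - 1.0) * e1
        model = spgr_signal(1.0, t1, AcquisitionSpec("spgr", 15.0, 30.0))
        assert model == pytest.approx(mxy, rel=1e-3)

    def test_invalid_t1_raises(self):
        with pytest.raises(ValueError):
            spgr_signal(1.0, -1.0, AcquisitionSpec("spgr", 15.0, 30.0))


class TestTwoPoolBssfp:
    def test_single_pool_limit_machine_precision(self, reference_seq):
        p = TwoPoolParams(m0=1000.0, f=0.0, kf=0.0, t1f=1.0, t2f=0.08)
        ref = single_pool_bssfp(1000.0, 1.0, 0.08, reference_seq.flip_rad, 4.81e-3)
        assert bssfp_two_pool_signal(p, reference_seq) == pytest.approx(ref, rel=1e-9)

    def test_stronger_saturation_lowers_signal(self, gray_tissue):
        # shrinking trf at fixed flip raises the per-pulse saturation
        signals = [
            bssfp_two_pool_signal(
                gray_tissue,
                AcquisitionSpec(kind="bssfp", flip_angle=35.0, tr=4.81, trf=trf),
            )
            for trf in (2.0, 1.0, 0.5, 0.25)
        ]
        assert all(a > b for a, b in zip(signals, signals[1:]))

    def test_signal_linear_in_m0(self, gray_tissue, reference_seq):
        s1 = bssfp_two_pool_signal(gray_tissue, reference_seq)
        p2 = TwoPoolParams(
            m0=gray_tissue.m0 * 3.5, f=gray_tissue.f, kf=gray_tissue.kf,
            t1f=gray_tissue.t1f, t2f=gray_tissue.t2f,
        )
        assert bssfp_two_pool_signal(p2, reference_seq) == pytest.approx(3.5 * s1, rel=1e-12)

    def test_signal_non_increasing_in_w(self, gray_tissue, reference_seq):
        arrs = protocol_arrays([reference_seq])
        w_grid = np.linspace(0.0, 3000.0, 20)
        sig = _bssfp_signal_arrays(
            gray_tissue.m0, gray_tissue.f, gray_tissue.kf, gray_tissue.t1f,
            gray_tissue.t1b, gray_tissue.t2f, w_grid,
            reference_seq.flip_rad, 4.81e-3, 1.15e-3,
        )
        assert np.all(np.diff(sig) <= 1e-12)

    def test_invalid_parameters_raise(self, reference_seq):
        with pytest.raises(ValueError):
            TwoPoolParams(f=1.2)
        with pytest.raises(ValueError):
            TwoPoolParams(kf=-1.0)

    @settings(max_examples=25, deadline=None)
    @given(
        f=st.floats(0.02, 0.3),
        kf=st.floats(0.5, 8.0),
        t2f=st.floats(0.03, 0.15),
        flip=st.floats(5.0, 40.0),
    )
    def test_positive_over_physiological_range(self, f, kf, t2f, flip):
        seq = AcquisitionSpec(kind="bssfp", flip_angle=flip, tr=4.81, trf=1.15)
        p = TwoPoolParams(m0=1000.0, f=f, kf=kf, t1f=1.0, t2f=t2f)
        assert bssfp_two_pool_signal(p, seq) > 0.0


class TestBlochMcConnellOracle:
    def test_single_pool_limit(self, reference_seq):
        p = TwoPoolParams(m0=1000.0, f=0.0, kf=0.0, t1f=1.0, t2f=0.08)
        ref = single_pool_bssfp(1000.0, 1.0, 0.08, reference_seq.flip_rad, 4.81e-3)
        sim = bloch_mcconnell_steady_state(p, reference_seq)
        assert sim == pytest.approx(ref, rel=1e-3)

    def test_step_halving_consistency(self, gray_tissue, reference_seq):
        trf_s = reference_seq.trf * 1e-3
        s1 = bloch_mcconnell_steady_state(gray_tissue, reference_seq, dt=trf_s / 20)
        s2 = bloch_mcconnell_steady_state(gray_tissue, reference_seq, dt=trf_s / 40)
        s3 = bloch_mcconnell_steady_state(gray_tissue, reference_seq, dt=trf_s / 80)
        # RK4: halving dt shrinks the step error ~16x
        assert abs(s2 - s3) <= abs(s1 - s2) + 1e-9 * gray_tissue.m0

    def test_invariant_to_initial_state(self, gray_tissue, reference_seq):
        s_eq = bloch_mcconnell_steady_state(gray_tissue, reference_seq)
        s_alt = bloch_mcconnell_steady_state(
            gray_tissue, reference_seq, x0=[200.0, -100.0, 40.0]
        )
        assert s_alt == pytest.approx(s_eq, rel=1e-6)

    def test_closed_form_agrees_on_physiological_samples(self, gray_tissue):
        # spot-check both protocol regimes; the full grid runs in the
        # acceptance suite
        for seq in (
            AcquisitionSpec(kind="bssfp", flip_angle=10.0, tr=4.81, trf=1.15),
            AcquisitionSpec(kind="bssfp", flip_angle=35.0, tr=5.96, trf=2.53),
        ):
            cf = bssfp_two_pool_signal(gray_tissue, seq)
            bm = bloch_mcconnell_steady_state(gray_tissue, seq)
            assert cf == pytest.approx(bm, rel=1e-2)

    def test_batch_matches_scalar(self, reference_seq):
        fs = np.array([0.05, 0.2])
        batch = bloch_mcconnell_batch(
            1000.0, fs, np.array([2.0, 4.0]), 1.0, 1.0, np.array([0.06, 0.09]),
            reference_seq,
        )
        for i, (f, kf, t2f) in enumerate([(0.05, 2.0, 0.06), (0.2, 4.0, 0.09)]):
            p = TwoPoolParams(m0=1000.0, f=f, kf=kf, t1f=1.0, t2f=t2f)
            # batch stops when the slowest member converges, so individual
            # entries may differ from scalar runs by ~ the tolerance
            assert batch[i] == pytest.approx(
                bloch_mcconnell_steady_state(p, reference_seq), rel=1e-6
            )


class TestProtocol:
    def test_default_protocol_composition(self, protocol):
        bssfp = [s for s in protocol if s.kind == "bssfp"]
        spgr = [s for s in protocol if s.kind == "spgr"]
        assert len(bssfp) == 22 and len(spgr) == 3
        flips = {s.flip_angle for s in bssfp}
        assert min(flips) == 5.0 and max(flips) == 40.0
        trs = [s.tr for s in bssfp]
        assert min(trs) == pytest.approx(3.66) and max(trs) == pytest.approx(5.96)
        assert [s.flip_angle for s in spgr] == [5.0, 15.0, 25.0]

    def test_acquisition_validation(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(kind="bssfp", flip_angle=35.0, tr=4.0, trf=5.0)
        with pytest.raises(ValueError):
            AcquisitionSpec(kind="bssfp", flip_angle=120.0, tr=4.0, trf=1.0)
        # spgr may omit trf
        AcquisitionSpec(kind="spgr", flip_angle=15.0, tr=30.0)
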