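"""4-phase rhinomanometry: resistances, classification, overlay, I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhinoflow.fourphase import (
    FourPhaseRecording,
    OverlayPoint,
    Phase,
    Side,
    analyze,
    classify_resistance,
    combined_log_resistance,
    effective_resistance,
    load_recording,
    log_effective_resistance,
    overlay_data,
    save_recording,
    vertex_resistance,
)
from rhinoflow.phantoms.waveform import make_4pr_waveform


def sinusoid_recording(ratio=2.0, n=201, T=4.0, peak=300.0):
    t = np.linspace(0.0, T, n)
    vdot = peak * np.sin(2 * np.pi * t / T)
    return FourPhaseRecording(Side.LEFT, t, ratio * vdot, vdot)


class TestRecordingIO:
    def test_csv_roundtrip_identity(self, tmp_path):
        rec, _ = make_4pr_waveform(0.3, noise=0.05, seed=7)
        p = tmp_path / "rec.csv"
        save_recording(rec, p)
        back = load_recording(p, Side.TOTAL)
        np.testing.assert_allclose(back.t, rec.t, rtol=0, atol=1e-12)
        np.testing.assert_allclose(back.delta_p, rec.delta_p, rtol=1e-12)
        np.testing.assert_allclose(back.vdot, rec.vdot, rtol=1e-12)

    def test_four_row_csv_duration(self, tmp_path):
        p = tmp_path / "r.csv"
        pd.DataFrame(
            {"time_s": [0, 1, 2, 3], "delta_p_pa": [0, 1, 0, -1], "vdot_cm3s": [0, 10, 0, -10]}
        ).to_csv(p, index=False)
        rec = load_recording(p, "left")
        assert rec.T == 3.0

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError, match="non-monotone"):
            FourPhaseRecording(Side.LEFT, [0, 1, 1, 2], [0, 0, 0, 0], [1, 1, 1, 1])

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"time_s": [0, 1, 2, 3], "delta_p_pa": [0, 1, 0, 1]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="missing column"):
            load_recording(p, "left")


class TestEffectiveResistance:
    def test_constant_ratio_conventions_differ(self):
        # dp = 2*vdot: the RMS ratio gives 2, the printed integral sqrt(2);
        # this pins down the deliberate two-convention design.
        rec = sinusoid_recording(ratio=2.0)
        assert effective_resistance(rec, "rms_ratio") == pytest.approx(2.0, rel=1e-9)
        assert effective_resistance(rec, "printed_integral") == pytest.approx(
            math.sqrt(2.0), rel=1e-9
        )

    def test_proportional_waveforms(self):
        t = np.linspace(0, 4, 301)
        vd = 1.5 * np.sin(2 * np.pi * t / 4)
        rec = FourPhaseRecording(Side.LEFT, t, 3.0 * np.sin(2 * np.pi * t / 4), vd)
        assert effective_resistance(rec, "rms_ratio") == pytest.approx(2.0, rel=1e-9)

    def test_random_cycle_matches_dense_riemann_oracle(self):
        rng = np.random.default_rng(42)
        T = 4.0
        n = 4001
        t = np.linspace(0, T, n)
        # smooth random cycle built from a few harmonics
        vd = 300 * np.sin(2 * np.pi * t / T) + 40 * np.sin(4 * np.pi * t / T + 0.3)
        dp = 0.4 * vd + 0.05 * np.abs(vd) * np.sin(2 * np.pi * t / T)
        rec = FourPhaseRecording(Side.LEFT, t, dp, vd)
        # independent dense Riemann-sum oracle
        dt = t[1] - t[0]
        rms_dp = math.sqrt(np.sum(((dp[:-1] + dp[1:]) / 2) ** 2 * dt) / T)
        rms_vd = math.sqrt(np.sum(((vd[:-1] + vd[1:]) / 2) ** 2 * dt) / T)
        assert effective_resistance(rec, "rms_ratio") == pytest.approx(
            rms_dp / rms_vd, rel=1e-6
        )

    def test_degenerate_recording_rejected(self):
        t = np.linspace(0, 4, 10)
        with pytest.raises(ValueError, match="degenerate"):
            effective_resistance(
                FourPhaseRecording(Side.LEFT, t, np.ones(10), np.zeros(10)), "rms_ratio"
            )

    def test_sign_flip_invariance(self):
        rec = sinusoid_recording(ratio=0.7)
        flipped = FourPhaseRecording(rec.side, rec.t, -rec.delta_p, -rec.vdot)
        assert effective_resistance(flipped, "rms_ratio") == pytest.approx(
            effective_resistance(rec, "rms_ratio"), rel=1e-12
        )

    def test_resampling_invariance(self):
        # Uniform re-sampling changes quadrature nodes, not the value.
        a = sinusoid_recording(ratio=1.3, n=501)
        b = sinusoid_recording(ratio=1.3, n=1501)
        assert effective_resistance(a, "rms_ratio") == pytest.approx(
            effective_resistance(b, "rms_ratio"), rel=1e-4
        )


class TestVertexResistance:
    def test_proportional_cycle_both_phases(self):
        rec = sinusoid_recording(ratio=2.0)
        assert vertex_resistance(rec, Phase.INSPIRATION) == pytest.approx(2.0)
        assert vertex_resistance(rec, Phase.EXPIRATION) == pytest.approx(2.0)

    def test_triangular_inspiration_peak(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        vd = np.array([0.0, 100.0, 200.0, 100.0, 0.0])
        dp = np.array([0.0, 4.0, 8.0, 4.0, 0.0])
        rec = FourPhaseRecording(Side.LEFT, t, dp, vd)
        assert vertex_resistance(rec, "inspiration") == pytest.approx(0.04)

    def test_matches_argmax_scan_oracle(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 4, 200)
        vd = 300 * np.sin(2 * np.pi * t / 4) + 30 * np.sin(6 * np.pi * t / 4)
        dp = 0.3 * vd + 10 * np.sin(2 * np.pi * t / 4) ** 3
        rec = FourPhaseRecording(Side.LEFT, t, dp, vd)
        # exhaustive scan oracle
        best, val = None, -1.0
        for k in range(len(t)):
            if vd[k] > 0 and abs(vd[k]) > val:
                best, val = k, abs(vd[k])
        assert vertex_resistance(rec, "inspiration") == pytest.approx(dp[best] / vd[best])

    def test_absent_phase_errors(self):
        t = np.linspace(0, 4, 10)
        vd = np.full(10, 100.0)
        with pytest.raises(ValueError, match="absent"):
            vertex_resistance(FourPhaseRecording(Side.LEFT, t, vd, vd), "expiration")


class TestLogsAndClassification:
    @pytest.mark.parametrize(
        "r, expected",
        [(0.1, 0.0), (1.0, 1.0), (0.5689, math.log10(5.689))],
    )
    def test_log_effective_resistance(self, r, expected):
        assert log_effective_resistance(r) == pytest.approx(expected, abs=1e-12)

    def test_log_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log_effective_resistance(0.0)

    def test_combined_equal_sides(self):
        assert combined_log_resistance(0.2, 0.2) == pytest.approx(0.0, abs=1e-12)

    def test_combined_one_side_blocked_limit(self):
        assert combined_log_resistance(1e12, 0.3) == pytest.approx(
            math.log10(10 * 0.3), abs=1e-9
        )

    def test_combined_matches_parallel_resistance_oracle(self):
        r_l, r_r = 0.3, 0.7
        r_par = 1.0 / (1.0 / r_l + 1.0 / r_r)
        assert combined_log_resistance(r_l, r_r) == pytest.approx(
            math.log10(10 * r_par), abs=1e-12
        )

    def test_parallel_identity_equal_sides(self):
        # LR_eff^2(r, r) = LR_eff^1(r) - log10(2) exactly
        for r in (0.1, 0.37, 2.0):
            assert combined_log_resistance(r, r) == pytest.approx(
                log_effective_resistance(r) - math.log10(2), abs=1e-12
            )

    @pytest.mark.parametrize(
        "lr, expected",
        [(0.5, 1), (0.755, 1), (0.93, 2), (0.97, 3), (1.2, 4), (1.365, 4), (1.40, 5)],
    )
    def test_one_sided_classes(self, lr, expected):
        cls = classify_resistance(lr, "one")
        assert cls.number == expected

    def test_class_labels(self):
        assert classify_resistance(0.5, "one").label == "very low"
        assert classify_resistance(1.40, "one").label == "very high"

    def test_two_sided_table_runs(self):
        assert classify_resistance(0.4, "two").number == 1
        assert classify_resistance(2.0, "two").number == 5

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_resistance(float("nan"), "one")

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.floats(-1.0, 3.0, allow_nan=False),
        b=st.floats(-1.0, 3.0, allow_nan=False),
    )
    def test_classifier_monotone_and_total(self, a, b):
        lo, hi = sorted((a, b))
        ca = classify_resistance(lo, "one").number
        cb = classify_resistance(hi, "one").number
        assert 1 <= ca <= 5 and 1 <= cb <= 5
        assert ca <= cb


class TestOverlay:
    def test_measurement_only(self):
        insp, exp = make_4pr_waveform(0.3, seed=0)
        df = overlay_data(insp, exp, [])
        assert set(df["source"]) == {"measurement"}
        assert len(df) == len(insp.t) + len(exp.t)

    def test_sim_points_appended(self):
        insp, exp = make_4pr_waveform(0.3, seed=0)
        pts = [OverlayPoint(20.0, 250.0), OverlayPoint(-18.0, -250.0)]
        df = overlay_data(insp, exp, pts)
        assert (df["source"] == "simulation").sum() == 2
        assert len(df) == len(insp.t) + len(exp.t) + 2

    def test_unsteady_sim_point_rejected(self):
        insp, exp = make_4pr_waveform(0.3, seed=0)
        with pytest.raises(ValueError, match="Sr == 0"):
            overlay_data(insp, exp, [OverlayPoint(1.0, 1.0, sr=0.5)])


class TestWaveformPhantom:
    def test_noiseless_rms_recovery_exact(self):
        rec, _ = make_4pr_waveform(0.42, convention="rms")
        assert effective_resistance(rec, "rms_ratio") == pytest.approx(0.42, rel=1e-9)

    def test_noiseless_printed_recovery_exact(self):
        rec, _ = make_4pr_waveform(0.42, convention="printed")
        assert effective_resistance(rec, "printed_integral") == pytest.approx(
            0.42, rel=1e-6
        )

    def test_seed_determinism(self):
        a, _ = make_4pr_waveform(0.3, noise=0.05, seed=11)
        b, _ = make_4pr_waveform(0.3, noise=0.05, seed=11)
        np.testing.assert_array_equal(a.delta_p, b.delta_p)

    def test_analyze_full_result(self):
        rec, _ = make_4pr_waveform(0.3, convention="rms")
        res = analyze(rec)
        assert res.r_eff == pytest.approx(0.3, rel=1e-9)
        assert res.obstruction_class == classify_resistance(res.lr_eff_1, "one").number
        assert res.vr_insp == pytest.approx(0.3, rel=1e-9)
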