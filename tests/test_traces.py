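import numpy as np
import pytest

from unzipmap.elastic import ElasticTables
from unzipmap.simulate import TraceSignatureModel, render_trace
from unzipmap.traces import (
    PeakCall,
    ProcessedTrace,
    Thresholds,
    Trace,
    align_to_theory,
    bp_from_force_extension,
    call_interactions,
    correct_transcript_annealing,
    decimate,
    detect_tether_shortening,
)


def _make_trace(n=1000, rate=10_000.0, force=15.0, ext0=250.0):
    t = np.arange(1, n + 1) / rate
    return Trace(
        time_s=t,
        force_pN=np.full(n, force),
        extension_nm=ext0 + 0.05 * np.arange(n),
        rate_hz=rate,
    )


class TestDecimate:
    def test_constant_series_unchanged(self):
        tr = decimate(_make_trace(force=12.0), 1000.0)
        assert np.allclose(tr.force_pN, 12.0)
        assert tr.rate_hz == 1000.0

    def test_sine_equals_brute_force_block_means(self):
        n, factor = 5000, 10
        t = np.arange(1, n + 1) / 10_000.0
        f = 15 + np.sin(2 * np.pi * 40 * t)
        tr = Trace(t, f, 250 + 0.05 * np.arange(n), 10_000.0)
        out = decimate(tr, 1000.0)
        expected = f[: (n // factor) * factor].reshape(-1, factor).mean(axis=1)
        assert np.allclose(out.force_pN, expected)
        assert len(out.time_s) == n // factor

    def test_factor_one_is_identity(self):
        tr = _make_trace()
        assert decimate(tr, 10_000.0) is tr

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            decimate(_make_trace(), 3000.0)


class TestBpConversion:
    def test_forward_model_inversion(self, construct, elastic, tables):
        """Oracle: build extension from known fork positions via the forward
        model, then require the inversion to recover them to 0.1 bp."""
        j_true = np.linspace(50, 500, 200)
        f = np.full_like(j_true, 14.5)
        ext = construct.arm_bp * tables.ds_at(f) + 2 * j_true * tables.ss_at(f)
        tr = Trace(np.arange(1, 201) / 1e3, f, ext, 1000.0)
        pt = bp_from_force_extension(tr, elastic, construct, tables=tables)
        assert np.all(np.abs(pt.bp_unzipped - j_true) < 0.1)

    def test_arms_only_extension_gives_zero(self, construct, elastic, tables):
        f = np.array([12.0, 15.0, 18.0])
        ext = construct.arm_bp * tables.ds_at(f)
        tr = Trace(np.arange(1, 4) / 1e3, f, ext, 1000.0)
        pt = bp_from_force_extension(tr, elastic, construct, tables=tables)
        assert np.all(np.abs(pt.bp_unzipped) < 0.01)

    def test_monotone_extension_gives_monotone_bp(self, construct, elastic, tables):
        n = 100
        f = np.full(n, 15.0)
        ext = construct.arm_bp * tables.ds_at(15.0) + np.linspace(0, 400, n)
        tr = Trace(np.arange(1, n + 1) / 1e3, f, ext, 1000.0)
        pt = bp_from_force_extension(tr, elastic, construct, tables=tables)
        assert np.all(np.diff(pt.bp_unzipped) > 0)

    def test_low_force_masked(self, construct, elastic, tables):
        f = np.array([1.0, 2.0, 15.0])
        ext = construct.arm_bp * tables.ds_at(f)
        tr = Trace(np.arange(1, 4) / 1e3, f, ext, 1000.0)
        pt = bp_from_force_extension(tr, elastic, construct, tables=tables)
        assert len(pt.force_pN) == 1


def _rendered(category, construct, thermo, elastic, tables, schedule, seed, **sig_kw):
    sig = TraceSignatureModel(**sig_kw)
    rng = np.random.default_rng(seed)
    tr, truth = render_trace(
        category, construct, sig, thermo, elastic, rng, tables=tables, schedule=schedule
    )
    return decimate(tr, 1000.0), truth


class TestAlignment:
    def test_known_shift_recovered(
        self, construct, thermo, elastic, tables, theory, schedule
    ):
        tr, _ = _rendered("Nak", construct, thermo, elastic, tables, schedule, 5)
        pt = bp_from_force_extension(tr, elastic, construct, tables=tables)
        shifted = ProcessedTrace(pt.bp_unzipped - 5.0, pt.force_pN)
        out = align_to_theory(shifted, theory)
        assert out.offset_bp == pytest.approx(5.0, abs=0.5)
        assert not out.alignment_failed

    def test_already_aligned_identity(
        self, construct, thermo, elastic, tables, theory, schedule
    ):
        tr, _ = _rendered("Nak", construct, thermo, elastic, tables, schedule, 6)
        pt = bp_from_force_extension(tr, elastic, construct, tables=tables)
        out = align_to_theory(pt, theory)
        assert abs(out.offset_bp) <= 0.5
        assert abs(out.scale - 1.0) <= 0.005

    def test_pure_noise_trace_flagged(self, theory, rng):
        pt = ProcessedTrace(
            bp_unzipped=np.linspace(0, 500, 2000),
            force_pN=15.0 + rng.normal(0, 3.0, 2000),
        )
        out = align_to_theory(pt, theory)
        assert out.alignment_failed

    def test_insufficient_overlap_rejected(self, theory):
        pt = ProcessedTrace(np.linspace(0, 50, 60), np.full(60, 15.0))
        with pytest.raises(ValueError, match="overlap"):
            align_to_theory(pt, theory)


class TestCallInteractions:
    def test_unaligned_trace_rejected(self, theory):
        pt = ProcessedTrace(np.linspace(0, 500, 100), np.full(100, 15.0))
        with pytest.raises(ValueError, match="aligned"):
            call_interactions(pt, theory)

    def test_naked_false_positive_rate(
        self, construct, thermo, elastic, tables, theory, schedule
    ):
        """Null simulation: naked traces at default noise must call a peak
        in < 5% of traces."""
        fp = 0
        n = 60
        for seed in range(n):
            tr, _ = _rendered(
                "Nak", construct, thermo, elastic, tables, schedule, 1000 + seed
            )
            pt = align_to_theory(
                bp_from_force_extension(tr, elastic, construct, tables=tables), theory
            )
            if call_interactions(pt, theory):
                fp += 1
        assert fp / n < 0.05

    def test_cooccupied_trace_two_rises(
        self, construct, thermo, elastic, tables, theory, schedule
    ):
        tr, truth = _rendered(
            "A20_dCas", construct, thermo, elastic, tables, schedule, 7
        )
        pt = align_to_theory(
            bp_from_force_extension(tr, elastic, construct, tables=tables), theory
        )
        rises = [c for c in call_interactions(pt, theory) if c.sign == "rise"]
        assert len(rises) == 2
        for call, true_pos in zip(rises, sorted(truth.rise_positions)):
            assert call.position_bp == pytest.approx(true_pos, abs=3.0)

    def test_distal_dcas_dip_precedes_rise(
        self, construct, thermo, elastic, tables, theory, schedule
    ):
        """Unzipping into the PAM-distal side: the R-loop bubble dips the
        force before the clamp rise, starting upstream of the hybrid
        (thermal breathing)."""
        from unzipmap.traces import bin_by_bp

        tr, _ = _rendered("dCas_only", construct, thermo, elastic, tables, schedule, 8)
        pt = align_to_theory(
            bp_from_force_extension(tr, elastic, construct, tables=tables), theory
        )
        calls = call_interactions(pt, theory)
        dips = [c for c in calls if c.sign == "dip"]
        rises = [c for c in calls if c.sign == "rise"]
        assert len(dips) == 1 and len(rises) >= 1
        assert dips[0].position_bp < min(r.position_bp for r in rises)
        # thermal breathing: the force already softens upstream of the hybrid
        centers, force = bin_by_bp(pt)
        dev = force - theory.baseline_force(centers)
        lo = construct.rloop_window[0]
        ahead = dev[(centers >= lo - 5.0) & (centers < lo)]
        assert ahead.size and ahead.mean() < -0.3

    def test_alignment_equivariance(
        self, construct, thermo, elastic, tables, theory, schedule
    ):
        """Shifting a processed trace and realigning yields identical calls."""
        tr, _ = _rendered("A20_dCas", construct, thermo, elastic, tables, schedule, 9)
        pt = bp_from_force_extension(tr, elastic, construct, tables=tables)
        a = align_to_theory(pt, theory)
        shifted = ProcessedTrace(pt.bp_unzipped + 7.0, pt.force_pN)
        b = align_to_theory(shifted, theory)
        calls_a = call_interactions(a, theory)
        calls_b = call_interactions(b, theory)
        assert [(c.sign, c.position_bp) for c in calls_a] == [
            (c.sign, c.position_bp) for c in calls_b
        ]


class TestAnnealingCorrection:
    def test_no_shortening_is_noop(self, rng):
        pt = ProcessedTrace(np.linspace(0, 500, 2000), 15 + rng.normal(0, 0.2, 2000))
        calls = [PeakCall(447.0, "rise", 8.0, 6.0)]
        out, shift = correct_transcript_annealing(pt, calls)
        assert shift == 0.0
        assert out == calls

    def test_injected_shortening_corrects_dcas_call(self, rng):
        """Oracle: a 4-bp backward jump injected at bp 300 must shift a
        downstream dCas call by 4 ± 1 bp."""
        bp = np.linspace(0, 500, 2000)
        bp[bp > 300] -= 4.0
        pt = ProcessedTrace(bp, 15 + rng.normal(0, 0.1, 2000))
        events = detect_tether_shortening(pt)
        assert len(events) == 1
        assert events[0].magnitude_bp == pytest.approx(4.0, abs=1.0)
        calls = [PeakCall(443.0, "rise", 8.0, 6.0)]
        out, shift = correct_transcript_annealing(
            pt, calls, dcas_window=(429, 449), events=events
        )
        assert out[0].position_bp == pytest.approx(447.0, abs=1.0)
        assert shift == pytest.approx(4.0, abs=1.0)

    def test_shortening_after_last_call_no_change(self, rng):
        bp = np.linspace(0, 500, 2000)
        bp[bp > 480] -= 4.0
        pt = ProcessedTrace(bp, 15 + rng.normal(0, 0.1, 2000))
        calls = [PeakCall(440.0, "rise", 8.0, 6.0)]
        out, _ = correct_transcript_annealing(pt, calls, dcas_window=(429, 449))
        assert out[0].position_bp == 440.0


def test_trace_validation():
    with pytest.raises(ValueError, match="equal length"):
        Trace(np.array([0.1, 0.2]), np.array([1.0]), np.array([1.0, 2.0]), 10.0)
    with pytest.raises(ValueError, match="increasing"):
        Trace(np.array([0.2, 0.1]), np.ones(2), np.ones(2), 10.0)


def test_peakcall_sign_validation():
    with pytest.raises(ValueError):
        PeakCall(10.0, "rise", -1.0, 5.0)
    with pytest.raises(ValueError):
        PeakCall(10.0, "dip", 1.0, 5.0)
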