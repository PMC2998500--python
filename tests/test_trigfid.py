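import numpy as np
import pytest

from cardiogate import siggen, trigfid
from cardiogate.exceptions import (DegenerateSignalError, InsufficientDataError,
                                   ValidationError)
from cardiogate.physio_io import ChannelTrace, TriggerTrain
from cardiogate.trigfid import (BreathHoldInterval, CycleOffsets,
                                apply_segmentation_mask, cycle_statistics,
                                failure_rate, flag_sd_ratio,
                                identify_breath_holds, load_table1,
                                reassign_tickmarks, segment_rr, trigger_jitter,
                                trigger_offset_stats)


class TestBreathHolds:
    def test_pure_breathing_no_holds(self):
        cfg = siggen.SimulationConfig(breath_hold_schedule=(), seed=0)
        resp = siggen.synthesize_respiration(cfg, 60.0)
        assert identify_breath_holds(resp) == []

    def test_single_plateau_located(self):
        cfg = siggen.SimulationConfig(breath_hold_schedule=((20.0, 12.0),), seed=0)
        resp = siggen.synthesize_respiration(cfg, 60.0)
        holds = identify_breath_holds(resp)
        assert len(holds) == 1
        assert holds[0].start == pytest.approx(20.0, abs=1.0)
        assert holds[0].end == pytest.approx(32.0, abs=1.0)

    def test_simulated_holds_within_half_second(self):
        schedule = ((5.0, 15.0), (25.0, 15.0), (45.0, 15.0))
        cfg = siggen.SimulationConfig(breath_hold_schedule=schedule, seed=1)
        resp = siggen.synthesize_respiration(cfg, 65.0)
        holds = identify_breath_holds(resp)
        assert len(holds) == 3
        for (start, dur), h in zip(schedule, holds):
            assert abs(h.start - start) <= 0.5
            assert abs(h.end - (start + dur)) <= 0.5

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            identify_breath_holds(ChannelTrace("RESP", 50.0, np.zeros(10)))

    def test_interval_invariant(self):
        with pytest.raises(ValidationError):
            BreathHoldInterval(5.0, 5.0)


def _clean_session(n_cycles=30, seed=0, rr_sd=50.0):
    cfg = siggen.SimulationConfig(n_cycles=n_cycles, rr_mean=900.0, rr_sd=rr_sd,
                                  seed=seed)
    return cfg, *siggen.simulate_session_with_truth(cfg)


class TestSegmentation:
    def test_periodic_noise_free_zero_shifts(self):
        cfg = siggen.SimulationConfig(n_cycles=20, rr_mean=900.0, rr_sd=0.0, seed=0)
        sch = siggen.draw_cycle_schedule(cfg)
        ecg = siggen.synthesize_ecg(sch, cfg)
        seg = segment_rr(ecg, [])
        assert np.allclose(seg.shifts, 0.0, atol=1e-9)

    def test_constant_ecg_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            segment_rr(ChannelTrace("ECG", 400.0, np.zeros(4000)), [])

    def test_too_few_cycles(self):
        cfg = siggen.SimulationConfig(n_cycles=1, seed=0)
        sch = siggen.draw_cycle_schedule(cfg)
        ecg = siggen.synthesize_ecg(sch, cfg, duration=2.0)
        with pytest.raises(InsufficientDataError):
            segment_rr(ecg, [])

    def test_reference_is_first_hold_cycle(self):
        cfg, log, truth = _clean_session()
        holds = identify_breath_holds(log.channel("RESP"))
        seg = segment_rr(log.channel("ECG"), holds)
        assert seg.reference == tuple(seg.cycles[0])
        assert holds[0].contains(seg.cycles[0][0])

    def test_shifts_match_brute_force(self):
        # exhaustive oracle over all admissible integer shifts
        cfg, log, truth = _clean_session(n_cycles=15, seed=7)
        holds = identify_breath_holds(log.channel("RESP"))
        seg = segment_rr(log.channel("ECG"), holds)
        oracle = _brute_force_shifts(log.channel("ECG"), seg)
        np.testing.assert_allclose(seg.shifts, oracle, atol=1e-9)


def _brute_force_shifts(ecg, seg):
    """Independent exhaustive realignment search (np.corrcoef based)."""
    rate = ecg.rate
    ref = seg.reference
    ref_i0 = int(round((ref[0] - ecg.t0) * rate))
    ref_len = min(int(round((ref[1] - ref[0]) * rate)),
                  int(round(trigfid.CORR_WINDOW_S * rate)))
    ref_seg = ecg.samples[ref_i0:ref_i0 + ref_len]
    max_shift = int(round(trigfid.MAX_SHIFT_S * rate))
    ref_snap = ref_i0 / rate + ecg.t0 - ref[0]
    out = np.zeros(seg.n)
    for ci, (start, end) in enumerate(seg.cycles):
        if (start, end) == tuple(ref):
            continue
        i0 = int(round((start - ecg.t0) * rate))
        candidates = {}
        for sh in range(-max_shift, max_shift + 1):
            lo = i0 + sh
            if lo < 0 or lo + ref_len > ecg.samples.size:
                continue
            candidates[sh] = np.corrcoef(ref_seg, ecg.samples[lo:lo + ref_len])[0, 1]
        best = max(candidates, key=candidates.get)
        snap = i0 / rate + ecg.t0 - start
        out[ci] = -(best / rate + snap - ref_snap) * 1000.0
    return out


class TestMask:
    def test_mask_on_ecg_never_degrades_correlation(self):
        # realigned excerpts correlate with the reference at least as well
        # as the unshifted ones (definition of the maximization)
        cfg, log, truth = _clean_session(seed=3)
        holds = identify_breath_holds(log.channel("RESP"))
        ecg = log.channel("ECG")
        seg = segment_rr(ecg, holds)
        tau, shifted = apply_segmentation_mask(seg, ecg)
        unshifted_seg = trigfid.CycleSegmentation(
            reference=seg.reference, cycles=seg.cycles,
            shifts=np.zeros(seg.n), rate=seg.rate)
        _, unshifted = apply_segmentation_mask(unshifted_seg, ecg)
        ref = shifted[0]
        c_shift = np.mean([np.corrcoef(ref, e)[0, 1] for e in shifted[1:]])
        c_raw = np.mean([np.corrcoef(ref, e)[0, 1] for e in unshifted[1:]])
        assert c_shift >= c_raw - 1e-3

    def test_constant_trace_constant_excerpts(self):
        cfg, log, truth = _clean_session()
        holds = identify_breath_holds(log.channel("RESP"))
        seg = segment_rr(log.channel("ECG"), holds)
        const = ChannelTrace("POX", 50.0, np.full(int(50 * log.channel("ECG").duration), 2.5))
        tau, excerpts = apply_segmentation_mask(seg, const)
        for exc in excerpts:
            assert np.allclose(exc, 2.5)

    def test_disjoint_trace_rejected(self):
        cfg, log, truth = _clean_session()
        holds = identify_breath_holds(log.channel("RESP"))
        seg = segment_rr(log.channel("ECG"), holds)
        far = ChannelTrace("POX", 50.0, np.zeros(100), t0=10000.0)
        with pytest.raises(ValidationError):
            apply_segmentation_mask(seg, far)

    def test_act_excerpt_s1_phase_consistent(self):
        cfg, log, truth = _clean_session(seed=5)
        holds = identify_breath_holds(log.channel("RESP"))
        seg = segment_rr(log.channel("ECG"), holds)
        tau, excerpts = apply_segmentation_mask(seg, log.channel("ACT"))
        peaks = [tau[np.argmax(np.abs(e[: int(0.25 * trigfid.OVERLAY_RATE)]))]
                 for e in excerpts]
        # S1 envelope peaks occupy the same within-cycle phase (up to the
        # drawn onset-delay scatter plus one ACT sample)
        assert np.std(peaks) * 1000 < cfg.r_to_s1_sd * 3 + 5.0


class TestReassignment:
    def _seg(self, r_times):
        cycles = [(r_times[i], r_times[i + 1]) for i in range(len(r_times) - 1)]
        return trigfid.CycleSegmentation(reference=cycles[0], cycles=cycles,
                                         shifts=np.zeros(len(cycles)), rate=400.0)

    def test_ticks_at_r_zero_offsets(self):
        r = np.arange(10) * 0.9 + 1.0
        seg = self._seg(r)
        offs = reassign_tickmarks(seg, TriggerTrain("ECG", r[:-1]))
        np.testing.assert_allclose(offs.finite, 0.0, atol=1e-6)

    def test_constant_30ms_offsets(self):
        r = np.arange(10) * 0.9 + 1.0
        seg = self._seg(r)
        offs = reassign_tickmarks(seg, TriggerTrain("ACT", r[:-1] + 0.030))
        np.testing.assert_allclose(offs.finite, 30.0, atol=1e-6)

    def test_matches_containment_brute_force(self):
        rng = np.random.default_rng(8)
        r = np.cumsum(rng.uniform(0.7, 1.1, size=12)) + 1.0
        seg = self._seg(r)
        ticks = np.sort(rng.uniform(r[0], r[-1], size=25))
        ticks = ticks[np.r_[True, np.diff(ticks) > 0.002]]
        offs = reassign_tickmarks(seg, TriggerTrain("POX", ticks))
        # brute-force interval containment oracle (earliest tick per cycle)
        guard = trigfid.CYCLE_GUARD_S
        for i, (start, end) in enumerate(seg.cycles):
            inside = [round(t, 3) for t in ticks
                      if start - guard <= round(t, 3) < end - guard]
            if inside:
                expected = (min(inside) - start) * 1000.0
                assert offs.offsets[i] == pytest.approx(expected, abs=1e-6)
            else:
                assert np.isnan(offs.offsets[i])

    def test_missed_cycles_reported(self):
        r = np.arange(5) * 0.9 + 1.0
        seg = self._seg(r)
        offs = reassign_tickmarks(seg, TriggerTrain("ACT", [r[0] + 0.03, r[2] + 0.03]))
        assert offs.n_missed == 2


class TestStatistics:
    def test_jitter_constant_zero(self):
        assert trigger_jitter([10.0, 10.0, 10.0]) == 0.0

    def test_jitter_range(self):
        assert trigger_jitter([10.0, 40.0, 82.0]) == pytest.approx(72.0)

    def test_jitter_needs_two(self):
        with pytest.raises(InsufficientDataError):
            trigger_jitter([5.0])

    def test_cycle_statistics_exact(self):
        mean, sd = cycle_statistics(TriggerTrain("ACT", [0.0, 0.869, 1.738, 2.607]))
        assert mean == pytest.approx(869.0, abs=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_cycle_statistics_needs_three(self):
        with pytest.raises(InsufficientDataError):
            cycle_statistics(TriggerTrain("ACT", [0.0, 0.9]))

    def test_offset_stats_constant(self):
        mean, sd = trigger_offset_stats([30.0] * 5)
        assert (mean, sd) == (30.0, 0.0)

    def test_offset_stats_needs_two(self):
        with pytest.raises(InsufficientDataError):
            trigger_offset_stats([30.0])

    def test_failure_rate_tight_cluster(self):
        assert failure_rate(np.full(10, 30.0) + np.linspace(0, 5, 10)) == 0.0

    def test_failure_rate_counting(self):
        offs = np.full(10, 30.0)
        offs[:3] += 400.0
        assert failure_rate(offs) == pytest.approx(0.30)

    def test_missed_count_as_failures(self):
        offs = np.array([30.0, 30.0, 31.0, np.nan])
        assert failure_rate(offs) == pytest.approx(0.25)

    def test_failure_rate_empty(self):
        with pytest.raises(InsufficientDataError):
            failure_rate(np.array([]))

    def test_mhd_gain_sweep_monotone_in_the_mean(self):
        gains = (0.0, 0.6, 0.9, 1.2, 1.5)
        means = []
        for g in gains:
            rates = []
            for seed in range(4):
                cfg = siggen.SimulationConfig(n_cycles=100, rr_mean=900.0,
                                              rr_sd=50.0, seed=seed,
                                              field_position="isocenter",
                                              mhd_gain_at_7T=g)
                sch = siggen.draw_cycle_schedule(cfg)
                ecg = siggen.synthesize_ecg(sch, cfg)
                train = siggen.simulate_cpmu_triggers({"ECG": ecg}, "ECG", cfg)
                offs = np.full(sch.n - 1, np.nan)
                for i in range(sch.n - 1):
                    m = (train.times >= sch.r_times[i] - 0.05) & \
                        (train.times < sch.r_times[i + 1] - 0.05)
                    if m.any():
                        offs[i] = (train.times[m][0] - sch.r_times[i]) * 1000.0
                rates.append(failure_rate(offs))
            means.append(np.mean(rates))
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))


class TestSdRatioFlags:
    def test_interval_rule_counts_four(self):
        t1 = load_table1()
        assert flag_sd_ratio(t1.ecg_interval_sd, t1.act_interval_sd, 1.5) == 4

    def test_ratio_zero_counts_all(self):
        t1 = load_table1()
        assert flag_sd_ratio(t1.ecg_interval_sd, t1.act_interval_sd, 0.0) == len(t1)

    def test_offset_rule_strict_vs_nonstrict(self):
        # subject 5 sits exactly on the 4x boundary (56 = 4 * 14)
        t1 = load_table1()
        assert flag_sd_ratio(t1.ecg_offset_sd, t1.act_offset_sd, 4.0) == 5
        assert flag_sd_ratio(t1.ecg_offset_sd, t1.act_offset_sd, 4.0, strict=True) == 4


class TestPipeline:
    def test_act_jitter_small_on_clean_session(self):
        cfg = siggen.SimulationConfig(n_cycles=60, rr_mean=900.0, rr_sd=0.0,
                                      r_to_s1_sd=0.0, seed=2)
        log = siggen.simulate_session(cfg)
        stats, _ = trigfid.analyze_session(log)
        assert stats["ACT"].jitter <= 5.0

    def test_hold_gating_never_adds_cycles(self, session_200):
        cfg, log, truth = session_200
        holds = identify_breath_holds(log.channel("RESP"))
        seg_gated = segment_rr(log.channel("ECG"), holds)
        seg_all = segment_rr(log.channel("ECG"), [])
        assert seg_gated.n <= seg_all.n

    def test_full_pipeline_recovery(self, session_200):
        cfg, log, truth = session_200
        stats, per = trigfid.analyze_session(log)
        act = stats["ACT"]
        assert abs(act.offset_mean - 29.65) < 1.0
        assert abs(act.interval_mean - 900.0) < 3 * 50.0 / np.sqrt(act.n_cycles)
        assert abs(act.interval_sd - 50.0) < 15.0
        assert stats["POX"].offset_mean > 250.0
        assert stats["ECG"].failure_rate <= 0.05   # home position
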