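"""Synthetic cohort generator: schedules, physiology, waveform morphology,
artifacts and hematocrit dilution."""

import numpy as np
import pytest

from blvest.cohort import (
    BleedSegment,
    ConfigError,
    PhysioState,
    SimConfig,
    compensatory_response,
    generate_cohort,
    hct_trajectory,
    inject_artifacts,
    physio_trajectory,
    reference_blv,
    synth_abp_beat,
    synth_ppg_beat,
)

from conftest import fast_config


def _state(f=0.0, pr=72.0, sbp=120.0, dbp=80.0, amp=1.0):
    return PhysioState(blv=0.0, blv_fraction=f, pulse_rate=pr, sbp=sbp, dbp=dbp, ppg_amp_scale=amp)


class TestReferenceBLV:
    def test_single_active_segment(self):
        sched = [BleedSegment(0.0, 600.0, 20.0)]
        assert reference_blv(300.0, sched) == pytest.approx(100.0)

    def test_zero_time(self):
        sched = [BleedSegment(0.0, 600.0, 20.0)]
        assert reference_blv(0.0, sched) == 0.0

    def test_multi_segment_with_rest(self):
        sched = [
            BleedSegment(0.0, 300.0, 20.0),
            BleedSegment(300.0, 900.0, 0.0),
            BleedSegment(900.0, 1200.0, 20.0),
        ]
        assert reference_blv(1200.0, sched) == pytest.approx(200.0)
        # beyond the schedule: terminal cumulative volume
        assert reference_blv(99999.0, sched) == pytest.approx(200.0)

    def test_nondecreasing_piecewise_linear(self):
        sched = [BleedSegment(60.0, 360.0, 20.0), BleedSegment(500.0, 700.0, 20.0)]
        t = np.linspace(0, 900, 400)
        v = np.array([reference_blv(ti, sched) for ti in t])
        assert np.all(np.diff(v) >= -1e-12)
        assert v[-1] == pytest.approx(20.0 * (300 + 200) / 60.0)


class TestCohortGeneration:
    def test_weight_and_ebv_distribution(self, cohort40):
        weights = np.array([r.weight for r in cohort40])
        ebvs = np.array([r.ebv for r in cohort40])
        # cohort of 40 drawn from N(31.82, 3.52^2): mean within 3 SE
        se = 3.52 / np.sqrt(40)
        assert abs(weights.mean() - 31.82) < 3 * se
        # EBV at 67.9 mL/kg: cohort mean within 2 SE of 2160 mL
        se_ebv = 67.9 * 3.52 / np.sqrt(40)
        assert abs(ebvs.mean() - 2160.0) < 2 * se_ebv

    def test_baseline_duration_bounds(self, cohort40):
        for r in cohort40:
            assert 18 * 60 <= r.baseline_duration <= 31 * 60

    def test_terminal_loss_realism(self, cohort40):
        fracs = [
            reference_blv(r.duration, r.bleed_schedule) / r.ebv for r in cohort40
        ]
        assert 0.30 < np.mean(fracs) < 0.65

    def test_seeded_determinism(self):
        cfg = fast_config()
        a = generate_cohort(2, cfg, seed=42)
        b = generate_cohort(2, cfg, seed=42)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.ppg, rb.ppg)
            assert np.array_equal(ra.abp, rb.abp)
            assert ra.hct_draws == rb.hct_draws
            assert ra.bleed_schedule == rb.bleed_schedule

    def test_subjects_differ_in_baseline_gain_offset(self, fast_cohort):
        offsets = {r.physio.ppg_offset for r in fast_cohort}
        gains = {r.physio.ppg_gain for r in fast_cohort}
        assert len(offsets) == len(fast_cohort)
        assert len(gains) == len(fast_cohort)

    def test_schedule_segments_ordered_nonoverlapping(self, fast_cohort):
        for r in fast_cohort:
            segs = r.bleed_schedule
            assert all(s.end > s.start for s in segs)
            assert all(b.start >= a.end for a, b in zip(segs[:-1], segs[1:]))
            assert segs[0].start == pytest.approx(r.baseline_duration)

    def test_invalid_config_names_field(self):
        cfg = SimConfig(baseline_min_s=2000.0, baseline_max_s=1000.0)
        with pytest.raises(ConfigError, match="baseline_min_s"):
            generate_cohort(2, cfg, seed=0)

    def test_min_subjects(self):
        with pytest.raises(ValueError):
            generate_cohort(1, fast_config(), seed=0)


class TestPhysioTrajectory:
    def test_baseline_identity(self, fast_cohort):
        r = fast_cohort[0]
        st = compensatory_response(0.0, r.physio)
        assert st.pulse_rate == pytest.approx(r.physio.pr0)
        assert st.ppg_amp_scale == pytest.approx(1.0)

    def test_monotone_responses(self, fast_cohort):
        phys = fast_cohort[0].physio
        grid = np.linspace(0.0, phys.f_shock, 50)
        states = [compensatory_response(f, phys) for f in grid]
        pr = np.array([s.pulse_rate for s in states])
        amp = np.array([s.ppg_amp_scale for s in states])
        assert np.all(np.diff(pr) >= 0)
        assert np.all(np.diff(amp) < 0)

    def test_deeper_loss_lowers_amplitude_and_sbp(self, fast_cohort):
        phys = fast_cohort[0].physio
        lo = compensatory_response(0.1, phys)
        hi = compensatory_response(0.4, phys)
        assert hi.ppg_amp_scale < lo.ppg_amp_scale
        assert hi.sbp < lo.sbp

    def test_terminal_map_at_shock_threshold(self, fast_cohort):
        for r in fast_cohort:
            st = physio_trajectory(r, r.duration)
            assert st.map <= r.physio.shock_map + 1.0

    def test_out_of_range_time(self, fast_cohort):
        with pytest.raises(ValueError):
            physio_trajectory(fast_cohort[0], fast_cohort[0].duration + 100.0)

    def test_rest_segments_allow_partial_recovery(self, fast_cohort):
        # effective deficit decreases during a rest pause (capillary refill)
        for r in fast_cohort:
            rests = [
                (a.end, b.start)
                for a, b in zip(r.bleed_schedule[:-1], r.bleed_schedule[1:])
                if b.start - a.end > 60
            ]
            for start, end in rests:
                f0 = float(r.effective_fraction(start))
                f1 = float(r.effective_fraction(end))
                assert f1 < f0


class TestBeatMorphology:
    def test_amplitude_scales_linearly(self):
        full = synth_ppg_beat(_state(amp=1.0), offset=2.0, gain=1.5)
        half = synth_ppg_beat(_state(amp=0.5), offset=2.0, gain=1.5)
        assert (half.max() - half.min()) == pytest.approx(0.5 * (full.max() - full.min()), rel=1e-9)

    def test_single_systolic_peak_and_notch(self):
        beat = synth_ppg_beat(_state())
        peak = int(np.argmax(beat))
        # brute-force extrema scan: local maxima strictly before the notch
        interior = np.flatnonzero(
            (beat[1:-1] > beat[:-2]) & (beat[1:-1] > beat[2:])
        ) + 1
        # first local minimum after the peak is the notch
        minima = np.flatnonzero(
            (beat[1:-1] < beat[:-2]) & (beat[1:-1] < beat[2:])
        ) + 1
        notch = minima[minima > peak][0]
        assert (interior < notch).sum() == 1  # exactly one max before the notch
        assert peak < notch < len(beat) - 1
        assert beat[notch] < beat[peak]

    def test_shape_invariant_under_gain_offset(self):
        a = synth_ppg_beat(_state(), offset=1.0, gain=0.7)
        b = synth_ppg_beat(_state(), offset=5.0, gain=2.4)
        na = (a - a.min()) / (a.max() - a.min())
        nb = (b - b.min()) / (b.max() - b.min())
        assert np.allclose(na, nb, atol=1e-9)

    def test_abp_beat_spans_dbp_to_sbp(self):
        beat = synth_abp_beat(_state(sbp=120.0, dbp=80.0))
        assert beat.max() == pytest.approx(120.0, abs=0.5)
        assert beat.min() == pytest.approx(80.0, abs=0.5)
        assert (beat.max() - beat.min()) == pytest.approx(40.0, abs=1.0)

    def test_map_decreases_along_bleed(self, fast_cohort):
        r = fast_cohort[0]
        seg = r.bleed_schedule[-1]
        maps = [physio_trajectory(r, t).map for t in np.linspace(seg.start, seg.end, 10)]
        assert maps[-1] < maps[0]

    def test_nonphysiological_rate_rejected(self):
        with pytest.raises(ValueError):
            _state(pr=300.0)
        with pytest.raises(ValueError):
            _state(pr=20.0)


class TestArtifacts:
    def test_zero_fraction_is_identity(self, rng):
        x = rng.normal(size=250 * 600)
        out, mask = inject_artifacts(x, 0.0, seed=1)
        assert np.array_equal(out, x)
        assert not mask.any()

    def test_deterministic_for_seed(self, rng):
        x = rng.normal(size=250 * 3600)
        _, m1 = inject_artifacts(x, 0.033, seed=9)
        _, m2 = inject_artifacts(x, 0.033, seed=9)
        assert np.array_equal(m1, m2)

    def test_corrupted_window_share_near_target(self, rng):
        # expected share of 60-s windows (30-s hop) touching an artifact
        # is ~3.3 % on long records, averaged over seeds
        x = rng.normal(size=250 * 9000)  # 2.5 h
        n_win = int((9000 - 60) / 30) + 1
        shares = []
        for seed in range(30):
            _, mask = inject_artifacts(x, 0.033, seed=seed)
            hit = 0
            for k in range(n_win):
                a = int(k * 30 * 250)
                if mask[a : a + 60 * 250].any():
                    hit += 1
            shares.append(hit / n_win)
        assert abs(np.mean(shares) - 0.033) < 0.01

    def test_fraction_bounds(self, rng):
        with pytest.raises(ValueError):
            inject_artifacts(rng.normal(size=1000), 0.7, seed=0)


class TestHematocrit:
    def test_no_loss_draw_is_baseline(self, fast_cohort):
        r = fast_cohort[0]
        draws = hct_trajectory(r, [r.baseline_duration / 2], refill=False, noise_sd=0.0)
        assert draws[0][1] == pytest.approx(r.physio.hct0, abs=1e-9)

    def test_ward_inversion_exact_without_lag(self, fast_cohort):
        # pure exponential dilution: Ward's log formula recovers BLV < 1 mL
        r = fast_cohort[0]
        t_end = r.duration
        draws = hct_trajectory(r, [t_end], refill=False, noise_sd=0.0)
        hct_f = draws[0][1]
        recovered = r.ebv * np.log(r.physio.hct0 / hct_f)
        truth = reference_blv(t_end, r.bleed_schedule)
        assert abs(recovered - truth) < 1.0

    def test_refill_lag_underrepresents_loss(self, fast_cohort):
        # fractional HCT drop < fractional BLV at the same draw
        r = fast_cohort[0]
        t = r.bleed_schedule[0].end  # end of first active segment
        (_, h) = hct_trajectory(r, [t], refill=True, noise_sd=0.0)[0]
        frac_hct_drop = 1.0 - h / r.physio.hct0
        frac_blv = reference_blv(t, r.bleed_schedule) / r.ebv
        assert frac_hct_drop < frac_blv

    def test_draws_in_physiological_range(self, cohort10):
        for r in cohort10:
            for _, h in r.hct_draws:
                assert 0.0 < h < 100.0
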