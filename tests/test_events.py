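"""Detection, magnitude, recovery kinetics and responsiveness calls."""
import numpy as np
import pytest

import scn_coupling as sc
from scn_coupling.events import (SuppressionEvent, classify_duration,
                                 recovery_time)
from scn_coupling.io_formats import BinnedSeries, Bout, Ethogram
from scn_coupling.rhythm import ArrhythmicError, smooth_mua


def test_baseline_rate_means():
    s = BinnedSeries(0.0, 2.0, np.full(200, 40.0))  # 20 Hz
    assert sc.baseline_rate(s, 300.0) == pytest.approx(20.0)
    alt = BinnedSeries(0.0, 2.0, np.tile([20.0, 60.0], 100))  # 10/30 Hz
    assert sc.baseline_rate(alt, 300.0) == pytest.approx(20.0)
    with pytest.raises(ValueError, match="insufficient"):
        sc.baseline_rate(s, 60.0)


def test_suppression_magnitude_formula():
    assert sc.suppression_magnitude(30.0, 18.0, 25.0) == pytest.approx(48.0)
    assert sc.suppression_magnitude(20.0, 20.0, 25.0) == 0.0
    with pytest.raises(ArrhythmicError):
        sc.suppression_magnitude(30.0, 18.0, 0.0)


@pytest.mark.parametrize("dur_s,cls", [
    (10.0, "<1 min"), (59.0, "<1 min"), (60.0, "1-25 min"),
    (25 * 60.0, "1-25 min"), (25 * 60.0 + 1, ">25 min"), (2700.0, ">25 min"),
])
def test_duration_class_boundaries(dur_s, cls):
    assert classify_duration(dur_s) == cls


def _clean_step_recording(depth=0.5, bout=(30 * 3600.0, 30 * 3600.0 + 300.0)):
    """Noiseless trapezoid with a single injected step suppression."""
    cfg = sc.SimulationConfig(duration_h=48.0, depth_sd=0.0,
                              day_depth_scale=1.0, night_depth_scale=1.0,
                              depth_table={"walking": depth})
    rate = sc.simulate_circadian_rate(cfg)
    b = Bout.from_segments([(bout[0], bout[1], "walking")])
    mod, truth = sc.apply_coupling(rate, [b], None, cfg, seed=0)
    mua = BinnedSeries(0.0, cfg.mua_bin_s, mod * cfg.mua_bin_s, "mua")
    eth = Ethogram(np.array([0.0, bout[0], bout[1]]),
                   np.array([bout[0], bout[1], 48 * 3600.0]),
                   np.array(["lying", "walking", "lying"], dtype=object))
    sch = sc.synthetic_data.make_light_schedule(cfg)
    return cfg, mua, eth, sch, truth


def test_injected_step_detected_at_bout_bounds():
    cfg, mua, eth, sch, truth = _clean_step_recording()
    fit = smooth_mua(mua, sch, exclude_windows=[(mua.t0, 0.0)])
    events = sc.detect_suppressions(mua, eth, fit, sch)
    det = [e for e in events if e.detected]
    assert len(det) == 1
    e = det[0]
    assert abs(e.onset_s - 30 * 3600.0) <= cfg.mua_bin_s
    assert e.magnitude_pct == pytest.approx(50.0, abs=2.5)
    assert e.initiating == "walking"


def test_ten_second_bout_detected():
    t0 = 30 * 3600.0
    cfg, mua, eth, sch, _ = _clean_step_recording(depth=0.6, bout=(t0, t0 + 10))
    fit = smooth_mua(mua, sch)
    events = sc.detect_suppressions(mua, eth, fit, sch)
    det = [e for e in events if e.detected]
    assert len(det) == 1 and det[0].duration_class == "<1 min"


def test_close_bouts_merge_into_one_event():
    eth = Ethogram(np.array([0.0, 600.0, 660.0, 720.0]),
                   np.array([600.0, 660.0, 720.0, 780.0]),
                   np.array(["lying", "grooming", "sitting", "walking"],
                            dtype=object))
    bouts = eth.active_bouts(merge_gap_s=120.0)
    assert len(bouts) == 1
    assert bouts[0].onset_s == 600.0 and bouts[0].offset_s == 780.0
    assert bouts[0].initiating == "grooming"


def test_arrhythmic_fit_blocks_detection():
    cfg, mua, eth, sch, _ = _clean_step_recording()
    flat = BinnedSeries(0.0, 2.0, np.full(mua.n, 100.0))
    fit = smooth_mua(flat, sch)
    assert not fit.rhythmic
    with pytest.raises(ArrhythmicError):
        sc.detect_suppressions(mua, eth, fit, sch)


def _recovery_series(B=100.0, D=20.0, tau_min=5.0, minutes=40.0):
    t = (np.arange(int(minutes * 60 / 2)) + 0.5) * 2.0
    rate = B - D * np.exp(-t / (tau_min * 60.0))
    return BinnedSeries(0.0, 2.0, rate * 2.0, "mua")


def _stub_event(offset_s=0.0, B=100.0):
    return SuppressionEvent(onset_s=offset_s - 60, offset_s=offset_s,
                            initiating="walking", baseline_hz=B,
                            suppressed_hz=B - 20, amplitude_hz=60.0,
                            magnitude_pct=33.0, z_score=10.0, phase_h=6.0,
                            is_day=True, detected=True)


def test_return_time_closed_form():
    # noiseless exponential deficit, band at 5% of D -> t = tau * ln 20
    s = _recovery_series()
    res = recovery_time(s, _stub_event(), band_hz=0.05 * 20.0)
    assert not res.censored
    assert res.return_min == pytest.approx(5.0 * np.log(20.0), abs=0.2)


def test_return_time_instant_recovery():
    s = BinnedSeries(0.0, 2.0, np.full(600, 200.0))  # flat at baseline
    res = recovery_time(s, _stub_event())
    assert res.return_min <= 10.0 / 60.0  # within one 10-s bin


def test_tau_fit_recovers_time_constant():
    s = _recovery_series(tau_min=5.0)
    res = recovery_time(s, _stub_event(), band_hz=1.0)
    assert res.tau_min == pytest.approx(5.0, rel=0.02)


def test_return_time_censored_when_baseline_not_reattained():
    s = BinnedSeries(0.0, 2.0, np.full(600, 100.0))  # stuck 50 Hz below B
    res = recovery_time(s, _stub_event(B=150.0))
    assert res.censored and np.isnan(res.return_min)


def test_magnitude_scale_invariance(analysis):
    for e in analysis.detected[:20]:
        m1 = sc.suppression_magnitude(e.baseline_hz, e.suppressed_hz,
                                      e.amplitude_hz)
        m3 = sc.suppression_magnitude(3.0 * e.baseline_hz,
                                      3.0 * e.suppressed_hz,
                                      3.0 * e.amplitude_hz)
        assert m3 == pytest.approx(m1, rel=1e-12)


def test_magnitude_unbiased_for_long_events(recording, analysis):
    truth = {b.onset_s: b for b in recording.truth.bouts}
    errs = [e.magnitude_pct - 100.0 * truth[e.onset_s].depth
            for e in analysis.detected
            if e.stationary and e.duration_s >= 60.0]
    assert len(errs) > 20
    assert abs(np.mean(errs)) < 2.0


def test_recovery_estimates_on_simulation(recording, analysis):
    df = analysis.events_df
    ok = df[df.detected & df.stationary & (df.recovery_censored == False)]  # noqa: E712
    assert len(ok) > 30
    assert 11.0 < ok.recovery_min.mean() < 19.0
    tau = ok.tau_min.dropna()
    assert abs(tau.median() - recording.config.tau_rec_min) \
        / recording.config.tau_rec_min < 0.15


def test_excitation_detection_and_duration():
    cfg = sc.SimulationConfig(duration_h=48.0, seed=5)
    rate = sc.simulate_circadian_rate(cfg)
    times = [(30 * 3600.0, 60.0), (32 * 3600.0, 150.0)]
    mod, truth = sc.apply_coupling(rate, [], times, cfg, seed=0)
    counts = sc.sample_spikes(mod, cfg.mua_bin_s, seed=1)
    mua = BinnedSeries(0.0, cfg.mua_bin_s, counts, "mua")
    sch = sc.synthetic_data.make_light_schedule(cfg)
    fit = smooth_mua(mua, sch)
    events, excluded = sc.detect_excitations(mua, [t for t, _ in times],
                                             fit, sch)
    assert all(e.detected for e in events)
    assert events[0].duration_s == pytest.approx(60.0, abs=10.0)
    assert events[1].duration_s == pytest.approx(150.0, abs=20.0)
    assert all(e.post_class == "return" for e in events)
    assert events[0].peak_increment_pct == pytest.approx(40.0, abs=12.0)


def test_excitation_with_undershoot_classified():
    cfg = sc.SimulationConfig(duration_h=48.0, seed=5,
                              excitation_undershoot=True)
    rate = sc.simulate_circadian_rate(cfg)
    times = [(30 * 3600.0, 120.0)]
    mod, _ = sc.apply_coupling(rate, [], times, cfg, seed=0)
    counts = sc.sample_spikes(mod, cfg.mua_bin_s, seed=1)
    mua = BinnedSeries(0.0, cfg.mua_bin_s, counts, "mua")
    sch = sc.synthetic_data.make_light_schedule(cfg)
    events, _ = sc.detect_excitations(mua, [times[0][0]],
                                      smooth_mua(mua, sch), sch)
    assert events[0].detected and events[0].post_class == "undershoot"


def test_disturbance_inside_bout_excluded(recording, analysis):
    b = recording.truth.bouts[2]
    events, excluded = sc.detect_excitations(
        recording.mua, [b.onset_s + 2.0], analysis.fit, recording.schedule,
        ethogram=recording.ethogram)
    assert excluded == [b.onset_s + 2.0]
    assert events == []


def test_responsiveness_classifier_thresholds():
    assert sc.classify_animal_responsiveness(3, 10) == "indeterminate"
    assert sc.classify_animal_responsiveness(0, 40) == "non-responsive"
    assert sc.classify_animal_responsiveness(1, 40) == "non-responsive"
    assert sc.classify_animal_responsiveness(40, 40) == "responsive"
    assert sc.classify_animal_responsiveness(5, 40) == "responsive"


def test_responsiveness_robust_to_halved_depths():
    table = {k: v / 2 for k, v in
             sc.SimulationConfig().depth_table.items()}
    cfg = sc.SimulationConfig(duration_h=96.0, seed=19, depth_table=table)
    rec = sc.simulate_recording(cfg)
    res = sc.analyze_recording_obj(rec)
    n_det = sum(e.detected for e in res.events)
    assert sc.classify_animal_responsiveness(n_det, res.n_candidates) \
        == "responsive"
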