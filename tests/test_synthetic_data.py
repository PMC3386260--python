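"""Generator contracts: waveform, schedule, coupling, observation channels."""
import numpy as np
import pytest

import scn_coupling as sc
from scn_coupling.io_formats import Bout
from scn_coupling.synthetic_data import (ConfigError, apply_coupling,
                                         make_light_schedule,
                                         mean_bout_duration_s)


def test_circadian_rate_plateaus():
    cfg = sc.SimulationConfig(peak_rate=35.0, trough_rate=8.0, duration_h=48.0)
    rate = sc.simulate_circadian_rate(cfg)
    assert abs(rate.max() - 35.0) < 0.35
    assert abs(rate.min() - 8.0) < 0.35


def test_circadian_rate_degenerate_constant():
    cfg = sc.SimulationConfig(peak_rate=20.0, trough_rate=20.0, duration_h=24.0)
    rate = sc.simulate_circadian_rate(cfg)
    assert np.allclose(rate, 20.0)


def test_config_validation_errors():
    with pytest.raises(ConfigError, match="trough_rate"):
        sc.SimulationConfig(peak_rate=10.0, trough_rate=20.0).validate()
    with pytest.raises(ConfigError, match="duration_h"):
        sc.simulate_circadian_rate(sc.SimulationConfig(duration_h=-1.0))
    with pytest.raises(ConfigError, match="duration_mixture"):
        sc.SimulationConfig(duration_mixture=(0.5, 0.2, 0.2)).validate()
    with pytest.raises(ConfigError, match="pir_miss_prob"):
        sc.SimulationConfig(pir_miss_prob=1.5).validate()
    with pytest.raises(ConfigError, match="nocturnality"):
        sc.simulate_behavior_schedule(sc.SimulationConfig(nocturnality=1.2))
    with pytest.raises(ConfigError, match="n_responsive"):
        sc.SimulationConfig(n_animals=3, n_responsive=5,
                            n_light_responsive_nonbehavioral=0).validate()


def test_schedule_deterministic_under_seed():
    cfg = sc.SimulationConfig(duration_h=72.0, seed=5)
    e1, b1 = sc.simulate_behavior_schedule(cfg, 5)
    e2, b2 = sc.simulate_behavior_schedule(cfg, 5)
    assert np.array_equal(e1.start_s, e2.start_s)
    assert list(e1.labels) == list(e2.labels)
    assert len(b1) == len(b2)


def test_recording_deterministic_under_seed():
    cfg = sc.SimulationConfig(duration_h=48.0, seed=9)
    r1 = sc.simulate_recording(cfg)
    r2 = sc.simulate_recording(cfg)
    assert np.array_equal(r1.mua.values, r2.mua.values)
    assert np.array_equal(r1.pir.values, r2.pir.values)


def test_duration_mixture_fractions():
    # ~10 000 bouts from the default mixture
    cfg = sc.SimulationConfig(duration_h=24.0 * 650, seed=1)
    _, bouts = sc.simulate_behavior_schedule(cfg, 1)
    assert len(bouts) >= 9000
    d = np.array([b.duration_s for b in bouts])
    fr = [(d < 60).mean(), ((d >= 60) & (d <= 1500)).mean(), (d > 1500).mean()]
    assert abs(fr[0] - 0.20) < 0.02
    assert abs(fr[1] - 0.65) < 0.02
    assert abs(fr[2] - 0.15) < 0.02


def _night_bout_time_fraction(cfg, bouts):
    sch = make_light_schedule(cfg)
    night = tot = 0.0
    for b in bouts:
        secs = np.arange(b.onset_s, b.offset_s)
        night += np.sum(sch.phase_h(secs) >= 12.0)
        tot += secs.size
    return night / tot


def test_nocturnality_realized():
    cfg = sc.SimulationConfig(duration_h=24.0 * 60, seed=3)
    _, bouts = sc.simulate_behavior_schedule(cfg, 3)
    assert abs(_night_bout_time_fraction(cfg, bouts) - 0.85) < 0.03


def test_nocturnality_one_means_no_day_bout_time():
    cfg = sc.SimulationConfig(duration_h=24.0 * 30, seed=3, nocturnality=1.0)
    _, bouts = sc.simulate_behavior_schedule(cfg, 3)
    assert len(bouts) > 50
    sch = make_light_schedule(cfg)
    for b in bouts:
        secs = np.arange(b.onset_s, b.offset_s)
        assert np.all(sch.phase_h(secs) >= 12.0)


def test_quiescence_precedes_every_bout():
    cfg = sc.SimulationConfig(duration_h=24.0 * 20, seed=6)
    _, bouts = sc.simulate_behavior_schedule(cfg, 6)
    gaps = [b2.onset_s - b1.offset_s for b1, b2 in zip(bouts, bouts[1:])]
    assert min(gaps) >= 120.0
    assert bouts[0].onset_s >= 120.0


def _flat_config(**kw):
    """Constant-amplitude setup with deterministic depths for step tests."""
    return sc.SimulationConfig(peak_rate=35.0, trough_rate=8.0, depth_sd=0.0,
                               day_depth_scale=1.0, night_depth_scale=1.0,
                               duration_h=12.0, **kw)


def test_coupling_step_is_depth_times_amplitude():
    cfg = _flat_config()
    rate = sc.simulate_circadian_rate(cfg)  # day plateau 35 Hz, A = 27 Hz
    bout = Bout.from_segments([(7200.0, 7500.0, "walking")])
    mod, truth = apply_coupling(rate, [bout], None, cfg, seed=0)
    i = int(7200 / cfg.mua_bin_s)
    drop = rate[i] - mod[i]
    assert abs(drop - 0.59 * 27.0) < 1e-9      # 15.93 Hz at onset, one bin
    assert mod[i - 1] == rate[i - 1]           # no pre-onset change
    assert abs(truth.bouts[0].deficit_hz - 15.93) < 1e-9


def test_recovery_tail_is_exponential():
    cfg = _flat_config()
    rate = sc.simulate_circadian_rate(cfg)
    bout = Bout.from_segments([(7200.0, 7500.0, "walking")])
    mod, truth = apply_coupling(rate, [bout], None, cfg, seed=0)
    d0 = truth.bouts[0].deficit_hz
    tau_s = cfg.tau_rec_min * 60.0
    i = int((7500 + tau_s) / cfg.mua_bin_s)
    assert abs((rate[i] - mod[i]) - d0 * np.exp(-1.0)) < 0.01 * d0


def test_escalation_steps_down_then_lower():
    # moving -> eating (holds) -> walking (deeper), Fig-4a-style bout
    cfg = _flat_config()
    rate = sc.simulate_circadian_rate(cfg)
    bout = Bout.from_segments([(7200.0, 7500.0, "moving"),
                               (7500.0, 7800.0, "eating"),
                               (7800.0, 8100.0, "walking")])
    mod, _ = apply_coupling(rate, [bout], None, cfg, seed=0)

    def level(t):
        return mod[int(t / cfg.mua_bin_s)]

    assert abs((rate[0] * 0 + 35.0) - level(7200) - 0.43 * 27.0) < 1e-9
    assert level(7600) == level(7300)             # eating sustains the level
    assert abs(level(7300) - level(7900) - (0.59 - 0.43) * 27.0) < 1e-9


def test_sample_spikes_poisson_moments():
    rate = np.full(100_000, 20.0)
    counts = sc.sample_spikes(rate, 2.0, seed=0)
    assert abs(counts.mean() - 40.0) < 0.4
    disp = counts.var() / counts.mean()
    assert 0.97 < disp < 1.03
    assert np.all(sc.sample_spikes(np.zeros(100), 2.0, seed=0) == 0)
    with pytest.raises(ValueError, match="non-negative"):
        sc.sample_spikes(np.array([-1.0]), 2.0, seed=0)


def test_pir_channel_miss_probability(recording):
    cfg = recording.config
    eth = recording.ethogram
    active = eth.activity_indicator(0.0, cfg.mua_bin_s, recording.mua.n)
    assert active.sum() > 10_000
    # no false positives
    assert not np.any(recording.pir.values[~active] > 0)
    det_frac = recording.pir.values[active].mean()
    assert abs(det_frac - (1.0 - cfg.pir_miss_prob)) < 0.02


def test_pir_extremes():
    cfg = sc.SimulationConfig(duration_h=24.0, seed=2, pir_miss_prob=0.0)
    eth, _ = sc.simulate_behavior_schedule(cfg, 2)
    n = int(24 * 3600 / cfg.mua_bin_s)
    pir0 = sc.simulate_pir(eth, cfg, 2, 0.0, n)
    active = eth.activity_indicator(0.0, cfg.mua_bin_s, n)
    assert np.array_equal(pir0.values > 0, active)
    pir1 = sc.simulate_pir(eth, cfg.replace(pir_miss_prob=1.0), 2, 0.0, n)
    assert not np.any(pir1.values > 0)


def test_conservation_outside_event_windows(recording):
    base = recording.truth.base_rate_hz
    mod = recording.truth.true_rate_hz
    bin_s = recording.config.mua_bin_s
    untouched = np.ones(base.size, dtype=bool)
    for b in recording.truth.bouts:
        i0 = int(b.onset_s / bin_s)
        i1 = min(int(np.ceil(b.tail_end_s / bin_s)) + 1, base.size)
        untouched[i0:i1] = False
    assert np.array_equal(base[untouched], mod[untouched])
    assert not np.array_equal(base, mod)


def test_rhythm_antiphase_with_behavior(recording):
    counts_10m = recording.mua.rebin(600.0).values
    eth = recording.ethogram
    active = eth.activity_coverage(0.0, 600.0, counts_10m.size)
    r = np.corrcoef(counts_10m, active[:counts_10m.size])[0, 1]
    assert r < -0.3


def test_cohort_composition():
    cfg = sc.SimulationConfig(seed=11, animal_duration_h=24.0)
    animals = sc.simulate_cohort(cfg)
    assert len(animals) == 14
    coupled = [a for a in animals if len(a.recording.truth.bouts) > 0]
    assert len(coupled) == 9
    assert sum(a.light_responsive for a in animals) == 4
    assert all(not a.light_responsive for a in animals if a.responsive)


def test_cohort_uncoupled_when_zero_responsive():
    cfg = sc.SimulationConfig(seed=11, n_responsive=0,
                              n_light_responsive_nonbehavioral=0,
                              n_animals=3, animal_duration_h=24.0)
    animals = sc.simulate_cohort(cfg)
    assert all(len(a.recording.truth.bouts) == 0 for a in animals)


def test_mean_bout_duration_matches_draws():
    cfg = sc.SimulationConfig(duration_h=24.0 * 200, seed=4)
    _, bouts = sc.simulate_behavior_schedule(cfg, 4)
    d = np.mean([b.duration_s for b in bouts])
    assert abs(d - mean_bout_duration_s(cfg)) / mean_bout_duration_s(cfg) < 0.1


def test_config_yaml_round_trip(tmp_path):
    cfg = sc.SimulationConfig(seed=7, peak_rate=99.0)
    p = tmp_path / "config.yaml"
    sc.write_config(cfg, p)
    back = sc.read_config(p)
    assert back == cfg


def test_waveform_mode_stream_covers_bouts():
    cfg = sc.SimulationConfig(duration_h=48.0, seed=3, waveform_mode=True)
    rec = sc.simulate_recording(cfg)
    st = rec.amplitudes
    assert st is not None and st.times_s.size > 10_000
    assert set(st.labels) == {"responsive", "nonresponsive", "noise"}
    # spikes exist only around bouts (110 s lead-in to 10 min into the bout)
    windows = [(max(b.onset_s - 110.0, 0.0), min(b.offset_s, b.onset_s + 600.0))
               for b in rec.truth.bouts]
    inside = np.zeros(st.times_s.size, dtype=bool)
    for lo, hi in windows:
        inside |= (st.times_s >= lo) & (st.times_s <= hi + 1.0)
    assert inside.all()
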