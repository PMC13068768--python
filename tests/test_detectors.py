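import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gazebench import (
    ConfigurationError,
    DetectorConfig,
    DETECTORS,
    EventLabel,
    SimulationConfig,
    detect_engbert,
    detect_idt,
    detect_idvt,
    detect_ivt,
    detect_ivvt,
    detect_nh,
    detect_remodnav,
    enforce_durations,
    generate,
    generate_pursuit_segment,
    labels_to_events,
)

from conftest import make_recording

F, S, P, SP, B = (
    int(EventLabel.FIXATION),
    int(EventLabel.SACCADE),
    int(EventLabel.PSO),
    int(EventLabel.SMOOTH_PURSUIT),
    int(EventLabel.BLINK),
)


def burst_recording(n=100, burst_at=40, burst_len=6, step=0.4):
    """Still trace with a constant-velocity burst (step°/sample, 500 Hz)."""
    x = np.zeros(n)
    x[burst_at:] = step * np.minimum(np.arange(n - burst_at), burst_len)
    return make_recording(x)


class TestIVT:
    def test_slow_trace_is_all_fixation(self, still_recording):
        assert np.all(detect_ivt(still_recording) == F)

    def test_burst_yields_one_saccade_event(self):
        # 0.4°/sample at 500 Hz = 200 °/s for 6 samples = 12 ms >= 10 ms
        rec = burst_recording()
        labels = detect_ivt(rec)
        events = labels_to_events(labels, rec)
        sacs = [e for e in events if e.label == EventLabel.SACCADE]
        assert len(sacs) == 1
        assert sacs[0].n_samples == 6
        assert sacs[0].start_index == 41  # speed sits on the later sample
        assert labels[0] == F and labels[-1] == F

    def test_short_burst_dissolved_by_duration_rule(self):
        rec = burst_recording(burst_len=3)  # 6 ms < 10 ms minimum
        events = labels_to_events(detect_ivt(rec), rec)
        assert all(e.label == EventLabel.FIXATION for e in events)

    def test_missing_samples_become_blink(self):
        x = np.zeros(100)
        x[50:60] = np.nan
        labels = detect_ivt(make_recording(x))
        assert np.all(labels[50:60] == B)


class TestIVVT:
    def test_intermediate_drift_is_pursuit(self):
        # 35 °/s sits in the (26, 45] band
        rec = make_recording(0.07 * np.arange(200))
        labels = detect_ivvt(rec)
        assert np.all(labels[1:] == SP)

    def test_still_trace_is_all_fixation(self, still_recording):
        assert np.all(detect_ivvt(still_recording) == F)

    def test_pursuit_threshold_must_be_below_saccade_threshold(self, still_recording):
        with pytest.raises(ConfigurationError):
            detect_ivvt(still_recording, DetectorConfig(v_sp=50.0, v_sac=45.0))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_per_sample_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rec = make_recording(
            np.cumsum(rng.normal(0, 0.05, 300)), np.cumsum(rng.normal(0, 0.05, 300))
        )
        cfg = DetectorConfig()
        got = detect_ivvt(rec, cfg, postprocess=False)
        v = np.hypot(*(np.diff(rec.x), np.diff(rec.y))) * rec.sampling_rate
        expected = [F]
        for vi in v:
            if vi > cfg.v_sac:
                expected.append(S)
            elif vi > cfg.v_sp:
                expected.append(SP)
            else:
                expected.append(F)
        assert np.array_equal(got, expected)


class TestIDT:
    def test_single_stationary_cluster_is_one_fixation(self, still_recording):
        labels = detect_idt(still_recording)
        assert np.all(labels == F)

    def test_two_clusters_split_by_saccade_sample(self):
        # 100-sample clusters 5° apart; protocol inspected pre-enforcement
        x = np.concatenate([np.zeros(100), np.full(100, 5.0)])
        labels = detect_idt(make_recording(x), postprocess=False)
        assert np.all(labels[:100] == F)
        assert labels[100] == S
        assert np.all(labels[101:] == F)

    def test_transition_ramp_yields_three_events(self):
        # 12-sample, 16° ramp: the window protocol absorbs up to 2.7° of the
        # ramp into each flanking fixation, leaving a dispersed transition
        # long enough (>= 10 ms) to survive enforcement
        ramp = np.linspace(16.0 / 12, 16.0, 12)
        x = np.concatenate([np.zeros(100), ramp, np.full(100, 16.0)])
        events = labels_to_events(detect_idt(make_recording(x)), make_recording(x))
        kinds = [e.label for e in events]
        assert kinds == [EventLabel.FIXATION, EventLabel.SACCADE, EventLabel.FIXATION]

    def test_dispersion_exactly_at_threshold_is_still_fixation(self):
        # alternate between 0 and 2.7° so window dispersion == disp_max
        x = np.tile([0.0, 2.7], 50)
        labels = detect_idt(make_recording(x))
        assert np.all(labels == F)

    def test_terminal_under_threshold_window_is_fixation(self):
        x = np.concatenate([np.zeros(100), np.full(10, 5.0)])  # tail < 55 ms window
        labels = detect_idt(make_recording(x), postprocess=False)
        assert np.all(labels[101:] == F)


class TestIDVT:
    def test_fast_transitions_match_idt(self):
        x = np.concatenate([np.zeros(100), np.full(100, 5.0)])
        rec = make_recording(x)
        assert np.array_equal(
            detect_idvt(rec, postprocess=False) == F,
            detect_idt(rec, postprocess=False) == F,
        )
        assert detect_idvt(rec, postprocess=False)[100] == S  # 2500 °/s jump

    def test_slow_transition_is_pursuit(self):
        # 0.07°/sample = 35 °/s < 45: dispersed but slow -> smooth pursuit.
        # A 200 ms window makes the drift exceed the dispersion threshold
        # within one initial window (at 55 ms no constant sub-45°/s drift can).
        cfg = DetectorConfig(min_fix_ms=200.0)
        ramp = 0.07 * np.arange(100)
        x = np.concatenate([np.zeros(150), ramp, np.full(150, ramp[-1])])
        labels = detect_idvt(make_recording(x), cfg)
        # each flank absorbs ~2.7° of the 6.93° drift into fixation, leaving
        # a pursuit run of roughly (6.93 - 2*2.7)/0.07 ~ 22 samples
        assert np.sum(labels == SP) > 15
        assert np.sum(labels == S) == 0

    def test_still_trace_all_fixation(self, still_recording):
        assert np.all(detect_idvt(still_recording) == F)


class TestEngbert:
    def test_abrupt_jump_on_still_trace_is_one_saccade(self):
        x = np.concatenate([np.zeros(200), np.linspace(0.8, 5.0, 6), np.full(200, 5.0)])
        with pytest.warns(UserWarning, match="degenerate"):
            labels = detect_engbert(make_recording(x))
        events = labels_to_events(labels, make_recording(x))
        sacs = [e for e in events if e.label == EventLabel.SACCADE]
        assert len(sacs) == 1
        assert abs(sacs[0].start_index - 200) <= 2

    @pytest.mark.parametrize("seed", range(5))
    def test_scale_invariance(self, seed):
        sim = generate(SimulationConfig(n_saccades=8, seed=seed))
        rec = sim.recording
        doubled = make_recording(2 * rec.x, 2 * rec.y, rate=rec.sampling_rate)
        assert np.array_equal(detect_engbert(rec), detect_engbert(doubled))

    def test_translation_invariance(self):
        sim = generate(SimulationConfig(n_saccades=8, seed=11))
        rec = sim.recording
        shifted = make_recording(rec.x + 30.0, rec.y - 12.5, rate=rec.sampling_rate)
        assert np.array_equal(detect_engbert(rec), detect_engbert(shifted))

    def test_jitter_only_trace_has_no_saccades(self):
        # pure Gaussian jitter: the lambda=6 threshold should sit above it
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rec = make_recording(
                rng.normal(0, 0.02, 10_000), rng.normal(0, 0.02, 10_000)
            )
            events = labels_to_events(detect_engbert(rec), rec)
            if not any(e.label == EventLabel.SACCADE for e in events):
                clean += 1
        assert clean >= 19

    def test_constant_trace_all_fixation_with_warning(self, still_recording):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = detect_engbert(still_recording)
        assert np.all(labels == F)


class TestNH:
    def test_still_trace_all_fixation(self, still_recording):
        assert np.all(detect_nh(still_recording) == F)

    def test_saccade_with_ringing_yields_pso(self):
        sim = generate(
            SimulationConfig(
                n_saccades=6, pso_probability=1.0, blink_probability=0.0,
                noise_sd=0.02, seed=4,
            )
        )
        labels = detect_nh(sim.recording)
        events = labels_to_events(labels, sim.recording)
        kinds = [e.label for e in events]
        assert EventLabel.PSO in kinds
        # every PSO run must directly follow a saccade run
        for k, lab in enumerate(kinds):
            if lab == EventLabel.PSO:
                assert kinds[k - 1] == EventLabel.SACCADE

    def test_identical_saccades_get_identical_boundaries(self):
        # two copies of the same waveform far apart: onsets/offsets must sit
        # at the same offsets relative to each launch index
        wave = np.linspace(0.4, 4.0, 10)
        x = np.concatenate(
            [np.zeros(400), wave, np.full(400, 4.0), 4.0 + wave, np.full(400, 8.0)]
        )
        rng = np.random.default_rng(0)
        x = x + rng.normal(0, 0.01, x.size)
        rec = make_recording(x)
        events = labels_to_events(detect_nh(rec), rec)
        sacs = [e for e in events if e.label == EventLabel.SACCADE]
        assert len(sacs) == 2
        launch = [400, 810]
        rel = [(e.start_index - l, e.end_index - l) for e, l in zip(sacs, launch)]
        assert rel[0] == rel[1]


class TestREMoDNaV:
    def test_still_trace_all_fixation(self, still_recording):
        assert np.all(detect_remodnav(still_recording) == F)

    def test_constant_ramp_is_smooth_pursuit(self):
        sim = generate_pursuit_segment(duration_ms=400.0, speed=30.0)
        labels = detect_remodnav(sim.recording)
        sp_idx = np.flatnonzero(labels == SP)
        gt_idx = np.flatnonzero(sim.labels == SP)
        assert sp_idx.size > 0
        # one pursuit run roughly covering the drift
        assert abs(sp_idx[0] - gt_idx[0]) <= 30 and abs(sp_idx[-1] - gt_idx[-1]) <= 30

    def test_chunk_thresholds_adapt_to_local_noise(self):
        # second half has 5x the jitter: its chunks need higher thresholds
        rng = np.random.default_rng(7)
        sim = generate(
            SimulationConfig(n_saccades=8, noise_sd=0.01, pso_probability=0.0,
                             blink_probability=0.0, seed=7)
        )
        x, y = sim.recording.x.copy(), sim.recording.y.copy()
        half = x.size // 2
        x[half:] += rng.normal(0, 0.05, x.size - half)
        y[half:] += rng.normal(0, 0.05, x.size - half)
        rec = make_recording(x, y, rate=sim.recording.sampling_rate)
        _, info = detect_remodnav(rec, return_info=True)
        chunks = info["chunks"]
        quiet = [c["peak_threshold"] for c in chunks if c["end"] < half]
        noisy = [c["peak_threshold"] for c in chunks if c["start"] >= half]
        assert quiet and noisy
        assert np.median(noisy) > np.median(quiet)


class TestEnforceDurations:
    cfg = DetectorConfig()

    def test_single_sample_saccade_dissolved(self):
        labels = np.array([F] * 10 + [S] + [F] * 10, dtype=np.int8)
        rec = make_recording(np.zeros(21))
        assert np.all(enforce_durations(labels, rec, self.cfg) == F)

    def test_six_sample_saccade_survives(self):
        labels = np.array([F] * 10 + [S] * 6 + [F] * 10, dtype=np.int8)
        rec = make_recording(np.zeros(26))
        assert np.array_equal(enforce_durations(labels, rec, self.cfg), labels)

    def test_compliant_sequence_unchanged(self):
        labels = np.array([F] * 30 + [S] * 6 + [F] * 30, dtype=np.int8)
        rec = make_recording(np.zeros(66))
        assert np.array_equal(enforce_durations(labels, rec, self.cfg), labels)

    def test_tie_merges_into_preceding_run(self):
        labels = np.array([F] * 10 + [P] + [SP] * 10, dtype=np.int8)
        rec = make_recording(np.zeros(21))
        out = enforce_durations(labels, rec, self.cfg)
        assert np.all(out[:11] == F) and np.all(out[11:] == SP)

    def test_blink_runs_never_dissolved(self):
        labels = np.array([F] * 10 + [B] + [F] * 10, dtype=np.int8)
        x = np.zeros(21)
        x[10] = np.nan
        rec = make_recording(x)
        out = enforce_durations(labels, rec, self.cfg)
        assert out[10] == B

    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_and_no_surviving_short_runs(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice([F, S, P, SP], size=80).astype(np.int8)
        rec = make_recording(np.zeros(80))
        once = enforce_durations(labels, rec, self.cfg)
        assert np.array_equal(once, enforce_durations(once, rec, self.cfg))
        # no non-blink run below its minimum survives
        runs = np.split(once, np.flatnonzero(np.diff(once)) + 1)
        min_sac = 5  # 10 ms at 500 Hz
        for run in runs:
            need = min_sac if run[0] == S else 2
            assert run.size >= need


class TestAllDetectors:
    @pytest.mark.parametrize("name", sorted(DETECTORS))
    def test_one_label_per_sample_from_closed_set(self, name):
        sim = generate(SimulationConfig(n_saccades=6, seed=2))
        labels = DETECTORS[name](sim.recording)
        assert labels.shape == (sim.recording.n_samples,)
        assert set(np.unique(labels)) <= {int(v) for v in EventLabel}

    @pytest.mark.parametrize("name", sorted(DETECTORS))
    def test_deterministic(self, name):
        sim = generate(SimulationConfig(n_saccades=4, seed=9))
        a = DETECTORS[name](sim.recording)
        b = DETECTORS[name](sim.recording)
        assert np.array_equal(a, b)
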