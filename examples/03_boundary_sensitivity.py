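"""Boundary matching, RTO/RTD, and the boundary-sensitivity d' sweep.

Detected saccade onsets are paired with the nearest ground-truth onset
within +/- delta_t samples.  RTO (mean signed difference; positive = late)
and RTD (its SD) describe systematic and random timing error; d' combines
the hit rate with a false-alarm rate whose denominator is the number of
boundary-free windows of 2*delta_t+1 samples in the ground truth.
"""

from gazebench import (
    EventLabel,
    MatchConfig,
    SimulationConfig,
    detect_engbert,
    dprime_sweep,
    extract_boundaries,
    generate,
    labels_to_events,
    match_boundaries,
    rto_rtd,
)

sim = generate(SimulationConfig(n_saccades=20, seed=3))
events = labels_to_events(detect_engbert(sim.recording), sim.recording)

det_b = extract_boundaries(events, EventLabel.SACCADE, "onset")
gt_b = extract_boundaries(sim.events, EventLabel.SACCADE, "onset")
res = match_boundaries(det_b, gt_b, MatchConfig(delta_t=20))
rto, rtd = rto_rtd(res)
print(f"saccade onsets: {len(res.pairs)}/{res.n_gt} matched "
      f"(hit rate {100 * res.hit_rate:.1f}%)")
print(f"RTO = {rto:+.2f} samples (negative = detector early), "
      f"RTD = {rtd:.2f} samples")

curve = dprime_sweep(events, sim.events, EventLabel.SACCADE, "onset",
                     sim.recording.n_samples, range(0, 21))
print("\nd' by temporal window (a larger window forgives larger timing error):")
print(curve[["hits", "false_alarms", "negatives", "dprime"]]
      .loc[[0, 1, 2, 5, 10, 20]].round(3))
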