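"""Sample-level agreement of every detector against the ground truth.

Cohen's kappa and MCC are chance-corrected per-sample agreement scores in
[-1, 1]; 1-NLD is one minus the normalized edit distance, which tends to be
more forgiving.  Values near 1 mean the detector labels almost every sample
as the ground truth does.
"""

import warnings

from gazebench import DETECTORS, SimulationConfig, agreement_report, generate

sim = generate(SimulationConfig(n_saccades=20, seed=7))

print(f"{'detector':>10s} {'kappa':>7s} {'MCC':>7s} {'1-NLD':>7s}")
for name, fn in DETECTORS.items():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = fn(sim.recording)
    r = agreement_report(sim.labels, labels)
    print(f"{name:>10s} {r['cohens_kappa']:7.3f} {r['mcc']:7.3f} "
          f"{r['one_minus_nld']:7.3f}")

print("\nThe dispersion-threshold detectors (idt/idvt) miss small saccades "
      "whose spatial extent stays below 2.7°, which is why they trail the "
      "velocity-based and adaptive detectors.")
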