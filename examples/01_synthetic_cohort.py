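"""Generate a synthetic BCG cohort and inspect its class contrast.

The generator emulates mattress-sensor ballistocardiography: heartbeat
pulses placed by a per-subject inter-beat-interval process (hypertensive
group 77.1 +- 9.2 bpm, control 73.6 +- 8.3 bpm), a respiratory baseline and
sensor noise. Hypertensive beats are stronger and slightly narrower.
"""
import numpy as np

from bcghyper import SynthCohortConfig, generate_bcg_cohort

cfg = SynthCohortConfig(n_normal=10, n_hyper=10, duration=60.0, seed=0)
records = generate_bcg_cohort(cfg)

print(f"{len(records)} records, {records[0].n_samples} samples each "
      f"({cfg.duration:g} s at {cfg.fs:g} Hz)")
for label, name in ((0, "normal"), (1, "hypertensive")):
    rms = [np.sqrt(np.mean(r.primary**2)) for r in records if r.label == label]
    print(f"  {name:13s} mean RMS amplitude: {np.mean(rms):.3f}")
# The hypertensive group's larger RMS reflects the pulse-amplitude contrast
# (ratio 1.3 by default) that stands in for unknown morphological differences.
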