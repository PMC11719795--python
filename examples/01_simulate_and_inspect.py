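"""Simulate one pivot-shift test and look at its signal and segments.

A grade-2 injury, standard maneuver class 3: the X-axis trace has a
positive flexion lobe as the knee is flexed to 90 degrees and a negative
shift lobe (the tibial reduction) in the final third, 60 deg/s deep for
grade 2.  The printed numbers show how the three segments carry different
parts of the maneuver.
"""

import numpy as np

from pivotshift import normalize, segment_signal, select_axis, simulate_recording

rec = simulate_recording(grade=2, klass=3, seed=42)
print(f"test {rec.test_id}: {rec.n_samples} samples at {rec.sample_rate_hz:.0f} Hz, "
      f"{rec.duration_s:.2f} s")

x = select_axis(rec, "X")
seg = segment_signal(x)
for name, s in (("S1", seg.S1), ("S2", seg.S2), ("S3", seg.S3)):
    print(f"  {name}: n={len(s)}  max={np.max(s.values):7.2f}  "
          f"min={np.min(s.values):7.2f}  range={np.ptp(s.values):7.2f} deg/s")

print("The flexion lobe peaks in S2; the shift lobe pulls S3's minimum down")
print("by about grade x 30 deg/s, so S3's range tracks injury severity.")

xn = normalize(x)
print(f"normalized trace spans [{xn.values.min():.0f}, {xn.values.max():.0f}]"
      " - amplitude-free morphology for maneuver-class features")
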