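"""Measure flow speed by PIV on a rendered microtubule-texture sequence.

Renders an aligned filamentous texture advected at a programmed 2 um/s
inside an always-on illumination schedule, runs windowed
cross-correlation PIV on every consecutive frame pair, and compares the
recovered mean speed with the programmed value.
"""

import optoflow as of
from optoflow.core import Episode, IlluminationSchedule

schedule = IlluminationSchedule([Episode(0, 1e6, 1.0)])
texture = of.gen_texture(seed=3, shape=(192, 192), correlation_length=6.0)
sequence = of.render_sequence(texture, of.FlowSpec(kind="uniform", speed=2.0),
                              schedule, n_frames=12, dt=1.0, seed=1)

trace = of.speed_trace(sequence, schedule, window_px=32, overlap_px=16)

print(f"programmed speed : 2.000 um/s")
print(f"PIV mean speed   : {trace.speed.mean():.3f} um/s "
      f"({abs(trace.speed.mean() - 2) / 2:.1%} error)")
print()
print("Each value is the mean cross-correlation displacement over all")
print("32-px interrogation windows of one frame pair, after normalized-")
print("median outlier replacement.")
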