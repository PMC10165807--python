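"""Fit photoswitching kinetics to a synthetic light-cycled speed trace.

Builds one activation/deactivation cycle with the non-processive-motor
parameters (plateau 1.2 um/s, tau_on = 8 s, tau_off = 13 s), adds 10%
measurement noise, and refits both time constants.
"""

import numpy as np

import optoflow as of
from optoflow.core import Episode, IlluminationSchedule

schedule = IlluminationSchedule([
    Episode(0, 120, 1.0),     # light on at 1 uW/mm^2 for 2 min
    Episode(120, 320, 0.0),   # then dark
])

trace = of.gen_speed_trace(vmax=1.2, tau_on=8.0, tau_off=13.0,
                           schedule=schedule, noise_sd=0.12, seed=11, dt=2.0)

on_fit = of.fit_activation(trace.restrict(0, 120))
off_seg = of.normalized_deactivation_segment(trace, schedule)
off_fit = of.fit_deactivation(off_seg)

print(f"plateau speed : {on_fit.vmax:.3f} um/s   (programmed 1.2)")
print(f"tau_on        : {on_fit.tau_on:.2f} s     (programmed 8)")
print(f"tau_off       : {off_fit.tau_off:.2f} s    (programmed 13)")
print()
print("tau_on is the timescale for motor clusters to assemble and spin up")
print("the flow after illumination; tau_off is the decay timescale of the")
print("flow after the light is removed, fitted as a normalized logistic.")
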