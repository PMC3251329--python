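"""Dynamic framing, decay correction and SUV normalization.

Builds the 41-frame, 90-min acquisition scheme, decay-corrects a measured
striatal curve to injection time, and expresses it as standardized uptake
value (SUV): concentration scaled by body weight over injected activity.
"""

import numpy as np

import fdopaquant as fq

scheme = fq.build_framing(fq.DEFAULT_FRAMING)
print(f"frames: {scheme.n_frames}, total: {scheme.total_duration_s / 60:.0f} min")
print(f"first mid-times (s): {np.round(scheme.mid_times_min[:5] * 60, 1)}")

# a plausible as-measured (decaying) striatal curve
t = scheme.mid_times_min
measured = 40 * (1 - np.exp(-t / 3)) * np.exp(-np.log(2) * t / fq.F18_HALF_LIFE_MIN)
tac = fq.TimeActivityCurve(scheme, measured, region="striatum")

corrected = fq.decay_correct(tac)  # back to injection-time activity scale
suv = fq.to_suv(corrected, fq.DoseInfo(injected_activity_mbq=55, body_weight_g=440))

print(f"last-frame measured activity : {tac.values[-1]:.2f} kBq/mL")
print(f"last-frame decay-corrected   : {corrected.values[-1]:.2f} kBq/mL")
print(f"last-frame SUV               : {suv.values[-1]:.3f}")
print("SUV ~ 0.3 means the region holds ~0.3x the whole-body mean concentration.")
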