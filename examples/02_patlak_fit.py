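"""Reference-tissue Patlak estimation of the influx constant K_i.

Simulates a bolus plasma input, a cerebellar reference curve (no trapping)
and a striatal curve with known influx, then recovers K_i from the 10-60 min
Patlak fit — the quantitation core of the whole chain.
"""

import fdopaquant as fq
from fdopaquant.synthetic import REFERENCE_KINETICS

scheme = fq.build_framing(fq.DEFAULT_FRAMING)
plasma = fq.simulate_input_function(fq.BolusShape(), scheme.mid_times_min)

reference = fq.simulate_tissue_tac(plasma, REFERENCE_KINETICS, scheme, "cerebellum")
target_ki = 0.0162  # 1/min, an intact-striatum influx constant
striatum = fq.simulate_tissue_tac(
    plasma, fq.striatal_params_for_ki(target_ki), scheme, "striatum"
)

points = fq.patlak_transform(striatum, reference)
fit = fq.fit_patlak(points, (10, 60))

print(f"true K_i : {target_ki * 1e3:.2f} x10^-3 /min")
print(f"fitted   : {fit.ki * 1e3:.2f} x10^-3 /min  (V = {fit.v:.3f}, "
      f"r^2 = {fit.r_squared:.5f}, {fit.n_points} frames in window)")
print(f"error    : {100 * (fit.ki / target_ki - 1):+.2f}%")
print("The slope of the late linear portion of the Patlak plot is the net")
print("trapping rate of the tracer; the intercept approximates the initial")
print("distribution volume.")

# a lesioned side at 30% residual influx, and the asymmetry index
lesioned = fq.simulate_tissue_tac(
    plasma, fq.striatal_params_for_ki(0.3 * target_ki), scheme, "striatum_lesioned"
)
fit_les = fq.fit_patlak(fq.patlak_transform(lesioned, reference), (10, 60))
print(f"ipsi/contra K_i ratio: {fq.ki_ratio(fit_les, fit):.1f}% (truth 30%)")
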