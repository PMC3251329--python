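"""Voxel phantom round trip: NIfTI image + label mask -> VOI TACs -> K_i.

Builds a noisy 4D phantom whose striatal and cerebellar regions carry known
kinetics, writes it to NIfTI with a frame-timing sidecar, re-loads it,
extracts VOI-mean TACs and refits the influx constants.
"""

import tempfile
from pathlib import Path

import fdopaquant as fq
from fdopaquant import io as fio
from fdopaquant.synthetic import REFERENCE_KINETICS

scheme = fq.build_framing(fq.DEFAULT_FRAMING)
plasma = fq.simulate_input_function(fq.BolusShape(), scheme.mid_times_min)

ki_contra, ki_ipsi = 0.0162, 0.0055
tacs = {
    1: fq.simulate_tissue_tac(plasma, fq.striatal_params_for_ki(ki_contra), scheme),
    2: fq.simulate_tissue_tac(plasma, fq.striatal_params_for_ki(ki_ipsi), scheme),
    3: fq.simulate_tissue_tac(plasma, REFERENCE_KINETICS, scheme),
}
phantom = fq.generate_phantom(scheme, tacs, noise_cv=0.05, seed=7)

with tempfile.TemporaryDirectory() as tmp:
    paths = fio.save_phantom(phantom, Path(tmp))
    back = fio.load_phantom(paths["image"], paths["mask"], paths["timing"])

ref = fq.extract_voi_tac(back, 3)
for label, name, truth in [(1, "left striatum ", ki_contra), (2, "right striatum", ki_ipsi)]:
    voi = fq.extract_voi_tac(back, label)
    fit = fq.fit_patlak(fq.patlak_transform(voi, ref), (10, 60))
    print(f"{name}: K_i = {fit.ki * 1e3:6.2f} x10^-3 /min "
          f"(truth {truth * 1e3:5.2f}, r^2 = {fit.r_squared:.4f})")
print("VOI means over ~1000-voxel regions average out the 5% voxel noise,")
print("so the refitted influx constants sit within a few percent of truth.")
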