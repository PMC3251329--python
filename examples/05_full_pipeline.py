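"""One-call pipeline: simulate, fit Patlak bilaterally, run all statistics.

Writes a report directory (cohort table, per-animal Patlak fits, paired-t,
ANOVA/Dunnett and regression tables, plain-text summary) that is
byte-reproducible from the seed and config hash in its headers.
"""

import tempfile
from pathlib import Path

import fdopaquant as fq

with tempfile.TemporaryDirectory() as tmp:
    out = fq.run_all(fq.RunConfig(seed=1), Path(tmp) / "report")
    print("files written:")
    for p in sorted(out.iterdir()):
        print(f"  {p.name}")
    print()
    print((out / "summary.txt").read_text())
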