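"""Chloride diffusion along a path through a branched dendritic tree.

A small synthetic tree (procedurally generated, granule-cell-like in its
sparse branching) receives a focal Cl⁻ release in the middle of its longest
root-to-tip path. Side branches and spines both act as reservoirs that
retard spread along the path, raising the path tortuosity.
"""

import tempfile
from pathlib import Path

from cldend.experiments import run_branched, synthetic_tree_swc

with tempfile.TemporaryDirectory() as d:
    swc = Path(d) / "granule_like.swc"
    swc.write_text(synthetic_tree_swc("granule"))
    smooth = run_branched(swc, density=0.0, t_end=500.0)
    spiny = run_branched(swc, density=2.0, seed=0, t_end=500.0)

print("tree (path metrics at t = 500 ms)    D_app (μm²/ms)   tortuosity λ")
print(f"smooth branched tree                 {smooth.d_app_end:10.3f}      "
      f"{smooth.tortuosity:8.3f}")
print(f"spiny branched tree (2/μm)           {spiny.d_app_end:10.3f}      "
      f"{spiny.tortuosity:8.3f}")
print()
print("Branch points alone push λ above 1; adding spines raises it further —")
print("in real morphologies both effects compound.")
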