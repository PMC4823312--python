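"""Sweep the skull-defect conductivity and watch the MEG signal change.

For the tangential source centered under defect 1, compares the forward map
of the defect model against the same-position intact-skull map as the
defect filling ranges from quasi-air (1e-6 S/m) to conducting agar
(1.0 S/m).  MAG_rel is the norm ratio minus one (negative = weaker signal);
RDM* is the scale-free topography distance.
"""

import numpy as np

from megfem.study import (
    build_models, default_study_config, run_forward_concordance,
)

cfg = default_study_config()
models = build_models(cfg)
center = 14          # full-step position closest to the defect-1 center

fc = run_forward_concordance(cfg, models, indices=[center])
print("defect conductivity sweep, source centered under defect 1:")
print(f"{'sigma (S/m)':>12s} {'MAG_rel':>9s} {'RDM*':>7s}")
for _, row in fc.table.sort_values("defect_sigma").iterrows():
    print(f"{row.defect_sigma:12.3g} {row.mag_rel:+9.4f} {row.rdm_star:7.4f}")

diff = fc.difference_maps[(center, 1.0)]
intact = fc.intact_maps[center].values
corr = np.corrcoef(diff, intact)[0, 1]
print(f"\ndefect-minus-intact map at 1.0 S/m correlates {corr:+.3f} with "
      "the intact map:")
print("the defect-induced component is dipolar and approximately opposes "
      "the intact topography")
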