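"""Build the 10 x 11 electrode-mesh tensors the classifier consumes.

Each channel is assigned one grid cell by projecting its standard scalp
position (anterior rows first, left columns first); unassigned cells are
"null electrodes" and stay exactly zero.  Depth is either the 72 window
samples or the five canonical band powers.
"""

import numpy as np

from eci import SimConfig, build_layout, generate_cohort, standard_chain, window
from eci import to_spatiospectral, to_spatiotemporal

cohort = generate_cohort(SimConfig(n_participants_per_domain=2,
                                   trials_per_session=6, seed=3))
clean, _ = standard_chain(cohort)
win = window(clean, 200.0, 400.0)

layout = build_layout(win.channel_labels)
print(f"layout: {len(layout.mapping)} electrodes on a "
      f"{layout.n_rows} x {layout.n_cols} grid, {len(layout.null_cells)} null cells")
print("Pz sits at cell", layout.mapping["Pz"])

temporal = to_spatiotemporal(win, layout)
spectral = to_spatiospectral(win, layout)
print("spatiotemporal tensor:", temporal.values.shape)
print("spatio-spectral tensor:", spectral.values.shape)

r, c = next(iter(layout.null_cells))
print("a null cell is exactly zero:", bool(np.all(temporal.values[:, r, c, :] == 0)))
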