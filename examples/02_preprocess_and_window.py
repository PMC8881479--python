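"""Run the standard preprocessing chain and extract the analysis window.

The chain downsamples to 362.5 Hz, band-passes 0.5-45 Hz (zero-phase
order-2 Butterworth), baseline-corrects with the 400 ms pre-pulse window,
rejects trials exceeding +/-100 microvolts, and re-references to the common
average.  The 200-400 ms post-pulse window then contains exactly 72 samples
— the depth of the spatiotemporal feature tensor.
"""

import numpy as np

from eci import SimConfig, generate_cohort, standard_chain, window
from eci.synthetic import inject_outliers

cohort = generate_cohort(SimConfig(n_participants_per_domain=2,
                                   trials_per_session=8, seed=7))
# add one artifact trial to show the rejection stage doing its job
cohort = inject_outliers(cohort, [0], amplitude_uv=150.0, width_ms=80.0)

clean, log = standard_chain(cohort)
print("chain steps:")
for step in log.steps:
    print("  -", step)
print(f"{log.n_in} trials in, {log.n_rejected} rejected, {log.n_out} out "
      f"at {log.srate_out} Hz")

win = window(clean, 200.0, 400.0)
print(f"analysis window: {win.n_samples} samples "
      f"({win.times_ms[0]:.1f}..{win.times_ms[-1]:.1f} ms)")
print("average-reference residual:", float(np.abs(win.data.mean(axis=1)).max()))
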