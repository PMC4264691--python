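"""Simulate a spatially biased slide and remove the bias.

Builds the default 132 x 44 slide carrying a smooth +/-30% multiplicative
bias plus 5% lognormal noise, derives the correction-factor surface from
the 96 positive-control anchors, and reports how close the corrected
intensities come to the known truth.
"""

import numpy as np

from rppanorm import (
    SimulationConfig, build_default_layout, low_freq_sinusoid,
    normalize_slide, simulate_slide,
)

layout = build_default_layout()
config = SimulationConfig(layout=layout, noise_sigma_log=0.05,
                          bias=low_freq_sinusoid(layout, amplitude=0.3))
slide, truth = simulate_slide(config, seed=1)
norm = normalize_slide(slide)  # bilinear surface, median-of-set anchors

raw_err = np.abs(slide.spots["intensity"] / truth.true_intensity - 1)
cor_err = np.abs(norm.corrected / truth.true_intensity - 1)
print(f"anchors used:            {len(norm.surface.anchors)}")
print(f"reference <PCI>:         {norm.surface.reference:.1f}")
print(f"CF range:                {norm.surface.cf.min():.3f} .. "
      f"{norm.surface.cf.max():.3f}")
print(f"median |error| raw:      {np.median(raw_err):.3f}")
print(f"median |error| corrected:{np.median(cor_err):.3f}")
# The raw error mixes the +/-30% bias with 5% noise; after correction the
# residual error shrinks to roughly the noise floor, showing the spatial
# component has been divided out.
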