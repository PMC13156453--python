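"""Build a synthetic 8-channel field set and evaluate 10 g-averaged SAR.

Generates Maxwell-consistent per-channel B/E fields over a cylindrical
phantom, synthesizes the circularly polarized (CP) excitation mode, and
compares voxelwise SAR against its 10 g mass average and the Q-matrix
quadratic form.
"""

import numpy as np

from sarbound import (MassAverager, SyntheticSpec, generate_fieldset,
                      make_canonical_modes, psar10g, qmatrices_from_fieldset,
                      voxel_sar)

fs = generate_fieldset(SyntheticSpec(seed=1))
cp = make_canonical_modes(fs.n_channels)[0]

sar = voxel_sar(fs.E, cp, fs.phantom)
averager = MassAverager(fs.phantom, fs.grid, mass_g=10.0, mask=fs.e_mask)
sar10g = averager.average(sar)

q = qmatrices_from_fieldset(fs)
peak = psar10g(q, cp)

print(f"channels: {fs.n_channels}, grid: {fs.grid.shape}, "
      f"phantom voxels: {fs.phantom.mask.sum()}")
print(f"raw peak SAR (CP):        {sar.max():8.3f} W/kg per unit drive")
print(f"peak 10g-averaged SAR:    {peak.value:8.3f} W/kg at voxel {peak.location}")
print(f"averaging dilution:       {peak.value / sar.max():8.3f}")
# The 10 g average is always below the raw voxel peak: averaging over a
# ~22 cm^3 region smooths the hotspot, which is why regulatory limits are
# defined on the mass-averaged quantity.
assert np.isclose(peak.value, sar10g[np.unravel_index(peak.location, fs.grid.shape)])
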