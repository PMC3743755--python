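"""Simulate a homogeneous brain-like phantom and reconstruct its moduli.

A single 50 Hz plane shear wave (G* = 1.2 kPa, loss angle 0.9 rad) is turned
into a raw wrapped-phase acquisition, pushed through the full chain
(unwrap -> smooth -> temporal harmonic -> curl -> inversion), and the
recovered |G*| and phi are compared with the ground truth.
"""

import numpy as np

from mdevmre import AcquisitionGrid, PhantomSpec, WaveSource, simulate_dataset
from mdevmre.pipeline import reconstruct

s2 = 1 / np.sqrt(2)
grid = AcquisitionGrid(
    shape=(64, 64, 12),
    voxel_size=(0.002, 0.002, 0.002),  # 2 mm isotropic
    frequencies=(50.0,),
    n_timesteps=8,
    n_components=3,
)
spec = PhantomSpec(
    grid=grid,
    gstar=1200.0 * np.exp(0.9j),  # |G*| = 1.2 kPa, phi = 0.9 rad
    sources=(WaveSource(direction=(s2, s2, 0), polarization=(0, 0, 1), amplitude=30e-6),),
    noise_sigma=0.0,
    seed=1,
)
series, truth = simulate_dataset(spec)
result = reconstruct(series, butterworth=False)  # noise-free: no filter needed
e = result.elastogram

interior = np.zeros_like(e.mask)
interior[2:-2, 4:-4, 4:-4] = True
sel = e.mask & interior
print(f"stages: {' -> '.join(result.stages)}")
print(f"recovered |G*| median: {np.median(e.gabs[sel]):7.1f} Pa   (truth 1200.0 Pa)")
print(f"recovered phi  median: {np.median(e.phi[sel]):7.4f} rad  (truth 0.9000 rad)")
# The ~1% |G*| excess is the second-order finite-difference Laplacian bias
# at ~12 voxels per wavelength; it shrinks quadratically with resolution.
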