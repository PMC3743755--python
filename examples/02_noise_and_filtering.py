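"""Noise response of MDEV inversion and its recovery by filtering.

Gaussian noise (sigma = 0.2 rad) on the raw phase biases the pooled
estimators: |G*| collapses and the loss angle overshoots.  Gaussian
smoothing of the wave data and the 100 1/m k-space Butterworth on the curl
recover both, reproducing the characteristic unfiltered < smoothed <
filtered ladder.  The Helmholtz scatter shows the same mechanism at region
level: noise inflates mean |Delta c|, so a through-origin fit
underestimates |G*| while an offset-allowing fit does not.
"""

import numpy as np

from mdevmre import (
    AcquisitionGrid,
    PhantomSpec,
    WaveSource,
    helmholtz_scatter,
    make_plane_wave_field,
    simulate_dataset,
)
from mdevmre.pipeline import reconstruct

s2 = 1 / np.sqrt(2)
grid = AcquisitionGrid(shape=(48, 48, 12), voxel_size=(0.002,) * 3,
                       frequencies=(30.0, 40.0, 50.0, 60.0), n_timesteps=8, n_components=3)
src = WaveSource(direction=(s2, s2, 0), polarization=(0, 0, 1), amplitude=160e-6)
spec = PhantomSpec(grid=grid, gstar=1200.0 * np.exp(0.9j), sources=(src,),
                   noise_sigma=0.2, seed=0)

# evaluation region: well-insonified interior (amplitude >= 50% of max)
clean_field, _ = make_plane_wave_field(spec)
amp = np.abs(clean_field.u[:, 2]).max(axis=0)
core = np.zeros(grid.vol_shape_zyx, bool)
core[2:-2, 4:-4, 4:-4] = True
core &= amp > 0.5 * amp[core].max()

series, _ = simulate_dataset(spec)
print("variant                      mean |G*| (Pa)   mean phi (rad)")
for label, kw in (("unfiltered", dict(smooth=False, butterworth=False)),
                  ("smoothed", dict(smooth=True, butterworth=False)),
                  ("smoothed + Butterworth", dict(smooth=True, butterworth=True))):
    r = reconstruct(series, **kw)
    sel = r.elastogram.mask & core
    print(f"{label:28s} {r.elastogram.gabs[sel].mean():10.1f} {r.elastogram.phi[sel].mean():14.3f}")
print("truth                            1200.0          0.900")

r_sm = reconstruct(series, smooth=True, butterworth=False)
sc = helmholtz_scatter(r_sm.curl, core & r_sm.curl.mask)
print(f"\nHelmholtz scatter (smoothed curl, {len(sc.mean_lap)} points):")
print(f"  through-origin slope : {sc.slope_through_origin:7.1f} Pa   (biased low by noise)")
print(f"  offset-allowing slope: {sc.slope_with_offset:7.1f} Pa")
print(f"  abscissa intercept   : {-sc.intercept / sc.slope_with_offset:.3g} 1/m^2  (positive = noise floor)")
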