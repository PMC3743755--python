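"""Heterogeneous 2D phantom: a stiff inclusion recovered by MDEV inversion.

The finite-difference solver produces the exact wave field for a disc twice
as stiff as the background; the inversion should recover the 2:1 modulus
contrast inside homogeneous subregions (the local-homogeneity assumption
fails only on the interface ring).
"""

import numpy as np
from scipy import ndimage

from mdevmre import AcquisitionGrid, InversionConfig, mdev_invert, shear_wavenumber, solve_helmholtz_2d
from mdevmre.wavefield_io import CurlField

h, f, rho = 0.002, 40.0, 1000.0
g_bg, g_inc = 1000.0 * np.exp(0.5j), 2000.0 * np.exp(0.5j)
ny = nx = 120
yy, xx = np.mgrid[0:ny, 0:nx]
inclusion = (yy - ny / 2) ** 2 + (xx - nx / 2) ** 2 < 18**2
gmap = np.where(inclusion, g_inc, g_bg)

k = shear_wavenumber(g_bg, rho, 2 * np.pi * f)
print(f"background wavelength: {2 * np.pi / k.real * 1e3:.1f} mm "
      f"({2 * np.pi / k.real / h:.1f} voxels)")
boundary = np.zeros((ny, nx), complex)
boundary[:, 0] = np.exp(-1j * k * yy[:, 0] * h)
boundary[0, :] = 0.8 * np.exp(-1j * k * xx[0, :] * h)
boundary[:, -1] = 0.3 * np.exp(-0.7j * k * yy[:, -1] * h)
u = solve_helmholtz_2d(gmap, (h, h), rho, f, boundary)

grid = AcquisitionGrid(shape=(nx, ny, 1), voxel_size=(h,) * 3, frequencies=(f,),
                       n_timesteps=8, n_components=1, density=rho)
c = CurlField(grid=grid, c=u[None, None, None], mask=np.ones((1, ny, nx), bool))
e = mdev_invert(c, InversionConfig(laplacian_mode="2d"))

valid = e.mask[0]
inc_core = ndimage.binary_erosion(inclusion, iterations=5) & valid
bg_core = ndimage.binary_erosion(~inclusion & valid, iterations=7) & valid
g_in = np.median(e.gabs[0][inc_core])
g_out = np.median(e.gabs[0][bg_core])
print(f"|G*| inclusion (median): {g_in:7.1f} Pa   (truth 2000 Pa)")
print(f"|G*| background (median): {g_out:6.1f} Pa   (truth 1000 Pa)")
print(f"contrast ratio: {g_in / g_out:.3f}          (truth 2.0)")
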