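# Full-size in-silico subject for the `mdevmre simulate` command:
# 96 x 88 x 30 voxels at 2 mm, four drive frequencies, three motion-encoding
# components, eight samples per vibration cycle.
grid:
  shape: [96, 88, 30]
  voxel_size_mm: [2, 2, 2]
  frequencies_hz: [30, 40, 50, 60]
  n_timesteps: 8
  n_components: 3
  density_kg_m3: 1000.0
phantom:
  gstar_abs_pa: 1200.0        # |G*| ground truth
  gstar_phi_rad: 0.9          # loss angle ground truth
  noise_sigma_rad: 0.2        # Gaussian noise on raw phase
  scale_factor_rad_per_m: 5.0e4
  amplitude_m: 160.0e-6       # source displacement amplitude
  amplitude_exponent: -2.0    # amplitude ~ (f/f_min)^-2 across frequencies
  seed: 11
  # omit `sources` to use the three default oblique shear sources
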