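# Reference print scenario: seven-layer melt-extrusion print of a 1 g
# tablet-shaped form on a cooled platform, four extrusion speeds.
# Thermal properties are those of the high-oleic sunflower-oil base
# (~90 % of the formulation); convection is natural (2 W/m^2 K).
material:
  k: 0.16        # W/(m K)
  rho: 880.0     # kg/m^3
  cp: 2400.0     # J/(kg K)
boundaries:
  Tp: 8.5        # platform temperature, deg C (Dirichlet base)
  Tinf: 22.1     # ambient air temperature, deg C
  h: 2.0         # convective coefficient, W/(m^2 K)
  T0: 79.7       # nozzle-exit (initial) temperature, deg C
grid:
  Nx: 20
  Ny: 20
  Nz: 10
layers:
  count: 7
dt: 0.01          # s, explicit time step
output_stride_s: 1.0
# Per-speed slab dimensions (m) of one printed layer and its print time (s).
speeds:
  - {v_mm_s: 1, Lx: 0.01988, Ly: 0.01197, Lz: 0.00103, layer_time_s: 314.0}
  - {v_mm_s: 3, Lx: 0.01822, Ly: 0.01128, Lz: 0.00111, layer_time_s: 106.8}
  - {v_mm_s: 5, Lx: 0.01874, Ly: 0.0095,  Lz: 0.001,   layer_time_s: 72.29}
  - {v_mm_s: 6, Lx: 0.01855, Ly: 0.01174, Lz: 0.00102, layer_time_s: 55.14}
# Nozzle shear-rate jobs: whole-print mass/time per speed.
nozzle:
  mass_g: 1.0
  radius_um: 415.0
  density_gcm3: 0.8793   # melt density at 70 deg C
  jobs:
    - {v_mm_s: 1, time_s: 2198.0}
    - {v_mm_s: 3, time_s: 748.0}
    - {v_mm_s: 5, time_s: 506.0}
    - {v_mm_s: 6, time_s: 386.0}
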