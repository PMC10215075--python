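# mcfrw — water diffusion in the mineralized collagen fibril

`mcfrw` is a 3D random-walk model of water transport through the
nanostructure of bone. The mineralized collagen fibril (MCF) — a cylinder
roughly 200 nm across and 1000 nm long — is built explicitly from its two
obstacle families: plate-shaped apatite crystals arranged in the classic
staggered pattern with a 67 nm axial period, and tropocollagen molecules
modelled as 1.23 nm cylinders on a hexagonal lattice. Water molecules
perform obstructed Gaussian random walks through the remaining pore
space, and the package measures how the structure bends and slows them:
local **tortuosity** and **diffusion coefficients** resolved along the
fibril's longitudinal axis. It is intended for researchers studying
nanoscale mass transport in mineralized tissue and for the design of
bone-mimicking scaffold architectures.

## Model in brief

* Geometry: apatite platelets with Gaussian dimensions (mean
  41.80 × 3.55 × 94.51 nm, truncated to literature ranges) on a staggered
  lattice with gaps a_W = 13.19, a_T = 2.35 and a_L = 2·D_period − ℓ =
  39.49 nm, disordered by 6·10⁶ random trial moves with platelet
  inclinations capped at ±20°; mineral volume fraction ≈ 32%.
* Walk: per-coordinate steps of σ = √(2 D₀ Δt) ≈ 1.03 nm with
  D₀ = 2.66·10⁻⁹ m²/s and Δt = 2·10⁻¹⁰ s; a move whose straight path
  would touch an obstacle is rejected and the particle stays put for that
  time step; walks run from the L = 0 plane to the fibril's upper
  extremity.
* Analysis: per-trajectory time-averaged MSD, least-squares line
  MSD = β₀ + β₁t, Einstein relation D = β₁/6; tortuosity = effective path
  length / start-to-end distance; statistics aggregated over
  first-passage sub-trajectories at seven reference quote planes
  (multiples of the 134 nm building block), with 95% Student-t
  confidence intervals.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Build the fibril, check its mineral content (`examples/01_build_geometry.py`):

```text
built lattice: MCFGeometry(986 platelets, R=100.0 nm, L=1000.0 nm, collagen=on)
after perturbation: max platelet inclination 19.9 deg (bound: 20 deg)
mineral volume fraction: 0.329 +/- 0.001  (target 0.32)
```

Profile tortuosity and diffusivity along the axis with ten
fibril-spanning walkers (`examples/04_quote_profile.py`, a few minutes):

```text
 quote_L_nm  n_subtraj  mean_tortuosity  tort_ci_lo  tort_ci_hi  mean_D_m2_per_s      D_ci_lo      D_ci_hi
      134.0         10         2.364277    1.572217    3.156338     1.605746e-10 1.084038e-10 2.127455e-10
      268.0         10         4.891985    2.768709    7.015261     1.742029e-10 1.145271e-10 2.338787e-10
      402.0         10         9.780855    6.263780   13.297931     1.249239e-10 9.747450e-11 1.523732e-10
      536.0         10        10.811956    6.184949   15.438963     1.194957e-10 8.689994e-11 1.520914e-10
      670.0         10        14.657961    4.726412   24.589510     1.211379e-10 7.731792e-11 1.649578e-10
      804.0         10        20.137861    9.311896   30.963825     1.091650e-10 6.623642e-11 1.520936e-10
      938.0         10        27.144921    9.051261   45.238582     1.072545e-10 6.100006e-11 1.535089e-10

tortuosity growth 11.5x from L=134 to L=938 nm; D decrease 33%
```

Reading the numbers: sub-trajectories that only have to reach the first
quote plane (134 nm) are nearly direct (mean tortuosity ≈ 2.4), while
paths spanning the whole fibril wander roughly an order of magnitude
farther than their straight-line distance; correspondingly the mean
diffusion coefficient falls by a few tens of percent and sits at
~10⁻¹⁰ m²/s — an order of magnitude below free water, the signature of
nanoconfinement between apatite platelets and collagen.

`examples/02_free_diffusion.py` verifies the chain end to end in an
empty medium (recovers D₀ within statistical error), and
`examples/03_obstructed_walk.py` exports single trajectories as CSV/XYZ.

A thin CLI wraps the same library calls:

```bash
mcfrw run --config my_config.yaml --out run/     # build -> simulate -> analyze
mcfrw make-fixture --kind slab_array --out maze.txt
```

Every stage is seeded; `run/manifest.json` suffices to replay a pipeline
bit-identically.

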