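"""Simulate water walkers through the mineralized fibril and export one path.

Builds a reduced fibril (for speed), runs a few obstructed walks from the
L = 0 plane to the upper extremity, and writes one trajectory as CSV and
XYZ.  Rejection rates around 80% reflect the nanoconfinement between
apatite platelets and tropocollagen molecules.
"""

from mcfrw import PerturbationConfig, WalkConfig, build_lattice, perturb, \
    simulate_ensemble
from mcfrw.io import trajectory_to_csv, trajectory_to_xyz

geom = build_lattice(rng=1, envelope_radius=50.0, envelope_length=400.0)
geom = perturb(geom, PerturbationConfig(n_moves=500_000, rng_seed=3))
print(f"geometry: {geom!r}")

cfg = WalkConfig(n_trajectories=5, record_stride=10, max_steps=20_000_000,
                 master_seed=8)
ens = simulate_ensemble(geom, cfg)
for i, tr in enumerate(ens):
    rate = tr.n_rejections / max(tr.n_steps, 1)
    print(f"walker {i}: {tr.n_steps} steps to cross 400 nm, "
          f"rejection rate {rate:.2f}, status {tr.status}")

trajectory_to_csv(ens[0], "walker0.csv")
trajectory_to_xyz(ens[0], "walker0.xyz")
print("wrote walker0.csv / walker0.xyz (positions in nm)")
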