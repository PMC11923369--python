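"""Per-domain structural metrics on a synthetic trajectory.

Computes whole-structure RMSD, per-residue RMSF, radius of gyration,
solvent-accessible surface area of one frame, and all-pairs interdomain
center-of-mass distances.
"""

import numpy as np

from pincermd import (PincerSpec, domain_map_for, generate_pincer_trajectory,
                      interdomain_distances, radius_of_gyration, rmsd_series,
                      rmsf, sasa)

spec = PincerSpec(n_domains=4, residues_per_domain=15, jaw_pair=("PAZ", "L2"),
                  amplitude=10.0, period=200, fluctuation_sigma=0.5,
                  n_frames=600, seed=2)
traj = generate_pincer_trajectory(spec)
dmap = domain_map_for(spec)

rmsd = rmsd_series(traj)
print(f"RMSD: mean {rmsd.values.mean():.2f} A, max {rmsd.values.max():.2f} A "
      "(drift from frame 0 after whole-structure superposition)")

# superpose on the static domains so the jaw stroke is not smeared into them
static = traj.topology.atom_indices_for_residues(
    [*dmap.residues_of("N"), *dmap.residues_of("L1")])
fluct = rmsf(traj, superpose_selection=static)
labels = dmap.label_residues(fluct.index)
for dom in ("N", "L2"):
    mask = [labels[int(r)] == dom for r in fluct.index]
    print(f"RMSF of {dom}: mean {fluct.values[mask].mean():.3f} A", end="  ")
print("\n  (N sits at the noise floor sigma*sqrt(3) = 0.87 A; the moving "
      "jaw L2 picks up the stroke)")

rg = radius_of_gyration(traj)
print(f"Rg: {rg.values.mean():.2f} +- {rg.values.std():.2f} A (compactness)")

total, _ = sasa(traj.coords[0], traj.topology)
print(f"SASA of frame 0: {total:.0f} A^2 (probe 1.4 A, Shrake-Rupley)")

dm = interdomain_distances(traj, dmap)
jaw = dm.get("PAZ", "L2").values
print(f"PAZ-L2 jaw distance: {jaw.min():.1f}-{jaw.max():.1f} A "
      "(the open/close stroke; other pairs stay flat)")
print(dm.summary().to_string(index=False))
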