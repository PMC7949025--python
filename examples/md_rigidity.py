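"""Trajectory rigidity statistics for a heterodimer with a rigidified interface.

Builds a two-chain helix-bundle model, generates a Gaussian-fluctuation
trajectory in which the end-helix (EH) surface of chain A is damped (as if
bound), and runs the RMSD / RMSF / delta-RMSF / PCA / H-bond analyses.
"""

import numpy as np

from pntkit import datasets, synth
from pntkit.md import delta_rmsf, hbond_persistence, pca, rmsd_series, rmsf
from pntkit.structures import Structure

a = synth.gen_helix_bundle(datasets.ETV6_HELICES, chain_id="A")
b = synth.gen_helix_bundle(datasets.ETV6_HELICES, chain_id="B")
b.set_coordinates(b.coordinates() + np.array([60.0, 0.0, 0.0]))
dimer = Structure(chains={"A": a.chains["A"], "B": b.chains["B"]})

damped = set(datasets.EH_SURFACE.residues)
sigma = {(res.chain_id, res.number): (0.10 if res.chain_id == "A" and res.number in damped
                                      else 0.45)
         for res in dimer.residues}
traj = synth.gen_trajectory(dimer, sigma, n_frames=300, seed=1)

core = rmsd_series(traj, residue_range=(57, 120), chain_id="A")
print(f"chain A core backbone RMSD vs frame 0: mean {core['rmsd_A'][1:].mean():.2f} A "
      "(a rigid helical core stays near 1 A in the real simulations)")

prof_a = rmsf(traj, chain_id="A")
prof_b = rmsf(traj, chain_id="B")
out = delta_rmsf(prof_b, prof_a)  # positive where chain A fluctuates less
flagged = sorted(out.loc[out["classification"] == "reduced_in_b", "residue"])
print(f"delta-RMSF > 0.3 A flags {len(flagged)} residues rigidified in chain A; "
      f"they coincide with the damped EH surface: {flagged == sorted(damped)}")

result = pca(traj, residue_range=(57, 120), chain_id="A")
top3 = result["variance_fractions"][:3]
print(f"PCA of chain A core motions: first three components carry "
      f"{100 * top3.sum():.0f}% of the variance — uncorrelated Gaussian "
      "fluctuations spread variance across all modes, whereas real "
      "trajectories concentrate it in a few collective terminal motions")

hb = hbond_persistence(traj)
bonded = hb.loc[hb["bonded"] & (hb["chain"] == "A"), "residue"]
helical = [r for r in bonded if datasets.ETV6_HELICES.contains(r)]
print(f"{len(bonded)} chain-A amides are hydrogen bonded (mean N...O <= 3.5 A); "
      f"{len(helical)} of them lie in helices — the residues expected to show "
      "measurable HX protection (log PF > 3)")
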