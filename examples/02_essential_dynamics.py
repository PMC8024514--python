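"""Essential dynamics of a clamping trajectory.

Generates a 1200-frame trajectory in which only the clamp coordinate
oscillates (plus 0.1 A atom noise), aligns it, computes Calpha covariance
PCA and projects the frames onto PC1.  Because the planted motion is a
single collective mode, PC1 captures nearly all variance and its
projection tracks the planted clamp series.
"""

import numpy as np

from ugdyn import align_trajectory, ccs_for_trajectory, compute_pca, make_cc_trajectory, project

t = np.arange(1200)
cc1_series = 40 + 4 * np.sin(2 * np.pi * t / 300)
traj, truth = make_cc_trajectory(cc1_series, 120.0, 10.0, noise_sigma=0.1,
                                 seed=1, n_atoms_per_domain=6)

aligned = align_trajectory(traj)
pcs = compute_pca(aligned)
p1 = project(pcs, aligned, components=[1])[:, 0]
measured_cc1 = np.array([r.cc1 for r in ccs_for_trajectory(aligned, "A")])

explained = pcs.eigenvalues[0] / pcs.eigenvalues.sum()
corr = abs(np.corrcoef(p1, measured_cc1)[0, 1])
print(f"frames: {traj.n_frames}, Calpha atoms: {pcs.n_atoms}")
print(f"PC1 explains {100 * explained:.1f}% of the aligned-ensemble variance")
print(f"|corr(PC1 projection, clamp coordinate)| = {corr:.4f}")
print("A single planted inter-domain motion shows up as one dominant")
print("essential mode whose projection is the motion's time series.")
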