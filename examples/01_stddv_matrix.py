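"""Compute a pair-distance fluctuation (STDDV) matrix from a trajectory.

Builds a synthetic two-domain trajectory with a flexible linker, computes
S without any superposition onto a reference frame, and prints per-atom
mobility summaries.
"""

import numpy as np

from semirigid import (
    DomainSpec,
    compute_stddv,
    generate_domain_trajectory,
    mean_stddv,
    row_means,
)

spec = DomainSpec(domain_sizes=(8, 8), internal_noise_sd=0.02,
                  inter_domain_motion_sd=0.4, n_linker_atoms=3,
                  linker_noise_sd=0.5, n_frames=150, seed=0)
traj, truth = generate_domain_trajectory(spec)
s = compute_stddv(traj, selection=None)

print(f"atoms: {s.n_atoms}, frames used: {s.n_frames_used}")
print(f"mean STDDV over all pairs: {mean_stddv(s):.4f} nm")

means = row_means(s)
print(f"row-mean STDDV, domain atoms:  {means[truth == 0].mean():.4f} nm")
print(f"row-mean STDDV, linker atoms:  {means[truth == -1].mean():.4f} nm")
within = s.values[np.ix_(truth == 0, truth == 0)]
cross = s.values[np.ix_(truth == 0, truth == 1)]
print(f"mean STDDV inside domain 1:    {within.sum() / (8 * 7):.4f} nm")
print(f"mean STDDV across domains:     {cross.mean():.4f} nm")
# Within-domain pair distances barely fluctuate while cross-domain and
# linker distances fluctuate strongly: the block structure the clustering
# stage will exploit.
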