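"""Assess cluster stability across sub-trajectory windows.

Splits a synthetic trajectory into windows, clusters each independently,
aligns labels to the first window, and prints migrations, the per-atom
Kullback-Leibler stability profile and the stiff kernel.
"""

import numpy as np

from semirigid import (
    DomainSpec,
    SearchConfig,
    cluster_windows,
    generate_domain_trajectory,
    mean_stddv,
    migration_series,
    net_migrations,
    stability_profile,
    stiff_kernel,
    two_segment_trend,
)

spec = DomainSpec(domain_sizes=(10, 10, 10), internal_noise_sd=0.05,
                  inter_domain_motion_sd=0.5, n_frames=400, seed=8)
traj, _ = generate_domain_trajectory(spec)

series = cluster_windows(traj, n_clust=3, n_windows=8,
                         cfg=SearchConfig(restarts=20, seed=0))
migr = migration_series(series)
print(f"migrations between consecutive windows: {migr.tolist()}")
print(f"net migrations (first vs last window):  {net_migrations(series)}")

prof = stability_profile(series)
print(f"KLD profile: min {prof.kld.min():.4f}, max {prof.kld.max():.4f} "
      f"(upper bound log10(3) = {np.log10(3):.4f})")
kernel = stiff_kernel(series)
print(f"stiff kernel: {len(kernel)} of {series.n_atoms} atoms never migrate")
# Persistent domains show KLD at the upper bound and a full-size stiff
# kernel; low-KLD atoms hop between clusters and should not anchor a fit.

means = [mean_stddv(w.matrix) for w in series.windows]
first, second = two_segment_trend(means)
print(f"mean-STDDV trend slopes: first {first.slope:+.4f}, "
      f"second {second.slope:+.4f} nm/window")
# A strongly negative first slope would flag a non-equilibrated start;
# here both slopes are near zero because the generator is stationary.
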