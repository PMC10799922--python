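"""Track filtering, MSD analysis, and intensity-based cluster detection.

Simulates membrane-receptor trajectories at 20 Hz (monomeric vs half
4-mer), applies the standard track filter (max step 390 nm = 3 pixels,
minimum lifetime 3 frames = 150 ms), recovers the diffusion coefficient
from the MSD slope, and compares background-subtracted track intensities
between the two conditions.
"""

from iabkit import (
    SimParams,
    estimate_D,
    filter_tracks,
    intensity_distribution,
    msd_curve,
    simulate_tracks,
)

mono = simulate_tracks(SimParams(D_um2_s=0.1, n_particles=300, n_frames=100,
                                 sigma_nm=20.0, multimer_fraction=0.0, seed=0))
clustered = simulate_tracks(SimParams(D_um2_s=0.1, n_particles=300, n_frames=100,
                                      sigma_nm=20.0, multimer_fraction=0.5,
                                      multimer_size=4, seed=1))

for name, ts in (("monomeric", mono), ("clustered", clustered)):
    kept = filter_tracks(ts, max_step_nm=390.0, min_frames=3)
    curve = msd_curve(kept, max_lag=8)
    d_est, intercept = estimate_D(curve)
    _, stats = intensity_distribution(kept, background=50.0)
    print(f"{name}: {len(kept)}/{len(ts)} tracks retained, "
          f"D = {d_est:.3f} um^2/s (truth 0.1), "
          f"mean track intensity = {stats['mean']:.0f} a.u.")

print("\nBoth conditions diffuse alike, but the clustered condition's track "
      "intensity is shifted upward: co-diffusing 4-mers carry ~4x the "
      "fluorescence per spot — the single-particle signature of receptor "
      "clustering without immobilization.")
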