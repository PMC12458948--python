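"""Online similarity matching: binned population activity -> smooth trajectories.

Simulates a session whose 12 units are driven by 2 latent dimensions,
runs the online similarity-matching network over the binned counts, and
measures how close the learned subspace is to the batch PCA subspace
(alignment error 0 = identical).  The smoothed 2-D trajectory is what a
population-dynamics analysis would plot.
"""

import spikesight as ss

activity, latents = ss.synth_latent_session(
    d_latent=2, n_units=12, mixing_seed=0, duration=500.0, bin_width=0.2
)
print(f"activity matrix: {activity.counts.shape[0]} bins x {activity.n_units} units")

traj, state = ss.run_sma(activity, d_out=2, learning_rate=2e-3, seed=0, n_passes=3)
err = ss.subspace_alignment_error(state, activity.counts)
print(f"subspace alignment error vs batch PCA: {err:.4f} (0 = same plane)")

smooth = ss.smooth_trajectory(traj, sigma_s=0.5)
print(f"trajectory: {smooth.coords.shape[0]} time points, "
      f"smoothed with sigma = {smooth.smoothing_sigma} s")
print("first three smoothed coordinates:")
for t in range(3):
    print(f"  t={smooth.times[t]:.2f}s  y=({smooth.coords[t, 0]:+.3f}, {smooth.coords[t, 1]:+.3f})")
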