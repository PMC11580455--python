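"""Single-cell motility metrics from trajectories with programmed reversals.

Generates 20 trajectories recorded for 15 min at 30-s intervals (the
standard gliding assay settings) moving at 2 um/min, each reversing
direction at 5 and 10 min, with positional noise.  Computes per-interval
speeds, counts reversals (>120-degree direction change persisting two
intervals), applies the moved-throughout inclusion filter, and prints the
per-cell summary.
"""

import polefrac as pf

spec = pf.TrackSpec(
    n_tracks=20,
    speed_um_per_min=2.0,
    frame_interval_s=30.0,
    duration_min=15.0,
    reversal_times_min=[5.0, 10.0],
    positional_noise_sd_um=0.08,
    seed=7,
)
tracks, truth = pf.generate_tracks(spec)

table = pf.summarize_motility(tracks, interval_s=30.0, window_min=15.0)

print(table.head(6).round(3).to_string(index=False))
print()
print(f"cells included (moved every interval): {len(table)} / {len(tracks)}")
print(f"mean speed     : {table.mean_speed_um_per_min.mean():.2f} um/min "
      "(programmed 2.00; noise inflates per-interval displacements slightly)")
print(f"mean reversals : {table.reversals_per_window.mean():.2f} per 15 min "
      "(programmed 2 per track)")
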