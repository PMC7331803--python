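"""Marker-cluster kinematics on a synthetic stepping-down trial.

A virtual trial is synthesized (seven rigid marker clusters at 100/s) and
pushed through the full analysis: rigid-pose estimation, gait-event
detection, Euler joint angles, time normalization, and spatiotemporal
outcomes.  The generator's latent truth serves as the yardstick.
"""

import numpy as np

from stepdown import (CohortParameters, analyze_trial, generate_cohort,
                      synthesize_markers, time_normalize)

p = generate_cohort(CohortParameters(n_participants=1, seed=5))[0]
trial = synthesize_markers(p, "low", 0.05, "heel", np.random.default_rng(1),
                           noise_sd_deg=0.0)
kin = analyze_trial(trial.markers, trial.geometry, trial.fs)

lat = trial.latent
print(f"events   latent: {lat.events.hs_pre}/{lat.events.landing}/"
      f"{lat.events.hs_next}   detected: {kin.events.hs_pre}/"
      f"{kin.events.landing}/{kin.events.hs_next}  (samples)")
print(f"walking speed: {kin.walking_speed_mps:.4f} m/s "
      f"(latent {lat.speed_mps:.4f})")
print(f"step length  : {kin.step_length_m:.4f} m "
      f"(latent {lat.step_length_m:.4f})")
for joint in ("ankle", "knee"):
    truth = time_normalize(lat.angles_deg[joint], lat.events)
    rms = np.sqrt(np.mean((kin.curves[f"{joint}_deg"] - truth) ** 2))
    print(f"{joint:5s} angle curve RMS vs latent: {rms:.2e} deg")
print("\nAt zero marker noise the pipeline reproduces the latent joint "
      "angles exactly (rigid round trip); landing is pinned at node 50 of "
      "the 101-node normalized cycle.")
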