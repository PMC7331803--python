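"""Simulate one participant through the adaptive protocol and fit the
psychometric switching-height curve.

The protocol presents 6-trial blocks on the 0.025-0.150 m height grid,
bracketing the height at which the participant switches from heel to toe
landings; the logistic fit estimates that switching height h_crit.
"""

import numpy as np

from stepdown import (CohortParameters, fit_psychometric, generate_cohort,
                      heel_probability, respond, run_protocol)

cohort = generate_cohort(CohortParameters(n_participants=1, seed=42))
p = cohort[0]
print(f"latent truth: h_crit(low) = {p.true_hcrit_low:.4f} m, "
      f"slope = {p.true_slope:.0f} /m")

rng = np.random.default_rng(0)
records = run_protocol(lambda h: respond(p, "low", h, rng),
                       participant_id=p.id, condition="low")
for height in sorted({r.step_height_m for r in records}):
    block = [r.strategy for r in records if r.step_height_m == height]
    print(f"  {height:.3f} m : {block.count('heel')}/6 heel")

fit = fit_psychometric([r.step_height_m for r in records],
                       [r.strategy for r in records])
print(f"\nfit: h_crit = {fit.h_crit:.4f} m ({fit.status}), "
      f"slope = {fit.slope:.0f} /m, {fit.n_trials} trials")
print(f"error vs latent truth: {abs(fit.h_crit - p.true_hcrit_low) * 1000:.1f} mm")
if fit.status in ("interior", "separated"):
    print(f"P(heel) at the fitted h_crit = "
          f"{heel_probability(fit, fit.h_crit):.2f}  (0.5 by definition)")
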