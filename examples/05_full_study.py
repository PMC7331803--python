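"""Run a complete synthetic study end to end and print its report table.

Covers every stage: cohort generation, adaptive protocol, psychometric
fits, sequential and fixed-n Bayesian tests, electrodermal and fear
summaries, fear-group interaction, arousal regression, kinematics, and
the trajectory SPM on the heel-landing subset.
"""

from stepdown import CohortParameters, StudyConfig, run_study

report = run_study(StudyConfig(cohort=CohortParameters(seed=7)))

print(report.table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(f"\nsequential design: stopped at n = {report.sequential.n_current} "
      f"({report.sequential.stop_reason})")
print("prior robustness  :",
      ", ".join(f"gamma={s:.3f} -> BF10={b:.1f}" for s, b in report.robustness))
inter = report.results["interaction"]
reg = report.results["regression"]
print(f"fear-group interaction BF10 = {inter.bf10:.2f}" if inter else
      "fear-group interaction: not estimable (a group was empty)")
print(f"arousal regression: R^2 = {reg.r_squared:.2f}, BF10 = {reg.bf10:.2f}")
for key, res in report.spm_results.items():
    where = res.clusters if res.clusters else "none"
    print(f"SPM {key:12s}: clusters {where}")
print("\nEach row mirrors the study's summary layout: condition means, the "
      "t statistic, the Bayes factor and the posterior effect summary.  "
      "SPM clusters are absent or small on heel-landing curves, echoing "
      "the published null trajectory finding (the slight walking-speed "
      "drop under threat scales angular-velocity amplitudes, so a stray "
      "velocity cluster can appear).")
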