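"""Moderated multilevel mediation with Monte-Carlo inference.

Fits the behavior->perception model for the patient group: does the motor
response (reaction time) mediate the effect of stimulus intensity on
perceptual ratings, and does the mediation differ between pain and touch?
"""

from trialmed import (GeneratorConfig, TrialTable, generate_dataset, exclude_trials,
                      center_intensity, zscore_by_stratum, fit_mediation_models,
                      estimate_effects, modality_difference_p, backtransform)

table = generate_dataset(GeneratorConfig(seed=7))
table, _ = exclude_trials(table)
table = zscore_by_stratum(center_intensity(table))

patients = TrialTable(table.df[table.df.group == "patient"].reset_index(drop=True),
                      dict(table.meta))
pair = fit_mediation_models(patients, "behavior_perception")
est = estimate_effects(pair, n_sims=1000, seed=1)

for lvl in ("pain", "touch"):
    me, (lo, hi) = est.points[("me", lvl)], est.cis[("me", lvl)]
    prop = est.points[("prop", lvl)]
    print(f"{lvl:6s} ME = {me:+.3f} [{lo:+.3f}; {hi:+.3f}]  "
          f"prop mediated = {100 * prop:5.1f}%  "
          f"significant: {est.significant[('me', lvl)]}")

diff = modality_difference_p(est, "me")
print(f"\npain - touch ME difference: {diff['diff_point']:+.3f} "
      f"[{diff['diff_ci'][0]:+.3f}; {diff['diff_ci'][1]:+.3f}], p {diff['p_str']}")

orig = backtransform(est, table.meta, "patient", pair.outcome_var)
print(f"\nIn original units ({orig.unit}) per one intensity level:")
for lvl in ("pain", "touch"):
    print(f"  {lvl:6s} ME = {orig.effects[('me', lvl)]:+.2f}  "
          f"DE = {orig.effects[('de', lvl)]:+.2f}")
# A large pain ME with a near-zero touch ME reproduces the planted
# moderated-mediation structure: motor responses carry a substantial share
# of the stimulus->perception effect for pain but not for touch.
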