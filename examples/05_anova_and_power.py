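"""Repeated-measures ANOVAs and simulation-based power.

First the mixed between(group) x within(modality, intensity) ANOVA on
subject cell means; then a small power grid for the mediation effect.
"""

from trialmed import (GeneratorConfig, generate_dataset, exclude_trials,
                      center_intensity, zscore_by_stratum, cell_means,
                      mixed_anova, power_analysis)

table = generate_dataset(GeneratorConfig(seed=7))
table, _ = exclude_trials(table)
table = zscore_by_stratum(center_intensity(table))

cm = cell_means(table)
res = mixed_anova(cm, "rt_ms")
print("ANOVA on reaction times:")
print(res.table[["effect", "df", "error_df", "F", "p"]].round(3).to_string(index=False))
# Strong intensity and modality:intensity effects mirror faster responses
# to more intense (especially painful) stimuli.

base = GeneratorConfig(n_subjects_per_group=11, n_blocks=2,
                       misident_rate=0.0, zero_rating_rate=0.0,
                       order_trials=False)
power = power_analysis(base, {"n_subjects": [6, 11, 22]}, n_replicates=20,
                       seed=9, group="patient", modality="pain", n_sims=300)
print("\nPower of the pain mediation effect by sample size:")
print(power.to_string(index=False))
# Power of detecting the planted ME rises with the number of subjects.
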