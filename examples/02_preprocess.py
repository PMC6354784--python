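"""Trial exclusion and standardization.

Applies the three exclusion rules in order (misidentified modality, zero
ratings, reaction times beyond 2 SDs of the subject's own mean), centers
stimulus intensity to -1/0/+1 and z-scores ratings and reaction times
within group x modality strata.
"""

from trialmed import (GeneratorConfig, generate_dataset, exclude_trials,
                      center_intensity, zscore_by_stratum)

table = generate_dataset(GeneratorConfig(seed=7))
table, report = exclude_trials(table)
print(f"input {report.n_input} trials -> retained {report.n_retained} "
      f"({report.n_misidentified} misidentified, {report.n_zero_rating} zero-rating, "
      f"{report.n_rt_outlier} RT outliers)")

table = zscore_by_stratum(center_intensity(table))
print("\nz-scoring strata (mean, SD) stored for back-transformation:")
for key, (mu, sd) in sorted(table.meta["zscore_stats"].items()):
    print(f"  {key:24s} mean={mu:7.2f}  sd={sd:6.2f}")
# Each stratum SD later converts standardized effects back to ms / NRS points.
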