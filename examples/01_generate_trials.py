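"""Generate a synthetic pain/touch psychophysics dataset.

Builds the full two-group paradigm — 22 chronic-pain patients and 22
controls, 4 blocks of 54 pseudorandomized trials (2 modalities x 3
calibrated intensity levels x 9 repeats), NRS ratings and reaction times
with a configurable mediation structure — and prints its shape.
"""

from trialmed import GeneratorConfig, generate_dataset, write_trials

cfg = GeneratorConfig(seed=7)
table = generate_dataset(cfg)
write_trials(table, "synthetic_trials.csv")

df = table.df
print(f"{len(df)} trials, {df.subject_id.nunique()} subjects "
      f"({(df.group == 'patient').sum() // 216} patients)")
print("\nMean rating per modality x intensity level:")
print(df.groupby(["modality", "intensity_level"])["rating"].mean().round(1))
print("\nMean reaction time (ms):")
print(df.groupby(["modality", "intensity_level"])["rt_ms"].mean().round(0))
# Ratings rise and reaction times fall with stimulus intensity: the
# stimulus drives both perception and the speeded motor response.
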