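import numpy as np
import pandas as pd
import pytest

from trialmed import (GeneratorConfig, PathSet, TrialTable, generate_dataset,
                      exclude_trials, center_intensity, zscore_by_stratum)


def make_table(df_kwargs: dict | None = None, n: int = 6) -> TrialTable:
    """Hand-buildable minimal valid table (single subject unless overridden)."""
    base = {
        "subject_id": ["P01"] * n,
        "group": ["patient"] * n,
        "modality": (["pain", "touch"] * n)[:n],
        "intensity_level": ([1, 2, 3] * n)[:n],
        "stimulus_magnitude": [500.0] * n,
        "rating": [50.0] * n,
        "rt_ms": [400.0] * n,
        "modality_correct": [True] * n,
        "block": [1] * n,
    }
    if df_kwargs:
        base.update(df_kwargs)
    return TrialTable(pd.DataFrame(base))


def preprocess(table: TrialTable) -> TrialTable:
    table, _ = exclude_trials(table)
    return zscore_by_stratum(center_intensity(table))


def standardize_only(table: TrialTable) -> TrialTable:
    """Centering + z-scoring without trial exclusion.

    The 2-SD RT rule truncates the mediator distribution when RT mediates,
    attenuating the stimulus->RT path; calibration/recovery experiments
    against closed-form latent truths therefore skip it.
    """
    return zscore_by_stratum(center_intensity(table))


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_subjects_per_group=8, n_blocks=2, order_trials=False,
                           seed=20260922)


@pytest.fixture(scope="session")
def small_raw(small_config) -> TrialTable:
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_preprocessed(small_raw) -> TrialTable:
    return preprocess(small_raw.copy())


@pytest.fixture(scope="session")
def strong_mediation_config() -> GeneratorConfig:
    """Comfortable effect sizes for recovery-style checks."""
    paths = {
        (g, m): PathSet(a=0.5, b=0.4, c_prime=0.1) for g in ("patient", "control")
        for m in ("pain", "touch")
    }
    # narrow observable mappings keep rating clipping / RT flooring negligible,
    # so closed-form latent truths apply exactly
    return GeneratorConfig(n_subjects_per_group=12, n_blocks=2, paths=paths,
                           misident_rate=0.0, zero_rating_rate=0.0,
                           rating_anchor=(40.0, 50.0, 60.0), rt_sd_ms=60.0,
                           order_trials=False, seed=7)
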