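"""Trial exclusion, intensity centering and stratified z-scoring.

Exclusion rules, applied in order (each trial counted once):

1. modality misidentified (``modality_correct == False``)
2. zero rating
3. reaction time farther than 2 SDs from the subject's own mean
   (computed over trials surviving 1-2, by default separately per
   modality; single pass, no re-trimming)

z-scoring is stratified — by default per group x modality — and the
stratum means/SDs are stored in the table meta so standardized effects can
later be expressed back in milliseconds or NRS points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .trial_data import TrialTable

logger = logging.getLogger(__name__)

__all__ = ["ExclusionReport", "exclude_trials", "center_intensity", "zscore_by_stratum",
           "ZeroVarianceError"]


class ZeroVarianceError(ValueError):
    """A z-scoring stratum has no variance in the requested variable."""


@dataclass
class ExclusionReport:
    """Bookkeeping of the exclusion pass; counts partition the input."""

    n_input: int
    n_misidentified: int
    n_zero_rating: int
    n_rt_outlier: int
    n_retained: int
    per_subject_per_cell_counts: dict = field(default_factory=dict)
    skipped_cells: list = field(default_factory=list)

    def __post_init__(self) -> None:
        total = self.n_misidentified + self.n_zero_rating + self.n_rt_outlier + self.n_retained
        if total != self.n_input:
            raise ValueError(
                f"exclusion counts do not partition input: {total} != {self.n_input}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_subject_per_cell_counts"] = {
            "|".join(map(str, k)): v for k, v in self.per_subject_per_cell_counts.items()
        }
        return d


def exclude_trials(
    table: TrialTable,
    rt_outlier_pool: str = "modality",
    rt_sd_threshold: float = 2.0,
) -> tuple[TrialTable, ExclusionReport]:
    """Apply the three exclusion rules in order; single pass.

    Parameters
    ----------
    table : TrialTable
        Raw (unexcluded) trials.
    rt_outlier_pool : {"modality", "all"}
        Whether the per-subject RT mean/SD pools both modalities ("all") or
        is computed per modality ("modality", default).
    rt_sd_threshold : float
        Trials with ``|rt - mean| > threshold * SD`` are dropped.

    Returns
    -------
    (TrialTable, ExclusionReport)

    Notes
    -----
    Cells (subject [x modality]) with fewer than 3 trials surviving rules
    1-2 skip the RT-outlier rule (logged in ``report.skipped_cells``): an
    SD from < 3 trials is too unstable to trim on.
    """
    if len(table) == 0:
        raise ValueError("exclude_trials: empty table")
    if table.meta.get("excluded"):
        raise ValueError("exclude_trials already applied to this table (single-pass rule)")
    if rt_outlier_pool not in ("modality", "all"):
        raise ValueError(f"rt_outlier_pool must be 'modality' or 'all', got {rt_outlier_pool!r}")

    df = table.df
    misident = ~df["modality_correct"].to_numpy(dtype=bool)
    zero = (df["rating"].to_numpy() == 0.0) & ~misident

    survivors = df[~(misident | zero)]
    keys = ["subject_id"] if rt_outlier_pool == "all" else ["subject_id", "modality"]
    grp = survivors.groupby(keys, observed=True)["rt_ms"]
    stats = grp.agg(["mean", "std", "count"])

    skipped = [k if isinstance(k, tuple) else (k,) for k in stats.index[stats["count"] < 3]]
    stats.loc[stats["count"] < 3, "std"] = np.inf  # disables the rule for that cell
    stats["std"] = stats["std"].fillna(0.0)  # count==1 handled by skip; safety

    merged = survivors[keys + ["rt_ms"]].join(stats, on=keys)
    outlier_local = (
        (merged["rt_ms"] - merged["mean"]).abs() > rt_sd_threshold * merged["std"]
    ).to_numpy()
    outlier = np.zeros(len(df), dtype=bool)
    outlier[np.flatnonzero(~(misident | zero))] = outlier_local

    keep = ~(misident | zero | outlier)
    out_df = df[keep].reset_index(drop=True)

    cell_counts = (
        out_df.groupby(["subject_id", "modality", "intensity_level"], observed=True)
        .size()
        .to_dict()
    )
    report = ExclusionReport(
        n_input=len(df),
        n_misidentified=int(misident.sum()),
        n_zero_rating=int(zero.sum()),
        n_rt_outlier=int(outlier.sum()),
        n_retained=int(keep.sum()),
        per_subject_per_cell_counts=cell_counts,
        skipped_cells=[tuple(k) for k in skipped],
    )
    for cell in report.skipped_cells:
        logger.warning("RT-outlier rule skipped for cell %s (<3 surviving trials)", cell)

    meta = dict(table.meta)
    meta["excluded"] = True
    meta["exclusion_report"] = report.to_dict()
    return TrialTable(out_df, meta=meta), report


def center_intensity(table: TrialTable) -> TrialTable:
    """Add ``centered_intensity = intensity_level - 2`` (values -1/0/+1)."""
    df = table.df.copy()
    df["centered_intensity"] = df["intensity_level"].astype(float) - 2.0
    return TrialTable(df, meta=dict(table.meta))


def zscore_by_stratum(
    table: TrialTable,
    variables: tuple[str, ...] = ("rating", "rt_ms"),
    strata: tuple[str, ...] = ("group", "modality"),
) -> TrialTable:
    """Standardize variables within strata; store the (mean, SD) per stratum.

    Default strata are group x modality: ratings and reaction times are
    z-transformed across all trials and subjects of a group, separately for
    pain and touch, so modality- and group-level distribution differences
    do not leak into the mediation paths. SD uses the n-1 denominator.

    Adds ``z_rating`` / ``z_rt`` columns; originals are preserved. The
    stratum statistics land in ``meta['zscore_stats']`` keyed
    ``"var|stratum1|stratum2"`` for later back-transformation.
    """
    df = table.df.copy()
    zname = {"rating": "z_rating", "rt_ms": "z_rt"}
    stats: dict[str, tuple[float, float]] = {}
    for var in variables:
        col = np.full(len(df), np.nan)
        for key, sub in df.groupby(list(strata), observed=True):
            key = key if isinstance(key, tuple) else (key,)
            x = sub[var].to_numpy(dtype=float)
            if len(x) < 2:
                raise ZeroVarianceError(
                    f"stratum {dict(zip(strata, key))} has < 2 trials for {var}"
                )
            mu = float(x.mean())
            sd = float(x.std(ddof=1))
            if sd == 0.0:
                raise ZeroVarianceError(
                    f"stratum {dict(zip(strata, key))} has zero variance in {var}"
                )
            col[df.index.get_indexer(sub.index)] = (x - mu) / sd
            stats["|".join([var, *map(str, key)])] = (mu, sd)
        df[zname.get(var, f"z_{var}")] = col
    meta = dict(table.meta)
    meta["zscore_stats"] = stats
    meta["zscore_strata"] = list(strata)
    return TrialTable(df, meta=meta)
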