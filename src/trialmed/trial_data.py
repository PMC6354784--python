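"""Trial-level data container and CSV I/O.

One row per stimulus trial. The :class:`TrialTable` is the currency every
pipeline stage consumes and returns: a validated :class:`pandas.DataFrame`
plus a ``meta`` dict that accumulates provenance (generator config hash,
z-scoring statistics, processing-stage flags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("patient", "control")
MODALITIES = ("pain", "touch")
INTENSITY_LEVELS = (1, 2, 3)

#: maximal paradigm-conformant stimulus magnitudes (laser mJ, von Frey mN)
MAX_MAGNITUDE = {"pain": 600.0, "touch": 512.0}

#: the nine canonical columns, in on-disk order
COLUMNS = [
    "subject_id",
    "group",
    "modality",
    "intensity_level",
    "stimulus_magnitude",
    "rating",
    "rt_ms",
    "modality_correct",
    "block",
]


class TrialDataError(ValueError):
    """Malformed trial data (missing column, bad cell, invariant violation)."""


def _as_bool(x: Any) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {x!r}")


@dataclass
class TrialTable:
    """Validated table of stimulus trials.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per trial with the nine canonical columns (extra derived
        columns such as ``centered_intensity`` or ``z_rating`` may be
        appended by pipeline stages).
    meta : dict
        Provenance: source path or generator seed/config hash, z-scoring
        statistics, processing-stage flags.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise TrialDataError(f"missing required column(s): {', '.join(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        if list(self.df.columns) != list(other.df.columns):
            return False
        try:
            pd.testing.assert_frame_equal(
                self.df.reset_index(drop=True), other.df.reset_index(drop=True)
            )
        except AssertionError:
            return False
        return True

    def copy(self) -> "TrialTable":
        return TrialTable(self.df.copy(), dict(self.meta))

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique().tolist())

    def subject_groups(self) -> dict[str, str]:
        """Map subject_id -> group (each subject belongs to exactly one)."""
        g = self.df.groupby("subject_id", observed=True)["group"].agg(set)
        bad = g[g.map(len) > 1]
        if len(bad):
            raise TrialDataError(
                f"subject(s) mapped to more than one group: {sorted(bad.index)}"
            )
        return {s: next(iter(v)) for s, v in g.items()}

    def validate(self, paradigm_conformant: bool = False) -> None:
        """Raise :class:`TrialDataError` on any invariant violation."""
        bad = _violation_mask(self.df, paradigm_conformant=paradigm_conformant)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialDataError(
                f"{int(bad.sum())} row(s) violate trial invariants (first: row {i})"
            )
        self.subject_groups()
        dup = self.df.duplicated(subset=["subject_id", "block", "trial_in_block"]).any() \
            if "trial_in_block" in self.df.columns else False
        if dup:
            raise TrialDataError("duplicate (subject_id, block, trial_in_block) key")


def _violation_mask(df: pd.DataFrame, paradigm_conformant: bool = False) -> pd.Series:
    """Boolean mask of rows violating per-record invariants."""
    m = pd.Series(False, index=df.index)
    m |= ~df["group"].isin(GROUPS)
    m |= ~df["modality"].isin(MODALITIES)
    m |= ~df["intensity_level"].isin(INTENSITY_LEVELS)
    m |= ~df["block"].between(1, 4)
    m |= ~df["rating"].between(0.0, 100.0)
    m |= ~(df["rt_ms"] > 0.0)
    m |= ~(df["stimulus_magnitude"] >= 0.0)
    if paradigm_conformant:
        cap = df["modality"].map(MAX_MAGNITUDE).astype(float)
        m |= df["stimulus_magnitude"] > cap
    return m


_DTYPES = {
    "subject_id": str,
    "group": str,
    "modality": str,
    "intensity_level": "int64",
    "stimulus_magnitude": "float64",
    "rating": "float64",
    "rt_ms": "float64",
    "block": "int64",
}


def read_trials(path: str | Path, strict: bool = True) -> TrialTable:
    """Read a trial table from CSV.

    Parameters
    ----------
    path : path
        Comma-separated file with a header row containing the nine
        canonical columns (extra columns are preserved).
    strict : bool
        If True, any invariant violation or unparseable cell raises
        :class:`TrialDataError`. If False, offending rows are dropped and
        counted in ``meta['n_dropped_on_read']``.

    Returns
    -------
    TrialTable
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise TrialDataError(f"{path}: missing required column(s): {', '.join(missing)}")

    n_dropped = 0
    if len(raw) == 0:
        df = pd.DataFrame({c: pd.Series(dtype=_DTYPES.get(c, object)) for c in raw.columns})
        df["modality_correct"] = pd.Series(dtype=bool)
        df = df[list(raw.columns)]
        return TrialTable(df, meta={"source": str(path), "n_dropped_on_read": 0})

    df = raw.copy()
    parse_bad = pd.Series(False, index=df.index)
    for col, dt in _DTYPES.items():
        if col in ("subject_id", "group", "modality"):
            continue
        conv = pd.to_numeric(df[col], errors="coerce")
        parse_bad |= conv.isna()
        df[col] = conv
    try:
        df["modality_correct"] = raw["modality_correct"].map(_as_bool)
    except ValueError:
        bools = raw["modality_correct"].map(
            lambda x: _as_bool(x) if str(x).strip().lower() in ("true", "false", "0", "1") else None
        )
        parse_bad |= bools.isna()
        df["modality_correct"] = bools

    if parse_bad.any():
        if strict:
            i = int(np.flatnonzero(parse_bad.to_numpy())[0])
            raise TrialDataError(f"{path}: unparseable cell(s) in data row {i}")
        n_dropped += int(parse_bad.sum())
        df = df[~parse_bad]

    # integer coercion after NaN filtering
    for col in ("intensity_level", "block"):
        nonint = df[col] != df[col].round()
        if nonint.any():
            if strict:
                i = int(np.flatnonzero(nonint.to_numpy())[0])
                raise TrialDataError(f"{path}: non-integer {col} in data row {i}")
            n_dropped += int(nonint.sum())
            df = df[~nonint]
        df[col] = df[col].round().astype("int64")

    bad = _violation_mask(df)
    if bad.any():
        if strict:
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialDataError(
                f"{path}: {int(bad.sum())} row(s) violate invariants (first: data row {i})"
            )
        n_dropped += int(bad.sum())
        df = df[~bad]

    df = df.reset_index(drop=True)
    df["modality_correct"] = df["modality_correct"].astype(bool)
    # derived pipeline columns (z-scores, centered intensity) come back numeric
    for col in df.columns:
        if col in COLUMNS:
            continue
        conv = pd.to_numeric(df[col], errors="coerce")
        if not conv.isna().any():
            df[col] = conv
    table = TrialTable(df, meta={"source": str(path), "n_dropped_on_read": n_dropped})
    if n_dropped:
        logger.info("read_trials(%s): dropped %d invalid row(s)", path, n_dropped)
    if strict:
        table.validate()
    return table


def write_trials(table: TrialTable, path: str | Path) -> Path:
    """Write a trial table to CSV, losslessly re-readable by :func:`read_trials`.

    Floats are serialized with ``repr`` round-trip precision.
    """
    path = Path(path)
    df = table.df.copy()
    df.to_csv(path, index=False, float_format=None)
    return path
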