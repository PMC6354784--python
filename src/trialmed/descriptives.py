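"""Supporting statistics: mixed between-within repeated-measures ANOVA on
subject-level cell means, and Pearson correlations for covariate checks
(e.g., medication load vs average ratings).

The ANOVA is the classical univariate decomposition for one between-subject
factor (group) crossed with two within-subject factors (modality,
intensity), subjects nested in groups, one cell-mean observation per
subject x modality x intensity. Each within-subject effect is tested
against its own effect-by-subject interaction error term. Group sizes may
be unequal; the within-subject design must be complete (subjects with an
empty cell are dropped listwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trial_data import TrialTable

logger = logging.getLogger(__name__)

__all__ = ["CellMeansTable", "AnovaTable", "cell_means", "mixed_anova",
           "pearson_correlations"]

_CELL_FACTORS = ["modality", "intensity_level"]


@dataclass
class CellMeansTable:
    """Per-subject cell means of rating and rt_ms (long format).

    Exactly 6 within-subject cells per retained subject; subjects with an
    empty cell are listed in ``dropped_subjects``.
    """

    df: pd.DataFrame  # columns: subject_id, group, modality, intensity_level, rating, rt_ms
    dropped_subjects: list = field(default_factory=list)

    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()


@dataclass
class AnovaTable:
    """Mixed-design ANOVA results.

    ``table`` rows: one per tested effect with columns
    (effect, ss, df, error_term, error_ss, error_df, F, p
    [, partial_eta_sq, gg_epsilon, p_gg]).
    """

    table: pd.DataFrame
    error_ss: dict = field(default_factory=dict)
    error_df: dict = field(default_factory=dict)
    ss_total: float = 0.0

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.set_index("effect").loc[effect]


def cell_means(table: TrialTable) -> CellMeansTable:
    """Average rating and rt_ms per subject x modality x intensity cell.

    Subjects missing any of the 6 cells are dropped with a log entry.
    """
    df = table.df
    cm = (
        df.groupby(["subject_id", "group", *_CELL_FACTORS], observed=True)[["rating", "rt_ms"]]
        .mean()
        .reset_index()
    )
    counts = cm.groupby("subject_id", observed=True).size()
    dropped = sorted(counts.index[counts < 6].tolist())
    if dropped:
        logger.info("cell_means: dropped %d subject(s) with empty cells: %s",
                    len(dropped), dropped)
        cm = cm[~cm["subject_id"].isin(dropped)]
    return CellMeansTable(cm.reset_index(drop=True), dropped_subjects=dropped)


def _gg_epsilon(scores: np.ndarray, groups: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from pooled within-group contrast covariance."""
    mats = []
    weights = []
    for g in np.unique(groups):
        sub = scores[groups == g]
        if len(sub) < 2:
            continue
        mats.append(np.cov(sub, rowvar=False) * (len(sub) - 1))
        weights.append(len(sub) - 1)
    S = sum(mats) / sum(weights)
    T = contrasts @ S @ contrasts.T
    d = T.shape[0]
    eps = np.trace(T) ** 2 / (d * np.trace(T @ T))
    return float(min(max(eps, 1.0 / d), 1.0))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (Helmert-based)."""
    H = np.zeros((k - 1, k))
    for j in range(1, k):
        H[j - 1, :j] = 1.0
        H[j - 1, j] = -j
        H[j - 1] /= np.linalg.norm(H[j - 1])
    return H


def mixed_anova(cells: CellMeansTable, variable: str,
                gg_correction: bool = False,
                partial_eta_sq: bool = False) -> AnovaTable:
    """Mixed between(group) x within(modality, intensity) ANOVA.

    Sums of squares come from the orthogonal decomposition of the cell
    means around the weighted grand mean; each within effect is tested
    against its interaction with subjects (nested in groups). With
    ``gg_correction`` the Greenhouse-Geisser epsilon rescales the dfs of
    multi-df within-subject tests.
    """
    df = cells.df
    counts = df.groupby("subject_id", observed=True).size()
    if (counts != 6).any():
        raise ValueError("each subject must contribute exactly 6 cells")
    piv = df.pivot_table(index=["group", "subject_id"], columns=_CELL_FACTORS,
                         values=variable, observed=True)
    piv = piv.sort_index(axis=1)
    mods = piv.columns.get_level_values(0).unique().tolist()
    lvls = piv.columns.get_level_values(1).unique().tolist()
    m, i = len(mods), len(lvls)
    groups_arr = piv.index.get_level_values(0).to_numpy()
    glabels, gidx = np.unique(groups_arr, return_inverse=True)
    a = len(glabels)
    n_g = np.bincount(gidx).astype(float)
    if np.any(n_g < 2):
        raise ValueError("need >= 2 subjects per group")
    N = int(n_g.sum())

    # Y[s, m, i] per subject
    Y = piv.to_numpy().reshape(N, m, i)
    grand = Y.mean()
    T_gs = Y.mean(axis=(1, 2))                       # subject means
    T_g = np.array([T_gs[gidx == g].mean() for g in range(a)])
    M_gm = np.stack([Y[gidx == g].mean(axis=(0, 2)) for g in range(a)])  # (a, m)
    I_gi = np.stack([Y[gidx == g].mean(axis=(0, 1)) for g in range(a)])  # (a, i)
    C_gmi = np.stack([Y[gidx == g].mean(axis=0) for g in range(a)])      # (a, m, i)
    M_m = (n_g[:, None] * M_gm).sum(0) / N
    I_i = (n_g[:, None] * I_gi).sum(0) / N
    C_mi = (n_g[:, None, None] * C_gmi).sum(0) / N

    mi = m * i
    ss = {}
    ss["group"] = mi * float((n_g * (T_g - grand) ** 2).sum())
    ss_between = mi * float(((T_gs - grand) ** 2).sum())
    err_subj = ss_between - ss["group"]

    ss["modality"] = i * N * float(((M_m - grand) ** 2).sum())
    dev_gm = M_gm - T_g[:, None] - (M_m - grand)[None, :]
    ss["group:modality"] = i * float((n_g[:, None] * dev_gm ** 2).sum())
    Y_gsm = Y.mean(axis=2)
    err_m = i * float(((Y_gsm - T_gs[:, None] - (M_gm - T_g[:, None])[gidx]) ** 2).sum())

    ss["intensity"] = m * N * float(((I_i - grand) ** 2).sum())
    dev_gi = I_gi - T_g[:, None] - (I_i - grand)[None, :]
    ss["group:intensity"] = m * float((n_g[:, None] * dev_gi ** 2).sum())
    Y_gsi = Y.mean(axis=1)
    err_i = m * float(((Y_gsi - T_gs[:, None] - (I_gi - T_g[:, None])[gidx]) ** 2).sum())

    mi_dev = C_mi - M_m[:, None] - I_i[None, :] + grand
    ss["modality:intensity"] = N * float((mi_dev ** 2).sum())
    gmi_dev = (C_gmi - M_gm[:, :, None] - I_gi[:, None, :] + T_g[:, None, None]) - mi_dev[None]
    ss["group:modality:intensity"] = float((n_g[:, None, None] * gmi_dev ** 2).sum())
    within_cell = (
        Y - Y_gsm[:, :, None] - Y_gsi[:, None, :] + T_gs[:, None, None]
        - (C_gmi - M_gm[:, :, None] - I_gi[:, None, :] + T_g[:, None, None])[gidx]
    )
    err_mi = float((within_cell ** 2).sum())

    dfs = {
        "group": a - 1,
        "modality": m - 1,
        "group:modality": (a - 1) * (m - 1),
        "intensity": i - 1,
        "group:intensity": (a - 1) * (i - 1),
        "modality:intensity": (m - 1) * (i - 1),
        "group:modality:intensity": (a - 1) * (m - 1) * (i - 1),
    }
    error_ss = {"subjects": err_subj, "modality:subjects": err_m,
                "intensity:subjects": err_i, "modality:intensity:subjects": err_mi}
    error_df = {"subjects": N - a, "modality:subjects": (N - a) * (m - 1),
                "intensity:subjects": (N - a) * (i - 1),
                "modality:intensity:subjects": (N - a) * (m - 1) * (i - 1)}
    error_of = {
        "group": "subjects",
        "modality": "modality:subjects", "group:modality": "modality:subjects",
        "intensity": "intensity:subjects", "group:intensity": "intensity:subjects",
        "modality:intensity": "modality:intensity:subjects",
        "group:modality:intensity": "modality:intensity:subjects",
    }

    eps = {}
    if gg_correction:
        Cm = _orthonormal_contrasts(m)
        Ci = _orthonormal_contrasts(i)
        eps["modality:subjects"] = _gg_epsilon(Y_gsm, gidx, Cm) if m > 2 else 1.0
        eps["intensity:subjects"] = _gg_epsilon(Y_gsi, gidx, Ci) if i > 2 else 1.0
        eps["modality:intensity:subjects"] = (
            _gg_epsilon(Y.reshape(N, mi), gidx, np.kron(Cm, Ci)) if (m - 1) * (i - 1) > 1
            else 1.0
        )

    rows = []
    for eff, s in ss.items():
        et = error_of[eff]
        df1, df2 = dfs[eff], error_df[et]
        mse = error_ss[et] / df2 if df2 > 0 else np.nan
        F = (s / df1) / mse if mse > 0 else 0.0
        p = float(sps.f.sf(F, df1, df2)) if mse > 0 else np.nan
        row = {"effect": eff, "ss": s, "df": df1, "error_term": et,
               "error_ss": error_ss[et], "error_df": df2, "F": F, "p": p}
        if partial_eta_sq:
            denom = s + error_ss[et]
            row["partial_eta_sq"] = s / denom if denom > 0 else np.nan
        if gg_correction and et in eps:
            e = eps[et]
            row["gg_epsilon"] = e
            row["p_gg"] = float(sps.f.sf(F, df1 * e, df2 * e)) if mse > 0 else np.nan
        rows.append(row)
    out = AnovaTable(table=pd.DataFrame(rows), error_ss=error_ss, error_df=error_df,
                     ss_total=float(((Y - grand) ** 2).sum()))
    return out


def pearson_correlations(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-test p (n-2 df).

    Raises on fewer than 3 pairs or zero variance in either variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
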