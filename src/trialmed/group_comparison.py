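"""Permutation test for the group difference in proportion mediated.

The observed statistic is the patients-minus-controls difference of the
proportion mediated for one mediation direction and one modality. Under
the null of exchangeable group labels, subjects (all their trials at once)
are randomly reassigned to two groups of the original sizes, the full
mediation pipeline is re-run for both pseudo-groups, and the difference is
recomputed; the p-value carries the +1 Monte-Carlo correction so it can
never be zero.

Preprocessing (exclusion, centering, z-scoring) happens once, before
permutation; relabeling operates on the preprocessed table. The engine
precomputes per-subject sufficient statistics for both mixed models, so a
permutation costs four small REML fits rather than four passes over the
raw data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trial_data import TrialTable
from .mixed_models import (LmmSpec, build_design, subject_suffstats, reml_fit,
                           FitError, coding_values)
from .mediation import MediationModelPair, draw_parameters, TE_EPS

logger = logging.getLogger(__name__)


def _prop_point(fit_med, fit_out, med_terms, out_terms, w: float,
                n_sims: int, seed: int) -> float:
    """Lean single-modality proportion-mediated point (median of ratios)."""
    ss = np.random.SeedSequence(seed)
    c_med, c_out = ss.spawn(2)
    med = draw_parameters(fit_med, n_sims, np.random.default_rng(c_med))
    out = draw_parameters(fit_out, n_sims, np.random.default_rng(c_out))
    a = med[:, med_terms.index("X")] + med[:, med_terms.index("X:W")] * w
    b = out[:, out_terms.index("M")] + out[:, out_terms.index("M:W")] * w
    cp = out[:, out_terms.index("X")] + out[:, out_terms.index("X:W")] * w
    me = a * b
    te = me + cp
    ok = np.abs(te) >= TE_EPS
    if not ok.any():
        return np.nan
    return float(np.median(me[ok] / te[ok]))

__all__ = ["PermutationResult", "permute_group_labels", "PermutationEngine",
           "permutation_test"]


@dataclass
class PermutationResult:
    observed_diff: float
    perm_diffs: np.ndarray
    p_value: float
    n_perm: int
    sidedness: str  # one_sided_exceed | two_sided_abs
    seed: int
    direction: str
    modality: str
    n_sims_inner: int
    n_nonconverged: int = 0
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return {
            "observed_diff": self.observed_diff,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "sidedness": self.sidedness,
            "seed": self.seed,
            "direction": self.direction,
            "modality": self.modality,
            "n_sims_inner": self.n_sims_inner,
            "n_nonconverged": self.n_nonconverged,
            "n_redrawn": self.n_redrawn,
            "perm_diffs": np.asarray(self.perm_diffs).tolist(),
        }


def permute_group_labels(subject_groups: dict[str, str],
                         seed: int | np.random.Generator) -> dict[str, str]:
    """Uniformly random relabeling preserving the group sizes.

    All of a subject's trials move together (the subject, not the trial,
    is the exchangeable unit). Deterministic given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subjects = sorted(subject_groups)
    labels = np.array([subject_groups[s] for s in subjects])
    return dict(zip(subjects, rng.permutation(labels)))


class PermutationEngine:
    """Precomputed sufficient statistics for fast relabeled mediation runs."""

    def __init__(self, table: TrialTable, direction: str, coding: str = "reference",
                 random_slope: bool = True, reml: bool = True):
        med_var, out_var = MediationModelPair._VARS[direction]
        self.direction = direction
        self.coding = coding
        self.reml = reml
        med_spec = LmmSpec(outcome=med_var, fixed_terms=("intercept", "X", "W", "X:W"),
                           random_slope=random_slope, reml=reml)
        out_spec = LmmSpec(outcome=out_var,
                           fixed_terms=("intercept", "X", "W", "X:W", "M", "M:W"),
                           mediator=med_var, random_slope=random_slope, reml=reml)
        df = table.df
        Xm, Zm, ym, codes, ids = build_design(df, med_spec, coding)
        self.st_med = subject_suffstats(Xm, Zm, ym, codes, ids)
        Xo, Zo, yo, codes_o, ids_o = build_design(df, out_spec, coding)
        assert ids == ids_o
        self.st_out = subject_suffstats(Xo, Zo, yo, codes_o, ids_o)
        self.med_terms = med_spec.fixed_terms
        self.out_terms = out_spec.fixed_terms
        self.subject_ids = ids
        self.original_groups = {s: g for s, g in table.subject_groups().items()}
        self._warm: dict[str, np.ndarray | None] = {"med": None, "out": None}

    def group_prop(self, subject_idx: np.ndarray, modality: str, n_sims: int,
                   seed: int) -> tuple[float, bool]:
        """Proportion mediated for the subjects in ``subject_idx``.

        Returns (prop_point, all_fits_converged). Raises FitError if a
        model cannot be fit at all.
        """
        fit_med = reml_fit(self.st_med.subset(subject_idx), reml=self.reml,
                           term_names=self.med_terms, x0=self._warm["med"], fast=True)
        fit_out = reml_fit(self.st_out.subset(subject_idx), reml=self.reml,
                           term_names=self.out_terms, x0=self._warm["out"], fast=True)
        if self._warm["med"] is None and fit_med.theta is not None and fit_med.converged:
            self._warm["med"] = fit_med.theta
        if self._warm["out"] is None and fit_out.theta is not None and fit_out.converged:
            self._warm["out"] = fit_out.theta
        prop = _prop_point(fit_med, fit_out, self.med_terms, self.out_terms,
                           coding_values(self.coding)[modality], n_sims, seed)
        return prop, fit_med.converged and fit_out.converged

    def prop_diff(self, labels: dict[str, str], modality: str, n_sims: int,
                  seed: int) -> tuple[float, bool]:
        """Patients-minus-controls proportion-mediated difference."""
        idx_p = np.array([i for i, s in enumerate(self.subject_ids)
                          if labels[s] == "patient"])
        idx_c = np.array([i for i, s in enumerate(self.subject_ids)
                          if labels[s] == "control"])
        ss = np.random.SeedSequence(seed)
        s_p, s_c = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
        prop_p, ok_p = self.group_prop(idx_p, modality, n_sims, s_p)
        prop_c, ok_c = self.group_prop(idx_c, modality, n_sims, s_c)
        return prop_p - prop_c, ok_p and ok_c


def permutation_test(
    table: TrialTable,
    direction: str,
    modality: str,
    n_perm: int = 1000,
    n_sims_inner: int = 200,
    seed: int = 0,
    sidedness: str = "two_sided_abs",
    coding: str = "reference",
    reuse_inner_seed: bool = False,
    max_redraws_per_perm: int = 3,
    max_nonconverged_frac: float = 0.10,
) -> PermutationResult:
    """Subject-relabeling permutation test of the group prop-mediated difference.

    The observed statistic uses the same inner Monte-Carlo budget as the
    permuted ones, keeping observed and permuted values exchangeable.
    With ``reuse_inner_seed`` every relabeling (and the observed labeling)
    shares one set of inner Monte-Carlo draws, making the statistic a
    deterministic function of the labels — the variant that admits exact
    enumeration at tiny n (identical relabelings are then cached); by
    default inner draws are re-randomized per permutation.
    Permutations whose mediation fails outright are redrawn (bounded);
    fits that only needed the random-slope fallback are counted as
    non-converged diagnostics, and the test aborts if more than
    ``max_nonconverged_frac`` of permutations relied on them.
    """
    if sidedness not in ("one_sided_exceed", "two_sided_abs"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if modality not in ("pain", "touch"):
        raise ValueError(f"unknown modality {modality!r}")
    engine = PermutationEngine(table, direction, coding)
    groups0 = engine.original_groups
    if set(groups0.values()) != {"patient", "control"}:
        raise ValueError("table must contain both groups")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_perm + 1)
    obs_seed = int(children[0].generate_state(1)[0] % (2**31))
    observed, _ = engine.prop_diff(groups0, modality, n_sims_inner, obs_seed)

    diffs = np.empty(n_perm)
    n_nonconv = 0
    n_redrawn = 0
    cache: dict | None = {} if reuse_inner_seed else None
    for r in range(n_perm):
        rng = np.random.default_rng(children[r + 1])
        for attempt in range(max_redraws_per_perm + 1):
            labels = permute_group_labels(groups0, rng)
            inner_seed = obs_seed if reuse_inner_seed else int(rng.integers(0, 2**31))
            key = (frozenset(s for s, g in labels.items() if g == "patient")
                   if cache is not None else None)
            if key is not None and key in cache:
                d, ok = cache[key]
                break
            try:
                d, ok = engine.prop_diff(labels, modality, n_sims_inner, inner_seed)
                if key is not None:
                    cache[key] = (d, ok)
                break
            except FitError:
                n_redrawn += 1
                if attempt == max_redraws_per_perm:
                    raise
        diffs[r] = d
        if not ok:
            n_nonconv += 1
    if n_nonconv > max_nonconverged_frac * n_perm:
        raise RuntimeError(
            f"{n_nonconv}/{n_perm} permutations needed the non-convergence fallback; "
            "permutation p would be unreliable"
        )

    if sidedness == "two_sided_abs":
        n_qual = int((np.abs(diffs) >= abs(observed)).sum())
    else:
        n_qual = int((diffs >= observed).sum())
    p = (n_qual + 1) / (n_perm + 1)
    return PermutationResult(
        observed_diff=float(observed), perm_diffs=diffs, p_value=float(p),
        n_perm=n_perm, sidedness=sidedness, seed=seed, direction=direction,
        modality=modality, n_sims_inner=n_sims_inner,
        n_nonconverged=n_nonconv, n_redrawn=n_redrawn,
    )
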