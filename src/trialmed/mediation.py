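"""Quasi-Bayesian Monte-Carlo moderated mediation.

Given the two fitted mixed models (mediator model M ~ X*W, outcome model
Y ~ X*W + M + M:W), each Monte-Carlo draw k samples both models' fixed
effects from their asymptotic normal distributions and evaluates, at each
moderator level w (touch/pain):

    a_k(w)  = alpha_X + alpha_XW * w          (stimulus -> mediator)
    b_k(w)  = gamma_M + gamma_MW * w          (mediator -> outcome)
    c'_k(w) = gamma_X + gamma_XW * w          (direct)

    ME_k = a_k * b_k,  DE_k = c'_k,  TE_k = ME_k + DE_k,
    prop_k = ME_k / TE_k

Because the outcome model carries no X:M interaction, TE = ME + DE holds
exactly for every draw. Point estimates are draw means (median for the
heavy-tailed proportion mediated); 95% CIs are 2.5/97.5 percentiles; an
effect is significant when its CI excludes zero. Modality differences are
tested by subtracting the pain and touch draw vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mixed_models import LmmFit, coding_values

logger = logging.getLogger(__name__)

__all__ = [
    "MediationModelPair", "MediationEstimate", "OriginalUnitsReport",
    "draw_parameters", "estimate_effects", "modality_difference_p",
    "ci_nonoverlap", "backtransform",
]

#: draws with |TE| below this are dropped from the proportion distribution
TE_EPS = 1e-12

EFFECTS = ("me", "de", "te", "prop")
LEVELS = ("pain", "touch")


@dataclass
class MediationModelPair:
    """The two fitted models of one mediation direction for one group.

    direction 'perception_behavior': ratings mediate the stimulus -> RT
    effect (mediator = z_rating, outcome = z_rt). 'behavior_perception':
    RTs mediate the stimulus -> rating effect.
    """

    direction: str
    mediator_fit: LmmFit
    outcome_fit: LmmFit
    coding: str = "reference"

    _VARS = {
        "perception_behavior": ("z_rating", "z_rt"),
        "behavior_perception": ("z_rt", "z_rating"),
    }

    def __post_init__(self) -> None:
        if self.direction not in self._VARS:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def mediator_var(self) -> str:
        return self._VARS[self.direction][0]

    @property
    def outcome_var(self) -> str:
        return self._VARS[self.direction][1]


@dataclass
class MediationEstimate:
    """Monte-Carlo mediation summary per moderator level."""

    direction: str
    n_sims: int
    seed: int
    coding: str
    points: dict = field(default_factory=dict)       # (effect, level) -> float
    cis: dict = field(default_factory=dict)          # (effect, level) -> (lo, hi)
    draws: dict = field(default_factory=dict)        # (effect, level) -> ndarray
    significant: dict = field(default_factory=dict)  # (effect, level) -> bool
    n_prop_excluded: dict = field(default_factory=dict)  # level -> int

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "coding": self.coding,
            "points": {f"{e}_{l}": v for (e, l), v in self.points.items()},
            "cis": {f"{e}_{l}": list(v) for (e, l), v in self.cis.items()},
            "significant": {f"{e}_{l}": v for (e, l), v in self.significant.items()},
            "n_prop_excluded": dict(self.n_prop_excluded),
        }


@dataclass
class OriginalUnitsReport:
    """Effects per one-level intensity increase in outcome units.

    Milliseconds when the outcome is reaction time, NRS points when it is
    the perceptual rating.
    """

    outcome_var: str
    unit: str
    effects: dict = field(default_factory=dict)  # (effect, level) -> float
    cis: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outcome_var": self.outcome_var,
            "unit": self.unit,
            "effects": {f"{e}_{l}": v for (e, l), v in self.effects.items()},
            "cis": {f"{e}_{l}": list(v) for (e, l), v in self.cis.items()},
        }


def fit_mediation_models(table, direction: str, coding: str = "reference",
                         random_slope: bool = True, reml: bool = True) -> MediationModelPair:
    """Fit the mediator and outcome mixed models for one group's table.

    The mediator model is ``M ~ X*W`` and the outcome model
    ``Y ~ X*W + M + M:W`` (no X:M interaction, so the additive
    decomposition TE = ME + DE is exact), both with per-subject random
    intercept and intensity slope.
    """
    from .mixed_models import LmmSpec, fit_lmm

    pair_vars = MediationModelPair._VARS
    if direction not in pair_vars:
        raise ValueError(f"unknown direction {direction!r}")
    med_var, out_var = pair_vars[direction]
    med_spec = LmmSpec(outcome=med_var, fixed_terms=("intercept", "X", "W", "X:W"),
                       random_slope=random_slope, reml=reml)
    out_spec = LmmSpec(outcome=out_var,
                       fixed_terms=("intercept", "X", "W", "X:W", "M", "M:W"),
                       mediator=med_var, random_slope=random_slope, reml=reml)
    return MediationModelPair(
        direction=direction,
        mediator_fit=fit_lmm(table, med_spec, coding),
        outcome_fit=fit_lmm(table, out_spec, coding),
        coding=coding,
    )


def draw_parameters(fit: LmmFit, n_sims: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw fixed-effect vectors from N(beta, vcov_beta).

    This is the quasi-Bayesian approximation: the asymptotic sampling
    distribution of the fixed effects stands in for their posterior.
    Deterministic given seed; a zero covariance returns ``beta`` in every
    row. Raises on a non-positive-semidefinite covariance (no repair).
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    V = np.asarray(fit.vcov_beta, dtype=float)
    if not np.allclose(V, V.T, atol=1e-10):
        raise ValueError("vcov_beta not symmetric")
    w = np.linalg.eigvalsh(V)
    scale = max(1.0, float(w[-1]))
    if w[0] < -1e-10 * scale:
        raise ValueError(f"vcov_beta not positive semidefinite (min eigenvalue {w[0]:.3g})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_normal(np.asarray(fit.beta, float), V, size=n_sims,
                                   method="svd", check_valid="ignore")


def _paths_from_draws(pair: MediationModelPair, med_draws: np.ndarray,
                      out_draws: np.ndarray, w: float):
    mt = pair.mediator_fit.term_names
    ot = pair.outcome_fit.term_names
    a = med_draws[:, mt.index("X")] + med_draws[:, mt.index("X:W")] * w
    b = out_draws[:, ot.index("M")] + out_draws[:, ot.index("M:W")] * w
    cp = out_draws[:, ot.index("X")] + out_draws[:, ot.index("X:W")] * w
    return a, b, cp


def estimate_effects(pair: MediationModelPair, n_sims: int = 1000,
                     seed: int = 0) -> MediationEstimate:
    """Run the Monte-Carlo mediation for both moderator levels.

    Mediator- and outcome-model draws are independent (the models are fit
    separately, so no cross-model covariance exists). Per draw and level,
    TE = ME + DE exactly; the proportion mediated excludes draws with
    |TE| < 1e-12 and its point estimate is the median of the retained
    ratios (the ratio distribution is heavy-tailed).
    """
    ss = np.random.SeedSequence(seed)
    s_med, s_out = ss.spawn(2)
    med_draws = draw_parameters(pair.mediator_fit, n_sims, np.random.default_rng(s_med))
    out_draws = draw_parameters(pair.outcome_fit, n_sims, np.random.default_rng(s_out))

    est = MediationEstimate(direction=pair.direction, n_sims=n_sims, seed=seed,
                            coding=pair.coding)
    wmap = coding_values(pair.coding)
    for level in LEVELS:
        a, b, cp = _paths_from_draws(pair, med_draws, out_draws, wmap[level])
        me = a * b
        de = cp
        te = me + de
        ok = np.abs(te) >= TE_EPS
        n_excl = int((~ok).sum())
        if n_excl:
            logger.info("prop mediated: excluded %d near-zero-TE draw(s) at level %s",
                        n_excl, level)
        prop = me[ok] / te[ok]
        est.n_prop_excluded[level] = n_excl
        for name, vec in (("me", me), ("de", de), ("te", te), ("prop", prop)):
            est.draws[(name, level)] = vec
            if name == "prop":
                est.points[(name, level)] = float(np.median(vec)) if len(vec) else np.nan
            else:
                est.points[(name, level)] = float(vec.mean())
            lo, hi = (np.percentile(vec, [2.5, 97.5]) if len(vec) else (np.nan, np.nan))
            est.cis[(name, level)] = (float(lo), float(hi))
            est.significant[(name, level)] = bool(lo > 0.0 or hi < 0.0)
    return est


def modality_difference_p(estimate: MediationEstimate, effect: str = "me"):
    """Exact Monte-Carlo p for the pain-touch difference of an effect.

    Subtracts the two modality draw vectors; two-sided p is twice the
    smaller tail of the sign distribution (zeros split evenly), floored at
    2/n_sims and then reported as an inequality string alongside.

    Returns
    -------
    dict with keys ``p``, ``p_str``, ``diff_ci``, ``diff_point``, ``warning``.
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    d_pain = estimate.draws[(effect, "pain")]
    d_touch = estimate.draws[(effect, "touch")]
    warning = None
    if effect == "prop":
        n = min(len(d_pain), len(d_touch))
        n_excl = sum(estimate.n_prop_excluded.values())
        if n_excl > 0.2 * estimate.n_sims:
            warning = (f"{n_excl} of {estimate.n_sims} draws excluded for near-zero "
                       "total effect; p unreliable")
        d = d_pain[:n] - d_touch[:n]
    else:
        d = d_pain - d_touch
    n = len(d)
    n_pos = int((d > 0).sum())
    n_neg = int((d < 0).sum())
    n_zero = n - n_pos - n_neg
    p = 2.0 * (min(n_pos, n_neg) + 0.5 * n_zero) / n
    floor = 2.0 / n
    if p < floor:
        p_str = f"< {floor:g}"
        p = floor
    else:
        p_str = f"{min(p, 1.0):g}"
    lo, hi = np.percentile(d, [2.5, 97.5])
    return {
        "p": float(min(p, 1.0)),
        "p_str": p_str,
        "diff_point": float(d.mean()),
        "diff_ci": (float(lo), float(hi)),
        "warning": warning,
    }


def ci_nonoverlap(estimate: MediationEstimate, effect: str = "me") -> bool:
    """Screening helper: do the pain and touch 95% CIs fail to overlap?"""
    lo_p, hi_p = estimate.cis[(effect, "pain")]
    lo_t, hi_t = estimate.cis[(effect, "touch")]
    return bool(hi_p < lo_t or hi_t < lo_p)


def backtransform(estimate: MediationEstimate, meta: dict, group: str,
                  outcome_var: str) -> OriginalUnitsReport:
    """Express standardized effects in original outcome units.

    Multiplies each standardized effect (and CI) by the z-scoring stratum
    SD of the outcome variable for that group and modality, yielding the
    average effect of a one-level stimulus intensity increase in ms (RT
    outcomes) or NRS points (rating outcomes).
    """
    stats = meta.get("zscore_stats")
    if not stats:
        raise ValueError("table meta lacks zscore_stats; run zscore_by_stratum first")
    raw_var = {"z_rt": "rt_ms", "z_rating": "rating"}[outcome_var]
    unit = {"z_rt": "ms", "z_rating": "NRS points"}[outcome_var]
    rep = OriginalUnitsReport(outcome_var=outcome_var, unit=unit)
    for level in LEVELS:
        key = f"{raw_var}|{group}|{level}"
        if key not in stats:
            raise ValueError(f"missing z-scoring stratum statistics for {key!r}")
        sd = stats[key][1]
        for eff in ("me", "de", "te"):
            rep.effects[(eff, level)] = estimate.points[(eff, level)] * sd
            lo, hi = estimate.cis[(eff, level)]
            rep.cis[(eff, level)] = (lo * sd, hi * sd)
    return rep
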