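"""Synthetic trial generator for the pain/touch psychophysics paradigm.

Emulates the two-group experiment the analysis pipeline expects: patients
and controls, two stimulus modalities (laser heat = pain, von Frey = touch),
three calibrated intensity levels, four blocks of pseudorandomly ordered
trials, 0-100 NRS ratings and speeded modality-identification reaction
times.

The generative model lives on standardized latent scales with centered
intensity ``X in {-1, 0, +1}``::

    M = a*X + u0_i + u1_i*X + eps        (mediator latent)
    Y = c'*X + b*M + v0_i + v1_i*X + eta (outcome latent)

with per-subject random intercepts/slopes ``u, v`` and path coefficients
``a`` (stimulus->mediator), ``b`` (mediator->outcome) and ``c'`` (direct),
configurable per group and modality. Latents are affine-mapped to
observables; the *behavior* latent is sign-flipped into reaction times
(larger latent = faster response), so path signs follow the convention of
z-scored analyses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trial_data import TrialTable, COLUMNS, GROUPS, MODALITIES

__all__ = [
    "PathSet",
    "GeneratorConfig",
    "generate_dataset",
    "pseudorandom_sequence",
    "calibrate_intensities",
    "true_standardized_effects",
    "SequenceError",
    "CalibrationError",
]

#: centered intensity has Var = 2/3 over a balanced {-1, 0, +1} design
_VAR_X = 2.0 / 3.0

#: lower clip of physical magnitudes (von Frey filaments start at 8 mN)
_MAG_RANGE = {"pain": (0.0, 600.0), "touch": (8.0, 512.0)}


class SequenceError(RuntimeError):
    """Pseudorandom block sequence constraints unsatisfiable."""


class CalibrationError(ValueError):
    """Stimulus-response calibration failed (non-increasing perception)."""


@dataclass(frozen=True)
class PathSet:
    """Standardized mediation paths for one group x modality cell.

    a : stimulus -> mediator slope per intensity level
    b : mediator -> outcome slope
    c_prime : direct stimulus -> outcome slope
    """

    a: float
    b: float
    c_prime: float


def _default_paths() -> dict[tuple[str, str], PathSet]:
    # factored from published point estimates of the behavior->perception
    # mediation (ME = a*b, DE = c'): props ~ 46%/2% (patients), 31%/-2% (controls)
    return {
        ("patient", "pain"): PathSet(a=0.335, b=0.20, c_prime=0.08),
        ("patient", "touch"): PathSet(a=0.07, b=0.10, c_prime=0.32),
        ("control", "pain"): PathSet(a=0.25, b=0.20, c_prime=0.11),
        ("control", "touch"): PathSet(a=-0.05, b=0.10, c_prime=0.34),
    }


def _default_magnitudes() -> dict[str, tuple]:
    return {
        "pain": ((479.0, 525.0, 571.0), (57.0, 59.0, 62.0)),
        "touch": ((188.0, 290.0, 456.0), (73.0, 81.0, 91.0)),
    }


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic paradigm.

    Defaults reproduce the study layout: 22 subjects per group, 4 blocks of
    54 trials (9 per modality x intensity cell), intensity calibration
    aiming at NRS 30/50/70, reaction times around 500 ms decreasing with
    intensity, a small modality-misidentification rate and occasional zero
    ratings.
    """

    n_subjects_per_group: int = 22
    n_blocks: int = 4
    trials_per_cell_per_block: int = 9
    direction: str = "behavior_mediates"  # | perception_mediates | none
    paths: dict = field(default_factory=_default_paths)
    sd_subject_intercept_m: float = 0.3
    sd_subject_slope_m: float = 0.1
    sd_subject_intercept_y: float = 0.3
    sd_subject_slope_y: float = 0.1
    sd_resid_m: float = 0.9
    sd_resid_y: float = 0.9
    rating_anchor: tuple = (30.0, 50.0, 70.0)
    rt_mean_ms: float = 500.0
    rt_sd_ms: float = 100.0
    misident_rate: float = 0.04
    zero_rating_rate: float = 0.02
    magnitude_params: dict = field(default_factory=_default_magnitudes)
    order_trials: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_blocks < 1 or self.trials_per_cell_per_block < 1:
            raise ValueError("counts must be positive")
        if self.direction not in ("behavior_mediates", "perception_mediates", "none"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        for g in GROUPS:
            for m in MODALITIES:
                if (g, m) not in self.paths:
                    raise ValueError(f"paths missing cell {(g, m)}")
        sds = [
            self.sd_subject_intercept_m, self.sd_subject_slope_m,
            self.sd_subject_intercept_y, self.sd_subject_slope_y,
        ]
        if any(s < 0 for s in sds):
            raise ValueError("random-effect SDs must be >= 0")
        if self.sd_resid_m < 0 or self.sd_resid_y < 0:
            raise ValueError("residual SDs must be >= 0")
        for r in (self.misident_rate, self.zero_rating_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        if not (self.rating_anchor[0] < self.rating_anchor[1] < self.rating_anchor[2]):
            raise ValueError("rating anchors must be strictly increasing")
        if self.rt_sd_ms < 0 or self.rt_mean_ms <= 0:
            raise ValueError("rt parameters invalid")

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, PathSet):
                return asdict(o)
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        payload = json.dumps(enc(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _latent_sds(cfg: GeneratorConfig, group: str, modality: str) -> tuple[float, float]:
    """Marginal SDs of the mediator and outcome latents (balanced design)."""
    p = cfg.paths[(group, modality)]
    var_m = (
        p.a ** 2 * _VAR_X
        + cfg.sd_subject_intercept_m ** 2
        + cfg.sd_subject_slope_m ** 2 * _VAR_X
        + cfg.sd_resid_m ** 2
    )
    var_y = (
        (p.c_prime + p.a * p.b) ** 2 * _VAR_X
        + p.b ** 2 * (cfg.sd_subject_intercept_m ** 2 + cfg.sd_subject_slope_m ** 2 * _VAR_X + cfg.sd_resid_m ** 2)
        + cfg.sd_subject_intercept_y ** 2
        + cfg.sd_subject_slope_y ** 2 * _VAR_X
        + cfg.sd_resid_y ** 2
    )
    return float(np.sqrt(var_m)), float(np.sqrt(var_y))


def true_standardized_effects(
    cfg: GeneratorConfig, group: str, modality: str, analysis_direction: str | None = None
) -> dict[str, float]:
    """Closed-form population effects on the z-scored analysis scale.

    After stratum z-scoring the fitted paths become ``a/sd_M`` and
    ``b*sd_M/sd_Y`` (times a sign flip whenever the reaction-time variable
    enters, because faster responses mean a *larger* behavior latent), so::

        ME = +/- a*b / sd_Y,  DE = +/- c' / sd_Y,  prop = a*b / (a*b + c')

    The proportion mediated is invariant to all scalings and sign flips.
    """
    direction = analysis_direction or cfg.direction
    p = cfg.paths[(group, modality)]
    _, sd_y = _latent_sds(cfg, group, modality)
    me = p.a * p.b / sd_y
    de = p.c_prime / sd_y
    # RT is the outcome in the perception->behavior analysis: one sign flip
    # (accepts either generator or analysis naming for the direction)
    if direction in ("perception_mediates", "perception_behavior"):
        me, de = -me, -de
    te = me + de
    prop = (p.a * p.b) / (p.a * p.b + p.c_prime) if (p.a * p.b + p.c_prime) != 0 else np.nan
    return {"me": me, "de": de, "te": te, "prop": prop}


def pseudorandom_sequence(
    block_spec: Mapping[tuple[str, int], int] | None,
    seed: int,
    max_intensity_run: int = 2,
    max_modality_run: int = 3,
    max_restarts: int = 10_000,
) -> list[tuple[str, int]]:
    """Order one block's trials under the paradigm's run-length constraints.

    No more than ``max_intensity_run`` consecutive trials share an intensity
    level and no more than ``max_modality_run`` share a modality. Sampling is
    sequential: each next trial is drawn uniformly among the remaining trials
    that keep both constraints satisfiable locally; dead ends trigger a
    restart. Deterministic given ``seed``.

    Parameters
    ----------
    block_spec : mapping (modality, intensity_level) -> count, or None
        None means the standard block: 9 trials per modality x intensity.
    """
    if block_spec is None:
        block_spec = {(m, l): 9 for m in MODALITIES for l in (1, 2, 3)}
    cells = [c for c, n in block_spec.items() if n > 0]
    total = sum(block_spec.values())
    rng = np.random.default_rng(seed)

    for _ in range(max_restarts):
        counts = dict(block_spec)
        seq: list[tuple[str, int]] = []
        run_mod, run_int = 0, 0
        last_mod: str | None = None
        last_int: int | None = None
        ok = True
        for _t in range(total):
            cand = []
            weights = []
            for (mod, lvl) in cells:
                n = counts[(mod, lvl)]
                if n <= 0:
                    continue
                if mod == last_mod and run_mod >= max_modality_run:
                    continue
                if lvl == last_int and run_int >= max_intensity_run:
                    continue
                cand.append((mod, lvl))
                weights.append(n)
            if not cand:
                ok = False
                break
            w = np.asarray(weights, dtype=float)
            pick = cand[rng.choice(len(cand), p=w / w.sum())]
            counts[pick] -= 1
            mod, lvl = pick
            run_mod = run_mod + 1 if mod == last_mod else 1
            run_int = run_int + 1 if lvl == last_int else 1
            last_mod, last_int = mod, lvl
            seq.append(pick)
        if ok:
            return seq
    raise SequenceError(
        f"could not satisfy run-length constraints for block spec {dict(block_spec)} "
        f"after {max_restarts} restarts"
    )


def calibrate_intensities(
    calib: Sequence[tuple[float, float]],
    targets: Sequence[float] = (30.0, 50.0, 70.0),
    max_magnitude: float = 600.0,
) -> tuple[float, ...]:
    """Invert the calibration regression ``rating = b0 + b1*magnitude``.

    Returns the magnitudes whose predicted ratings equal the targets,
    clipped from above at ``max_magnitude`` (the paradigm's safety cap).

    Raises
    ------
    CalibrationError
        If fewer than two distinct magnitudes were given or the fitted
        slope is not positive (perception not increasing with intensity).
    """
    arr = np.asarray(calib, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(np.unique(arr[:, 0])) < 2:
        raise CalibrationError("need calibration pairs with >= 2 distinct magnitudes")
    b1, b0 = np.polyfit(arr[:, 0], arr[:, 1], deg=1)
    if b1 <= 0:
        raise CalibrationError(f"calibration slope {b1:.4g} is not positive")
    mags = [(t - b0) / b1 for t in targets]
    return tuple(float(min(m, max_magnitude)) for m in mags)


def _subject_ids(cfg: GeneratorConfig) -> list[tuple[str, str]]:
    ids = []
    for group, prefix in (("patient", "P"), ("control", "C")):
        for i in range(cfg.n_subjects_per_group):
            ids.append((f"{prefix}{i + 1:02d}", group))
    return ids


def generate_dataset(cfg: GeneratorConfig) -> TrialTable:
    """Generate a full two-group trial table. Deterministic given cfg.seed.

    Rows are ordered subject -> block -> within-block trial; when
    ``cfg.order_trials`` is set, the within-block order satisfies the
    paradigm's pseudorandomization constraints.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    subjects = _subject_ids(cfg)
    n_sub = len(subjects)
    tpc = cfg.trials_per_cell_per_block
    trials_per_block = 2 * 3 * tpc
    trials_per_subject = cfg.n_blocks * trials_per_block

    # per-subject random effects (mediator and outcome latents)
    u0 = rng.normal(0.0, cfg.sd_subject_intercept_m, n_sub)
    u1 = rng.normal(0.0, cfg.sd_subject_slope_m, n_sub)
    v0 = rng.normal(0.0, cfg.sd_subject_intercept_y, n_sub)
    v1 = rng.normal(0.0, cfg.sd_subject_slope_y, n_sub)

    # per-subject calibrated magnitudes, constant over a subject's cell
    mag = {}
    for si, (sid, _g) in enumerate(subjects):
        for mod in MODALITIES:
            means, sds = cfg.magnitude_params[mod]
            lo, hi = _MAG_RANGE[mod]
            vals = np.clip(rng.normal(means, sds), lo, hi)
            mag[(si, mod)] = np.sort(vals)  # calibration is monotone in level

    # base grid per subject: blocks x (modality x level x tpc)
    base_mods = np.repeat(np.array(MODALITIES, dtype=object), 3 * tpc)
    base_lvls = np.tile(np.repeat(np.array([1, 2, 3]), tpc), 2)

    frames = []
    for si, (sid, group) in enumerate(subjects):
        mods = np.tile(base_mods, cfg.n_blocks)
        lvls = np.tile(base_lvls, cfg.n_blocks)
        blocks = np.repeat(np.arange(1, cfg.n_blocks + 1), trials_per_block)
        if cfg.order_trials:
            mods = mods.copy()
            lvls = lvls.copy()
            for b in range(cfg.n_blocks):
                child = int(rng.integers(0, 2**31 - 1))
                seq = pseudorandom_sequence(
                    {(m, l): tpc for m in MODALITIES for l in (1, 2, 3)}, seed=child
                )
                sl = slice(b * trials_per_block, (b + 1) * trials_per_block)
                mods[sl] = np.array([m for m, _ in seq], dtype=object)
                lvls[sl] = np.array([l for _, l in seq])

        x = lvls.astype(float) - 2.0
        a = np.empty_like(x)
        b_path = np.empty_like(x)
        cp = np.empty_like(x)
        for mod in MODALITIES:
            p = cfg.paths[(group, mod)]
            sel = mods == mod
            a[sel], b_path[sel], cp[sel] = p.a, p.b, p.c_prime
        if cfg.direction == "none":
            b_path = np.zeros_like(b_path)

        eps = rng.normal(0.0, cfg.sd_resid_m, trials_per_subject)
        eta = rng.normal(0.0, cfg.sd_resid_y, trials_per_subject)
        m_lat = a * x + u0[si] + u1[si] * x + eps
        y_lat = cp * x + b_path * m_lat + v0[si] + v1[si] * x + eta

        if cfg.direction == "behavior_mediates":
            behav_lat, percept_lat = m_lat, y_lat
        else:  # perception_mediates or none
            behav_lat, percept_lat = y_lat, m_lat

        s_rating = (cfg.rating_anchor[2] - cfg.rating_anchor[0]) / 2.0
        rating = np.clip(cfg.rating_anchor[1] + s_rating * percept_lat, 0.0, 100.0)
        rt = np.maximum(cfg.rt_mean_ms - cfg.rt_sd_ms * behav_lat, 100.0)

        misident = rng.random(trials_per_subject) < cfg.misident_rate
        zeroed = rng.random(trials_per_subject) < cfg.zero_rating_rate
        rating = np.where(zeroed, 0.0, rating)

        magnitudes = np.empty(trials_per_subject)
        for mod in MODALITIES:
            sel = mods == mod
            magnitudes[sel] = mag[(si, mod)][lvls[sel] - 1]

        frames.append(pd.DataFrame({
            "subject_id": sid,
            "group": group,
            "modality": mods,
            "intensity_level": lvls,
            "stimulus_magnitude": magnitudes,
            "rating": rating,
            "rt_ms": rt,
            "modality_correct": ~misident,
            "block": blocks,
        }))

    df = pd.concat(frames, ignore_index=True)[COLUMNS]
    meta = {
        "generator": {
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "direction": cfg.direction,
            "sign_convention": (
                "larger standardized behavior latent = faster response; "
                "rt_ms = rt_mean_ms - rt_sd_ms * behavior_latent"
            ),
        }
    }
    return TrialTable(df, meta=meta)
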