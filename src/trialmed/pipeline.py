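"""End-to-end orchestration and the simulation-based power extension.

``run_full_analysis`` chains: generate-or-read -> trial exclusion ->
intensity centering -> stratified z-scoring -> per-group mixed-model fits
-> Monte-Carlo moderated mediation per direction -> modality-difference
p-values -> back-transformation to original units -> permutation group
tests -> repeated-measures ANOVAs. One master seed deterministically
derives every stage seed through a fixed ``numpy.random.SeedSequence``
spawn order (generator, mediation, permutations, in that order), so the
whole bundle is reproducible from a single integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .trial_data import TrialTable, read_trials, write_trials, GROUPS, MODALITIES
from .synthetic import GeneratorConfig, PathSet, generate_dataset
from .preprocessing import exclude_trials, center_intensity, zscore_by_stratum
from .mediation import (MediationModelPair, fit_mediation_models, estimate_effects,
                        modality_difference_p, ci_nonoverlap, backtransform)
from .group_comparison import permutation_test
from .descriptives import cell_means, mixed_anova

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ResultsBundle", "run_full_analysis", "power_analysis",
           "ANALYSIS_DIRECTIONS", "GENERATOR_TO_ANALYSIS"]

ANALYSIS_DIRECTIONS = ("perception_behavior", "behavior_perception")

#: which analysis direction matches a generator's mediation structure
GENERATOR_TO_ANALYSIS = {
    "behavior_mediates": "behavior_perception",
    "perception_mediates": "perception_behavior",
}


def _child_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; exactly one data source."""

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    rt_outlier_pool: str = "modality"
    directions: tuple = ANALYSIS_DIRECTIONS
    coding: str = "reference"
    random_slope: bool = True
    n_sims: int = 1000
    n_perm: int = 1000
    n_sims_inner: int = 200
    sidedness: str = "two_sided_abs"
    run_permutations: bool = True
    run_anova: bool = True
    gg_correction: bool = False
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path / generator must be set")
        for d in self.directions:
            if d not in ANALYSIS_DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.config_hash()
        d.pop("output_dir")

        def enc(o):
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        return hashlib.sha256(json.dumps(enc(d), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """All artifacts of one full analysis run."""

    exclusion_report: dict
    estimates: dict = field(default_factory=dict)       # (group, direction) -> MediationEstimate
    original_units: dict = field(default_factory=dict)  # (group, direction) -> OriginalUnitsReport
    modality_p: dict = field(default_factory=dict)      # (group, direction, effect) -> dict
    ci_nonoverlap: dict = field(default_factory=dict)   # (group, direction, effect) -> bool
    permutations: dict = field(default_factory=dict)    # (direction, modality) -> PermutationResult
    anovas: dict = field(default_factory=dict)          # variable -> AnovaTable
    manifest: dict = field(default_factory=dict)
    table: TrialTable | None = None                     # preprocessed table

    def to_dict(self) -> dict:
        out = {
            "manifest": self.manifest,
            "exclusion_report": self.exclusion_report,
            "estimates": {f"{g}|{d}": e.to_dict() for (g, d), e in self.estimates.items()},
            "original_units": {f"{g}|{d}": r.to_dict()
                               for (g, d), r in self.original_units.items()},
            "modality_p": {f"{g}|{d}|{e}": v for (g, d, e), v in self.modality_p.items()},
            "ci_nonoverlap": {f"{g}|{d}|{e}": v for (g, d, e), v in self.ci_nonoverlap.items()},
            "permutations": {f"{d}|{m}": r.to_dict()
                             for (d, m), r in self.permutations.items()},
            "anovas": {v: a.table.to_dict(orient="records") for v, a in self.anovas.items()},
        }
        return out


def run_full_analysis(config: PipelineConfig) -> ResultsBundle:
    """Run the complete pipeline; deterministic given ``config.seed``."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    ss_gen, ss_med, ss_perm = master.spawn(3)

    if config.generator is not None:
        gen_cfg = replace(config.generator, seed=_child_int(ss_gen))
        table = generate_dataset(gen_cfg)
        logger.info("generated %d trials (config %s)", len(table), gen_cfg.config_hash())
    else:
        table = read_trials(config.input_path, strict=True)
        logger.info("read %d trials from %s", len(table), config.input_path)

    table, report = exclude_trials(table, rt_outlier_pool=config.rt_outlier_pool)
    logger.info("exclusion: %d -> %d trials (%d misident, %d zero, %d RT outliers)",
                report.n_input, report.n_retained, report.n_misidentified,
                report.n_zero_rating, report.n_rt_outlier)
    table = center_intensity(table)
    table = zscore_by_stratum(table)

    bundle = ResultsBundle(exclusion_report=report.to_dict(), table=table)
    groups_present = [g for g in GROUPS if (table.df["group"] == g).any()]

    med_children = ss_med.spawn(len(config.directions) * len(groups_present))
    k = 0
    for direction in config.directions:
        for group in groups_present:
            sub = TrialTable(table.df[table.df["group"] == group].reset_index(drop=True),
                             meta=dict(table.meta))
            pair = fit_mediation_models(sub, direction, coding=config.coding,
                                        random_slope=config.random_slope)
            est = estimate_effects(pair, n_sims=config.n_sims,
                                   seed=_child_int(med_children[k]))
            k += 1
            bundle.estimates[(group, direction)] = est
            bundle.original_units[(group, direction)] = backtransform(
                est, table.meta, group, pair.outcome_var)
            for eff in ("me", "de", "prop"):
                bundle.modality_p[(group, direction, eff)] = modality_difference_p(est, eff)
                bundle.ci_nonoverlap[(group, direction, eff)] = ci_nonoverlap(est, eff)
            logger.info("mediation %s/%s: prop(pain)=%.3f prop(touch)=%.3f",
                        group, direction, est.points[("prop", "pain")],
                        est.points[("prop", "touch")])

    if config.run_permutations and len(groups_present) == 2:
        perm_children = ss_perm.spawn(len(config.directions) * len(MODALITIES))
        k = 0
        for direction in config.directions:
            for modality in MODALITIES:
                res = permutation_test(
                    table, direction, modality, n_perm=config.n_perm,
                    n_sims_inner=config.n_sims_inner,
                    seed=_child_int(perm_children[k]), sidedness=config.sidedness,
                    coding=config.coding)
                k += 1
                bundle.permutations[(direction, modality)] = res
                logger.info("permutation %s/%s: observed diff %.3f, p = %.4f",
                            direction, modality, res.observed_diff, res.p_value)

    if config.run_anova:
        cm = cell_means(table)
        for variable in ("rating", "rt_ms"):
            bundle.anovas[variable] = mixed_anova(cm, variable,
                                                  gg_correction=config.gg_correction)

    bundle.manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "seed_scheme": "SeedSequence(master).spawn(3) -> generator, mediation, permutations",
        "n_trials_input": report.n_input,
        "n_trials_retained": report.n_retained,
        "groups": groups_present,
    }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trials(table, outdir / "preprocessed_trials.csv")
        with open(outdir / "results.json", "w") as fh:
            json.dump(bundle.to_dict(), fh, indent=1)
        logger.info("wrote artifacts to %s", outdir)
    return bundle


def power_analysis(
    base_generator: GeneratorConfig,
    grid: dict[str, Sequence],
    n_replicates: int = 100,
    seed: int = 0,
    group: str = "patient",
    modality: str = "pain",
    c_prime: float | None = None,
    n_sims: int = 500,
    include_permutation: bool = False,
    n_perm: int = 99,
    n_sims_inner: int = 100,
) -> pd.DataFrame:
    """Monte-Carlo power of the mediation effect over a design grid.

    Grid keys (each a sequence): ``n_subjects``, ``a``, ``b``,
    ``n_trials`` (trials per modality x intensity cell per block). Power
    is the fraction of replicates whose 95% ME confidence interval for
    ``(group, modality)`` excludes zero, in the analysis direction
    matching the generator's mediation structure; optionally also the
    fraction with a significant permutation group difference.
    """
    from itertools import product

    direction = GENERATOR_TO_ANALYSIS.get(base_generator.direction,
                                          "behavior_perception")
    keys = list(grid)
    allowed = {"n_subjects", "a", "b", "n_trials"}
    unknown = set(keys) - allowed
    if unknown:
        raise ValueError(f"unknown grid key(s): {sorted(unknown)}")
    rows = []
    master = np.random.SeedSequence(seed)
    for values in product(*(grid[k] for k in keys)):
        point = dict(zip(keys, values))
        cfg = base_generator
        if "n_subjects" in point:
            cfg = replace(cfg, n_subjects_per_group=int(point["n_subjects"]))
        if "n_trials" in point:
            cfg = replace(cfg, trials_per_cell_per_block=int(point["n_trials"]))
        if "a" in point or "b" in point:
            paths = dict(cfg.paths)
            old = paths[(group, modality)]
            paths[(group, modality)] = PathSet(
                a=float(point.get("a", old.a)), b=float(point.get("b", old.b)),
                c_prime=old.c_prime if c_prime is None else c_prime)
            cfg = replace(cfg, paths=paths)
        hits = 0
        perm_hits = 0
        children = master.spawn(n_replicates)
        for r in range(n_replicates):
            ss = children[r]
            s_gen, s_est, s_perm = ss.spawn(3)
            rep_cfg = replace(cfg, seed=_child_int(s_gen), order_trials=False)
            table = generate_dataset(rep_cfg)
            table, _ = exclude_trials(table)
            table = center_intensity(table)
            table = zscore_by_stratum(table)
            sub = TrialTable(table.df[table.df["group"] == group].reset_index(drop=True),
                             meta=dict(table.meta))
            pair = fit_mediation_models(sub, direction)
            est = estimate_effects(pair, n_sims=n_sims, seed=_child_int(s_est))
            hits += est.significant[("me", modality)]
            if include_permutation:
                res = permutation_test(table, direction, modality, n_perm=n_perm,
                                       n_sims_inner=n_sims_inner,
                                       seed=_child_int(s_perm))
                perm_hits += res.p_value < 0.05
        row = dict(point)
        row["power_me"] = hits / n_replicates
        if include_permutation:
            row["power_perm"] = perm_hits / n_replicates
        row["n_replicates"] = n_replicates
        rows.append(row)
        logger.info("power grid point %s: %.3f", point, row["power_me"])
    return pd.DataFrame(rows)
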