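"""End-to-end orchestration: read -> standardize -> geometry -> MC effect
sizes -> local-adaptation moderator -> sampling covariance -> meta fits.

Also provides the ancestral-order sensitivity analysis: for comparisons whose
ancestral population could not be established unambiguously, the A/B labels
are randomly flipped and the whole analysis repeated, yielding a distribution
of pooled estimates around the baseline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effect_sizes_mc import (
    DEFAULT_N_REPS,
    EffectSize,
    build_sampling_covariance,
    compute_effect_sizes,
    seed_for_comparison,
)
from .errors import MissingDataError, PlastmetaError, ValidationError
from .local_adaptation import check_local_adaptation, local_adaptation_moderator
from .meta_model import (
    MetaDataset,
    MetaFit,
    compare_random_structures,
    fit_random_effects,
    phylo_correlation_matrix,
)
from .study_data import Comparison, UNIT_KEYS, read_study_table, standardize_traits
from .vector_geometry import EFFECT_NAMES, comparison_geometry

logger = logging.getLogger(__name__)

#: statistics that get an intercept-only meta-analytic model in the bundle
DEFAULT_META_NAMES = EFFECT_NAMES


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible run, loadable from YAML."""

    study_csv: str
    trait_csv: str
    out_dir: str
    fitness_csv: str | None = None
    tree_file: str | None = None
    master_seed: int = 1
    n_reps: int = DEFAULT_N_REPS
    shared_r: float = 0.5
    random_structure: str = "study"
    moderators: tuple[str, ...] = ("n_traits", "prop_morphology", "local_adaptation_g")
    standardize: bool = True
    require_local_adaptation: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError("n_reps must be positive")
        if self.n_reps < 1000:
            logger.warning(
                "n_reps=%d < 1000: sampling variances will be noisy", self.n_reps
            )
        if self.random_structure not in ("study", "phylo"):
            raise ValidationError("random_structure must be 'study' or 'phylo'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "moderators" in raw and raw["moderators"] is not None:
            raw["moderators"] = tuple(raw["moderators"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["moderators"] = list(self.moderators)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    comparisons: list[Comparison]
    effects: dict[str, dict[str, EffectSize]]  # comparison_id -> name -> effect
    effect_table: pd.DataFrame
    meta_fits: dict[str, MetaFit]
    moderator_fits: dict[str, MetaFit]
    structure_tables: dict[str, pd.DataFrame]
    manifest: dict
    errors: list[dict] = field(default_factory=list)


def flip_comparison(comp: Comparison) -> Comparison:
    """Swap the ancestral/derived roles: relabel population and environment
    A <-> B.  AinA becomes BinB, AinB becomes BinA, and so on; plasticity_A
    and plasticity_B exchange and the total difference reverses sign."""
    flip = {"A": "B", "B": "A"}
    new_units = {}
    for unit in comp.units.values():
        nu = dataclasses.replace(
            unit,
            population=flip[unit.population],
            environment=flip[unit.environment],
        )
        new_units[nu.key] = nu
    new_fitness = [
        dataclasses.replace(
            rec, unit_ref=(flip[rec.unit_ref[0]], flip[rec.unit_ref[1]])
        )
        for rec in comp.fitness
    ]
    return dataclasses.replace(comp, units=new_units, fitness=new_fitness)


def _moderator_row(comp: Comparison) -> dict:
    row = {
        "n_traits": comp.d,
        "prop_morphology": comp.prop_morphology,
        "local_adaptation_g": np.nan,
    }
    if comp.fitness:
        try:
            _, table = check_local_adaptation(comp)
            row["local_adaptation_g"] = local_adaptation_moderator(table)
        except (MissingDataError, PlastmetaError):
            pass
    return row


def compute_all_effects(
    comparisons: Sequence[Comparison],
    n_reps: int = DEFAULT_N_REPS,
    master_seed: int = 1,
    names: Sequence[str] = DEFAULT_META_NAMES,
    seed_salt: int = 0,
) -> tuple[dict[str, dict[str, EffectSize]], list[dict]]:
    """Monte-Carlo effect sizes for every comparison; per-comparison errors
    are collected, not raised."""
    effects: dict[str, dict[str, EffectSize]] = {}
    errors: list[dict] = []
    for comp in comparisons:
        seed = seed_for_comparison(master_seed, comp.comparison_id, salt=seed_salt)
        try:
            effects[comp.comparison_id] = compute_effect_sizes(
                comp, names=names, n_reps=n_reps, seed=seed
            )
        except PlastmetaError as exc:
            errors.append(
                {
                    "stage": "effect_sizes",
                    "comparison_id": comp.comparison_id,
                    "code": exc.code,
                    "message": str(exc),
                }
            )
    return effects, errors


def assemble_meta_dataset(
    comparisons: Sequence[Comparison],
    effects: dict[str, dict[str, EffectSize]],
    name: str,
    shared_r: float = 0.5,
    phylo: pd.DataFrame | None = None,
) -> MetaDataset | None:
    """One MetaDataset per statistic: the effect of that name from every
    comparison, with shared-unit sampling covariance and moderators."""
    rows: list[EffectSize] = []
    study_ids: list[str] = []
    species: list[str] = []
    mods: list[dict] = []
    unit_map: dict[str, set[str]] = {}
    for comp in comparisons:
        eff = effects.get(comp.comparison_id, {}).get(name)
        if eff is None or not np.isfinite(eff.point_estimate):
            continue
        rows.append(eff)
        study_ids.append(comp.study_id)
        species.append(comp.species)
        mods.append(_moderator_row(comp))
        unit_map[eff.effect_id] = {comp.units[k].unit_id for k in UNIT_KEYS}
    if len(rows) < 3:
        return None
    V = build_sampling_covariance(rows, unit_map, r=shared_r)
    phylo_sub = None
    if phylo is not None:
        keep = sorted(set(species), key=species.index)
        phylo_sub = phylo.loc[keep, keep]
    return MetaDataset(
        effects=rows,
        V=V,
        study_ids=study_ids,
        species=species,
        moderators=pd.DataFrame(mods),
        phylo=phylo_sub,
    )


def effect_table(
    comparisons: Sequence[Comparison],
    effects: dict[str, dict[str, EffectSize]],
) -> pd.DataFrame:
    """One row per comparison x statistic: estimates, variance, classification."""
    rows = []
    for comp in comparisons:
        geom = comparison_geometry(comp)
        for name, eff in effects.get(comp.comparison_id, {}).items():
            rows.append(
                {
                    "study_id": comp.study_id,
                    "comparison_id": comp.comparison_id,
                    "species": comp.species,
                    "name": name,
                    "point_estimate": eff.point_estimate,
                    "observed": eff.observed,
                    "sampling_variance": eff.sampling_variance,
                    "n_reps": eff.n_reps,
                    "rng_seed": eff.rng_seed,
                    "classification": geom.classification,
                    "n_traits": comp.d,
                    "prop_morphology": comp.prop_morphology,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the output bundle.

    Outputs in ``config.out_dir``: ``effects.csv`` (one row per comparison x
    statistic), ``densities/<name>.csv`` (MC draws per effect for circular
    plotting), ``meta_summary.csv`` (one row per fitted model) and
    ``manifest.json`` (config, seeds, versions).  Per-comparison failures are
    logged and skipped; dataset-level failures raise.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_errors: list[dict] = []

    comparisons = read_study_table(
        config.study_csv, config.trait_csv, fitness=config.fitness_csv
    )
    if not comparisons:
        raise ValidationError("input dataset contains no comparisons")

    if config.require_local_adaptation and config.fitness_csv is not None:
        kept = []
        for comp in comparisons:
            try:
                ok, _ = check_local_adaptation(comp)
            except MissingDataError as exc:
                run_errors.append(
                    {
                        "stage": "local_adaptation",
                        "comparison_id": comp.comparison_id,
                        "code": exc.code,
                        "message": str(exc),
                    }
                )
                continue
            if ok:
                kept.append(comp)
            else:
                logger.info("excluding %s: no local adaptation", comp.comparison_id)
        comparisons = kept
        if not comparisons:
            raise ValidationError("no comparison passed the local-adaptation filter")

    if config.standardize:
        std = []
        for comp in comparisons:
            try:
                std.append(standardize_traits(comp))
            except PlastmetaError as exc:
                run_errors.append(
                    {
                        "stage": "standardize",
                        "comparison_id": comp.comparison_id,
                        "code": exc.code,
                        "message": str(exc),
                    }
                )
        comparisons = std

    effects, eff_errors = compute_all_effects(
        comparisons, n_reps=config.n_reps, master_seed=config.master_seed
    )
    run_errors.extend(eff_errors)

    table = effect_table(comparisons, effects)
    table.to_csv(out / "effects.csv", index=False)

    dens_dir = out / "densities"
    dens_dir.mkdir(exist_ok=True)
    for name in DEFAULT_META_NAMES:
        cols = {
            cid: effs[name].mc_draws
            for cid, effs in effects.items()
            if name in effs
        }
        if cols:
            pd.DataFrame(cols).to_csv(dens_dir / f"{name}.csv", index=False)

    phylo = None
    if config.tree_file is not None:
        species = sorted({c.species for c in comparisons})
        phylo = phylo_correlation_matrix(config.tree_file, species)

    meta_fits: dict[str, MetaFit] = {}
    moderator_fits: dict[str, MetaFit] = {}
    structure_tables: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for name in DEFAULT_META_NAMES:
        data = assemble_meta_dataset(
            comparisons, effects, name, shared_r=config.shared_r, phylo=phylo
        )
        if data is None:
            continue
        try:
            fit = fit_random_effects(data, random=config.random_structure)
        except PlastmetaError as exc:
            run_errors.append(
                {"stage": "meta", "comparison_id": name, "code": exc.code,
                 "message": str(exc)}
            )
            continue
        meta_fits[name] = fit
        summary_rows.append(_summary_row(name, "intercept", fit))

        mods = [
            m
            for m in config.moderators
            if data.moderators is not None
            and data.moderators[m].notna().all()
            and data.moderators[m].std(ddof=1) > 0
        ]
        if mods and data.k >= len(mods) + 4:
            try:
                mfit = fit_random_effects(
                    data, random=config.random_structure, moderators=mods
                )
                moderator_fits[name] = mfit
                summary_rows.append(_summary_row(name, "moderators", mfit))
            except PlastmetaError as exc:
                run_errors.append(
                    {"stage": "meta_regression", "comparison_id": name,
                     "code": exc.code, "message": str(exc)}
                )
        if phylo is not None:
            try:
                cmpres = compare_random_structures(data)
                structure_tables[name] = cmpres.table
            except PlastmetaError as exc:
                run_errors.append(
                    {"stage": "structure_comparison", "comparison_id": name,
                     "code": exc.code, "message": str(exc)}
                )

    pd.DataFrame(summary_rows).to_csv(out / "meta_summary.csv", index=False)
    if structure_tables:
        pd.concat(
            structure_tables, names=["name", "row"]
        ).reset_index(level=0).to_csv(out / "random_structure_comparison.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_comparisons": len(comparisons),
        "n_effects": int(len(table)),
        "errors": run_errors,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        comparisons=comparisons,
        effects=effects,
        effect_table=table,
        meta_fits=meta_fits,
        moderator_fits=moderator_fits,
        structure_tables=structure_tables,
        manifest=manifest,
        errors=run_errors,
    )


def _summary_row(name: str, model: str, fit: MetaFit) -> dict:
    return {
        "name": name,
        "model": model,
        "random": fit.random,
        "k": fit.k,
        "estimate": fit.mu,
        "se": fit.se,
        "ci_low": fit.ci[0],
        "ci_high": fit.ci[1],
        "tau2_study": fit.tau2_study,
        "tau2_obs": fit.tau2_obs,
        "loglik_reml": fit.loglik_reml,
        "aicc": fit.aicc,
    }


@dataclass
class SensitivityResult:
    baseline: dict[str, float]
    randomized: pd.DataFrame  # columns: randomization, name, estimate
    n_ambiguous: int


def ancestral_order_sensitivity(
    comparisons: Sequence[Comparison],
    n_randomizations: int = 20,
    n_reps: int = DEFAULT_N_REPS,
    master_seed: int = 1,
    shared_r: float = 0.5,
    names: Sequence[str] = ("angle_pp", "angle_pt", "angle_pe"),
) -> SensitivityResult:
    """Randomize the ancestral order of ambiguous comparisons.

    Each randomization independently flips the A/B labels of every
    ambiguous comparison with probability 1/2 (Bernoulli per comparison),
    recomputes the Monte-Carlo effect sizes for flipped comparisons, refits
    the intercept-only meta-analytic model per statistic and records the
    pooled estimate.  With no ambiguous comparisons the baseline is returned
    alone, with a logged notice.
    """
    comparisons = list(comparisons)

    def pooled(comps: Sequence[Comparison], salt: int) -> dict[str, float]:
        effects, _ = compute_all_effects(
            comps, n_reps=n_reps, master_seed=master_seed, names=names, seed_salt=salt
        )
        out = {}
        for name in names:
            data = assemble_meta_dataset(comps, effects, name, shared_r=shared_r)
            if data is not None:
                out[name] = fit_random_effects(data, random="study").mu
        return out

    baseline = pooled(comparisons, salt=0)
    ambiguous_idx = [i for i, c in enumerate(comparisons) if c.ancestral_ambiguous]
    if not ambiguous_idx:
        logger.info("no ambiguous comparisons: sensitivity equals baseline")
        return SensitivityResult(
            baseline=baseline, randomized=pd.DataFrame(), n_ambiguous=0
        )

    rng = np.random.default_rng(master_seed)
    rows = []
    for r in range(n_randomizations):
        comps = list(comparisons)
        flipped_any = 0
        for i in ambiguous_idx:
            if rng.random() < 0.5:
                comps[i] = flip_comparison(comps[i])
                flipped_any += 1
        est = pooled(comps, salt=0)
        for name, value in est.items():
            rows.append(
                {
                    "randomization": r,
                    "name": name,
                    "estimate": value,
                    "n_flipped": flipped_any,
                }
            )
    return SensitivityResult(
        baseline=baseline,
        randomized=pd.DataFrame(rows),
        n_ambiguous=len(ambiguous_idx),
    )
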