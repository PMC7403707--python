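"""Data model, I/O and trait standardization for reciprocal transplant studies.

A reciprocal transplant comparison consists of four experimental units --
population A grown in environment A (``AinA``), A in B (``AinB``), B in B
(``BinB``) and B in A (``BinA``) -- each holding an individuals-by-traits
matrix of phenotypic measurements.  Traits are classified as morphology or
phenology.  Input is tidy CSV (one row per individual); fitness observations
live in a separate long CSV handled by :mod:`plastmeta.local_adaptation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTraitError,
    FormatError,
    InsufficientSampleError,
    MetadataError,
    StructureError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .local_adaptation import FitnessRecord

logger = logging.getLogger(__name__)

TRAIT_TYPES = ("morphology", "phenology")
UNIT_KEYS = ("AinA", "AinB", "BinB", "BinA")

#: Columns every study table must provide besides one column per trait.
REQUIRED_COLUMNS = (
    "study_id",
    "comparison_id",
    "species",
    "population",
    "environment",
    "individual_id",
)
_OPTIONAL_COLUMNS = ("ancestral_ambiguous", "unit_id")


@dataclass(frozen=True)
class TraitSpec:
    """One measured trait: its name, class (morphology/phenology) and units."""

    name: str
    trait_type: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValidationError(
                f"trait {self.name!r}: trait_type must be one of {TRAIT_TYPES}, "
                f"got {self.trait_type!r}"
            )


@dataclass
class ExperimentalUnit:
    """One population grown in one environment: an n x d trait matrix.

    ``population`` and ``environment`` are 'A' or 'B'; ``values`` holds one
    row per individual and one column per trait in ``traits`` order.
    """

    study_id: str
    comparison_id: str
    population: str
    environment: str
    traits: tuple[str, ...]
    values: np.ndarray
    unit_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.population not in ("A", "B") or self.environment not in ("A", "B"):
            raise ValidationError("population and environment must be 'A' or 'B'")
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D individuals-by-traits matrix")
        if self.values.shape[1] != len(self.traits):
            raise ValidationError("column count does not match trait list")
        if self.values.shape[0] < 1:
            raise ValidationError("a unit needs at least one individual")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("unit contains non-finite trait values")
        if self.unit_id is None:
            self.unit_id = f"{self.study_id}:{self.comparison_id}:{self.key}"

    @property
    def key(self) -> str:
        return f"{self.population}in{self.environment}"

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    @property
    def d(self) -> int:
        return int(self.values.shape[1])


@dataclass
class Comparison:
    """Four experimental units of one A-vs-B reciprocal transplant contrast."""

    study_id: str
    comparison_id: str
    species: str
    units: dict[str, ExperimentalUnit]
    traits: list[TraitSpec]
    ancestral_ambiguous: bool = False
    fitness: list["FitnessRecord"] = field(default_factory=list)
    #: per-trait (grand mean, pooled within-unit SD) applied by standardize_traits
    standardization: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        missing = [k for k in UNIT_KEYS if k not in self.units]
        if missing:
            raise StructureError(
                f"comparison {self.comparison_id!r} is missing unit(s): "
                + ", ".join(missing)
            )
        names = tuple(t.name for t in self.traits)
        if len(set(names)) != len(names):
            raise ValidationError("trait names must be unique within a comparison")
        if len(names) < 2:
            raise ValidationError(
                f"comparison {self.comparison_id!r}: at least two traits required"
            )
        for key in UNIT_KEYS:
            unit = self.units[key]
            if unit.traits != names:
                raise StructureError(
                    f"unit {key} of {self.comparison_id!r} has trait list "
                    f"{unit.traits}, expected {names}"
                )
            if unit.n < 3:
                raise InsufficientSampleError(
                    f"unit {key} of {self.comparison_id!r} has n={unit.n} < 3"
                )

    @property
    def d(self) -> int:
        return len(self.traits)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.traits)

    @property
    def prop_morphology(self) -> float:
        return sum(t.trait_type == "morphology" for t in self.traits) / self.d

    def unit(self, key: str) -> ExperimentalUnit:
        return self.units[key]


def read_trait_metadata(path: str | Path) -> dict[str, TraitSpec]:
    """Read the trait metadata CSV (columns: trait, trait_type[, units])."""
    meta = pd.read_csv(path)
    for col in ("trait", "trait_type"):
        if col not in meta.columns:
            raise FormatError(f"trait metadata {path} lacks required column {col!r}")
    specs: dict[str, TraitSpec] = {}
    for _, row in meta.iterrows():
        name = str(row["trait"])
        if name in specs:
            raise MetadataError(f"duplicate trait {name!r} in metadata")
        specs[name] = TraitSpec(
            name=name,
            trait_type=str(row["trait_type"]).strip().lower(),
            units=str(row.get("units", "") or ""),
        )
    return specs


def read_study_table(
    path: str | Path,
    trait_meta: str | Path,
    fitness: str | Path | None = None,
) -> list[Comparison]:
    """Read and validate a tidy study CSV into :class:`Comparison` objects.

    Rows with any missing trait value are dropped (listwise deletion, count
    logged).  Every comparison must contain all four units with n >= 3 after
    deletion.  ``fitness`` optionally points to a long fitness CSV (see
    :func:`plastmeta.local_adaptation.read_fitness_table`) whose records are
    attached to the matching comparisons.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"study table {path} lacks column(s): {missing_cols}")

    specs = read_trait_metadata(trait_meta)
    trait_cols = [
        c for c in df.columns if c not in REQUIRED_COLUMNS and c not in _OPTIONAL_COLUMNS
    ]
    unknown = [c for c in trait_cols if c not in specs]
    if unknown:
        raise MetadataError(f"trait(s) {unknown} present in data but not in metadata")
    if not trait_cols:
        raise FormatError("study table contains no trait columns")

    bad_pop = set(df["population"].astype(str)) - {"A", "B"}
    bad_env = set(df["environment"].astype(str)) - {"A", "B"}
    if bad_pop or bad_env:
        raise FormatError(
            f"population/environment labels must be 'A' or 'B' (got {bad_pop | bad_env})"
        )

    fitness_by_comparison: dict[str, list] = {}
    if fitness is not None:
        from .local_adaptation import read_fitness_table

        fitness_by_comparison = read_fitness_table(fitness)

    comparisons: list[Comparison] = []
    n_dropped = 0
    for (study_id, comparison_id), grp in df.groupby(
        ["study_id", "comparison_id"], sort=True
    ):
        # a trait belongs to this comparison iff it was measured at all here;
        # entirely-empty columns are other studies' traits in the wide table
        comp_traits = [c for c in trait_cols if not grp[c].isna().all()]
        if len(comp_traits) < 2:
            raise FormatError(
                f"comparison {comparison_id!r} measures fewer than two traits"
            )
        before = len(grp)
        grp = grp.dropna(subset=comp_traits)
        n_dropped += before - len(grp)
        species = str(grp["species"].iloc[0])
        ambiguous = False
        if "ancestral_ambiguous" in grp.columns:
            ambiguous = bool(grp["ancestral_ambiguous"].iloc[0])
        traits = [specs[c] for c in comp_traits]
        units: dict[str, ExperimentalUnit] = {}
        for (pop, env), ugrp in grp.groupby(["population", "environment"]):
            unit_id = None
            if "unit_id" in ugrp.columns and not ugrp["unit_id"].isna().all():
                unit_id = str(ugrp["unit_id"].iloc[0])
            unit = ExperimentalUnit(
                study_id=str(study_id),
                comparison_id=str(comparison_id),
                population=str(pop),
                environment=str(env),
                traits=tuple(comp_traits),
                values=ugrp[comp_traits].to_numpy(dtype=float),
                unit_id=unit_id,
            )
            if unit.n < 3:
                raise InsufficientSampleError(
                    f"unit {unit.key} of comparison {comparison_id!r} has "
                    f"n={unit.n} < 3 after dropping incomplete rows"
                )
            units[unit.key] = unit
        comparisons.append(
            Comparison(
                study_id=str(study_id),
                comparison_id=str(comparison_id),
                species=species,
                units=units,
                traits=traits,
                ancestral_ambiguous=ambiguous,
                fitness=fitness_by_comparison.get(str(comparison_id), []),
            )
        )
    if n_dropped:
        logger.info("dropped %d row(s) with missing trait values", n_dropped)
    return comparisons


def write_study_table(
    comparisons: Iterable[Comparison],
    path: str | Path,
    trait_meta: str | Path | None = None,
) -> None:
    """Write comparisons back to the tidy CSV schema read_study_table reads."""
    comparisons = list(comparisons)
    rows = []
    for comp in comparisons:
        for key in UNIT_KEYS:
            unit = comp.units[key]
            for i in range(unit.n):
                row = {
                    "study_id": comp.study_id,
                    "comparison_id": comp.comparison_id,
                    "species": comp.species,
                    "population": unit.population,
                    "environment": unit.environment,
                    "individual_id": f"{unit.key}_{i + 1}",
                    "ancestral_ambiguous": comp.ancestral_ambiguous,
                    "unit_id": unit.unit_id,
                }
                row.update(dict(zip(unit.traits, unit.values[i])))
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if trait_meta is not None:
        seen: dict[str, TraitSpec] = {}
        for comp in comparisons:
            for t in comp.traits:
                seen.setdefault(t.name, t)
        pd.DataFrame(
            [
                {"trait": t.name, "trait_type": t.trait_type, "units": t.units}
                for t in seen.values()
            ]
        ).to_csv(trait_meta, index=False)


def standardize_traits(comp: Comparison) -> Comparison:
    """z-score each trait by its grand mean and pooled within-unit SD.

    The pooled SD uses within-unit deviations across all four units
    (denominator: total n minus 4), so between-unit mean shifts -- the very
    signal the plasticity and divergence vectors measure -- are preserved
    while trait scales become comparable.  Idempotent to floating precision.
    """
    params: dict[str, tuple[float, float]] = {}
    all_values = np.vstack([comp.units[k].values for k in UNIT_KEYS])
    grand_mean = all_values.mean(axis=0)

    ss = np.zeros(comp.d)
    dof = 0
    for key in UNIT_KEYS:
        v = comp.units[key].values
        ss += ((v - v.mean(axis=0)) ** 2).sum(axis=0)
        dof += v.shape[0] - 1
    pooled_sd = np.sqrt(ss / dof)

    for j, name in enumerate(comp.trait_names):
        if pooled_sd[j] < 1e-12:
            raise DegenerateTraitError(
                f"trait {name!r} has zero pooled within-unit SD in comparison "
                f"{comp.comparison_id!r}"
            )
        params[name] = (float(grand_mean[j]), float(pooled_sd[j]))

    new_units = {
        key: replace(
            comp.units[key],
            values=(comp.units[key].values - grand_mean) / pooled_sd,
        )
        for key in UNIT_KEYS
    }
    return replace(comp, units=new_units, standardization=params)


def dataset_report(comparisons: Sequence[Comparison]) -> str:
    """Human-readable summary: studies, comparisons, traits, species."""
    studies = sorted({c.study_id for c in comparisons})
    species = sorted({c.species for c in comparisons})
    n_traits = [c.d for c in comparisons]
    lines = [
        f"studies:      {len(studies)}",
        f"comparisons:  {len(comparisons)}",
        f"species:      {len(species)}",
        f"traits/comp:  min {min(n_traits)}, max {max(n_traits)}, "
        f"mean {np.mean(n_traits):.2f}" if comparisons else "traits/comp:  -",
        f"ambiguous ancestral order: {sum(c.ancestral_ambiguous for c in comparisons)}",
    ]
    return "\n".join(lines)
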