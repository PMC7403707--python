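"""Fitness-based inclusion rule and the local-adaptation moderator.

A comparison qualifies as demonstrating local adaptation when at least one
fitness measure (or proxy: survival, seed count, biomass, ...) is higher in
at least one native unit than in the transplanted unit sharing its
environment.  The strength of local adaptation of the derived population is
quantified as Hedges' g between BinB (native) and AinB (transplant) fitness
and exported as the ``local_adaptation_g`` moderator of the meta-regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTraitError,
    FormatError,
    InsufficientSampleError,
    MissingDataError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .study_data import Comparison

logger = logging.getLogger(__name__)

FITNESS_COLUMNS = (
    "comparison_id",
    "population",
    "environment",
    "measure_name",
    "is_primary",
    "value",
)


@dataclass
class FitnessRecord:
    """Per-individual (or per-plot) fitness observations for one unit."""

    comparison_id: str
    unit_ref: tuple[str, str]  # (population, environment)
    measure_name: str
    values: np.ndarray
    is_primary: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError(
                "a fitness record needs at least two finite observations"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("fitness values must be finite")

    @property
    def key(self) -> str:
        return f"{self.unit_ref[0]}in{self.unit_ref[1]}"


def read_fitness_table(path: str | Path) -> dict[str, list[FitnessRecord]]:
    """Read the long fitness CSV into records grouped by comparison.

    Schema: comparison_id, population, environment, measure_name, is_primary,
    value -- one row per observation.
    """
    df = pd.read_csv(path)
    missing = [c for c in FITNESS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"fitness table {path} lacks column(s): {missing}")
    out: dict[str, list[FitnessRecord]] = {}
    keys = ["comparison_id", "population", "environment", "measure_name"]
    for (cid, pop, env, measure), grp in df.groupby(keys, sort=True):
        rec = FitnessRecord(
            comparison_id=str(cid),
            unit_ref=(str(pop), str(env)),
            measure_name=str(measure),
            values=grp["value"].to_numpy(dtype=float),
            is_primary=bool(grp["is_primary"].iloc[0]),
        )
        out.setdefault(str(cid), []).append(rec)
    return out


def write_fitness_table(
    records: Sequence[FitnessRecord], path: str | Path
) -> None:
    rows = []
    for rec in records:
        for v in rec.values:
            rows.append(
                {
                    "comparison_id": rec.comparison_id,
                    "population": rec.unit_ref[0],
                    "environment": rec.unit_ref[1],
                    "measure_name": rec.measure_name,
                    "is_primary": rec.is_primary,
                    "value": v,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def hedges_g(native: FitnessRecord | np.ndarray, foreign: FitnessRecord | np.ndarray) -> float:
    """Bias-corrected standardized mean fitness difference, native - foreign.

    g = J * (mean_native - mean_foreign) / s_pooled with the pooled SD using
    n-1 denominators and small-sample correction J = 1 - 3/(4(n1+n2) - 9).
    Positive g means the local (native) population is fitter.
    """
    x = native.values if isinstance(native, FitnessRecord) else np.asarray(native, float)
    y = foreign.values if isinstance(foreign, FitnessRecord) else np.asarray(foreign, float)
    if (
        isinstance(native, FitnessRecord)
        and isinstance(foreign, FitnessRecord)
        and native.measure_name != foreign.measure_name
    ):
        raise ValidationError("Hedges' g requires the same fitness measure")
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InsufficientSampleError("Hedges' g needs n >= 2 per group")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 1e-24:
        raise DegenerateTraitError("pooled fitness SD is zero")
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(J * (x.mean() - y.mean()) / np.sqrt(s2))


def check_local_adaptation(comp: "Comparison") -> tuple[bool, pd.DataFrame]:
    """Apply the inclusion rule and compute the moderator g table.

    Returns ``(qualifies, table)`` where ``table`` has one row per fitness
    measure with the two native-vs-transplant contrasts: ``g_B`` (BinB vs
    AinB, the derived population's home) and ``g_A`` (AinA vs BinA).  A
    comparison qualifies when any measure has g > 0 in either contrast.  The
    moderator exported to the meta-regression is ``g_B`` of the primary
    measure (first listed if none is flagged primary).
    """
    if not comp.fitness:
        raise MissingDataError(
            f"comparison {comp.comparison_id!r} has no fitness data"
        )
    by_measure: dict[str, dict[str, FitnessRecord]] = {}
    order: list[str] = []
    for rec in comp.fitness:
        if rec.measure_name not in by_measure:
            order.append(rec.measure_name)
        by_measure.setdefault(rec.measure_name, {})[rec.key] = rec

    rows = []
    for measure in order:
        recs = by_measure[measure]
        row = {
            "measure_name": measure,
            "is_primary": any(r.is_primary for r in recs.values()),
            "g_B": np.nan,
            "g_A": np.nan,
        }
        if "BinB" in recs and "AinB" in recs:
            row["g_B"] = hedges_g(recs["BinB"], recs["AinB"])
        if "AinA" in recs and "BinA" in recs:
            row["g_A"] = hedges_g(recs["AinA"], recs["BinA"])
        rows.append(row)
    table = pd.DataFrame(rows)
    if table[["g_B", "g_A"]].isna().all(axis=None):
        raise MissingDataError(
            f"comparison {comp.comparison_id!r}: no native-vs-transplant "
            "fitness contrast could be computed"
        )
    qualifies = bool((table[["g_B", "g_A"]] > 0).any(axis=None))
    if not qualifies:
        logger.info(
            "comparison %s flagged for exclusion: no native unit fitter",
            comp.comparison_id,
        )
    return qualifies, table


def local_adaptation_moderator(table: pd.DataFrame) -> float:
    """The g_B value of the primary (or first) measure, for the meta-regression."""
    primary = table[table["is_primary"]]
    row = primary.iloc[0] if len(primary) else table.iloc[0]
    return float(row["g_B"])
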