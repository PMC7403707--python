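"""Monte-Carlo sampling distributions and (co)variances of the effect sizes.

Sampling uncertainty of angle and length statistics is obtained by a
parametric bootstrap: each experimental unit is repeatedly resampled as n
individuals from a multivariate normal with the unit's observed centroid and
P-matrix, the statistic is recomputed on every joint 4-unit replicate, and
the Monte-Carlo mean and variance over replicates become the effect's point
estimate and sampling variance.  Effects computed from overlapping
experimental units are not independent; their sampling covariance is modeled
with a fixed correlation r on the shared-unit off-diagonals.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    InsufficientSampleError,
    NumericError,
    UnstableEffectError,
    ValidationError,
)
from .study_data import Comparison, ExperimentalUnit, UNIT_KEYS
from .vector_geometry import (
    EFFECT_NAMES,
    PMatrix,
    angle_directed,
    angle_undirected,
    batched_eigen_ratio,
    batched_leading_axis,
    comparison_geometry,
    projection_fraction,
)

logger = logging.getLogger(__name__)

#: Fraction of undefined replicates above which an effect is deemed unstable.
MAX_UNDEFINED_FRACTION = 0.10

DEFAULT_N_REPS = 10_000


@dataclass
class EffectSize:
    """One named statistic for one comparison, with its MC distribution.

    ``point_estimate`` is the Monte-Carlo mean (the value that enters the
    meta-analysis); ``observed`` is the plug-in estimate on the original
    data; ``sampling_variance`` is the variance over MC replicates.
    """

    comparison_id: str
    name: str
    point_estimate: float
    observed: float
    sampling_variance: float
    mc_draws: np.ndarray
    n_reps: int
    rng_seed: int

    def __post_init__(self) -> None:
        self.mc_draws = np.asarray(self.mc_draws, dtype=float)
        if self.n_reps != self.mc_draws.size:
            raise ValidationError("n_reps must equal the number of stored draws")

    @property
    def effect_id(self) -> str:
        return f"{self.comparison_id}:{self.name}"


@dataclass
class SamplingCovariance:
    """Sampling (co)variance matrix of a set of effects.

    Diagonal: the effects' MC sampling variances.  Off-diagonal (i, j):
    ``shared_r * sqrt(v_i v_j)`` when effects i and j were computed from at
    least one common experimental unit, else 0.
    """

    matrix: np.ndarray
    effect_ids: list[str]
    shared_r: float = 0.5

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.effect_ids)
        if self.matrix.shape != (k, k):
            raise ValidationError("covariance matrix shape must match effect_ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValidationError("sampling covariance must be symmetric")


@dataclass
class CorrelationResult:
    """A correlation with a Monte-Carlo percentile confidence interval."""

    rho: float
    ci: tuple[float, float]
    mc_draws: np.ndarray


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def seed_for_comparison(master_seed: int, comparison_id: str, salt: int = 0) -> int:
    """Stable per-comparison child seed below 2**31."""
    h = zlib.crc32(comparison_id.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h, int(salt)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _psd_sqrt(P: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix; eigenvalues below -1e-10 fail."""
    vals, vecs = np.linalg.eigh(P)
    if vals.min() < -1e-10:
        raise NumericError("matrix is not positive semi-definite")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------

def resample_unit(
    unit: ExperimentalUnit, seed: int | np.random.Generator
) -> ExperimentalUnit:
    """One parametric-bootstrap replicate of a unit.

    Draws ``unit.n`` new individuals from MVN(observed centroid, observed
    P-matrix).  Deterministic in the seed.
    """
    if unit.n < 3:
        raise InsufficientSampleError("resampling needs n >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = unit.values.mean(axis=0)
    P = np.cov(unit.values, rowvar=False, ddof=1)
    A = _psd_sqrt(np.atleast_2d(P))
    z = rng.standard_normal((unit.n, unit.d))
    return ExperimentalUnit(
        study_id=unit.study_id,
        comparison_id=unit.comparison_id,
        population=unit.population,
        environment=unit.environment,
        traits=unit.traits,
        values=mu + z @ A.T,
        unit_id=unit.unit_id,
    )


def _simulate_statistics(
    comp: Comparison,
    names: Sequence[str],
    n_reps: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorized joint resampling of all four units; returns draws per name."""
    cents: dict[str, np.ndarray] = {}
    pmats: dict[str, np.ndarray] = {}
    for key in UNIT_KEYS:
        unit = comp.units[key]
        mu = unit.values.mean(axis=0)
        P = np.atleast_2d(np.cov(unit.values, rowvar=False, ddof=1))
        A = _psd_sqrt(P)
        z = rng.standard_normal((n_reps, unit.n, unit.d))
        x = mu + z @ A.T
        cent = x.mean(axis=1)
        cents[key] = cent
        xc = x - cent[:, None, :]
        pmats[key] = np.einsum("rij,rik->rjk", xc, xc) / (unit.n - 1)

    pA = cents["AinB"] - cents["AinA"]
    pB = cents["BinA"] - cents["BinB"]
    total = cents["BinB"] - cents["AinA"]
    div = cents["BinB"] - cents["AinB"]

    out: dict[str, np.ndarray] = {}
    for name in names:
        if name == "angle_pp":
            out[name] = angle_directed(pA, pB)
        elif name == "angle_pt":
            out[name] = angle_directed(pA, total)
        elif name == "angle_pe":
            out[name] = angle_directed(pA, div)
        elif name == "angle_pmax_e":
            out[name] = angle_undirected(batched_leading_axis(pmats["AinB"]), div)
        elif name == "angle_pmax_p":
            out[name] = angle_undirected(batched_leading_axis(pmats["AinA"]), pA)
        elif name == "projection_pct":
            out[name] = projection_fraction(pA, total)
        elif name == "log_length_diff":
            with np.errstate(divide="ignore", invalid="ignore"):
                out[name] = np.log(np.linalg.norm(pB, axis=-1)) - np.log(
                    np.linalg.norm(pA, axis=-1)
                )
        elif name == "log_var_ratio_A":
            out[name] = np.log(
                np.trace(pmats["AinB"], axis1=-2, axis2=-1)
                / np.trace(pmats["AinA"], axis1=-2, axis2=-1)
            )
        elif name == "log_var_ratio_B":
            out[name] = np.log(
                np.trace(pmats["BinA"], axis1=-2, axis2=-1)
                / np.trace(pmats["BinB"], axis1=-2, axis2=-1)
            )
        elif name.startswith("eigen_ratio_"):
            key = name.removeprefix("eigen_ratio_")
            if key not in UNIT_KEYS:
                raise ValidationError(f"unknown effect size {name!r}")
            out[name] = batched_eigen_ratio(pmats[key])
        else:
            raise ValidationError(f"unknown effect size {name!r}")
        arr = np.asarray(out[name], dtype=float)
        out[name] = np.where(np.isfinite(arr), arr, np.nan)
    return out


def _to_effect(
    comp: Comparison,
    name: str,
    draws: np.ndarray,
    observed: float,
    seed: int,
) -> EffectSize:
    n_reps = draws.size
    bad = np.isnan(draws).mean()
    if bad > MAX_UNDEFINED_FRACTION:
        raise UnstableEffectError(
            f"{name} of comparison {comp.comparison_id!r}: "
            f"{bad:.1%} of replicates undefined"
        )
    valid = draws[~np.isnan(draws)]
    return EffectSize(
        comparison_id=comp.comparison_id,
        name=name,
        point_estimate=float(valid.mean()),
        observed=observed,
        sampling_variance=float(valid.var(ddof=1)),
        mc_draws=draws,
        n_reps=n_reps,
        rng_seed=seed,
    )


def effect_size_distribution(
    comp: Comparison,
    name: str,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> EffectSize:
    """Monte-Carlo distribution of one named statistic for one comparison."""
    if name not in EFFECT_NAMES:
        raise ValidationError(f"unknown effect size {name!r}")
    rng = np.random.default_rng(seed)
    draws = _simulate_statistics(comp, [name], n_reps, rng)[name]
    observed = comparison_geometry(comp).statistics[name]
    return _to_effect(comp, name, draws, observed, seed)


def compute_effect_sizes(
    comp: Comparison,
    names: Sequence[str] = EFFECT_NAMES,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> dict[str, EffectSize]:
    """All requested statistics from one joint simulation of the comparison.

    Sharing replicates across statistics is cheaper and preserves the
    within-comparison dependence among the draws.  Unstable effects (too many
    undefined replicates) are dropped with a logged warning rather than
    failing the comparison.
    """
    rng = np.random.default_rng(seed)
    sims = _simulate_statistics(comp, names, n_reps, rng)
    observed = comparison_geometry(comp).statistics
    out: dict[str, EffectSize] = {}
    for name in names:
        try:
            out[name] = _to_effect(comp, name, sims[name], observed[name], seed)
        except UnstableEffectError as exc:
            logger.warning("dropping effect: %s", exc)
    return out


# ---------------------------------------------------------------------------
# sampling covariance across effects
# ---------------------------------------------------------------------------

def build_sampling_covariance(
    effects: Sequence[EffectSize],
    unit_map: Mapping[str, Iterable[str]],
    r: float = 0.5,
) -> SamplingCovariance:
    """Shared-unit sampling covariance matrix of a set of effects.

    ``unit_map`` maps each effect's ``effect_id`` to the experimental-unit
    identifiers it was computed from.  V[i,j] = r*sqrt(v_i v_j) iff effects i
    and j share at least one unit.  A non-PSD result (possible for dense
    sharing patterns with large r) is projected to the nearest PSD matrix by
    eigenvalue clipping, with a logged warning.
    """
    k = len(effects)
    ids = [e.effect_id for e in effects]
    variances = np.array([e.sampling_variance for e in effects])
    if np.any(variances < 0) or np.any(~np.isfinite(variances)):
        raise ValidationError("all effects need finite nonnegative sampling variances")
    units = [frozenset(unit_map[i]) for i in ids]
    V = np.diag(variances)
    sd = np.sqrt(variances)
    for i in range(k):
        for j in range(i + 1, k):
            if units[i] & units[j]:
                V[i, j] = V[j, i] = r * sd[i] * sd[j]
    vals = np.linalg.eigvalsh(V)
    if vals.min() < -1e-10 * max(vals.max(), 1.0):
        logger.warning(
            "sampling covariance not PSD (min eigenvalue %.3g); clipping", vals.min()
        )
        w, Q = np.linalg.eigh(V)
        V = (Q * np.clip(w, 0.0, None)) @ Q.T
        V = (V + V.T) / 2.0
    return SamplingCovariance(matrix=V, effect_ids=ids, shared_r=r)


# ---------------------------------------------------------------------------
# P-matrix shape correlations
# ---------------------------------------------------------------------------

def _pearson_batched(x: np.ndarray, y: np.ndarray, axis: int = 0) -> np.ndarray:
    xm = x - x.mean(axis=axis, keepdims=True)
    ym = y - y.mean(axis=axis, keepdims=True)
    num = (xm * ym).sum(axis=axis)
    den = np.sqrt((xm**2).sum(axis=axis) * (ym**2).sum(axis=axis))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def eigen_ratio_correlation(
    pairs: Sequence[tuple[PMatrix, PMatrix]],
    n_reps: int = 2000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation of P-matrix shape (lambda2/lambda1) across pairs.

    Used to ask whether the shape of the phenotype distribution is preserved
    when a population is moved to a different environment (e.g. AinA vs
    AinB).  The CI is the 2.5/97.5 percentile band of the correlation
    recomputed on joint Monte-Carlo replicates of every P-matrix (Wishart-type
    resampling at each matrix's own sample size).
    """
    if len(pairs) < 3:
        raise InsufficientSampleError("eigen-ratio correlation needs >= 3 pairs")
    rng = np.random.default_rng(seed)

    obs = np.array(
        [
            [_ratio_of(P1), _ratio_of(P2)]
            for (P1, P2) in pairs
        ]
    )
    rho = float(_pearson_batched(obs[:, 0], obs[:, 1]))

    draws = np.empty((len(pairs), n_reps, 2))
    for ip, (P1, P2) in enumerate(pairs):
        for im, P in enumerate((P1, P2)):
            A = _psd_sqrt(P.values)
            z = rng.standard_normal((n_reps, P.n, P.d))
            x = z @ A.T
            xc = x - x.mean(axis=1, keepdims=True)
            cov = np.einsum("rij,rik->rjk", xc, xc) / (P.n - 1)
            draws[ip, :, im] = batched_eigen_ratio(cov)
    rep_corr = _pearson_batched(draws[:, :, 0], draws[:, :, 1], axis=0)
    rep_corr = rep_corr[np.isfinite(rep_corr)]
    lo, hi = np.percentile(rep_corr, [2.5, 97.5])
    return CorrelationResult(rho=rho, ci=(float(lo), float(hi)), mc_draws=rep_corr)


def _ratio_of(P: PMatrix) -> float:
    vals = np.sort(np.linalg.eigvalsh(P.values))[::-1]
    return float(max(vals[1], 0.0) / vals[0])
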