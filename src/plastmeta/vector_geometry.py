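"""Centroids, P-matrices, plasticity/divergence vectors and their statistics.

The four units of a reciprocal transplant comparison define four centroid
difference vectors in standardized trait space:

* ``plasticity_A``: AinA -> AinB, the ancestral population's plastic response;
* ``plasticity_B``: BinB -> BinA, the derived population's plastic response;
* ``total_difference``: AinA -> BinB, the in-situ phenotypic difference;
* ``evolutionary_divergence``: AinB -> BinB, genetic divergence revealed when
  both populations grow in the derived environment.

Effect sizes are angles between these vectors (and between vectors and the
leading eigenvector of a unit's phenotypic covariance matrix, P_max), vector
length contrasts, the projection of plasticity onto the total difference, and
trace-based phenotypic variance changes.  All angle functions broadcast over
leading axes so Monte-Carlo replicates can be evaluated in one vectorized
call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import (
    DegenerateMatrixError,
    InsufficientSampleError,
    StructureError,
    UndefinedAngleError,
    ValidationError,
)
from .study_data import Comparison, ExperimentalUnit, UNIT_KEYS

_ZERO_TOL = 1e-12

#: Names of the numeric per-comparison statistics produced by
#: :func:`comparison_geometry` (classification is categorical and separate).
EFFECT_NAMES = (
    "angle_pp",
    "angle_pt",
    "angle_pe",
    "angle_pmax_e",
    "angle_pmax_p",
    "projection_pct",
    "log_length_diff",
    "log_var_ratio_A",
    "log_var_ratio_B",
    "eigen_ratio_AinA",
    "eigen_ratio_AinB",
    "eigen_ratio_BinB",
    "eigen_ratio_BinA",
)

#: Undirected-axis statistics live in [0, 90]; directed angles in [0, 180].
UNDIRECTED_ANGLES = ("angle_pmax_e", "angle_pmax_p")
DIRECTED_ANGLES = ("angle_pp", "angle_pt", "angle_pe")

VECTOR_KINDS = ("plasticity_A", "plasticity_B", "total_difference", "evolutionary_divergence")

#: (from unit, to unit) defining each named vector.
VECTOR_DEFS: dict[str, tuple[str, str]] = {
    "plasticity_A": ("AinA", "AinB"),
    "plasticity_B": ("BinB", "BinA"),
    "total_difference": ("AinA", "BinB"),
    "evolutionary_divergence": ("AinB", "BinB"),
}


@dataclass(frozen=True)
class Centroid:
    values: np.ndarray
    unit_ref: tuple[str, str]  # (population, environment)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("centroid has non-finite entries")


@dataclass(frozen=True)
class PMatrix:
    """Sample phenotypic covariance matrix of one unit (denominator n-1)."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("P-matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("P-matrix must be symmetric (tol 1e-10)")
        if np.linalg.eigvalsh(v).min() < -1e-10:
            raise ValidationError("P-matrix must be positive semi-definite")

    @property
    def d(self) -> int:
        return int(self.values.shape[0])

    @property
    def trace(self) -> float:
        return float(np.trace(self.values))


@dataclass(frozen=True)
class DirectedVector:
    values: np.ndarray
    from_unit: tuple[str, str]
    to_unit: tuple[str, str]
    kind: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.kind not in VECTOR_KINDS:
            raise ValidationError(f"unknown vector kind {self.kind!r}")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class Axis:
    """Unit-norm, sign-normalized undirected direction with its eigenvalue."""

    values: np.ndarray
    eigenvalue: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
            raise ValidationError("axis must have unit norm")
        if self.eigenvalue < -1e-10:
            raise ValidationError("axis eigenvalue must be nonnegative")


# ---------------------------------------------------------------------------
# unit-level summaries
# ---------------------------------------------------------------------------

def centroid(unit: ExperimentalUnit) -> Centroid:
    """Arithmetic multivariate mean of a unit's individuals."""
    return Centroid(unit.values.mean(axis=0), (unit.population, unit.environment))


def p_matrix(unit: ExperimentalUnit) -> PMatrix:
    """Sample covariance (denominator n-1) of a unit; requires n >= 3."""
    if unit.n < 3:
        raise InsufficientSampleError(
            f"P-matrix needs n >= 3 individuals, unit {unit.key} has n={unit.n}"
        )
    cov = np.cov(unit.values, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    # symmetrize away last-bit asymmetry from summation order
    return PMatrix((cov + cov.T) / 2.0, unit.n)


def difference_vector(
    from_unit: ExperimentalUnit, to_unit: ExperimentalUnit, kind: str
) -> DirectedVector:
    """centroid(to) - centroid(from), tagged with its role in the design."""
    if from_unit.traits != to_unit.traits:
        raise StructureError("units measure different traits")
    if from_unit.d != to_unit.d:
        raise StructureError("units have mismatched trait dimensions")
    return DirectedVector(
        to_unit.values.mean(axis=0) - from_unit.values.mean(axis=0),
        from_unit=(from_unit.population, from_unit.environment),
        to_unit=(to_unit.population, to_unit.environment),
        kind=kind,
    )


# ---------------------------------------------------------------------------
# angles and scalar statistics (broadcast over leading axes)
# ---------------------------------------------------------------------------

def _as_values(v) -> np.ndarray:
    if isinstance(v, (DirectedVector, Axis, Centroid)):
        return v.values
    return np.asarray(v, dtype=float)


def angle_directed(v1, v2) -> float | np.ndarray:
    """Angle in degrees, range [0, 180], between two directed vectors.

    Accepts arrays of shape (..., d) and broadcasts.  For 1-D inputs a
    (near-)zero vector raises :class:`UndefinedAngleError`; in batched input
    the corresponding entries are NaN so Monte-Carlo replicates can be
    filtered downstream.
    """
    a, b = _as_values(v1), _as_values(v2)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    scalar = a.ndim == 1 and b.ndim == 1
    if scalar and (na <= _ZERO_TOL or nb <= _ZERO_TOL):
        raise UndefinedAngleError("angle with a zero vector is undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.sum(a * b, axis=-1) / (na * nb)
        cos = np.where((na <= _ZERO_TOL) | (nb <= _ZERO_TOL), np.nan, cos)
    ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return float(ang) if scalar else ang


def angle_undirected(axis, v) -> float | np.ndarray:
    """Angle in degrees, range [0, 90], between an undirected axis and a vector."""
    a, b = _as_values(axis), _as_values(v)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    scalar = a.ndim == 1 and b.ndim == 1
    if scalar and (na <= _ZERO_TOL or nb <= _ZERO_TOL):
        raise UndefinedAngleError("angle with a zero vector is undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.abs(np.sum(a * b, axis=-1)) / (na * nb)
        cos = np.where((na <= _ZERO_TOL) | (nb <= _ZERO_TOL), np.nan, cos)
    ang = np.degrees(np.arccos(np.clip(cos, 0.0, 1.0)))
    return float(ang) if scalar else ang


def projection_fraction(plasticity, total) -> float | np.ndarray:
    """Signed % of the total difference accounted for by plasticity.

    100 * (p . t-hat) / ||t||: the length of plasticity's projection onto the
    total-difference direction, as a percentage of the total-difference
    length.  Negative when the angle exceeds 90 degrees; above 100 when
    plasticity overshoots.
    """
    p, t = _as_values(plasticity), _as_values(total)
    nt2 = np.sum(t * t, axis=-1)
    scalar = p.ndim == 1 and t.ndim == 1
    if scalar and nt2 <= _ZERO_TOL**2:
        raise UndefinedAngleError("projection onto a zero total vector is undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 100.0 * np.sum(p * t, axis=-1) / nt2
        frac = np.where(nt2 <= _ZERO_TOL**2, np.nan, frac)
    return float(frac) if scalar else frac


def classify_alignment(angle: float, fraction: float) -> str:
    """Classify plasticity vs the total phenotypic difference.

    ``opposite`` if the angle exceeds 90 degrees; otherwise ``overshoot`` if
    the projection exceeds 100% of the total difference, else ``undershoot``.
    An angle of exactly 90 (projection 0) counts as undershoot.
    """
    if not 0.0 <= angle <= 180.0:
        raise ValidationError(f"angle {angle} outside [0, 180]")
    if angle > 90.0:
        return "opposite"
    return "overshoot" if fraction > 100.0 else "undershoot"


def log_length_difference(vB, vA) -> float:
    """ln||vB|| - ln||vA||: log-scale contrast of two vector lengths."""
    nb = float(np.linalg.norm(_as_values(vB)))
    na = float(np.linalg.norm(_as_values(vA)))
    if nb <= _ZERO_TOL or na <= _ZERO_TOL:
        raise UndefinedAngleError("log length difference of a zero vector is undefined")
    return float(np.log(nb) - np.log(na))


def variance_change(p_foreign: PMatrix, p_home: PMatrix) -> float:
    """Percent change in total phenotypic variance (trace) away from home."""
    if p_foreign.d != p_home.d:
        raise StructureError("P-matrices have different dimensions")
    if p_home.trace <= _ZERO_TOL:
        raise DegenerateMatrixError("home P-matrix has zero trace")
    return 100.0 * (p_foreign.trace / p_home.trace - 1.0)


def log_trace_ratio(p_foreign: PMatrix, p_home: PMatrix) -> float:
    """ln of the trace ratio; the scale variance changes are meta-analyzed on."""
    if p_home.trace <= _ZERO_TOL or p_foreign.trace <= _ZERO_TOL:
        raise DegenerateMatrixError("P-matrix with zero trace")
    return float(np.log(p_foreign.trace / p_home.trace))


def percent_from_log_ratio(log_ratio: float) -> float:
    """Back-transform a log trace ratio to a percent change for reporting."""
    return 100.0 * (np.exp(log_ratio) - 1.0)


# ---------------------------------------------------------------------------
# eigenstructure
# ---------------------------------------------------------------------------

def _sign_normalize(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvectors (last axis = components) so the largest-magnitude
    component is positive.  Works on (..., d) stacks."""
    idx = np.argmax(np.abs(vecs), axis=-1, keepdims=True)
    signs = np.sign(np.take_along_axis(vecs, idx, axis=-1))
    signs = np.where(signs == 0, 1.0, signs)
    return vecs * signs


def eigen_decomposition(P: PMatrix) -> list[Axis]:
    """Eigenvalues descending; sign-normalized axes; deterministic ties.

    Ties (eigenvalues equal to 1e-12) are ordered by descending magnitude of
    the loading on the first trait, so e.g. the identity matrix yields
    (1,0,...) first.
    """
    vals, vecs = np.linalg.eigh(P.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # deterministic tie-break within blocks of equal eigenvalues
    i = 0
    while i < len(vals):
        j = i + 1
        while j < len(vals) and abs(vals[j] - vals[i]) <= 1e-12:
            j += 1
        if j - i > 1:
            block = vecs[:, i:j]
            sub = np.argsort(-np.abs(block[0, :]), kind="stable")
            vecs[:, i:j] = block[:, sub]
        i = j
    vecs = _sign_normalize(vecs.T).T
    return [
        Axis(vecs[:, k] / np.linalg.norm(vecs[:, k]), float(max(vals[k], 0.0)))
        for k in range(len(vals))
    ]


def p_max(P: PMatrix) -> Axis:
    """Leading eigenvector of a P-matrix: the main axis of phenotypic variation."""
    return eigen_decomposition(P)[0]


def eigen_ratio(P: PMatrix) -> float:
    """lambda2 / lambda1: eccentricity/shape summary of the P-matrix in [0, 1]."""
    if P.d < 2:
        raise ValidationError("eigen ratio needs at least two traits")
    vals = np.sort(np.linalg.eigvalsh(P.values))[::-1]
    if vals[0] <= _ZERO_TOL:
        raise DegenerateMatrixError("leading eigenvalue is zero")
    return float(max(vals[1], 0.0) / vals[0])


def batched_leading_axis(mats: np.ndarray) -> np.ndarray:
    """Leading eigenvectors of a (..., d, d) stack, sign-normalized."""
    _, vecs = np.linalg.eigh(mats)
    lead = vecs[..., :, -1]
    return _sign_normalize(lead)


def batched_eigen_ratio(mats: np.ndarray) -> np.ndarray:
    """lambda2/lambda1 for a (..., d, d) stack; NaN where lambda1 == 0."""
    vals = np.linalg.eigvalsh(mats)
    lam1 = vals[..., -1]
    lam2 = np.clip(vals[..., -2], 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(lam1 > _ZERO_TOL, lam2 / lam1, np.nan)


# ---------------------------------------------------------------------------
# whole-comparison geometry
# ---------------------------------------------------------------------------

@dataclass
class ComparisonGeometry:
    """All plug-in point estimates for one comparison.

    ``statistics`` maps each name in :data:`EFFECT_NAMES` to its value (NaN
    where undefined, e.g. an angle with a zero vector); ``classification`` is
    the opposite/overshoot/undershoot call, or None when undefined.
    """

    comparison_id: str
    centroids: dict[str, Centroid]
    p_matrices: dict[str, PMatrix]
    vectors: dict[str, DirectedVector]
    statistics: dict[str, float] = field(default_factory=dict)
    classification: str | None = None


def comparison_geometry(comp: Comparison) -> ComparisonGeometry:
    """Compute every named statistic for one standardized comparison.

    Undefined components (zero vectors, degenerate matrices) are recorded as
    NaN / None rather than raised, so one degenerate statistic does not sink
    the rest of the comparison.
    """
    cents = {k: centroid(comp.units[k]) for k in UNIT_KEYS}
    pmats = {k: p_matrix(comp.units[k]) for k in UNIT_KEYS}
    vectors = {
        kind: difference_vector(comp.units[src], comp.units[dst], kind)
        for kind, (src, dst) in VECTOR_DEFS.items()
    }
    pA = vectors["plasticity_A"]
    pB = vectors["plasticity_B"]
    total = vectors["total_difference"]
    div = vectors["evolutionary_divergence"]

    stats: dict[str, float] = {}

    def _try(name: str, fn):
        try:
            stats[name] = float(fn())
        except (UndefinedAngleError, DegenerateMatrixError, ValidationError):
            stats[name] = float("nan")

    _try("angle_pp", lambda: angle_directed(pA, pB))
    _try("angle_pt", lambda: angle_directed(pA, total))
    _try("angle_pe", lambda: angle_directed(pA, div))
    _try("angle_pmax_e", lambda: angle_undirected(p_max(pmats["AinB"]), div))
    _try("angle_pmax_p", lambda: angle_undirected(p_max(pmats["AinA"]), pA))
    _try("projection_pct", lambda: projection_fraction(pA, total))
    _try("log_length_diff", lambda: log_length_difference(pB, pA))
    _try("log_var_ratio_A", lambda: log_trace_ratio(pmats["AinB"], pmats["AinA"]))
    _try("log_var_ratio_B", lambda: log_trace_ratio(pmats["BinA"], pmats["BinB"]))
    for key in UNIT_KEYS:
        _try(f"eigen_ratio_{key}", lambda key=key: eigen_ratio(pmats[key]))

    classification = None
    if np.isfinite(stats["angle_pt"]) and np.isfinite(stats["projection_pct"]):
        classification = classify_alignment(stats["angle_pt"], stats["projection_pct"])

    return ComparisonGeometry(
        comparison_id=comp.comparison_id,
        centroids=cents,
        p_matrices=pmats,
        vectors=vectors,
        statistics=stats,
        classification=classification,
    )
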