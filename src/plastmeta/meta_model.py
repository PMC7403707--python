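"""Multilevel random-effects meta-analysis with known sampling covariance.

Model: y = X beta + u + e + s, with
  u ~ N(0, tau2_study * S)    study-level effects (S = same-study indicator,
                              or a phylogenetic correlation matrix expanded
                              to the effect level),
  e ~ N(0, tau2_obs * I)      observation-level effects,
  s ~ N(0, V)                 known sampling errors from the Monte-Carlo
                              simulations (V may have shared-unit
                              off-diagonals).

Variance components are estimated by REML on the log-sigma^2 scale with
multiple starting points; fixed effects by GLS at the optimum, with Wald
(normal) 95% confidence intervals.  Random-effect structures (study vs
phylogeny) are compared by AICc.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .effect_sizes_mc import EffectSize, SamplingCovariance
from .errors import ConvergenceError, ValidationError
from .study_data import Comparison

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # Phi^-1(0.975)

#: Moderators that are z-scored before entering the design matrix.
STANDARDIZED_MODERATORS = ("n_traits", "prop_morphology", "local_adaptation_g")


@dataclass
class MetaDataset:
    """Effect sizes plus the structure needed to meta-analyze them."""

    effects: list[EffectSize]
    V: SamplingCovariance | np.ndarray
    study_ids: list[str]
    species: list[str] | None = None
    moderators: pd.DataFrame | None = None
    phylo: pd.DataFrame | None = None  # species x species correlation matrix

    def __post_init__(self) -> None:
        k = len(self.effects)
        if len(self.study_ids) != k:
            raise ValidationError("study_ids must align with effects")
        if self.species is not None and len(self.species) != k:
            raise ValidationError("species must align with effects")
        if self.moderators is not None and len(self.moderators) != k:
            raise ValidationError("moderator rows must align with effects")
        if self.phylo is not None:
            phi = self.phylo.to_numpy(dtype=float)
            if not np.allclose(np.diag(phi), 1.0, atol=1e-8):
                raise ValidationError("phylogenetic matrix must have unit diagonal")
            if np.linalg.eigvalsh((phi + phi.T) / 2).min() < -1e-8:
                raise ValidationError("phylogenetic matrix must be PSD")

    @property
    def k(self) -> int:
        return len(self.effects)

    @property
    def y(self) -> np.ndarray:
        return np.array([e.point_estimate for e in self.effects])

    @property
    def v_matrix(self) -> np.ndarray:
        if isinstance(self.V, SamplingCovariance):
            return self.V.matrix
        return np.asarray(self.V, dtype=float)


@dataclass
class MetaFit:
    """A fitted multilevel meta-analytic (or meta-regression) model."""

    mu: float
    ci: tuple[float, float]
    se: float
    tau2_study: float
    tau2_obs: float
    betas: pd.DataFrame  # term, estimate, se, ci_low, ci_high
    loglik_reml: float
    aicc: float
    k: int
    p: int
    random: str
    converged: bool
    #: predicted means at moderator mean +/- 1 SD, per moderator term
    predictions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"multilevel meta-analysis ({self.random} random effect), k={self.k}",
            f"pooled estimate: {self.mu:.4f}  (95% CI {self.ci[0]:.4f} to {self.ci[1]:.4f})",
            f"tau2_study={self.tau2_study:.5f}  tau2_obs={self.tau2_obs:.5f}",
            f"REML loglik={self.loglik_reml:.4f}  AICc={self.aicc:.4f}  p={self.p}",
        ]
        if len(self.betas) > 1:
            lines.append(self.betas.to_string(index=False))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# phylogenetic correlation matrix
# ---------------------------------------------------------------------------

def _norm_label(label: str) -> str:
    return " ".join(str(label).replace("_", " ").split()).lower()


def phylo_correlation_matrix(
    tree: dendropy.Tree | str | Path, species: Sequence[str]
) -> pd.DataFrame:
    """Species correlation matrix from a dated ultrametric tree.

    Entry (i, j) is the shared root-to-MRCA branch length divided by total
    tree depth (1 on the diagonal) under a Brownian-motion model of trait
    divergence.  The tree must be ultrametric (tip depths equal to a 1e-6
    relative tolerance) and strictly bifurcating; species names are matched
    case-insensitively with underscores treated as spaces.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = dendropy.Tree.get(path=str(tree), schema="newick")
    else:
        tree = tree.clone(depth=1)

    for node in tree.preorder_node_iter():
        if len(node.child_nodes()) > 2:
            raise ValidationError("tree contains a polytomy")

    tree.calc_node_root_distances(
        return_leaf_distances_only=False
    )
    leaf_depths = [leaf.root_distance for leaf in tree.leaf_node_iter()]
    depth = max(leaf_depths)
    if depth <= 0:
        raise ValidationError("tree has zero depth")
    if (depth - min(leaf_depths)) > 1e-6 * depth:
        raise ValidationError("tree is not ultrametric (tol 1e-6)")

    label_to_taxon = {_norm_label(t.label): t for t in tree.taxon_namespace}
    taxa = []
    for sp in species:
        key = _norm_label(sp)
        if key not in label_to_taxon:
            raise ValidationError(f"species {sp!r} missing from tree")
        taxa.append(label_to_taxon[key])

    pdm = tree.phylogenetic_distance_matrix()
    k = len(species)
    phi = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if taxa[i] is taxa[j]:
                phi[i, j] = phi[j, i] = 1.0
                continue
            dist = pdm.patristic_distance(taxa[i], taxa[j])
            # ultrametric: patristic distance = 2 * MRCA age
            shared = depth - dist / 2.0
            phi[i, j] = phi[j, i] = max(shared, 0.0) / depth
    return pd.DataFrame(phi, index=list(species), columns=list(species))


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _design_matrix(
    data: MetaDataset, moderators: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    k = data.k
    X = [np.ones(k)]
    names = ["intercept"]
    if moderators:
        if data.moderators is None:
            raise ValidationError("dataset has no moderator table")
        for m in moderators:
            if m not in data.moderators.columns:
                raise ValidationError(f"moderator {m!r} not in dataset")
            col = data.moderators[m].to_numpy(dtype=float)
            if m in STANDARDIZED_MODERATORS:
                sd = col.std(ddof=1)
                if sd <= 0:
                    raise ValidationError(f"moderator {m!r} is constant")
                col = (col - col.mean()) / sd
            X.append(col)
            names.append(m)
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("collinear moderators: design matrix is rank deficient")
    return X, names


def _random_structure(data: MetaDataset, random: str) -> np.ndarray:
    k = data.k
    if random == "study":
        sid = np.array(data.study_ids)
        return (sid[:, None] == sid[None, :]).astype(float)
    if random == "phylo":
        if data.phylo is None or data.species is None:
            raise ValidationError("phylogenetic model needs species and phylo matrix")
        phi = data.phylo
        idx = [list(phi.index).index(sp) for sp in data.species]
        return phi.to_numpy(dtype=float)[np.ix_(idx, idx)]
    raise ValidationError(f"unknown random structure {random!r}")


def _reml_loglik(
    y: np.ndarray, X: np.ndarray, sigma: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """REML log-likelihood plus GLS beta and its covariance at this Sigma."""
    k, p = X.shape
    L = np.linalg.cholesky(sigma)
    half_logdet = np.log(np.diag(L)).sum()
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    xtx = Xw.T @ Xw
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'S^-1X not positive definite")
    # Harville's formulation, including the +0.5 ln|X'X| constant
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * (
        (k - p) * np.log(2.0 * np.pi)
        - logdet_xx
        + 2.0 * half_logdet
        + logdet_xtx
        + resid @ resid
    )
    return float(ll), beta, xtx_inv


def fit_random_effects(
    data: MetaDataset,
    random: str = "study",
    moderators: Sequence[str] | None = None,
    fix_tau2: tuple[float, float] | None = None,
    n_restarts: int = 4,
    tol: float = 1e-8,
) -> MetaFit:
    """Fit the multilevel model by REML and return a :class:`MetaFit`.

    ``random`` chooses the grouping covariance: ``study`` (block indicator)
    or ``phylo`` (species correlation matrix).  ``fix_tau2`` pins
    (tau2_group, tau2_obs) instead of estimating them -- with (0, 0) and a
    diagonal V this reduces to the classical inverse-variance weighted mean.
    """
    if data.k < 3 and fix_tau2 is None:
        raise ValidationError("REML needs at least 3 effects")
    y = data.y
    V = data.v_matrix
    X, names = _design_matrix(data, moderators)
    R = _random_structure(data, random)
    k, p_fixed = X.shape
    I = np.eye(k)

    def sigma_of(tau2: np.ndarray) -> np.ndarray:
        return tau2[0] * R + tau2[1] * I + V

    if fix_tau2 is not None:
        tau2 = np.asarray(fix_tau2, dtype=float)
        ll, beta, cov = _reml_loglik(y, X, sigma_of(tau2))
        n_var = 0
        converged = True
    else:
        scale = max(float(np.var(y, ddof=1)), 1e-6)
        lo, hi = np.log(1e-10 * scale), np.log(1e4 * scale)

        def neg_reml(log_tau2: np.ndarray) -> float:
            try:
                ll, _, _ = _reml_loglik(y, X, sigma_of(np.exp(log_tau2)))
            except np.linalg.LinAlgError:
                return 1e12
            return -ll

        starts = [
            np.log([0.5 * scale, 0.5 * scale]),
            np.log([1e-8 * scale, scale]),
            np.log([scale, 1e-8 * scale]),
            np.log([0.1 * scale, 0.1 * scale]),
        ][: max(n_restarts, 1)]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                neg_reml,
                x0,
                method="L-BFGS-B",
                bounds=[(lo, hi)] * 2,
                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("REML optimization failed for all starting points")
        converged = bool(best.success) or np.isfinite(best.fun)
        tau2 = np.exp(best.x)
        # snap numerically-zero components to the boundary
        tau2 = np.where(tau2 < 1e-8 * scale, 0.0, tau2)
        ll, beta, cov = _reml_loglik(y, X, sigma_of(tau2))
        n_var = 2

    se = np.sqrt(np.diag(cov))
    betas = pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "se": se,
            "ci_low": beta - Z_95 * se,
            "ci_high": beta + Z_95 * se,
        }
    )
    p_total = p_fixed + n_var
    fit = MetaFit(
        mu=float(beta[0]),
        ci=(float(beta[0] - Z_95 * se[0]), float(beta[0] + Z_95 * se[0])),
        se=float(se[0]),
        tau2_study=float(tau2[0]),
        tau2_obs=float(tau2[1]),
        betas=betas,
        loglik_reml=ll,
        aicc=np.nan,
        k=k,
        p=p_total,
        random=random,
        converged=converged,
    )
    fit.aicc = aicc(fit)
    # predicted means at moderator mean +/- 1 SD (z-scored moderators: z = -/+1)
    if moderators:
        for name, b in zip(names[1:], beta[1:]):
            fit.predictions[name] = (float(beta[0] - b), float(beta[0] + b))
    return fit


def aicc(fit: MetaFit) -> float:
    """Small-sample corrected AIC: -2 ll + 2p + 2p(p+1)/(k - p - 1)."""
    k, p = fit.k, fit.p
    if k <= p + 1:
        warnings.warn(
            f"AICc undefined for k={k}, p={p} (k <= p + 1); returning inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(-2.0 * fit.loglik_reml + 2.0 * p + 2.0 * p * (p + 1) / (k - p - 1))


@dataclass
class RandomStructureComparison:
    table: pd.DataFrame
    selected: str
    fits: dict[str, MetaFit]


def compare_random_structures(
    data: MetaDataset, moderators: Sequence[str] | None = None
) -> RandomStructureComparison:
    """Fit study- and phylogeny-level random effects on identical data.

    The structure with the lower AICc is selected; within 2 AICc units the
    simpler, conventional study-level structure wins the tie.
    """
    if data.phylo is None:
        raise ValidationError("random-structure comparison needs a phylogeny")
    fits = {
        name: fit_random_effects(data, random=name, moderators=moderators)
        for name in ("study", "phylo")
    }
    table = pd.DataFrame(
        {
            "random": list(fits),
            "aicc": [fits[n].aicc for n in fits],
            "loglik_reml": [fits[n].loglik_reml for n in fits],
            "tau2": [fits[n].tau2_study for n in fits],
            "tau2_obs": [fits[n].tau2_obs for n in fits],
        }
    ).sort_values("aicc", kind="stable", ignore_index=True)
    if fits["study"].aicc <= fits["phylo"].aicc + 2.0:
        selected = "study"
    else:
        selected = "phylo"
    return RandomStructureComparison(table=table, selected=selected, fits=fits)
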