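import json
import subprocess
import textwrap

import dendropy
import numpy as np
import pandas as pd
import pytest

from plastmeta.effect_sizes_mc import EffectSize
from plastmeta.errors import ValidationError
from plastmeta.meta_model import (
    MetaDataset,
    MetaFit,
    aicc,
    compare_random_structures,
    fit_random_effects,
    phylo_correlation_matrix,
)


def _effects(y, v):
    return [
        EffectSize(f"c{i}", "angle_pt", float(yi), float(yi), float(vi),
                   np.array([float(yi)]), 1, 0)
        for i, (yi, vi) in enumerate(zip(y, v))
    ]


def _dataset(y, v, studies=None, **kwargs):
    y, v = np.asarray(y, float), np.asarray(v, float)
    studies = studies or [f"s{i}" for i in range(len(y))]
    return MetaDataset(
        effects=_effects(y, v), V=np.diag(v), study_ids=list(studies), **kwargs
    )


class TestFitRandomEffects:
    def test_no_heterogeneity_recovers_common_value(self):
        data = _dataset([42.0] * 5, [2.0] * 5)
        fit = fit_random_effects(data, random="study")
        assert fit.mu == pytest.approx(42.0, abs=1e-6)
        assert fit.tau2_study == pytest.approx(0.0, abs=1e-6)
        assert fit.ci[0] <= fit.mu <= fit.ci[1]

    def test_fixed_zero_tau_equals_inverse_variance_mean(self):
        data = _dataset([10.0, 20.0], [1.0, 4.0])
        fit = fit_random_effects(data, fix_tau2=(0.0, 0.0))
        assert fit.mu == pytest.approx(12.0, abs=1e-8)

    def test_gls_equals_closed_form_weighted_mean(self, rng):
        y = rng.normal(50, 5, 8)
        v = rng.uniform(1, 3, 8)
        data = _dataset(y, v)
        fit = fit_random_effects(data, fix_tau2=(0.0, 0.0))
        w = 1 / v
        assert fit.mu == pytest.approx(float((w * y).sum() / w.sum()), abs=1e-8)

    def test_location_invariance_of_reml(self, rng):
        y = rng.normal(30, 6, 12)
        v = rng.uniform(1, 4, 12)
        studies = [f"s{i // 3}" for i in range(12)]
        f1 = fit_random_effects(_dataset(y, v, studies))
        f2 = fit_random_effects(_dataset(y + 100.0, v, studies))
        assert f2.mu - f1.mu == pytest.approx(100.0, abs=1e-4)
        assert f2.tau2_study == pytest.approx(f1.tau2_study, abs=1e-4)
        assert f2.tau2_obs == pytest.approx(f1.tau2_obs, abs=1e-4)

    def test_matches_metafor_rma_mv(self, rng, tmp_path):
        """Independent oracle: metafor's rma.mv on the same data."""
        k = 15
        studies = [f"s{i // 3}" for i in range(k)]
        v = rng.uniform(2, 6, k)
        y = 30 + rng.normal(0, 4, k) + rng.normal(0, np.sqrt(v))
        data = _dataset(y, v, studies)
        fit = fit_random_effects(data, random="study")

        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "v": v, "study": studies, "obs": range(k)}).to_csv(
            csv, index=False
        )
        script = textwrap.dedent(f"""
            suppressMessages(library(metafor)); suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            m <- rma.mv(yi = y, V = diag(d$v), random = list(~1|study, ~1|obs),
                        data = d, method = "REML")
            cat(toJSON(list(mu = as.numeric(coef(m)), tau2 = as.numeric(m$sigma2),
                            ll = as.numeric(logLik(m)), se = m$se), digits = 12))
        """)
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout.strip().splitlines()[-1])
        assert fit.mu == pytest.approx(ref["mu"][0], abs=1e-4)
        assert fit.se == pytest.approx(ref["se"][0], abs=1e-4)
        assert fit.tau2_study == pytest.approx(ref["tau2"][0], abs=1e-3)
        assert fit.tau2_obs == pytest.approx(ref["tau2"][1], abs=1e-3)
        assert fit.loglik_reml == pytest.approx(ref["ll"][0], abs=1e-4)

    def test_moderator_model_predictions_at_one_sd(self, rng):
        k = 24
        nt = rng.integers(2, 9, k).astype(float)
        z = (nt - nt.mean()) / nt.std(ddof=1)
        v = np.full(k, 2.0)
        y = 40 + 6 * z + rng.normal(0, 1, k)
        data = _dataset(
            y, v, moderators=pd.DataFrame({"n_traits": nt})
        )
        fit = fit_random_effects(data, moderators=["n_traits"])
        slope = float(fit.betas.loc[fit.betas.term == "n_traits", "estimate"].iloc[0])
        assert slope == pytest.approx(6.0, abs=1.5)
        lo, hi = fit.predictions["n_traits"]
        assert lo == pytest.approx(fit.mu - slope)
        assert hi == pytest.approx(fit.mu + slope)

    def test_collinear_moderators_rejected(self, rng):
        k = 10
        nt = rng.integers(2, 9, k).astype(float)
        data = _dataset(
            rng.normal(30, 3, k), np.full(k, 1.0),
            moderators=pd.DataFrame({"n_traits": nt, "local_adaptation_g": 2 * nt}),
        )
        with pytest.raises(ValidationError, match="rank"):
            fit_random_effects(data, moderators=["n_traits", "local_adaptation_g"])

    def test_ci_coverage_under_the_model(self, rng):
        """Wald CIs from REML should cover the true mean ~95% of the time."""
        covered = 0
        n_sims = 100
        k, true_mu = 40, 30.0
        for _ in range(n_sims):
            studies = [f"s{i}" for i in range(k)]
            v = rng.uniform(4, 9, k)
            y = true_mu + rng.normal(0, 5, k) + rng.normal(0, np.sqrt(v))
            fit = fit_random_effects(_dataset(y, v, studies))
            if fit.ci[0] <= true_mu <= fit.ci[1]:
                covered += 1
        assert 88 <= covered <= 99


class TestAicc:
    def test_formula(self):
        fit = MetaFit(
            mu=0, ci=(0, 0), se=0, tau2_study=0, tau2_obs=0, betas=pd.DataFrame(),
            loglik_reml=-10.0, aicc=0, k=20, p=2, random="study", converged=True,
        )
        assert aicc(fit) == pytest.approx(24 + 12 / 17)

    def test_boundary_is_infinite_with_warning(self):
        fit = MetaFit(
            mu=0, ci=(0, 0), se=0, tau2_study=0, tau2_obs=0, betas=pd.DataFrame(),
            loglik_reml=-10.0, aicc=0, k=5, p=4, random="study", converged=True,
        )
        with pytest.warns(RuntimeWarning):
            assert aicc(fit) == np.inf

    def test_difference_between_nested_fits_matches_hand_formula(self, rng):
        y = rng.normal(25, 5, 20)
        v = np.full(20, 2.0)
        studies = [f"s{i // 2}" for i in range(20)]
        nt = rng.integers(2, 9, 20).astype(float)
        data = _dataset(y, v, studies, moderators=pd.DataFrame({"n_traits": nt}))
        f0 = fit_random_effects(data)
        f1 = fit_random_effects(data, moderators=["n_traits"])

        def hand(ll, p, k):
            return -2 * ll + 2 * p + 2 * p * (p + 1) / (k - p - 1)

        expected = hand(f1.loglik_reml, f1.p, f1.k) - hand(f0.loglik_reml, f0.p, f0.k)
        assert f1.aicc - f0.aicc == pytest.approx(expected, abs=1e-10)


class TestPhyloCorrelation:
    def test_sister_species_half_depth(self):
        tree = dendropy.Tree.get(
            data="((A:0.5,B:0.5):0.5,C:1.0);", schema="newick"
        )
        phi = phylo_correlation_matrix(tree, ["A", "B", "C"])
        assert phi.loc["A", "B"] == pytest.approx(0.5)
        assert phi.loc["A", "C"] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(phi), 1.0)

    def test_star_tree_is_identity(self):
        # pure bifurcating "comb" with all splits at the root (epsilon internal edges)
        tree = dendropy.Tree.get(
            data="((A:1.0,B:1.0):0.0,(C:1.0,D:1.0):0.0);", schema="newick"
        )
        phi = phylo_correlation_matrix(tree, ["A", "B", "C", "D"])
        np.testing.assert_allclose(phi.to_numpy(), np.eye(4), atol=1e-12)

    def test_balanced_four_taxon_hand_oracle(self):
        tree = dendropy.Tree.get(
            data="((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);", schema="newick"
        )
        phi = phylo_correlation_matrix(tree, ["A", "B", "C", "D"])
        expected = np.array([
            [1.0, 0.5, 0.0, 0.0],
            [0.5, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.5],
            [0.0, 0.0, 0.5, 1.0],
        ])
        np.testing.assert_allclose(phi.to_numpy(), expected, atol=1e-12)

    def test_missing_species_raises(self):
        tree = dendropy.Tree.get(data="(A:1.0,B:1.0);", schema="newick")
        with pytest.raises(ValidationError, match="missing"):
            phylo_correlation_matrix(tree, ["A", "Z"])

    def test_non_ultrametric_rejected(self):
        tree = dendropy.Tree.get(data="(A:1.0,B:0.3);", schema="newick")
        with pytest.raises(ValidationError, match="ultrametric"):
            phylo_correlation_matrix(tree, ["A", "B"])

    def test_polytomy_rejected(self):
        tree = dendropy.Tree.get(data="(A:1.0,B:1.0,C:1.0);", schema="newick")
        with pytest.raises(ValidationError, match="polytomy"):
            phylo_correlation_matrix(tree, ["A", "B", "C"])

    def test_output_is_psd_unit_diagonal(self, rng):
        from plastmeta.synthetic_data import random_ultrametric_tree

        labels = [f"sp{i}" for i in range(12)]
        tree = random_ultrametric_tree(labels, rng)
        phi = phylo_correlation_matrix(tree, labels)
        np.testing.assert_allclose(np.diag(phi), 1.0, atol=1e-9)
        assert np.linalg.eigvalsh(phi.to_numpy()).min() >= -1e-10


class TestRandomStructureComparison:
    def test_identity_phylo_one_species_per_study_is_same_model(self, rng):
        k = 10
        species = [f"sp{i}" for i in range(k)]
        phi = pd.DataFrame(np.eye(k), index=species, columns=species)
        y = rng.normal(30, 5, k)
        v = rng.uniform(1, 3, k)
        data = _dataset(y, v, [f"s{i}" for i in range(k)], species=species, phylo=phi)
        res = compare_random_structures(data)
        assert abs(res.fits["study"].aicc - res.fits["phylo"].aicc) < 1e-5
        assert res.selected == "study"  # documented tie rule

    def test_study_structure_preferred_for_study_generated_data(self, rng):
        """Data with study heterogeneity and a star phylogeny: the study
        model should win (or tie) in most replicates."""
        wins = 0
        n_sims = 20
        for _ in range(n_sims):
            n_study, per = 8, 2
            k = n_study * per
            studies = [f"s{i // per}" for i in range(k)]
            species = [f"sp{i // per}" for i in range(k)]
            labels = [f"sp{i}" for i in range(n_study)]
            phi = pd.DataFrame(np.eye(n_study), index=labels, columns=labels)
            v = rng.uniform(1, 2, k)
            u = np.repeat(rng.normal(0, 4, n_study), per)
            y = 30 + u + rng.normal(0, np.sqrt(v))
            data = _dataset(y, v, studies, species=species, phylo=phi)
            if compare_random_structures(data).selected == "study":
                wins += 1
        assert wins > n_sims / 2
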