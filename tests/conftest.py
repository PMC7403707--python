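import numpy as np
import pandas as pd
import pytest

from plastmeta.study_data import Comparison, ExperimentalUnit, TraitSpec, UNIT_KEYS


def make_unit(key, values, traits=("t1", "t2"), study="s1", comp="c1"):
    return ExperimentalUnit(
        study_id=study,
        comparison_id=comp,
        population=key[0],
        environment=key[-1],
        traits=tuple(traits),
        values=np.asarray(values, dtype=float),
    )


def make_comparison(centroids, rng=None, n=8, spread=0.5, traits=("t1", "t2"),
                    trait_types=("morphology", "morphology"), **kwargs):
    """Comparison with units scattered around the given centroids.

    ``centroids`` maps unit key -> centroid; with rng=None individuals are a
    deterministic symmetric cloud so unit means equal the centroids exactly.
    """
    d = len(traits)
    units = {}
    for key in UNIT_KEYS:
        c = np.asarray(centroids[key], dtype=float)
        if rng is None:
            # whole +/- pairs only, so the unit mean equals the centroid exactly
            base = np.vstack([np.eye(d), -np.eye(d)]) * spread
            reps = max(int(np.ceil(n / (2 * d))), 1)
            values = c + np.tile(base, (reps, 1))
        else:
            values = c + spread * rng.standard_normal((n, d))
        units[key] = make_unit(key, values, traits=traits)
    specs = [TraitSpec(nm, tt) for nm, tt in zip(traits, trait_types)]
    return Comparison(
        study_id="s1", comparison_id="c1", species="sp1",
        units=units, traits=specs, **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_csv(tmp_path):
    """Well-formed single-comparison study table: 4 units x 8 individuals x 2 traits."""
    rng = np.random.default_rng(0)
    rows = []
    for key in UNIT_KEYS:
        for i in range(8):
            rows.append({
                "study_id": "s1", "comparison_id": "c1", "species": "Arabidopsis thaliana",
                "population": key[0], "environment": key[-1],
                "individual_id": f"{key}_{i}",
                "height": rng.normal(10, 1), "leaf_area": rng.normal(5, 1),
            })
    study = tmp_path / "study.csv"
    pd.DataFrame(rows).to_csv(study, index=False)
    traits = tmp_path / "traits.csv"
    pd.DataFrame({
        "trait": ["height", "leaf_area"],
        "trait_type": ["morphology", "morphology"],
        "units": ["cm", "cm2"],
    }).to_csv(traits, index=False)
    return study, traits
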