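"""Shared fixtures: a small synthetic screening world built once per session."""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from riboscreen import (
    EnsembleConfig, build_holdout_splits, featurize_corpus, fit_normalizer,
    train_ensemble,
)
from riboscreen.simulate import (
    FixtureSpec, generate_random, generate_structured, generate_unlabeled,
)

warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def world():
    """Small synthetic corpora + a trained 5-member mini ensemble.

    240 structured positives with the skewed ligand distribution, 240
    mixed unlabeled, 200 random negative controls; structures are the
    generator's planted dot strings; the ensemble uses the first five
    ligand-holdout splits.
    """
    spec = FixtureSpec(seed=1)
    pos, pos_ss, ligand_table = generate_structured(spec, n=240, seed=1)
    unl, unl_ss = generate_unlabeled(spec, n=240, seed=1)
    rnd, rnd_ss = generate_random(200, spec, seed=1)
    norm = fit_normalizer(list(pos_ss.values()) + list(unl_ss.values()))
    X_pos = featurize_corpus(pos, pos_ss, norm)
    X_unl = featurize_corpus(unl, unl_ss, norm)
    X_rnd = featurize_corpus(rnd, rnd_ss, norm)
    ligands = [r.ligand for r in pos]
    splits = build_holdout_splits(ligands)
    ens = train_ensemble(X_pos, ligands, X_unl, splits=splits[:5],
                         config=EnsembleConfig(seed=7), normalizer=norm)
    return {
        "spec": spec, "pos": pos, "pos_ss": pos_ss, "ligand_table": ligand_table,
        "unl": unl, "unl_ss": unl_ss, "rnd": rnd, "rnd_ss": rnd_ss,
        "norm": norm, "X_pos": X_pos, "X_unl": X_unl, "X_rnd": X_rnd,
        "ligands": ligands, "splits": splits, "ensemble": ens,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
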